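"""Leukoaraiosis volumetry from FLAIR-like volumes.

The measurement chain: estimate and remove a smooth multiplicative
intensity inhomogeneity (polynomial fit in the log-intensity domain);
estimate the normal-white-matter intensity distribution from the
middle-cerebellar-peduncle (MCP) reference region; rescale intensities
so that region has mean 1000 and SD 100; threshold at a fixed cutoff
(default 3.5 reference SDs, i.e. standardized intensity > 1350) inside
the white-matter search region; and convert per-region voxel counts to
millilitres, reporting the four lobes and a pooled periventricular
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .grids import (
    LOBAR_WM_LABELS,
    PV_LABELS,
    WM_FRONTAL,
    WM_OCCIPITAL,
    WM_PARIETAL,
    WM_TEMPORAL,
    BrainVolume,
    RegionAtlas,
)

REPORTED_REGIONS = ("total", "frontal", "temporal", "parietal", "occipital",
                    "periventricular")
_LOBE_LABELS = {
    "frontal": WM_FRONTAL,
    "temporal": WM_TEMPORAL,
    "parietal": WM_PARIETAL,
    "occipital": WM_OCCIPITAL,
}


@dataclass
class NormalizationParams:
    """Reference-region intensity standardization parameters.

    The standardized threshold separating lesion from normal WM is
    ``target_mean + cutoff_sd * target_sd`` (1350 at the defaults).
    """

    mu_ref: float
    sigma_ref: float
    target_mean: float = 1000.0
    target_sd: float = 100.0
    cutoff_sd: float = 3.5

    def __post_init__(self) -> None:
        if self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")
        if self.cutoff_sd <= 0 or self.target_sd <= 0:
            raise ValueError("cutoff_sd and target_sd must be positive")

    @property
    def threshold(self) -> float:
        return self.target_mean + self.cutoff_sd * self.target_sd


# ---------------------------------------------------------------------------
# bias field


def _poly_terms(order: int):
    return [
        (a, b, c)
        for a, b, c in product(range(order + 1), repeat=3)
        if a + b + c <= order
    ]


def _design(shape, exponents, where=None) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    if where is not None:
        X, Y, Z = X[where], Y[where], Z[where]
    cols = [(X**a) * (Y**b) * (Z**c) for a, b, c in exponents]
    return np.stack(cols, axis=-1)


@dataclass
class BiasField:
    """Low-order polynomial model of log-domain intensity inhomogeneity."""

    coefficients: np.ndarray
    exponents: list[tuple[int, int, int]]
    order: int
    shape: tuple[int, int, int]
    fitted_on: np.ndarray = field(repr=False, default=None)

    def log_field(self) -> np.ndarray:
        d = _design(self.shape, self.exponents)
        return d @ self.coefficients

    def evaluate(self) -> np.ndarray:
        """The multiplicative field exp(log-polynomial); positive everywhere."""
        return np.exp(self.log_field())


def estimate_bias_field(
    volume: BrainVolume,
    tissue_mask: np.ndarray,
    order: int = 2,
    preserve_mean: bool = True,
) -> BiasField:
    """Least-squares polynomial fit to log-intensity over ``tissue_mask``.

    With ``preserve_mean`` (default) the fitted log-field is demeaned
    over the mask, so correction preserves the overall intensity scale;
    order 0 then yields the identity field.  Without it the constant
    term is kept and the order-0 field is the geometric-mean normalizer.
    """
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    vals = volume.data[mask]
    if (vals <= 0).any():
        raise ValueError("bias estimation needs positive intensities in the mask")
    exps = _poly_terms(order)
    A = _design(volume.shape, exps, where=mask)
    coef, _, rank, _ = np.linalg.lstsq(A, np.log(vals), rcond=None)
    if rank < len(exps):
        raise ValueError(
            f"degenerate mask geometry: design rank {rank} < {len(exps)} terms"
        )
    if preserve_mean:
        coef = coef.copy()
        coef[exps.index((0, 0, 0))] -= (A @ coef).mean()
    return BiasField(coef, exps, order, volume.shape, fitted_on=mask)


def correct_inhomogeneity(volume: BrainVolume, bias: BiasField) -> BrainVolume:
    """Divide out the multiplicative field."""
    if bias.shape != volume.shape:
        raise ValueError("bias field shape does not match volume")
    return volume.with_data(volume.data / bias.evaluate())


# ---------------------------------------------------------------------------
# reference stats and standardization


def estimate_reference_stats(
    volume: BrainVolume,
    atlas: RegionAtlas,
    min_voxels: int = 30,
    trim: float = 0.0,
) -> tuple[float, float]:
    """Mean and sample SD of the MCP reference region.

    ``trim`` optionally discards that fraction from each intensity tail
    before estimating (robust variant); the SD uses the n-1 convention
    since the region is a sample of normal WM.
    """
    vals = volume.data[atlas.mcp_mask]
    if vals.size < min_voxels:
        raise ValueError(
            f"MCP reference region has {vals.size} voxels; "
            f"need at least {min_voxels}"
        )
    if trim > 0:
        lo, hi = np.quantile(vals, [trim, 1 - trim])
        vals = vals[(vals >= lo) & (vals <= hi)]
    return float(vals.mean()), float(vals.std(ddof=1))


def standardize_intensities(
    volume: BrainVolume, params: NormalizationParams
) -> BrainVolume:
    """Affine rescale so the reference region has the target mean and SD."""
    z = (volume.data - params.mu_ref) / params.sigma_ref
    return volume.with_data(params.target_mean + params.target_sd * z)


# ---------------------------------------------------------------------------
# segmentation and quantification


def segment_wmh(
    standardized: BrainVolume,
    atlas: RegionAtlas,
    cutoff_sd: float = 3.5,
    target_mean: float = 1000.0,
    target_sd: float = 100.0,
    min_component_size: int = 0,
) -> np.ndarray:
    """Threshold the standardized volume inside the WM search region.

    A voxel is lesion iff its standardized intensity strictly exceeds
    ``target_mean + cutoff_sd * target_sd`` and it lies in cerebral WM
    or a periventricular band (MCP and infratentorial voxels excluded).
    ``min_component_size`` optionally removes 26-connected components
    smaller than the given voxel count (off by default).
    """
    if cutoff_sd <= 0:
        raise ValueError("cutoff_sd must be positive")
    search = atlas.search_region
    if not search.any():
        raise ValueError("atlas contains no white-matter search region")
    mask = (standardized.data > target_mean + cutoff_sd * target_sd) & search
    if min_component_size > 0 and mask.any():
        lab, nlab = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
        keep = np.flatnonzero(sizes >= min_component_size) + 1
        mask = np.isin(lab, keep)
    return mask


@dataclass
class WmhSegmentation:
    """Binary lesion mask with per-compartment volumes in ml."""

    mask: np.ndarray
    volumes_ml: dict[str, float]
    threshold_used: float
    params: NormalizationParams | None = None

    @property
    def total_ml(self) -> float:
        return self.volumes_ml["total"]


def parcellate_and_quantify(
    mask: np.ndarray,
    atlas: RegionAtlas,
    params: NormalizationParams | None = None,
) -> WmhSegmentation:
    """Convert the lesion mask to per-compartment volumes.

    Volume is voxel count x dx x dy x slice thickness, in ml.  The four
    periventricular bands are pooled into one figure; a voxel in a PV
    band counts there and never toward a lobe (single-label atlas).
    """
    if mask.shape != atlas.shape:
        raise ValueError("mask shape does not match atlas")
    vv_ml = atlas.voxel_volume_mm3 / 1000.0
    vols = {
        name: float((mask & atlas.mask(lab)).sum()) * vv_ml
        for name, lab in _LOBE_LABELS.items()
    }
    vols["periventricular"] = float((mask & atlas.mask(*PV_LABELS)).sum()) * vv_ml
    vols["total"] = sum(vols.values())
    thr = params.threshold if params is not None else 1350.0
    return WmhSegmentation(mask=mask, volumes_ml=vols, threshold_used=thr,
                           params=params)


def quantify_wmh(
    volume: BrainVolume,
    atlas: RegionAtlas,
    bias_order: int = 2,
    cutoff_sd: float = 3.5,
    params: NormalizationParams | None = None,
    min_component_size: int = 0,
    trim: float = 0.0,
) -> tuple[WmhSegmentation, dict]:
    """Full chain: bias correction, standardization, segmentation, volumes.

    If ``params`` is given the reference statistics are taken as known
    (e.g. phantom ground truth) and only standardization onward runs;
    otherwise they are estimated from the MCP region after bias
    correction.  Returns the segmentation and a provenance record.
    """
    corrected = volume
    if bias_order is not None and params is None:
        # fit on nominally homogeneous tissue: cerebral WM + PV + MCP.
        # One robust refit excludes hyperintense outliers (lesions) that
        # would otherwise drag the polynomial upward around them.
        wm_mask = atlas.search_region | atlas.mcp_mask
        bias = estimate_bias_field(volume, wm_mask, bias_order)
        resid = np.log(np.clip(volume.data, 1e-12, None)) - bias.log_field()
        r = resid[wm_mask]
        med = np.median(r)
        mad = 1.4826 * np.median(np.abs(r - med)) or np.inf
        inlier = wm_mask & (np.abs(resid - med) <= 4.0 * mad)
        if inlier.sum() >= wm_mask.sum() // 2:
            bias = estimate_bias_field(volume, inlier, bias_order)
        corrected = correct_inhomogeneity(volume, bias)
    if params is None:
        mu, sigma = estimate_reference_stats(corrected, atlas, trim=trim)
        params = NormalizationParams(mu, sigma, cutoff_sd=cutoff_sd)
    std = standardize_intensities(corrected, params)
    mask = segment_wmh(
        std, atlas, cutoff_sd=params.cutoff_sd,
        target_mean=params.target_mean, target_sd=params.target_sd,
        min_component_size=min_component_size,
    )
    seg = parcellate_and_quantify(mask, atlas, params)
    provenance = {
        "mu_ref": params.mu_ref,
        "sigma_ref": params.sigma_ref,
        "cutoff_sd": params.cutoff_sd,
        "threshold": params.threshold,
        "bias_order": bias_order,
        "spacing": list(atlas.spacing),
        "slice_thickness": atlas.slice_thickness,
    }
    return seg, provenance
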