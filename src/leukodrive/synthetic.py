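"""Synthetic phantoms and cohorts with known ground truth.

Nothing in the analysis pipeline requires external data: this module
builds (a) FLAIR-like head phantoms in a fixed template space, with
hyperintense white-matter lesions of known rasterized volume, a smooth
multiplicative bias field and additive Gaussian noise, and (b) cohort
tables drawn from a multivariate normal with a prescribed correlation
matrix — by default the published 17-variable reference matrix of the
driving cohort (see :mod:`leukodrive.tables`).

The phantom geometry is layered rather than anatomical: a CSF rim, a GM
shell, lobar WM quadrants around a central ventricle with adjacent
periventricular bands, and an infratentorial middle-cerebellar-peduncle
(MCP) block that serves as the normal-WM intensity reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import tables
from .behavior import DSP_LOCATION_RANGES, DvcSession, Trial
from .grids import (
    BACKGROUND,
    CSF,
    GM,
    LABEL_NAMES,
    LOBAR_WM_LABELS,
    MCP,
    PV_LABELS,
    BrainVolume,
    RegionAtlas,
)

MIN_SHAPE = (16, 16, 8)

#: Default tissue mean intensities (arbitrary units).  CSF is dark as on
#: FLAIR; GM brighter than WM so a 3-class intensity segmentation can
#: separate them.  WM, PV bands and MCP share one normal-WM mean.
DEFAULT_TISSUE_MEANS = {
    BACKGROUND: 0.0,
    CSF: 150.0,
    GM: 650.0,
    "wm": 500.0,
}

#: Nominal normal-WM intensity SD: the unit in which lesion contrast is
#: expressed, and the scale against which noise levels are chosen.
REFERENCE_SD = 50.0


# ---------------------------------------------------------------------------
# atlas


def make_atlas(
    shape: tuple[int, int, int] = (64, 64, 27),
    spacing: tuple[float, float] = (0.9375, 0.9375),
    slice_thickness: float = 5.0,
) -> RegionAtlas:
    """Build the deterministic layered head atlas.

    The inferior ~fifth of the slices is infratentorial and hosts the
    MCP block; above it, concentric shells give CSF rim, GM and a WM
    core split into four lobar quadrants, with a central ventricle box
    and one-voxel periventricular bands on its four sides.
    """
    nx, ny, nz = shape
    if nx < MIN_SHAPE[0] or ny < MIN_SHAPE[1] or nz < MIN_SHAPE[2]:
        raise ValueError(f"atlas shape {shape} too small; minimum is {MIN_SHAPE}")

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = nx / 2.0 - 1.0, ny / 2.0 - 1.0
    rmin = min(rx, ry)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    d = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)

    z_inf = max(1, nz // 5)  # infratentorial slice count

    # cerebral slices: shells then quadrants
    plane = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    plane[d <= 1.0] = CSF
    plane[d <= 1.0 - 1.5 / rmin] = GM
    wm = d <= 1.0 - 3.0 / rmin
    quad = np.where(
        y < cy,
        np.where(x < cx, LOBAR_WM_LABELS[0], LOBAR_WM_LABELS[1]),
        np.where(x < cx, LOBAR_WM_LABELS[2], LOBAR_WM_LABELS[3]),
    )
    plane[wm] = quad[wm]
    labels[:, :, z_inf:] = plane[:, :, None]

    # central ventricle box (CSF) over the middle cerebral slices
    hw = max(1, nx // 16)
    hwy = max(1, ny // 16)
    x0, x1 = nx // 2 - hw, nx // 2 + hw
    y0, y1 = ny // 2 - hwy, ny // 2 + hwy
    zc = nz - z_inf
    zv0 = z_inf + zc // 4
    zv1 = max(zv0 + 1, z_inf + (3 * zc) // 4)
    labels[x0:x1, y0:y1, zv0:zv1] = CSF

    # periventricular bands: one-voxel-thick WM strips hugging the box
    def _band(sl_x, sl_y, lab):
        sub = labels[sl_x, sl_y, zv0:zv1]
        sub[np.isin(sub, LOBAR_WM_LABELS)] = lab
        labels[sl_x, sl_y, zv0:zv1] = sub

    _band(slice(x0 - 1, x0), slice(y0, y1), PV_LABELS[0])
    _band(slice(x1, x1 + 1), slice(y0, y1), PV_LABELS[1])
    _band(slice(x0, x1), slice(y0 - 1, y0), PV_LABELS[2])
    _band(slice(x0, x1), slice(y1, y1 + 1), PV_LABELS[3])

    # infratentorial: CSF inside the skull outline, MCP block centred
    inf_plane = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    inf_plane[d <= 1.0] = CSF
    labels[:, :, :z_inf] = inf_plane[:, :, None]
    hm = max(2, nx // 8)
    hmy = max(2, ny // 8)
    labels[nx // 2 - hm : nx // 2 + hm, ny // 2 - hmy : ny // 2 + hmy, :z_inf] = MCP

    atlas = RegionAtlas(labels, spacing, slice_thickness)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# lesions


@dataclass
class LesionSpec:
    """A spherical hyperintense lesion with rasterized ground truth.

    ``radius_mm`` is a physical radius; the rasterization includes every
    voxel whose center lies within it, so ``true_volume_ml`` is the voxel
    count times the voxel volume, not 4/3*pi*r^3.  ``contrast`` is the
    intensity elevation in units of the nominal normal-WM SD.
    """

    region: str
    center: tuple[int, int, int]
    radius_mm: float
    contrast: float

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("lesion contrast must be positive")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")

    def rasterize(self, atlas: RegionAtlas) -> np.ndarray:
        nx, ny, nz = atlas.shape
        dx, dy = atlas.spacing
        dz = atlas.slice_thickness
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ci, cj, ck = self.center
        dist2 = ((i - ci) * dx) ** 2 + ((j - cj) * dy) ** 2 + ((k - ck) * dz) ** 2
        return dist2 <= self.radius_mm**2

    def true_volume_ml(self, atlas: RegionAtlas) -> float:
        return float(self.rasterize(atlas).sum()) * atlas.voxel_volume_mm3 / 1000.0


def place_lesion(
    atlas: RegionAtlas,
    region: str,
    radius_mm: float,
    contrast: float,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> LesionSpec:
    """Rejection-sample a lesion of the given size fully inside ``region``.

    ``region`` is a lobe name ('frontal', ...), 'periventricular', or 'wm'
    for anywhere in the lobar-WM-plus-PV search region.
    """
    from .grids import REGION_BY_NAME

    if region == "wm":
        host = atlas.search_region
        name = "wm"
    else:
        labs = REGION_BY_NAME[region]
        host = atlas.mask(*labs) if isinstance(labs, tuple) else atlas.mask(labs)
        name = region
    candidates = np.argwhere(host)
    if candidates.size == 0:
        raise ValueError(f"region {region!r} is empty in this atlas")
    for _ in range(max_tries):
        c = candidates[rng.integers(len(candidates))]
        lesion = LesionSpec(name, tuple(int(v) for v in c), radius_mm, contrast)
        ras = lesion.rasterize(atlas)
        if not (ras & ~host).any():
            return lesion
    raise ValueError(
        f"could not place a radius-{radius_mm} mm lesion inside {region!r}"
    )


# ---------------------------------------------------------------------------
# FLAIR simulation


def _bias_field(shape, amplitude, order, rng) -> np.ndarray:
    """Smooth multiplicative field exp(log(1 + amplitude) * f), max|f| = 1.

    The field is a polynomial in the log-intensity domain (the standard
    bias-field model); its maximum fractional deviation above 1 is
    exactly ``amplitude``.
    """
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    f = np.zeros(shape)
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                if a == b == c == 0:
                    continue
                f += rng.normal() * (X**a) * (Y**b) * (Z**c)
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return np.exp(np.log1p(amplitude) * f)


def simulate_flair(
    atlas: RegionAtlas,
    lesions: Sequence[LesionSpec] = (),
    bias_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    tissue_means: dict | None = None,
    reference_sd: float = REFERENCE_SD,
    bias_order: int = 2,
) -> tuple[BrainVolume, np.ndarray]:
    """Render a FLAIR-like volume and return it with the truth lesion mask.

    Intensities start from per-tissue means (WM, PV and MCP share one
    normal-WM mean); lesion voxels are elevated by ``contrast *
    reference_sd``; then the multiplicative bias field and additive
    Gaussian noise are applied, in that order.  ``bias_amplitude`` is the
    maximum fractional deviation of the field from 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= bias_amplitude < 1:
        raise ValueError("bias_amplitude must lie in [0, 1)")
    means = dict(DEFAULT_TISSUE_MEANS, **(tissue_means or {}))
    wm_mean = means["wm"]
    lut = np.zeros(max(LABEL_NAMES) + 1)
    lut[BACKGROUND] = means[BACKGROUND]
    lut[CSF] = means[CSF]
    lut[GM] = means[GM]
    for lab in (*LOBAR_WM_LABELS, *PV_LABELS, MCP):
        lut[lab] = wm_mean
    base = lut[atlas.labels]

    truth = np.zeros(atlas.shape, dtype=bool)
    elevation = np.zeros(atlas.shape)
    for lesion in lesions:
        host_name = LABEL_NAMES.get(int(atlas.labels[lesion.center]), "?")
        if lesion.region == "periventricular":
            ok = host_name.startswith("PV_")
        elif lesion.region == "wm":  # anywhere in the WM+PV search region
            ok = host_name.startswith(("WM_", "PV_"))
        else:
            ok = host_name == f"WM_{lesion.region}"
        if not ok:
            raise ValueError(
                f"lesion center {lesion.center} lies in {host_name}, "
                f"not in its declared region {lesion.region!r}"
            )
        ras = lesion.rasterize(atlas)
        if (ras & atlas.mcp_mask).any():
            raise ValueError(
                "lesion overlaps the MCP reference region; this would "
                "corrupt the normal-WM intensity estimate"
            )
        truth |= ras
        elevation = np.maximum(elevation, ras * lesion.contrast * reference_sd)

    rng = np.random.default_rng(seed)
    data = base + elevation
    if bias_amplitude > 0:
        data = data * _bias_field(atlas.shape, bias_amplitude, bias_order, rng)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, atlas.shape)
    vol = BrainVolume(data, atlas.spacing, atlas.slice_thickness)
    return vol, truth


# ---------------------------------------------------------------------------
# cohort tables


def nearest_psd_correlation(
    corr: pd.DataFrame, floor: float = 1e-6, max_iter: int = 20
) -> tuple[pd.DataFrame, bool]:
    """Project a (near-)correlation matrix onto the PSD cone.

    Eigenvalues are clipped at ``floor`` and the diagonal rescaled to 1,
    iterating until the smallest eigenvalue clears the floor.  Returns
    the repaired matrix and whether any repair was needed — printed
    2-decimal correlation tables are often slightly indefinite.
    """
    a = corr.to_numpy(dtype=float).copy()
    repaired = False
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= floor:
            break
        repaired = True
        a = (v * np.clip(w, floor, None)) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        np.fill_diagonal(a, 1.0)
    else:
        raise ValueError("correlation matrix could not be repaired to PSD")
    a = (a + a.T) / 2
    return pd.DataFrame(a, index=corr.index, columns=corr.columns), repaired


@dataclass
class CohortSpec:
    """Specification of a simulated cohort table.

    Defaults reproduce the reference driving cohort: the published
    17-variable correlation matrix with its published means and SDs.
    """

    n: int = tables.COHORT_N
    corr: pd.DataFrame = field(default_factory=tables.cohort_correlations)
    means: pd.Series = field(default_factory=tables.cohort_means)
    sds: pd.Series = field(default_factory=tables.cohort_sds)
    seed: int | None = None
    integerize_dsp: bool = False
    psd_floor: float = 1e-6

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        r = self.corr
        if list(r.index) != list(r.columns):
            raise ValueError("correlation matrix index/columns mismatch")
        a = r.to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        sds = self.sds.reindex(r.index)
        if sds.isna().any() or (sds <= 0).any():
            bad = list(sds.index[sds.isna() | (sds <= 0)])
            raise ValueError(f"SDs must be positive for all variables: {bad}")


def simulate_cohort(spec: CohortSpec | None = None, **kw) -> pd.DataFrame:
    """Draw a cohort table from the multivariate normal the spec describes.

    The returned frame carries ``attrs['psd_repaired']`` recording whether
    the target correlation matrix needed a nearest-PSD repair, and
    ``attrs['seed']``.  With ``integerize_dsp``, DSP columns are rounded
    half-away-from-zero and clipped to their legal integer ranges.
    """
    spec = spec or CohortSpec(**kw)
    spec.validate()
    names = list(spec.corr.index)
    corr, repaired = nearest_psd_correlation(spec.corr, spec.psd_floor)
    sds = spec.sds.reindex(names).to_numpy(dtype=float)
    means = spec.means.reindex(names).to_numpy(dtype=float)
    cov = corr.to_numpy() * np.outer(sds, sds)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(means, cov, size=spec.n, method="cholesky")
    df = pd.DataFrame(draws, columns=names)
    if spec.integerize_dsp:
        ranges = dict(DSP_LOCATION_RANGES)
        ranges["dsp_total"] = (
            sum(lo for lo, _ in DSP_LOCATION_RANGES.values()),
            sum(hi for _, hi in DSP_LOCATION_RANGES.values()),
        )
        for col, (lo, hi) in ranges.items():
            if col in df:
                rounded = np.sign(df[col]) * np.floor(np.abs(df[col]) + 0.5)
                df[col] = np.clip(rounded, lo, hi).astype(int)
    df.attrs["psd_repaired"] = repaired
    df.attrs["seed"] = spec.seed
    return df


# ---------------------------------------------------------------------------
# DVC sessions


def simulate_dvc_session(
    n_signal: int,
    n_noise: int,
    hit_rate: float,
    false_alarm_rate: float,
    seed: int | None = None,
    task: str = "sudden",
) -> DvcSession:
    """Bernoulli button presses for one task of the visual-cognition test.

    Signal trials (closed octagon) are pressed with ``hit_rate``; noise
    trials (open octagon) with ``false_alarm_rate``.  Trial order is
    shuffled by the seed.
    """
    if n_signal < 0 or n_noise < 0:
        raise ValueError("trial counts must be non-negative")
    if not (0 <= hit_rate <= 1 and 0 <= false_alarm_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trials = [
        Trial(task, "signal", bool(rng.random() < hit_rate)) for _ in range(n_signal)
    ] + [
        Trial(task, "noise", bool(rng.random() < false_alarm_rate))
        for _ in range(n_noise)
    ]
    order = rng.permutation(len(trials))
    return DvcSession([trials[i] for i in order])
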