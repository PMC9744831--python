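"""Tissue volumes and the brain-atrophy ratio.

Brain atrophy (BA) is the fraction of the intracranial space occupied
by CSF: with intracranial volume ICV = TBV + CFV,

    BA = CFV / ICV = (ICV - TBV) / ICV = 1 - TBV / ICV.

Tissue segmentation here is a deliberately simple 3-class intensity
classifier (fixed thresholds or 1-D k-means) suitable for phantoms with
separated class means; probabilistic tissue segmentation of real MRI is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .grids import BrainVolume, RegionAtlas

#: Class codes in the returned map.
UNLABELLED, CLS_CSF, CLS_GM, CLS_WM = 0, 1, 2, 3


@dataclass
class TissueVolumes:
    """Brain, CSF and intracranial volumes (ml) with the atrophy ratio."""

    tbv: float
    cfv: float
    icv: float
    ba: float


def compute_ba(tbv: float, cfv: float) -> TissueVolumes:
    """Atrophy ratio from total brain and CSF volume; TBV must be positive."""
    if tbv <= 0:
        raise ValueError(
            f"total brain volume must be positive (got {tbv}); "
            "an all-CSF segmentation is not a valid brain"
        )
    if cfv < 0:
        raise ValueError("CSF volume cannot be negative")
    icv = tbv + cfv
    return TissueVolumes(tbv=tbv, cfv=cfv, icv=icv, ba=1.0 - tbv / icv)


def segment_tissues_simple(
    volume: BrainVolume,
    atlas: RegionAtlas,
    thresholds: tuple[float, float] | None = None,
    min_mode_separation: float = 3.0,
    random_state: int = 0,
) -> np.ndarray:
    """Assign every intracranial voxel to CSF, WM or GM by intensity.

    With explicit ``thresholds`` (t1, t2): CSF below t1, WM in [t1, t2),
    GM above (darkest-to-brightest order of the FLAIR-like phantoms).
    Otherwise a 1-D 3-means clustering of intracranial intensities is
    used and clusters are ranked by center.  Clustering fails if the
    smallest gap between sorted centers does not exceed
    ``min_mode_separation`` times the largest within-cluster SD — the
    signature of fewer than three distinguishable modes (a unimodal
    distribution split by k-means gives gaps comparable to the
    within-cluster spread).
    """
    icv_mask = atlas.intracranial_mask
    if volume.shape != atlas.shape:
        raise ValueError("volume and atlas shapes differ")
    vals = volume.data[icv_mask]
    classes = np.full(volume.shape, UNLABELLED, dtype=np.int8)
    if thresholds is not None:
        t1, t2 = thresholds
        cls = np.where(vals < t1, CLS_CSF, np.where(vals < t2, CLS_WM, CLS_GM))
    else:
        if vals.std() == 0:
            raise ValueError(
                "fewer than three distinguishable intensity modes "
                "(constant intracranial intensity)"
            )
        km = KMeans(n_clusters=3, n_init=5, random_state=random_state).fit(
            vals.reshape(-1, 1)
        )
        centers = km.cluster_centers_.ravel()
        order = np.argsort(centers)
        gaps = np.diff(centers[order])
        within = max(
            vals[km.labels_ == lab].std() for lab in range(3)
        )
        if gaps.min() < min_mode_separation * within:
            raise ValueError(
                "fewer than three distinguishable intensity modes "
                f"(cluster centers {np.sort(centers).round(2)})"
            )
        rank = np.empty(3, dtype=np.int8)
        rank[order] = [CLS_CSF, CLS_WM, CLS_GM]
        cls = rank[km.labels_]
    classes[icv_mask] = cls
    return classes


def tissue_volumes(class_map: np.ndarray, atlas: RegionAtlas) -> TissueVolumes:
    """Volumes from class-map voxel counts; brain = GM + WM."""
    vv_ml = atlas.voxel_volume_mm3 / 1000.0
    tbv = float(np.isin(class_map, (CLS_GM, CLS_WM)).sum()) * vv_ml
    cfv = float((class_map == CLS_CSF).sum()) * vv_ml
    return compute_ba(tbv, cfv)
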