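"""In-memory containers for scalar volumes and region-label atlases.

Geometry is deliberately minimal: an axis-aligned grid with in-plane
voxel spacing ``(dx, dy)`` in mm and a slice thickness in mm.  Volumes
are stored in ``(x, y, z)`` index order and written as NIfTI-1 with a
diagonal affine, which is all the downstream volumetry needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

# Region labels.  PV (periventricular) bands are one label per
# lateral-ventricle-adjacent band; MCP is the middle cerebellar peduncle,
# the lesion-free white-matter reference region.
BACKGROUND = 0
CSF = 1
GM = 2
WM_FRONTAL = 3
WM_TEMPORAL = 4
WM_PARIETAL = 5
WM_OCCIPITAL = 6
PV_1, PV_2, PV_3, PV_4 = 7, 8, 9, 10
MCP = 11

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    CSF: "CSF",
    GM: "GM",
    WM_FRONTAL: "WM_frontal",
    WM_TEMPORAL: "WM_temporal",
    WM_PARIETAL: "WM_parietal",
    WM_OCCIPITAL: "WM_occipital",
    PV_1: "PV_1",
    PV_2: "PV_2",
    PV_3: "PV_3",
    PV_4: "PV_4",
    MCP: "MCP",
}

LOBAR_WM_LABELS = (WM_FRONTAL, WM_TEMPORAL, WM_PARIETAL, WM_OCCIPITAL)
PV_LABELS = (PV_1, PV_2, PV_3, PV_4)

#: Map from lobe/compartment short name to atlas label.
REGION_BY_NAME = {
    "frontal": WM_FRONTAL,
    "temporal": WM_TEMPORAL,
    "parietal": WM_PARIETAL,
    "occipital": WM_OCCIPITAL,
    "periventricular": PV_LABELS,
}


def _affine(spacing: tuple[float, float], slice_thickness: float) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], slice_thickness, 1.0])


@dataclass
class BrainVolume:
    """A 3-D scalar intensity grid with physical voxel geometry."""

    data: np.ndarray
    spacing: tuple[float, float] = (0.9375, 0.9375)
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("BrainVolume requires a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.slice_thickness)

    def with_data(self, data: np.ndarray) -> "BrainVolume":
        return BrainVolume(data, self.spacing, self.slice_thickness)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(
            self.data.astype(np.float32), _affine(self.spacing, self.slice_thickness)
        )
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BrainVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj, dtype=float),
                   (float(zooms[0]), float(zooms[1])), float(zooms[2]))


@dataclass
class RegionAtlas:
    """Per-voxel integer region labels sharing the volume geometry."""

    labels: np.ndarray
    spacing: tuple[float, float] = (0.9375, 0.9375)
    slice_thickness: float = 5.0
    label_table: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError("RegionAtlas requires a 3-D label array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.slice_thickness)

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.labels, labels)

    @property
    def mcp_mask(self) -> np.ndarray:
        return self.labels == MCP

    @property
    def wm_mask(self) -> np.ndarray:
        """Cerebral white matter: the four lobar labels."""
        return self.mask(*LOBAR_WM_LABELS)

    @property
    def search_region(self) -> np.ndarray:
        """Where lesions are looked for: cerebral WM plus PV bands."""
        return self.mask(*LOBAR_WM_LABELS, *PV_LABELS)

    @property
    def intracranial_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = [LABEL_NAMES[l] for l in LABEL_NAMES if l != BACKGROUND and l not in present]
        if missing:
            raise ValueError(f"atlas is missing regions: {missing}")
        # MCP must be infratentorial, i.e. share no voxel with cerebral WM/PV
        # (guaranteed by single-label storage, asserted for clarity)
        if not self.mcp_mask.any():
            raise ValueError("atlas has an empty MCP reference region")

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(
            self.labels.astype(np.int16), _affine(self.spacing, self.slice_thickness)
        )
        nib.save(img, str(path))
        Path(str(path) + ".labels.json").write_text(
            json.dumps({str(k): v for k, v in self.label_table.items()}, indent=1)
        )

    @classmethod
    def from_nifti(cls, path: str | Path) -> "RegionAtlas":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        table_path = Path(str(path) + ".labels.json")
        table = (
            {int(k): v for k, v in json.loads(table_path.read_text()).items()}
            if table_path.exists()
            else dict(LABEL_NAMES)
        )
        return cls(np.asanyarray(img.dataobj).astype(np.int16),
                   (float(zooms[0]), float(zooms[1])), float(zooms[2]), table)
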