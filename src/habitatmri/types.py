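"""Core containers shared across the pipeline.

The pipeline works on per-patient bundles of four co-registered MR volumes
(FLAIR, T1, post-contrast T1, T2) plus an integer segmentation that labels
normal tissue (CSF, gray matter, white matter) and the four canonical tumor
compartments (necrosis, edema, non-enhancing, enhancing).  Habitat maps carry
one of 16 labels per tumor voxel, obtained by dichotomizing each sequence into
high/low and reading the four bits as an integer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: MR sequences in the fixed order used throughout the package.
SEQUENCES = ("FLAIR", "T1", "T1c", "T2")

#: Bit weight of each sequence in the habitat label (FLAIR is the high bit).
SEQUENCE_BITS = {"FLAIR": 8, "T1": 4, "T1c": 2, "T2": 1}

N_HABITATS = 16

#: Segmentation label dictionary (BraTumIA-style classes).
LABEL_NAMES = {
    0: "background",
    1: "csf",
    2: "gray_matter",
    3: "white_matter",
    4: "necrosis",
    5: "edema",
    6: "non_enhancing",
    7: "enhancing",
}
REFERENCE_LABELS = (2, 3)  # gray matter, white matter
TUMOR_LABELS = (4, 5, 6, 7)
#: Canonical tumor sub-volumes in the fixed reporting order.
SUBVOLUME_LABELS = {"necrosis": 4, "edema": 5, "non_enhancing": 6, "enhancing": 7}
SUBVOLUME_NAMES = tuple(SUBVOLUME_LABELS)

#: Clinical covariates used for survival adjustment.
CLINICAL_COVARIATES = ("age_years", "kps", "tumor_volume_ml", "idh1_mutant")


def _affine_spacing(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass(frozen=True)
class VolumeGrid:
    """One 3D scalar MR volume with voxel-to-world affine metadata."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        affine = np.asarray(self.affine, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {values.ndim}D array")
        if min(values.shape) < 1:
            raise ValueError(f"all axes must have length >= 1, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite voxel values")
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        spacing = _affine_spacing(affine)
        if np.any(spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm."""
        return _affine_spacing(self.affine)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class SegmentationMap:
    """Co-registered integer label volume (tissue + tumor compartments)."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        affine = np.asarray(self.affine, dtype=np.float64)
        if labels.ndim != 3:
            raise ValueError(f"expected 3D segmentation, got {labels.ndim}D array")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = np.round(labels).astype(np.int64)
            if not np.allclose(labels, as_int):
                raise ValueError("segmentation contains non-integer labels")
            labels = as_int
        bad = np.setdiff1d(np.unique(labels), np.arange(8))
        if bad.size:
            raise ValueError(
                f"segmentation contains out-of-dictionary label(s) {bad.tolist()}; "
                f"allowed labels are 0..7"
            )
        object.__setattr__(self, "labels", labels.astype(np.int16))
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.labels, TUMOR_LABELS)

    @property
    def reference_mask(self) -> np.ndarray:
        """Gray + white matter voxels used for intensity normalization."""
        return np.isin(self.labels, REFERENCE_LABELS)

    @property
    def spacing(self) -> np.ndarray:
        return _affine_spacing(self.affine)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class HabitatMap:
    """3D habitat label volume: tumor voxels carry 0..15, others -1."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected 3D habitat map, got {labels.ndim}D array")
        labels = labels.astype(np.int16)
        vals = np.unique(labels)
        if vals.min() < -1 or vals.max() > 15:
            raise ValueError("habitat labels must lie in {-1} ∪ {0..15}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=np.float64))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass(frozen=True)
class HabitatComposition:
    """Per-patient 16-component habitat proportion vector."""

    proportions: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.shape != (N_HABITATS,):
            raise ValueError(f"expected {N_HABITATS} components, got shape {p.shape}")
        if np.any(p < 0):
            raise ValueError("habitat proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"habitat proportions must sum to 1, got {p.sum()!r}")
        if self.n_voxels < 1:
            raise ValueError("composition requires at least one tumor voxel")
        object.__setattr__(self, "proportions", p)
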