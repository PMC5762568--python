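"""NIfTI and CSV input/output plus cohort assembly.

Volumes and segmentations are stored as NIfTI-1 files; the clinical table and
the pathway-activity score matrix are CSVs keyed by ``patient_id``.  A cohort
directory holds, per patient, one file per MR sequence
(``<id>_FLAIR.nii[.gz]`` etc.) and one segmentation (``<id>_seg.nii[.gz]``).
``load_cohort`` intersects the three sources and never drops a patient
silently: every exclusion is recorded with a reason.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    CLINICAL_COVARIATES,
    SEQUENCES,
    SegmentationMap,
    VolumeGrid,
)

CLINICAL_COLUMNS = ("patient_id", "os_months", "event") + CLINICAL_COVARIATES


class CohortError(ValueError):
    """Raised when a cohort cannot be assembled consistently."""


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D scalar NIfTI volume.

    Raises a descriptive error for missing files, non-3D images and
    non-finite voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image at {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxel values")
    return VolumeGrid(values=data, affine=np.asarray(img.affine))


def write_volume(volume: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    nib.save(img, path)
    return path


def read_segmentation(path: str | Path) -> SegmentationMap:
    """Read an integer-valued NIfTI segmentation with labels in {0..7}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segmentation file not found: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected 3D segmentation, got {data.ndim}D image at {path}")
    return SegmentationMap(labels=data, affine=np.asarray(img.affine))


def write_segmentation(seg: SegmentationMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(seg.labels.astype(np.int16), seg.affine)
    nib.save(img, path)
    return path


@dataclasses.dataclass(frozen=True)
class PatientImages:
    """The four MR volumes plus segmentation of one patient."""

    volumes: Mapping[str, VolumeGrid]
    segmentation: SegmentationMap


@dataclasses.dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


@dataclasses.dataclass
class CohortBundle:
    """Patients complete in imaging, clinical and pathway sources."""

    patients: dict[str, PatientImages]
    clinical: pd.DataFrame  # indexed by patient_id
    pathways: pd.DataFrame  # indexed by patient_id
    exclusions: list[Exclusion]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"clinical CSV is missing column(s): {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortError(f"duplicate patient id(s) in clinical CSV: {dups}")
    df = df.set_index("patient_id")
    if (df["os_months"] < 0).any():
        raise CohortError("os_months must be nonnegative")
    if ((df["kps"] < 0) | (df["kps"] > 100)).any():
        raise CohortError("kps must lie in [0, 100]")
    return df


def read_pathways(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise CohortError("pathway CSV must have a patient_id column")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortError(f"duplicate patient id(s) in pathway CSV: {dups}")
    df = df.set_index("patient_id")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise CohortError("pathway matrix contains non-finite entries")
    return df


def _find_image(image_dir: Path, patient_id: str, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        candidate = image_dir / f"{patient_id}_{suffix}{ext}"
        if candidate.exists():
            return candidate
    return None


def load_patient_images(image_dir: str | Path, patient_id: str) -> PatientImages:
    """Load and cross-validate one patient's volumes and segmentation.

    All five images must share shape and affine; the segmentation must have
    non-empty tumor and reference (GM∪WM) masks.
    """
    image_dir = Path(image_dir)
    volumes: dict[str, VolumeGrid] = {}
    for seq in SEQUENCES:
        path = _find_image(image_dir, patient_id, seq)
        if path is None:
            raise FileNotFoundError(f"missing {seq} volume for patient {patient_id}")
        volumes[seq] = read_volume(path)
    seg_path = _find_image(image_dir, patient_id, "seg")
    if seg_path is None:
        raise FileNotFoundError(f"missing segmentation for patient {patient_id}")
    seg = read_segmentation(seg_path)

    ref_shape, ref_affine = seg.shape, seg.affine
    for seq, vol in volumes.items():
        if vol.shape != ref_shape:
            raise CohortError(
                f"patient {patient_id}: {seq} shape {vol.shape} does not match "
                f"segmentation shape {ref_shape}"
            )
        if not np.allclose(vol.affine, ref_affine, atol=1e-4):
            raise CohortError(
                f"patient {patient_id}: {seq} orientation differs from segmentation"
            )
    if not seg.tumor_mask.any():
        raise CohortError(f"patient {patient_id}: empty tumor mask")
    if not seg.reference_mask.any():
        raise CohortError(f"patient {patient_id}: empty reference (GM/WM) mask")
    return PatientImages(volumes=volumes, segmentation=seg)


def load_cohort(
    clinical_csv: str | Path,
    pathway_csv: str | Path,
    image_dir: str | Path,
) -> CohortBundle:
    """Assemble the cohort of patients complete in all three sources.

    Returns only complete patients; every excluded patient is listed in
    ``exclusions`` with the reason. Raises if no patient is complete.
    """
    clinical = read_clinical(clinical_csv)
    pathways = read_pathways(pathway_csv)
    image_dir = Path(image_dir)

    patients: dict[str, PatientImages] = {}
    exclusions: list[Exclusion] = []
    for pid in clinical.index:
        if pid not in pathways.index:
            exclusions.append(Exclusion(pid, "missing pathway scores"))
            continue
        try:
            patients[pid] = load_patient_images(image_dir, pid)
        except (FileNotFoundError, CohortError, ValueError) as exc:
            exclusions.append(Exclusion(pid, str(exc)))
    for pid in pathways.index:
        if pid not in clinical.index:
            exclusions.append(Exclusion(pid, "missing clinical record"))

    if not patients:
        raise CohortError(
            "no patient has a complete set of imaging, clinical and pathway data; "
            + "; ".join(f"{e.patient_id}: {e.reason}" for e in exclusions)
        )
    ids = list(patients)
    return CohortBundle(
        patients=patients,
        clinical=clinical.loc[ids],
        pathways=pathways.loc[ids],
        exclusions=exclusions,
    )
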