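"""Habitat mapping: from four co-registered MR volumes to 16-label habitat maps.

Workflow per cohort:

1. Per patient and sequence, tumor-voxel intensities are standardized against
   the patient's pooled gray+white matter voxels (z-scoring), which makes the
   result invariant to affine intensity rescaling across scanners.
2. The standardized tumor intensities are linearized to [0, 1] using the
   min/max over that patient's tumor voxels.
3. For each sequence, a single high/low threshold is derived by exact 1-D
   2-means over the linearized values pooled across all patients.
4. Each tumor voxel receives a 4-bit label (one bit per sequence, 1 = above
   threshold), read as an integer 0..15 with FLAIR the high bit:
   ``label = 8*FLAIR + 4*T1 + 2*T1c + 1*T2``.

Habitat proportions (fraction of tumor voxels per label) form a 16-component
composition per patient.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PatientImages
from .types import (
    N_HABITATS,
    SEQUENCES,
    SUBVOLUME_LABELS,
    SUBVOLUME_NAMES,
    HabitatComposition,
    HabitatMap,
    SegmentationMap,
    VolumeGrid,
)

COMPOSITION_COLUMNS = [f"p_{h}" for h in range(N_HABITATS)]


def scale_to_reference(
    volume: VolumeGrid,
    seg: SegmentationMap,
    min_reference_voxels: int = 100,
) -> np.ndarray:
    """Z-score tumor-voxel intensities against pooled GM∪WM reference tissue.

    Returns ``(I - mu_ref) / sigma_ref`` over tumor voxels in C order of
    ``np.nonzero(seg.tumor_mask)``. ``sigma_ref`` is the population standard
    deviation of reference-voxel intensities.
    """
    if volume.shape != seg.shape:
        raise ValueError("volume and segmentation shapes differ")
    ref = volume.values[seg.reference_mask]
    if ref.size < min_reference_voxels:
        raise ValueError(
            f"reference tissue too small: {ref.size} voxels "
            f"(need >= {min_reference_voxels})"
        )
    sigma = float(ref.std())
    if sigma == 0.0:
        raise ValueError("degenerate reference tissue: zero intensity spread")
    mu = float(ref.mean())
    tumor = volume.values[seg.tumor_mask]
    if tumor.size == 0:
        raise ValueError("empty tumor mask")
    return (tumor - mu) / sigma


def linearize(values: np.ndarray) -> np.ndarray:
    """Min-max scale a vector to [0, 1]; a constant vector maps to all 0.5."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot linearize an empty vector")
    if values.size < 2:
        raise ValueError("linearize requires at least 2 values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn(
            "constant intensity vector: linearized values set to 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


@dataclass(frozen=True)
class SequenceThreshold:
    """Exact 1-D 2-means solution for one sequence's pooled intensities."""

    center_low: float
    center_high: float
    threshold: float


def pooled_threshold(values: np.ndarray) -> SequenceThreshold:
    """Globally optimal 1-D 2-means by sorted breakpoint enumeration.

    The optimal 2-cluster partition of scalars is a split of the sorted
    sample; all n-1 breakpoints are scored by within-cluster SSE using prefix
    sums, making the solution exact, deterministic and seed-free.  The
    threshold is the midpoint of the two cluster means.
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("2-means requires at least 2 distinct values")
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    k = np.arange(1, n)  # size of the left cluster
    sse_left = c2[k] - c1[k] ** 2 / k
    nr = n - k
    right_sum = c1[n] - c1[k]
    sse_right = (c2[n] - c2[k]) - right_sum**2 / nr
    split = int(np.argmin(sse_left + sse_right)) + 1  # first optimum on ties
    low = float(c1[split] / split)
    high = float((c1[n] - c1[split]) / (n - split))
    return SequenceThreshold(
        center_low=low, center_high=high, threshold=0.5 * (low + high)
    )


def dichotomize(values: np.ndarray, threshold: float) -> np.ndarray:
    """High/low bit per value: 1 iff strictly above the threshold (ties → low)."""
    return (np.asarray(values, dtype=np.float64) > threshold).astype(np.int8)


def encode_habitat(b_flair, b_t1, b_t1c, b_t2):
    """Habitat label = 8·FLAIR + 4·T1 + 2·T1c + 1·T2 (bits in {0, 1}).

    Scalar bits give a scalar int; array bits give an int array.
    """
    bits = [np.asarray(b, dtype=np.int64) for b in (b_flair, b_t1, b_t1c, b_t2)]
    for b in bits:
        if not np.isin(b, (0, 1)).all():
            raise ValueError("habitat bits must be 0 or 1")
    label = 8 * bits[0] + 4 * bits[1] + 2 * bits[2] + bits[3]
    return int(label) if label.ndim == 0 else label


def decode_habitat(label: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`encode_habitat`: label → (FLAIR, T1, T1c, T2) bits."""
    label = int(label)
    if not 0 <= label <= 15:
        raise ValueError("habitat label must lie in 0..15")
    return ((label >> 3) & 1, (label >> 2) & 1, (label >> 1) & 1, label & 1)


def build_habitat_map(
    bits: Mapping[str, np.ndarray],
    voxel_indices: tuple[np.ndarray, ...],
    shape: tuple[int, ...],
    affine: np.ndarray | None = None,
) -> HabitatMap:
    """Assemble the 3D habitat map: tumor voxels get 0..15, others -1.

    ``bits`` maps each sequence name to its per-voxel bit vector over the
    tumor voxels addressed by ``voxel_indices`` (as from ``np.nonzero``).
    """
    missing = set(SEQUENCES) - set(bits)
    if missing:
        raise ValueError(f"missing bit vectors for sequence(s): {sorted(missing)}")
    n = len(voxel_indices[0])
    if n == 0:
        raise ValueError("empty tumor mask: cannot build habitat map")
    labels = encode_habitat(bits["FLAIR"], bits["T1"], bits["T1c"], bits["T2"])
    grid = np.full(shape, -1, dtype=np.int16)
    grid[voxel_indices] = labels
    return HabitatMap(labels=grid, affine=np.eye(4) if affine is None else affine)


def composition(habitat_map: HabitatMap) -> HabitatComposition:
    """Fraction of tumor voxels in each of the 16 habitats."""
    labels = habitat_map.labels[habitat_map.tumor_mask]
    if labels.size == 0:
        raise ValueError("habitat map has no tumor voxels")
    counts = np.bincount(labels, minlength=N_HABITATS)
    return HabitatComposition(
        proportions=counts / labels.size, n_voxels=int(labels.size)
    )


def subvolume_fractions(seg: SegmentationMap) -> np.ndarray:
    """Fractions of the tumor in (necrosis, edema, non-enhancing, enhancing)."""
    tumor = seg.labels[seg.tumor_mask]
    if tumor.size == 0:
        raise ValueError("segmentation has no tumor voxels")
    return np.array(
        [(tumor == SUBVOLUME_LABELS[name]).mean() for name in SUBVOLUME_NAMES]
    )


@dataclass
class CohortHabitats:
    """Cohort-level habitat results: thresholds, per-patient maps, compositions."""

    thresholds: pd.DataFrame  # index: sequence; columns: center_low/high, threshold
    maps: dict[str, HabitatMap]
    compositions: pd.DataFrame  # index: patient_id; columns: p_0..p_15, n_voxels
    subvolumes: pd.DataFrame  # index: patient_id; columns: SUBVOLUME_NAMES


def compute_cohort_habitats(
    patients: Mapping[str, PatientImages],
    subsample_cap: int | None = None,
    seed: int = 0,
) -> CohortHabitats:
    """Run the habitat workflow over a cohort.

    Thresholds are estimated from linearized tumor intensities pooled across
    all patients (optionally subsampled to ``subsample_cap`` voxels per
    patient with a fixed seed, to bound memory; default is no subsampling).
    """
    if not patients:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    linearized: dict[str, dict[str, np.ndarray]] = {}
    pooled: dict[str, list[np.ndarray]] = {seq: [] for seq in SEQUENCES}
    indices: dict[str, tuple[np.ndarray, ...]] = {}

    for pid, pat in patients.items():
        seg = pat.segmentation
        indices[pid] = np.nonzero(seg.tumor_mask)
        linearized[pid] = {}
        for seq in SEQUENCES:
            z = scale_to_reference(pat.volumes[seq], seg)
            lin = linearize(z)
            linearized[pid][seq] = lin
            if subsample_cap is not None and lin.size > subsample_cap:
                take = rng.choice(lin.size, size=subsample_cap, replace=False)
                pooled[seq].append(lin[take])
            else:
                pooled[seq].append(lin)

    thresholds = {
        seq: pooled_threshold(np.concatenate(pooled[seq])) for seq in SEQUENCES
    }
    thr_df = pd.DataFrame(
        {
            "center_low": [thresholds[s].center_low for s in SEQUENCES],
            "center_high": [thresholds[s].center_high for s in SEQUENCES],
            "threshold": [thresholds[s].threshold for s in SEQUENCES],
        },
        index=pd.Index(SEQUENCES, name="sequence"),
    )

    maps: dict[str, HabitatMap] = {}
    comp_rows, sub_rows = [], []
    for pid, pat in patients.items():
        bits = {
            seq: dichotomize(linearized[pid][seq], thresholds[seq].threshold)
            for seq in SEQUENCES
        }
        hmap = build_habitat_map(
            bits, indices[pid], pat.segmentation.shape, pat.segmentation.affine
        )
        maps[pid] = hmap
        comp = composition(hmap)
        comp_rows.append(list(comp.proportions) + [comp.n_voxels])
        sub_rows.append(subvolume_fractions(pat.segmentation))

    ids = pd.Index(list(patients), name="patient_id")
    compositions = pd.DataFrame(
        comp_rows, index=ids, columns=COMPOSITION_COLUMNS + ["n_voxels"]
    )
    compositions["n_voxels"] = compositions["n_voxels"].astype(int)
    subvolumes = pd.DataFrame(sub_rows, index=ids, columns=list(SUBVOLUME_NAMES))
    return CohortHabitats(
        thresholds=thr_df, maps=maps, compositions=compositions, subvolumes=subvolumes
    )
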