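"""Synthetic multiparametric-MRI cohorts with known habitat structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without clinical data:

* Anatomy: concentric ellipsoidal shells of CSF, gray matter and white matter
  inside a zero background, plus one ellipsoidal tumor.
* Habitats: tumor voxels are partitioned into up to 16 contiguous angular
  sectors whose sizes are drawn from a Dirichlet distribution — spatially
  coherent habitat geometry with exactly controllable fractions.
* Intensities: reference tissue is drawn per sequence from Gaussian GM/WM
  distributions; each tumor voxel's intensity is placed, in units of the
  patient's realized reference mean/SD, at ``z_mid ± separation·signature_sd``
  according to its habitat's high/low bit for that sequence, plus Gaussian
  signature noise.  ``separation`` is therefore the habitat-vs-threshold gap
  in signature SDs.
* Survival: exponential proportional-hazards times with hazard
  ``lambda0 · exp(Σ_h beta_h p_h + Σ_c beta_c (x_c − center_c))`` and
  independent exponential censoring.
* Pathway scores: a linked pathway is a noisy monotone (logit) transform of
  one habitat's proportion; null pathways are independent standard noise.

Fixed seeds give byte-identical cohorts.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .io import CohortBundle, PatientImages, write_segmentation, write_volume
from .types import (
    CLINICAL_COVARIATES,
    N_HABITATS,
    SEQUENCES,
    SUBVOLUME_NAMES,
    SegmentationMap,
    VolumeGrid,
)

#: Reference values at which clinical covariates contribute zero log-hazard.
COVARIATE_CENTERS = {
    "age_years": 60.0,
    "kps": 80.0,
    "tumor_volume_ml": 20.0,
    "idh1_mutant": 0.0,
}

#: Per-sequence Gaussian intensity parameters (gm_mean, wm_mean, sd) in
#: arbitrary scanner units, plus a CSF mean, loosely shaped after typical
#: relative tissue contrasts of each sequence.
TISSUE_INTENSITY = {
    "FLAIR": {"gm": 240.0, "wm": 180.0, "sd": 25.0, "csf": 60.0},
    "T1": {"gm": 300.0, "wm": 380.0, "sd": 25.0, "csf": 120.0},
    "T1c": {"gm": 310.0, "wm": 390.0, "sd": 25.0, "csf": 130.0},
    "T2": {"gm": 330.0, "wm": 250.0, "sd": 25.0, "csf": 520.0},
}


class SimulationConfig(BaseModel):
    """All knobs of the synthetic cohort generator (validated, frozen)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_patients: int = Field(default=85, ge=1)
    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = Field(default=2.0, gt=0)
    tumor_radius_range: tuple[float, float] = (6.0, 12.0)  # voxels
    min_tumor_voxels: int = Field(default=50, ge=1)

    # habitat composition prior: symmetric Dirichlet unless fixed_fractions set
    habitat_alpha: float = Field(default=0.5, gt=0)
    fixed_fractions: Optional[tuple[float, ...]] = None

    # intensity signature (in reference-SD units)
    z_mid: float = 1.5
    separation: float = Field(default=2.0, ge=0)
    signature_sd: float = Field(default=0.5, gt=0)

    # canonical sub-volume Dirichlet prior (necrosis, edema, non-enh, enhancing)
    subvolume_alpha: tuple[float, float, float, float] = (2.0, 4.0, 2.0, 4.0)

    # survival model
    habitat_betas: dict[int, float] = Field(
        default_factory=lambda: {2: 5.0, 7: 3.5, 10: -3.5}
    )
    clinical_betas: dict[str, float] = Field(
        default_factory=lambda: {
            "age_years": 0.03,
            "kps": -0.015,
            "tumor_volume_ml": 0.01,
            "idh1_mutant": -0.5,
        }
    )
    baseline_hazard: float = Field(default=0.05925, gt=0)  # per month
    censoring_rate: float = Field(default=0.015, ge=0)  # per month

    # pathway linkage: (name, habitat, gamma) triples plus independent nulls
    linked_pathways: tuple[tuple[str, int, float], ...] = (
        ("PW_linked_h2_up", 2, 1.5),
        ("PW_linked_h7_up", 7, 1.5),
        ("PW_linked_h10_down", 10, -1.5),
    )
    n_null_pathways: int = Field(default=17, ge=0)
    pathway_noise_sd: float = Field(default=0.5, ge=0)

    seed: int = 0

    @field_validator("tumor_radius_range")
    @classmethod
    def _radius_ok(cls, v):
        if v[0] <= 0 or v[1] < v[0]:
            raise ValueError("tumor_radius_range must be 0 < lo <= hi")
        return v

    @field_validator("fixed_fractions")
    @classmethod
    def _fractions_ok(cls, v):
        if v is None:
            return v
        arr = np.asarray(v, dtype=float)
        if arr.shape != (N_HABITATS,) or np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
            raise ValueError("fixed_fractions must be 16 nonnegative values summing to 1")
        return v

    @field_validator("habitat_betas")
    @classmethod
    def _habitats_ok(cls, v):
        for h in v:
            if not 0 <= h <= 15:
                raise ValueError(f"habitat_betas key {h} outside 0..15")
        return v

    @field_validator("clinical_betas")
    @classmethod
    def _covariates_ok(cls, v):
        bad = set(v) - set(CLINICAL_COVARIATES)
        if bad:
            raise ValueError(f"unknown clinical covariate(s): {sorted(bad)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump()
        # YAML-friendly habitat_betas keys
        data["habitat_betas"] = {int(k): float(v) for k, v in data["habitat_betas"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclasses.dataclass
class PatientSample:
    """One simulated patient: images, truth, clinical outcome ingredients."""

    patient_id: str
    volumes: dict[str, VolumeGrid]
    segmentation: SegmentationMap
    true_fractions: np.ndarray  # realized habitat voxel fractions (16,)
    true_habitat_map: np.ndarray  # 3D int array, -1 outside tumor
    subvolume_fractions: np.ndarray  # realized (necrosis, edema, non-enh, enh)
    tumor_volume_ml: float


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` closest to ``fractions*total``."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _draw_fractions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.fixed_fractions is not None:
        return np.asarray(config.fixed_fractions, dtype=float)
    return rng.dirichlet(np.full(N_HABITATS, config.habitat_alpha))


def generate_patient_images(
    config: SimulationConfig, patient_seed, patient_id: str = "SIM"
) -> PatientSample:
    """Simulate one patient's four volumes, segmentation and ground truth."""
    rng = np.random.default_rng(patient_seed)
    nx, ny, nz = config.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    center = np.array([nx, ny, nz]) / 2.0
    brain_radii = 0.46 * np.array([nx, ny, nz])
    r2 = (
        ((ii - center[0]) / brain_radii[0]) ** 2
        + ((jj - center[1]) / brain_radii[1]) ** 2
        + ((kk - center[2]) / brain_radii[2]) ** 2
    )
    labels = np.zeros(config.shape, dtype=np.int16)
    labels[r2 <= 1.0] = 1  # CSF shell
    labels[r2 <= 0.85] = 2  # gray matter shell
    labels[r2 <= 0.60] = 3  # white matter core

    # tumor: ellipsoid centered inside white matter
    lo, hi = config.tumor_radius_range
    radii = rng.uniform(lo, hi, size=3)
    offset_scale = 0.15 * np.array([nx, ny, nz])
    t_center = center + rng.uniform(-1, 1, size=3) * offset_scale
    t2 = (
        ((ii - t_center[0]) / radii[0]) ** 2
        + ((jj - t_center[1]) / radii[1]) ** 2
        + ((kk - t_center[2]) / radii[2]) ** 2
    )
    tumor_mask = (t2 <= 1.0) & (r2 <= 0.85)  # keep tumor inside brain tissue
    n_tumor = int(tumor_mask.sum())
    if n_tumor < config.min_tumor_voxels:
        raise ValueError(
            f"degenerate tumor: {n_tumor} voxels < {config.min_tumor_voxels}"
        )
    tix = np.nonzero(tumor_mask)

    # canonical sub-volumes by radial quantile: necrotic core, enhancing rim,
    # then non-enhancing and edema toward the periphery
    sub_fracs = rng.dirichlet(np.asarray(config.subvolume_alpha))
    radial_order = np.argsort(t2[tix], kind="stable")
    sub_counts = _largest_remainder_counts(sub_fracs, n_tumor)
    seg_tumor = np.empty(n_tumor, dtype=np.int16)
    pos = 0
    for name, sub_label in (("necrosis", 4), ("enhancing", 7), ("non_enhancing", 6), ("edema", 5)):
        cnt = sub_counts[SUBVOLUME_NAMES.index(name)]
        seg_tumor[radial_order[pos: pos + cnt]] = sub_label
        pos += cnt
    labels[tix] = seg_tumor
    realized_sub = np.array(
        [(seg_tumor == {"necrosis": 4, "edema": 5, "non_enhancing": 6, "enhancing": 7}[n]).mean()
         for n in SUBVOLUME_NAMES]
    )

    # habitat sectors: contiguous azimuthal runs sized by the drawn fractions
    fractions = _draw_fractions(config, rng)
    habitat_counts = _largest_remainder_counts(fractions, n_tumor)
    azimuth = np.arctan2(tix[1] - t_center[1], tix[0] - t_center[0])
    az_order = np.argsort(azimuth, kind="stable")
    habitat_of_voxel = np.empty(n_tumor, dtype=np.int16)
    pos = 0
    for h in range(N_HABITATS):
        habitat_of_voxel[az_order[pos: pos + habitat_counts[h]]] = h
        pos += habitat_counts[h]
    realized_fractions = habitat_counts / n_tumor

    true_map = np.full(config.shape, -1, dtype=np.int16)
    true_map[tix] = habitat_of_voxel

    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    seg = SegmentationMap(labels=labels, affine=affine)

    volumes: dict[str, VolumeGrid] = {}
    bits = np.array(
        [[(h >> shift) & 1 for h in range(N_HABITATS)] for shift in (3, 2, 1, 0)]
    )  # rows: FLAIR, T1, T1c, T2
    for s_idx, seq in enumerate(SEQUENCES):
        pars = TISSUE_INTENSITY[seq]
        vals = np.zeros(config.shape, dtype=np.float64)
        for lab, mean in ((1, pars["csf"]), (2, pars["gm"]), (3, pars["wm"])):
            m = labels == lab
            vals[m] = rng.normal(mean, pars["sd"], size=int(m.sum()))
        # tumor intensities expressed in realized reference units so that
        # recovered z-scores reproduce the planted signature exactly
        ref = vals[seg.reference_mask]
        mu_hat, sd_hat = float(ref.mean()), float(ref.std())
        voxel_bits = bits[s_idx][habitat_of_voxel]
        z = (
            config.z_mid
            + (2.0 * voxel_bits - 1.0) * config.separation * config.signature_sd
            + rng.normal(0.0, config.signature_sd, size=n_tumor)
        )
        vals[tix] = mu_hat + sd_hat * z
        volumes[seq] = VolumeGrid(values=vals, affine=affine)

    return PatientSample(
        patient_id=patient_id,
        volumes=volumes,
        segmentation=seg,
        true_fractions=realized_fractions,
        true_habitat_map=true_map,
        subvolume_fractions=realized_sub,
        tumor_volume_ml=n_tumor * float(np.prod([config.voxel_size_mm] * 3)) / 1000.0,
    )


def generate_clinical_covariates(
    config: SimulationConfig, rng: np.random.Generator, tumor_volume_ml: float
) -> dict[str, float]:
    age = float(np.clip(rng.normal(59.0, 12.0), 18.0, 84.0))
    kps = float(rng.choice([60, 70, 80, 90, 100], p=[0.1, 0.2, 0.3, 0.25, 0.15]))
    idh1 = int(rng.random() < 2.0 / 85.0)
    return {
        "age_years": age,
        "kps": kps,
        "tumor_volume_ml": tumor_volume_ml,
        "idh1_mutant": idh1,
    }


def generate_survival(
    true_fractions: np.ndarray,
    clinical: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Draw (os_months, event) from the exponential proportional-hazards model."""
    p = np.asarray(true_fractions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("habitat fractions must sum to 1")
    eta = sum(beta * p[h] for h, beta in config.habitat_betas.items())
    eta += sum(
        beta * (clinical[c] - COVARIATE_CENTERS[c])
        for c, beta in config.clinical_betas.items()
    )
    hazard = config.baseline_hazard * float(np.exp(eta))
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate)
    else:
        t_cens = np.inf
    os_months = float(min(t_event, t_cens))
    return os_months, int(t_event <= t_cens)


def pathway_names(config: SimulationConfig) -> list[str]:
    return [name for name, _, _ in config.linked_pathways] + [
        f"PW_null_{i:03d}" for i in range(config.n_null_pathways)
    ]


def generate_pathway_scores(
    true_fractions: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Patients × pathways score matrix with planted monotone linkage.

    Linked pathway (name, h, gamma): score = gamma·logit(p*_h) + noise, where
    p*_h is the boundary-compressed habitat-h fraction, so the planted
    association direction is sign(gamma).  Null pathways are standard normal.
    """
    frac = np.atleast_2d(np.asarray(true_fractions, dtype=float))
    n = frac.shape[0]
    cols: dict[str, np.ndarray] = {}
    for name, h, gamma in config.linked_pathways:
        p = (frac[:, h] * (n - 1) + 0.5) / n if n > 1 else np.clip(frac[:, h], 0.01, 0.99)
        score = gamma * np.log(p / (1.0 - p))
        cols[name] = score + rng.normal(0.0, config.pathway_noise_sd, size=n)
    for i in range(config.n_null_pathways):
        cols[f"PW_null_{i:03d}"] = rng.normal(0.0, 1.0, size=n)
    if patient_ids is None:
        patient_ids = [f"SIM-{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(cols, index=pd.Index(patient_ids, name="patient_id"))


def _patient_rngs(config: SimulationConfig, stream: int, i: int):
    # independent, reproducible streams per (stage, patient)
    return np.random.default_rng([config.seed, stream, i])


def generate_cohort_bundle(
    config: SimulationConfig,
) -> tuple[CohortBundle, pd.DataFrame]:
    """Simulate a full in-memory cohort.

    Returns the bundle (images + clinical + pathway tables) and a ground-truth
    DataFrame of realized habitat fractions (index patient_id, p_0..p_15).
    """
    patients: dict[str, PatientImages] = {}
    clin_rows, truth_rows, ids = [], [], []
    fractions = np.empty((config.n_patients, N_HABITATS))
    for i in range(config.n_patients):
        pid = f"SIM-{i + 1:03d}"
        sample = generate_patient_images(config, [config.seed, 0, i], patient_id=pid)
        rng_c = _patient_rngs(config, 1, i)
        clinical = generate_clinical_covariates(config, rng_c, sample.tumor_volume_ml)
        os_months, event = generate_survival(
            sample.true_fractions, clinical, config, rng_c
        )
        patients[pid] = PatientImages(
            volumes=sample.volumes, segmentation=sample.segmentation
        )
        clin_rows.append(
            {"patient_id": pid, "os_months": os_months, "event": event, **clinical}
        )
        fractions[i] = sample.true_fractions
        truth_rows.append(sample.true_fractions)
        ids.append(pid)

    clinical_df = pd.DataFrame(clin_rows).set_index("patient_id")
    pathway_df = generate_pathway_scores(
        fractions, config, np.random.default_rng([config.seed, 2]), patient_ids=ids
    )
    truth = pd.DataFrame(
        truth_rows,
        index=pd.Index(ids, name="patient_id"),
        columns=[f"p_{h}" for h in range(N_HABITATS)],
    )
    bundle = CohortBundle(
        patients=patients, clinical=clinical_df, pathways=pathway_df, exclusions=[]
    )
    return bundle, truth


def generate_cohort(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a cohort directory consumable by :func:`habitatmri.io.load_cohort`.

    Layout: ``<id>_<seq>.nii`` and ``<id>_seg.nii`` per patient, plus
    ``clinical.csv``, ``pathways.csv``, and a ``truth/`` sidecar with realized
    habitat fractions, the survival coefficients and pathway linkage used.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_cohort_bundle(config)
    for pid, pat in bundle.patients.items():
        for seq in SEQUENCES:
            write_volume(pat.volumes[seq], out_dir / f"{pid}_{seq}.nii")
        write_segmentation(pat.segmentation, out_dir / f"{pid}_seg.nii")
    bundle.clinical.to_csv(out_dir / "clinical.csv")
    bundle.pathways.to_csv(out_dir / "pathways.csv")

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.to_csv(truth_dir / "habitat_fractions.csv")
    pd.DataFrame(
        {"habitat": list(config.habitat_betas), "beta": list(config.habitat_betas.values())}
    ).to_csv(truth_dir / "habitat_betas.csv", index=False)
    pd.DataFrame(
        config.linked_pathways, columns=["pathway", "habitat", "gamma"]
    ).to_csv(truth_dir / "pathway_linkage.csv", index=False)
    config.to_yaml(truth_dir / "config.yaml")
    return out_dir
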