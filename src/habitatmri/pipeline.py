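"""End-to-end orchestration of the habitat analysis stages.

Each stage reads the previous stage's files from the output directory, so
stages are independently re-runnable:

``simulate``      cohort/ (NIfTI volumes + clinical.csv + pathways.csv)
``habitats``      habitats/ (habitat-map NIfTIs, compositions.csv, thresholds.csv,
                  subvolumes.csv)
``survival``      survival/ (importance.csv, cox.csv, relevant.csv)
``associations``  associations/ (subvolume_assoc.csv, pathway_assoc_h<h>.csv,
                  top5_summary.csv)
``run_all``       all of the above plus manifest.json

Existing stage outputs are never silently overwritten; a stage aborts with a
machine-readable error code if its outputs are already present.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .habitats import COMPOSITION_COLUMNS, compute_cohort_habitats
from .io import load_cohort, read_clinical, read_pathways
from .simulate import SimulationConfig, generate_cohort
from .survival import build_survival_frame, relevant_habitats
from .associations import pathway_screen, subvolume_screen
from .types import CLINICAL_COVARIATES

log = logging.getLogger("habitatmri")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


class HabitatParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subsample_cap: Optional[int] = Field(default=None, ge=1)


class SurvivalParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = Field(default=500, ge=1)
    mtry: Optional[int] = Field(default=None, ge=1)
    min_leaf: int = Field(default=3, ge=1)
    p_threshold: float = Field(default=0.05, gt=0, lt=1)


class AssociationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(default=0.05, gt=0, lt=1)
    top_k: int = Field(default=5, ge=1)


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    cohort_dir: Optional[str] = None  # use an existing cohort instead of simulating
    habitat: HabitatParams = Field(default_factory=HabitatParams)
    survival: SurvivalParams = Field(default_factory=SurvivalParams)
    association: AssociationParams = Field(default_factory=AssociationParams)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.model_validate(data)


def _fresh(stage: str, *paths: Path) -> None:
    for p in paths:
        if p.exists():
            raise PipelineError(
                stage, "output-exists", f"refusing to overwrite existing output {p}"
            )


def _cohort_dir(config: RunConfig) -> Path:
    if config.cohort_dir is not None:
        return Path(config.cohort_dir)
    return Path(config.out_dir) / "cohort"


def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort directory."""
    if config.simulation is None:
        raise PipelineError("simulate", "no-config", "no simulation section in config")
    out = Path(config.out_dir) / "cohort"
    _fresh("simulate", out / "clinical.csv")
    sim = config.simulation
    if sim.seed != config.seed:
        sim = sim.model_copy(update={"seed": config.seed})
    log.info("simulating cohort of %d patients into %s", sim.n_patients, out)
    generate_cohort(sim, out)
    return out


def run_habitats(config: RunConfig) -> Path:
    """Compute habitat maps, compositions and sub-volume fractions."""
    cohort_dir = _cohort_dir(config)
    out = Path(config.out_dir) / "habitats"
    _fresh("habitats", out / "compositions.csv")
    try:
        cohort = load_cohort(
            cohort_dir / "clinical.csv", cohort_dir / "pathways.csv", cohort_dir
        )
    except Exception as exc:
        raise PipelineError("habitats", "cohort-load", str(exc)) from exc
    for exc_rec in cohort.exclusions:
        log.warning("excluded %s: %s", exc_rec.patient_id, exc_rec.reason)
    result = compute_cohort_habitats(
        cohort.patients, subsample_cap=config.habitat.subsample_cap, seed=config.seed
    )
    out.mkdir(parents=True, exist_ok=True)
    result.thresholds.to_csv(out / "thresholds.csv")
    result.compositions.to_csv(out / "compositions.csv")
    result.subvolumes.to_csv(out / "subvolumes.csv")
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for pid, hmap in result.maps.items():
        img = nib.Nifti1Image(hmap.labels.astype(np.int16), hmap.affine)
        nib.save(img, maps_dir / f"{pid}_habitats.nii")
    return out


def run_survival(config: RunConfig) -> Path:
    """Two-stage relevance screen: RSF VIMP then covariate-adjusted Cox."""
    out = Path(config.out_dir) / "survival"
    _fresh("survival", out / "relevant.csv")
    hab_dir = Path(config.out_dir) / "habitats"
    comp_path = hab_dir / "compositions.csv"
    if not comp_path.exists():
        raise PipelineError("survival", "missing-input", f"{comp_path} not found")
    compositions = pd.read_csv(comp_path, index_col="patient_id")
    clinical = read_clinical(_cohort_dir(config) / "clinical.csv")
    try:
        data = build_survival_frame(compositions, clinical)
        result = relevant_habitats(
            data,
            alpha=config.survival.p_threshold,
            n_trees=config.survival.n_trees,
            mtry=config.survival.mtry,
            min_leaf=config.survival.min_leaf,
            seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("survival", "model-failure", str(exc)) from exc
    out.mkdir(parents=True, exist_ok=True)
    imp = result.importance.table.copy()
    imp["oob_error"] = result.importance.oob_error
    imp.to_csv(out / "importance.csv")
    cox_rows = []
    for h, fit in result.cox_fits.items():
        for name in fit.params.index:
            cox_rows.append(
                {
                    "habitat": h,
                    "term": name,
                    "beta": fit.params[name],
                    "se": fit.se[name],
                    "z": fit.z[name],
                    "p": fit.p[name],
                }
            )
    pd.DataFrame(cox_rows).to_csv(out / "cox.csv", index=False)
    pd.DataFrame({"habitat": result.relevant}).to_csv(out / "relevant.csv", index=False)
    if result.skipped:
        pd.DataFrame(
            {"habitat": list(result.skipped), "reason": list(result.skipped.values())}
        ).to_csv(out / "skipped.csv", index=False)
    log.info(
        "relevant habitats: %s (no multiple-testing correction at the Cox stage)",
        result.relevant,
    )
    return out


def run_associations(config: RunConfig) -> Path:
    """Spearman sub-volume screen + Dirichlet pathway screen per relevant habitat."""
    out = Path(config.out_dir) / "associations"
    _fresh("associations", out / "subvolume_assoc.csv")
    base = Path(config.out_dir)
    try:
        compositions = pd.read_csv(
            base / "habitats" / "compositions.csv", index_col="patient_id"
        )
        subvolumes = pd.read_csv(
            base / "habitats" / "subvolumes.csv", index_col="patient_id"
        )
        relevant = pd.read_csv(base / "survival" / "relevant.csv")["habitat"].tolist()
    except FileNotFoundError as exc:
        raise PipelineError("associations", "missing-input", str(exc)) from exc
    pathways = read_pathways(_cohort_dir(config) / "pathways.csv")

    out.mkdir(parents=True, exist_ok=True)
    subvolume_screen(compositions, subvolumes, relevant).to_csv(
        out / "subvolume_assoc.csv", index=False
    )
    summary_rows = []
    for h in relevant:
        table = pathway_screen(
            compositions[f"p_{h}"],
            pathways,
            alpha=config.association.alpha,
            top_k=config.association.top_k,
        )
        table.to_csv(out / f"pathway_assoc_h{h}.csv", index=False)
        top = table[table["top5"] == True]  # noqa: E712
        for _, row in top.iterrows():
            summary_rows.append(
                {
                    "habitat": h,
                    "direction": row["direction"],
                    "rank": int(row["rank"]),
                    "pathway": row["pathway"],
                    "coefficient": row["coefficient"],
                    "bonferroni_p": row["bonferroni_p"],
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "top5_summary.csv", index=False)
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage and write a manifest with config, seed and timings."""
    stages = [("habitats", run_habitats), ("survival", run_survival),
              ("associations", run_associations)]
    if config.cohort_dir is None:
        stages.insert(0, ("simulate", run_simulate))
    timings = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        fn(config)
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s finished in %.1fs", name, timings[name])
    resolved = config.model_dump(mode="json")
    manifest = {
        "package": "habitatmri",
        "version": __version__,
        "seed": config.seed,
        "config": resolved,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest(),
        "covariates": list(CLINICAL_COVARIATES),
        "composition_columns": COMPOSITION_COLUMNS,
        "multiple_testing": {
            "cox_stage": "none (raw p < threshold)",
            "pathway_stage": "Bonferroni over pathways per habitat",
        },
        "stage_seconds": timings,
    }
    manifest_path = Path(config.out_dir) / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
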