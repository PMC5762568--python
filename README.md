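# habitatmri

Spatial habitat analysis of multiparametric brain-tumor MRI.

Glioblastoma is radiographically heterogeneous: different sub-regions of the
same tumor enhance, swell, or necrose differently across MR sequences.
`habitatmri` implements a voxel-level "habitat" decomposition of that
heterogeneity and the downstream statistics that connect it to outcome and
molecular data. It is aimed at imaging-genomics researchers who have, per
patient, four co-registered MR volumes (FLAIR, T1, post-contrast T1, T2),
a BraTumIA-style tissue/tumor segmentation, survival data, and a
pathway-activity score matrix.

## Method

For each patient and sequence, tumor-voxel intensities are z-scored against
the patient's pooled gray+white matter, then min–max scaled to [0, 1] over
the tumor. For each sequence *s*, one cohort-wide threshold *t<sub>s</sub>*
is the midpoint of the two cluster centers of an **exact 1-D 2-means**
(sorted breakpoint enumeration — deterministic, no seeds). Each tumor voxel
then carries four bits *b<sub>s</sub>* = 1{value > *t<sub>s</sub>*}, read as
an integer habitat label

    h = 8·b_FLAIR + 4·b_T1 + 2·b_T1c + 1·b_T2  ∈ {0, …, 15},

so habitat 0 is low in all four sequences and habitat 15 high in all four.
The fraction of tumor voxels per label gives each patient a 16-component
composition **p** on the simplex.

Downstream:

* **Relevance screen.** A random survival forest on the 16 proportions ranks
  habitats by out-of-bag permutation importance (VIMP); habitats with
  VIMP > 0 are then tested one at a time in a Cox proportional-hazards model
  (Breslow ties, Newton–Raphson) adjusted for age, KPS, tumor volume and
  IDH1 status. Habitats with VIMP > 0 **and** Wald p < 0.05 are "relevant".
* **Sub-volume associations.** Spearman rank correlation of each relevant
  habitat's proportion with the necrosis / edema / non-enhancing / enhancing
  fractions of the tumor.
* **Pathway associations.** For each relevant habitat *h* and pathway score
  *x*, a two-part Dirichlet regression of (p<sub>h</sub>, 1−p<sub>h</sub>)
  with log-linked concentrations α<sub>c</sub> = exp(β<sub>c0</sub> +
  β<sub>c1</sub>x). The association coefficient is the mean-model contrast
  β<sub>h1</sub> − β<sub>rest,1</sub> (its sign is the direction of
  dE[p<sub>h</sub>]/dx); pathways are Bonferroni-screened and ranked by
  |coefficient| within direction, top-5 up and down.

A synthetic-data module generates full cohorts (NIfTI volumes with planted
habitat signatures, exponential proportional-hazards survival, linked and
null pathway scores) with known ground truth, so the entire pipeline is
testable end to end.

## Worked example

```python
from habitatmri.pipeline import RunConfig, run_all

config = RunConfig.model_validate({
    "out_dir": "example_run", "seed": 1,
    "simulation": {"n_patients": 85},   # synthetic stand-in cohort
})
run_all(config)
```

or equivalently `habitatmri run-all --config config.yaml --seed 1`. On the
default 85-patient synthetic cohort (seed 1) this prints/writes:

* `habitats/thresholds.csv` — pooled 2-means thresholds near 0.5 per
  sequence (e.g. FLAIR: centers 0.313 / 0.686, threshold 0.4998), as expected
  when low and high signature clusters are symmetric after linearization.
* `survival/importance.csv` — habitat 2 has the largest VIMP (0.046 against
  an OOB baseline error of 0.47).
* `survival/relevant.csv` — habitats {2, 10} pass both stages at this seed:
  Cox β = 11.3 (p = 1.3e-5) for p₂ and β = −6.3 (p = 0.0016) for p₁₀,
  consistent with the planted log-hazards (+5 and −3.5 per unit proportion;
  habitat 7's weaker planted effect lands at p = 0.15 here — a realistic
  power miss at n = 85).
* `associations/top5_summary.csv` — the planted habitat-2-linked pathway is
  the rank-1 upregulated hit (coefficient 0.47, Bonferroni p ≈ 1e-149); the
  planted habitat-10 pathway is the rank-1 downregulated hit for habitat 10.

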