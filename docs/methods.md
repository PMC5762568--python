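# Methods

## Habitat construction

**Normalization.** Intensities are comparable neither across scanners nor
across patients, so tumor voxels are standardized per patient and sequence:
z = (I − μ_ref)/σ_ref with μ_ref, σ_ref the mean and population SD over the
patient's pooled gray+white matter voxels (≥ 100 voxels required; zero
spread is an error). Z-scoring confers exact invariance to affine intensity
transforms I → aI + b (a > 0), which is the point of normalizing against
reference tissue; the whole pipeline (thresholds, habitat labels,
compositions) inherits this invariance, and a property test asserts it.

**Linearization.** Standardized tumor values are min–max scaled to [0, 1]
per patient and sequence, using the min/max over the *tumor* voxels only:
habitat analysis operates on the tumor region, and a whole-image min/max
would couple thresholds to background air. A constant tumor vector maps to
all 0.5 with a warning rather than failing, so one degenerate patient cannot
abort a cohort run.

**Dichotomization.** For each sequence, the linearized values of all
patients are pooled and split by exact 1-D 2-means: the optimal 2-partition
of scalars is a split of the sorted sample, so all n−1 breakpoints are
scored by within-cluster SSE via prefix sums and the global optimum taken
(first optimum on ties). This is deterministic and seed-free — no Lloyd
iterations, no initialization choices. The threshold is the midpoint of the
two cluster means; a voxel is "high" iff strictly above it (ties → low).
Pooling can optionally subsample to a per-patient cap with a fixed seed to
bound memory (default: no subsampling).

**Encoding.** Habitat label = 8·b_FLAIR + 4·b_T1 + 2·b_T1c + 1·b_T2, a
bijection between {0,1}⁴ and {0..15}. With k sequences the same construction
yields 2^k habitats; only k = 4 is exercised here.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
realistic MR physics (no bias fields, partial-volume effects, or coil
profiles — conclusions from passing tests are about the pipeline's
statistics, not about robustness to those artifacts).

* **Anatomy.** Concentric ellipsoidal CSF/GM/WM shells in a zero background;
  one ellipsoidal tumor (default radii 6–12 voxels at 2 mm isotropic in a
  64×64×48 grid — a desk-scale stand-in for full-resolution MR chosen so a
  cohort generates in seconds) carved into the brain, relabeled into
  radial-quantile canonical sub-volumes (necrotic core, enhancing rim, then
  non-enhancing and edema outward) with Dirichlet(2,4,2,4)-drawn fractions.
* **Habitats.** Tumor voxels are partitioned into contiguous azimuthal
  sectors sized by largest-remainder rounding of Dirichlet-drawn fractions
  (default symmetric concentration 0.5, giving the skewed compositions real
  habitat maps show). Sectors make the planted geometry spatially coherent
  while keeping realized fractions exactly known.
* **Intensities.** Reference tissue is drawn first; tumor voxels are then
  placed in units of the *realized* reference mean/SD at
  z_mid ± separation·signature_sd by their habitat's bit, plus Gaussian
  signature noise (defaults z_mid = 1.5, separation = 2, signature_sd =
  0.5). Because placement uses realized reference statistics, recovered
  z-scores reproduce the planted signature exactly; per-sequence
  misclassification is ≈ Φ(−separation) regardless of the SD scale.
* **Survival.** Exponential times with hazard λ₀·exp(Σ_h β_h p_h +
  Σ_c β_c (x_c − center_c)) and independent exponential censoring — the
  simplest model satisfying proportional hazards exactly, giving closed-form
  checks (median = ln2/λ₀ under the null). Defaults: λ₀ = ln2/11.7 per month
  (marginal median ≈ 11.7 months), censoring 0.015/month (≈ 20% censored),
  prognostic habitats {2: +5.0, 7: +3.5, 10: −3.5} per unit proportion —
  across the observed proportion spread this is a hazard ratio of roughly
  3–4, large enough to be detectable at the default n = 85 — and mild
  clinical effects (age +0.03/yr, KPS −0.015, volume +0.01/ml, IDH1 −0.5).
  IDH1 prevalence 2/85; age ≈ N(59, 12) truncated to 18–84.
* **Pathways.** A linked pathway is γ·logit(p*_h) + N(0, σ) with p*_h the
  boundary-compressed habitat fraction (defaults γ = ±1.5, σ = 0.5, three
  linked + 17 null pathways); null pathways are standard normal.

Fixed seeds give byte-identical cohorts (volumes are written as uncompressed
NIfTI-1 so on-disk bytes are reproducible).

## Survival modeling

**Cox regression** maximizes the Breslow-tie partial likelihood by
Newton–Raphson with step-halving; convergence at score max-norm < 1e-8
(≤ 100 iterations, else an error carrying the likelihood trace). Standard
errors come from the inverse observed information; Wald tests are two-sided.
Predictors are centered internally (invariant for β, stabilizes exp).
Constant predictors and < 2 events are rejected up front. OS is modeled as
continuous time; no OS ≥/< 12-month dichotomy enters the modeling.

**Random survival forest.** scikit-survival's log-rank-split forest
(defaults: 500 trees, mtry = ⌈√p⌉, min_samples_leaf = 3 — a samples-based
stand-in for a 3-events-per-leaf rule, which the underlying library does not
expose). VIMP is Ishwaran-style out-of-bag permutation importance computed
on top of the forest: the increase in OOB ensemble error (1 − Harrell's C of
the OOB-averaged risk score) when a column is permuted among each tree's OOB
samples. Deterministic given the seed (tree bootstraps are reconstructed
from each tree's stored seed).

**Relevance rule.** Cox models are fitted only for habitats with VIMP > 0
(one model per habitat: its proportion + the four clinical covariates —
per-habitat models avoid the exact collinearity of 16 proportions summing
to 1); "relevant" = VIMP > 0 and habitat-coefficient Wald p < 0.05. No
multiple-testing correction is applied at this stage (recorded in the run
manifest); an empty selection is a valid, reported outcome.

## Composition associations

**Spearman** uses midranks with the t-approximation p-value (|rho| = 1 →
p = 0); constant inputs yield a flagged result, not an exception. Sub-volume
associations are reported uncorrected.

**Two-part Dirichlet regression.** For habitat h the response is
(p_h, 1 − p_h) compressed off the boundary by y* = (y(n−1) + 1/2)/n —
applied unconditionally (it is a no-op at 0.5 and asymptotically
negligible), removing a data-dependent branch. Both concentrations are
log-linked in the pathway score; the 4-parameter likelihood is maximized by
L-BFGS with analytic digamma gradients from three deterministic starts
(zeros, method-of-moments intercepts, perturbed moments), followed by a
Newton polish with the analytic observed information until the gradient
max-norm is < 1e-6; the best final likelihood wins, and the ascent property
(optimum ≥ every start) is asserted in tests. Standard errors come from the
inverse observed information.

The reported association coefficient is the mean-model contrast
β_h1 − β_rest,1, not the habitat slope alone: sign(dE[p_h]/dx) equals the
sign of this contrast at every x, it negates exactly under component
exchange, and it equals the logit-mean slope of the equivalent Beta
regression. A single component's slope mixes mean and precision effects —
for skewed compositions a strong positive linkage can fit with the habitat
slope near zero and the rest slope strongly negative — so it does not
identify the direction that "up/down-regulated" is meant to convey.

**Screen.** One fit per pathway; Bonferroni over the number of pathways
tested for that habitat (min(1, m·p), monotone and capped); results split by
coefficient sign, ranked by |coefficient| within direction, top-5 flagged.
Non-converged fits are excluded from ranking with a logged reason.

## Known limitations

* The Wald test of the Dirichlet contrast is well calibrated at moderate
  compositions (type-I ≈ 5% at n = 85 in simulation) but anti-conservative
  when the composition is concentrated near the simplex boundary (observed
  ≈ 13% for a Beta(0.5, 7.5)-shaped component), because the boundary
  compression misspecifies the likelihood near 0. Rankings by |coefficient|
  are unaffected; Bonferroni absorbs part of the excess. Treat borderline
  Bonferroni-significant hits for near-empty habitats with caution.
* min_samples_leaf approximates an events-per-leaf constraint; with heavy
  censoring terminal nodes can hold fewer events than intended.
* The relevance screen's power at n = 85 is modest: weakly prognostic
  planted habitats are missed at some seeds (as in the worked example).
* The synthetic generator's tumors are single ellipsoids with sector
  habitats; it does not emulate infiltrative margins, multifocality, or
  scanner artifacts.

## Problem sizes used in tests

Simulation-based tests use reduced but statistically meaningful sizes chosen
as the package's own trade-off between Monte-Carlo resolution and turnaround:
composition recovery at n = 20 patients (32×32×24 grids), Cox calibration
200 × n = 100, RSF sanity 50 replicates × 100 trees (n = 100 null, n = 300
power), Dirichlet recovery/calibration 200 replicates, pathway screen 50
replicates × 100 pathways at n = 85.
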