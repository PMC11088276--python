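# Methods

This note documents the models, estimators and numerical choices behind
`polyqhcs`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the design was genuinely open.

## 1. Screen simulation (`synthdata`)

### Design and geometry

A screen is a set of 384-well (16 × 24) plate *layouts*, each replicated
`n_replicate_plates` times (default 3, a triplicate screen).  Each
(compound, dose) pair occupies one well per replicate plate; the default
library size is 1,216 compounds (1,122 approved drugs plus 94 epigenetic
compounds) at a single 1 µM dose, so a primary screen spans 4 layouts
× 3 replicates = 12 plates.  Each plate carries ≥ 8 (default 16)
*no-dox* control wells (toxin never induced; the assay's positive-growth
reference) and the same number of *dox-only* control wells (toxin
induced, no compound; the negative reference that defines both the
normalization denominator and the hit threshold).  Controls are placed
at seed-determined scattered interior positions — never on the plate
border — and at the same positions on all replicate plates of a layout.
Unassigned wells on the last layout are left empty and are not read out.

### Count model

The expected nuclei count of a well is multiplicative:

    mean = baseline × dox_effect^[dox] × effect_c × plate_factor × edge_factor

with defaults `baseline_count = 200` (no-dox wells) and
`dox_effect = 0.5`, so an uncompounded dox-only well expects 100 nuclei.
Planted rescuers carry `effect_c > 1` (default 1.5, i.e. half-way back
to the no-dox level), planted toxic compounds `effect_c < 1` (default
0.6).  Per-plate factors are log-normal (median 1, configurable SD) and
border wells get a single multiplicative `edge_effect` — the simplest
structures that stress per-plate normalization and the edge diagnostic.

Counts are drawn negative-binomially (Gamma–Poisson, size parameter
`dispersion`) with the Poisson limit as the default (`dispersion=None`).
At the default dox-only mean of 100 this gives a control coefficient of
variation of 10%, a typical assay window for a cell-growth readout.  A
`noise="gaussian"` option draws continuous values with the same
mean–variance relation; it exists for calibration studies of the hit
rule, where the Gaussian tail is the analytic reference (§3).

### Seeding

All generators derive their streams from a single integer seed through
named substreams (`SeedSequence([seed, crc32(name)])`), so adding a
generator never perturbs another's stream, and every generator is
byte-reproducible given (config, seed).

### Other generators

* **Nuclei images** — Gaussian-profile spots (radius 6–9 px, σ =
  radius/2, amplitude 2,000–4,000) on a noisy background (100 ± 15,
  16-bit).  Under the default `disjoint` policy, placement is rejection
  sampling with pairwise center distances > r_i + r_j + 2 px; failure to
  place raises rather than silently truncating.
* **DE tables** — planted up/down genes get |LFC| ≥ 2 and p ∈
  [10⁻¹², 10⁻⁶]; nulls get LFC ~ N(0, 0.1) and Uniform(0,1) p-values.
* **Reference rank matrices** — each drug's latent gene score is
  √c · class_vector + √(1−c) · noise, giving within-class score
  correlation exactly c (`class_concordance`); the ranking is the
  descending sort.  A class's latent vector can be anchored to a
  supplied expression profile, which is how the pipeline makes the
  planted agonist class resemble the query signature, emulating a drug
  whose transcriptional consequences match a known agonist class.
* **Competition, survival, bends** — binomial counts around the
  logistic decline (§5), binomial dead-embryo counts (default 150 eggs
  × 3 replicates), and Poisson (optionally NB) bend counts.

### What the generators do not emulate

Optics beyond Gaussian spots (no PSF, illumination gradients, focus
drift), cell morphology and clumping beyond circular nuclei,
spatially-structured plate artefacts other than a uniform edge factor,
raw sequencing reads or flow-cytometry event data, and any
compound-specific dose–response shape (planted effects are flat across
doses).  Passing tests therefore demonstrate the correctness and
calibration of the *analysis* under the stated noise models, not
robustness to every artefact of real instruments.

## 2. Nuclei segmentation (`imaging`)

The pipeline is classical and fully parameterized: Gaussian smoothing
(σ = 2 px) → global Otsu threshold → hole filling →
distance-transform watershed seeded by local maxima ≥
`min_split_distance` (8 px) apart → area gate (40–2,000 px) → optional
border exclusion.  Watershed seeds are relabelled in raster order so
declumping is deterministic.  Two guards matter in practice:

* **Minimum contrast.** Otsu always returns a threshold, even on pure
  background noise; the threshold must clear the image median by
  ≥ `min_contrast_sigmas` (3) robust SDs (1.4826 × MAD), otherwise the
  image is declared empty with a QC warning.  Constant images likewise
  return zero objects with a warning, never an exception.
* **Area gating happens after smoothing**, so the gate refers to the
  smoothed/thresholded footprint, which is slightly larger than the
  underlying object.

Per-cell intensity is the plain masked mean (or median) of a signal
channel over each retained object, computed per label with ordinary
NumPy reductions so that it is bit-identical to the per-pixel
definition.  For cytoplasmic dyes quantified against a nuclear mask,
labels can first be expanded by a fixed radius (`expand_labels`, which
never invades a neighbour).

Whole-well counts are the sum of per-tile counts over the images
covering the well (border exclusion off by default for counting, since
tiles abut; on by default nowhere else than the user asks).

## 3. Normalization and the 3SD hit rule (`screen`)

Normalization is strictly per plate: v = count / mean(dox-only controls
of that plate).  Per-compound summaries are unweighted means over
replicate plates.  Wells with zero nuclei are kept (v = 0, flagged);
they can never be one-sided hits.

The hit rule is v̄_c > μ_ctrl + k σ_ctrl with k = 3, strict inequality,
increase only.  Two estimator choices make the rule *calibrated*, i.e.
give a null exceedance probability equal to the Gaussian tail Φ(−k):

1. **Scale matching.** The compound statistic is a triplicate mean, so
   control wells are aggregated the same way: each control position is
   averaged over its replicate plates before μ and σ are computed
   (`aggregate="replicate_mean"`; per-well and robust median/MAD
   estimators remain available, as does per-plate scope).
2. **Leave-one-out re-expression.** A control well sits inside its own
   plate's normalization denominator: self-normalized controls average
   to exactly 1 with variance deflated by (1 − 1/m), whereas an
   independent compound well has mean 1 + CV²/m and variance inflated
   by (1 + 1/m) (ratio-estimator Jensen terms, m controls per plate).
   Each control value v is therefore re-expressed against the mean of
   the *other* m − 1 controls on its plate — algebraically
   v(m−1)/(m−v) — which reproduces both moments of the compound-well
   sampling distribution.  Without this, the 3SD tail is inflated by
   ~25% at m = 16.

With count noise the statistic retains a small positive skew
(≈ CV/√3 for Poisson triplicate means), which adds a few percent to the
3SD tail relative to the Gaussian value; the calibration study in the
acceptance suite therefore uses the Gaussian noise option, for which
Φ(−3) is the exact reference.  The study pools control statistics
across replicated screens (~5,000 control values): a threshold
estimated from one screen's 64 control means has a t₆₃-like null tail
(~1.9 × 10⁻³), an irreducible small-sample property of the rule itself.

**Validation** retests candidates at {0.5, 1, 3, 10} µM in triplicate.
Per compound: one-way ANOVA across {control, doses}; if it rejects at
α, per-dose Dunnett comparisons against control (Holm-adjusted Welch
t-tests as fallback).  A dose counts when adjusted p < α *and* its mean
exceeds the control mean; `validated` requires ≥ 2 such doses.  The
Dunnett p-values come from a randomized-QMC multivariate-t CDF; its
stream is pinned so verdicts are reproducible.

**QC**: per-plate Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| between no-dox and
dox-only controls (undefined windows reported as missing, never ±∞),
control CVs, and a border/interior mean ratio over compound wells as
the edge diagnostic.

## 4. Signatures and connectivity (`signatures`)

`bh_adjust` is the Benjamini–Hochberg step-up, implemented directly
(sorted p·m/rank, reverse running minimum, clip at 1) and cross-checked
in the tests against both a brute-force double-loop oracle and
statsmodels.

Signatures are the top-N (default 150) up and down genes among
BH-significant ones (padj < 0.05), ranked by LFC; ties break by smaller
raw p, then gene id, so extraction is invariant to row order.  An
option ranks by significance instead, since "top by LFC" vs "top by p"
is ambiguous in common practice.

The connectivity statistic is the classic unweighted bidirectional KS
enrichment: walk down the drug's ranking, +1/n_hit at signature genes,
−1/n_miss elsewhere; ES is the walk value of largest magnitude.  The
walk is computed in integers (steps ±n_miss/±n_hit scaled by
n_hit·n_miss) so the extreme values ±1 are floating-point exact.  The
combined score is τ = (ES_up − ES_down)/2 when the two walks deviate in
strictly opposite directions, else 0.  No cell-line summarization or
reference-distribution normalization is applied — scores are raw ES
combinations with the same qualitative contract as production
connectivity tools, chosen for transparency and testability.

Signature genes absent from the reference universe raise by default; an
`ignore_missing` relaxation drops them and records the count.  Class
enrichment among the top-k drugs (default k = 5% of drugs) is the
one-sided hypergeometric tail.

## 5. Phenotype statistics (`phenotypes`)

**Competition fitness.** With a constant growth-rate difference s
(day⁻¹) between polyQ-positive and control cells, the positive fraction
follows p_t = p₀e^(−st)/(p₀e^(−st)+1−p₀), i.e. logit p_t is linear in
t with slope −s.  The fit is weighted least squares on observed
logit proportions with binomial delta-method weights w_t = n_t p_t(1−p_t);
the estimate is exact on noiseless logistic data (the model is an
identity there).  The reported SE is the known-variance WLS error
scaled by √max(1, X²/df) — a quasi-binomial dispersion floored at 1.
The floor matters because a typical design has 3 timepoints and hence
1 residual df: a purely residual-based SE would be uselessly noisy,
while the known-variance SE alone would understate uncertainty under
any extra-binomial scatter.  Proportions of exactly 0 or 1 receive a
Haldane correction (+½ cell to each category) and are flagged; a series
degenerate at every timepoint is non-identifiable and raises.
Condition contrasts are Wald tests on Δs; a rescue is Δs < 0 versus
vehicle.

**Survival.** Default is a Welch t-test on per-replicate survival
fractions (respecting well-level clustering in the 3-replicate design);
a pooled two-proportion z-test is available, and is required when only
one replicate exists.  Outputs carry both SD and SEM per arm.

**Bends and intensities.** Welch t-tests by default everywhere a t-test
is called for (the equal-variance variant is never assumed);
Mann–Whitney optional for bends; > 2 intensity groups switch to one-way
ANOVA with Holm-adjusted pairwise Welch post-hocs.  Bend comparisons
require ≥ 5 worms per arm; intensity groups ≥ 3 cells.

**Conversion metrics.** purity = TAU⁺/DAPI⁺, efficiency =
TAU⁺/plated; zero denominators raise, and the (biologically expected)
TAU⁺ ≤ DAPI⁺ constraint is optionally enforced.

## 6. Pipeline (`workflow`)

Stages hand off through plain files (CSV/TSV/JSON) so each is
independently testable and replaceable.  Determinism is a contract:
file writes use fixed float formatting, sorted keys, and no timestamps;
the scientific-parameter hash of the config (output directory excluded)
is stamped as a comment header in every CSV, and two runs with the same
config and seed are byte-identical.  Stage timing goes to the log only.
Unknown config keys are rejected at load.  A stage failure aborts with
the stage name; partial outputs are retained for inspection.

Default pipeline conditions: 1,216 compounds with 4 planted rescuers
(1.5×) and 60 toxic compounds (0.6×), plate-factor SD 0.1, edge effect
0.95; 2,000-gene DE table with 200 planted genes per direction; 100
reference drugs with a 10-member anchored agonist class at concordance
0.7; competition at s = 0.2 vs 0.05 day⁻¹, days {0, 5, 15}, 4 × 10⁴
cells; survival at death probabilities {0.05, 0.6, 0.3} × 150 eggs × 3;
bends at means 8 vs 14 over 30 worms.  The imaging stage of the
pipeline is a 4-image self-check at 20 nuclei per image; the screen's
well counts come from the count generator directly, exercising the
stage-decoupling contract.

## 7. Known limitations

* The hit-rule calibration analysis assumes independent wells; real
  screens have spatial autocorrelation the generator only caricatures
  (one edge factor, one plate factor).
* Planted compound effects are dose-flat, so validation power estimates
  do not speak to EC50-shaped dose responses (curve fitting is
  deliberately out of scope).
* The connectivity score is the raw ES combination; absolute τ values
  are not comparable across signature sizes, only ranks within one
  query are meaningful.
* The fitness model assumes a constant growth-rate difference;
  time-varying selection (e.g. drug tachyphylaxis) would bias s toward
  an average.
* Segmentation is tuned for round, well-separated nuclei at 10×-like
  sampling; heavily clumped or irregular nuclei need parameter changes
  and may break the exact-count guarantee.
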