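# Methods

## Model

The classifier assumes that sex-chromosome dosage leaves a strong,
low-dimensional signature in array methylation:

* **ChrX.** In two-X cells, X inactivation silences (and
  hypermethylates) one copy, so most ChrX CpGs measure an intermediate
  beta (~0.2–0.8); in one-X cells the single active copy is
  hypomethylated (beta < 0.2). A minority of X-linked genes escape
  inactivation and run the other way (more methylated when only one,
  methylated, allele is present).
* **ChrY.** With a Y present, ChrY CpGs are highly methylated
  (beta > 0.6); without one, the measured signal is background and
  cross-hybridisation only.

Given labelled training data, probes carrying this signature are found
by a pooled-variance two-sample t-test on **raw** beta values per probe,
Bonferroni-corrected over the number of probes actually tested, with
selection requiring corrected p < 0.01 **and** |Δβ| > 0.2. The
Δβ condition is what keeps the selection biologically meaningful: at
cohort sizes in the hundreds, trivially small shifts reach significance.
Autosomal probes that pass are reported in the selection table but
excluded from the model.

For the model fit, all betas of a sample are standardized by the mean
and standard deviation of that sample's **autosomal** betas. Because
autosomes are unaffected by sex-chromosome dosage, this per-sample
statistic is sex-independent by construction; it removes per-array scale
and shift while preserving the ChrX/ChrY signal. Two separate PCAs are
then run on the Z-scores of a sex-balanced training subset — one on the
selected ChrX probes, one on the selected ChrY probes. PCA is computed
on probe-mean-centered data without per-probe variance scaling
(covariance PCA): the per-sample Z-score already handles scaling, and a
per-probe standardization on top would double-standardize. Each axis
keeps only the per-probe centering means, the unit-norm PC1 loading
vector, and an orientation sign chosen so that females score higher on
the ChrX axis and males higher on the ChrY axis.

Prediction projects a sample's Z-scores onto both axes
(`score = sign · Σ loading · (z − center)`) and reads the karyotype off
the quadrant: (x>0, y≤0) → 46,XX; (x≤0, y>0) → 46,XY; (x≤0, y≤0) →
45,XO; (x>0, y>0) → 47,XXY. Aneuploid calls report `predicted_sex =
"aneuploid"` rather than forcing a binary sex, and are never counted as
label mismatches.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| p threshold (Bonferroni-corrected) | 0.01 | probability | strict by design; captures only robustly dimorphic probes |
| delta threshold | 0.2 | beta units | minimum between-sex mean difference |
| balanced training size per sex | minority count | samples | equalizes the sexes before the PCA fit |
| Z-score sd convention | ddof = 0 | — | population sd; configurable, recorded in model metadata (matters only at small probe counts) |
| sample missingness cutoff | 0.10 | fraction | strictly-greater-than exclusion |
| prediction probe-missingness cap | 0.2 per axis | fraction | scores are rescaled by total/available probes up to this cap, then it is an error |
| decision boundary | 0 on both axes | score units | centering on training means puts the between-group midline near 0 |
| near-boundary annotation | 5% of the training-group separation | — | flags possible low-level mosaics; annotation only, the call stands |

Design choices where the design was genuinely open:

* **Pooled-variance (Student's) t-test rather than Welch.** The
  conventional default two-sample routine in the statistical stacks this
  kind of analysis is run with pools variances; the choice is recorded
  in model metadata.
* **Selection on raw betas, PCA on Z-scores.** The asymmetry is
  deliberate: the Δβ threshold has meaning only on the natural beta
  scale, while the projection needs per-sample standardized values.
* **Selection on all labelled samples; balancing only for the PCA.**
  The t-test tolerates mildly unequal groups, and discarding samples
  before testing wastes power; the PCA subset is balanced so neither sex
  dominates the principal axis. A `balance_before_selection` flag swaps
  this if exact balance is wanted throughout.
* **Bonferroni multiplicity = probes actually tested**, not a nominal
  platform count; the correction must match the tests performed.
* **Imputation uses within-dataset probe means** at both training and
  prediction time (probe-mean imputation after the sample-missingness
  filter; probes missing everywhere are dropped, never invented).
* **Boundary ties** (score exactly 0) fall to the "lower" side of each
  axis, so (0, 0) → 45,XO, flagged `boundary` in the output notes.
* **Manual density inspection** is replaced by `flag_abnormal_density`,
  an advisory per-sample bimodality check that warns and never drops:
  a manual step cannot be reproduced, and silent dropping hides
  problems.

## The synthetic-data generator

`generate_cohort` emulates the distributional geometry above, not real
arrays. Per cohort it draws one regime mean per probe per state —
two-X ChrX means uniform on [0.2, 0.8], one-X means uniform on
[0.02, 0.2], Y-present means uniform on [0.6, 0.95], Y-absent means
normal(0.35, 0.07) truncated to [0, 1], autosomal means from a bimodal
mixture peaked near 0.1 and 0.9 identical across karyotypes — then adds
per-sample Gaussian noise (sd 0.03) and clips to [0, 0.999]. A 7%
subset of ChrX probes models XCI escape: intermediate in two-X samples
(uniform 0.2–0.5, one methylated allele), high in one-X samples
(uniform 0.65–0.95). Probe counts default to 2000 autosomal / 400 X /
60 Y — the X:Y ratio (~14:1) mirrors what selection finds on real
450K/EPIC data at desk scale. `generate_intensity_tables` inverts betas
into paired (M, U) intensities with per-cell totals around 10^4, scaling
Y-probe totals of Y-absent samples to ~11% of the Y-present level to
mimic background-only ChrY signal; the inversion is exact to float
rounding, so `compute_beta` recovers the cohort's betas to ≤ 1e-9.

What the generator does **not** model: probe-probe correlation, batch
and dye effects, cell-composition differences, platform-specific probe
sets, or gene-level escape fidelity. Passing tests therefore demonstrate
the pipeline's correctness and its recovery of the intended geometry,
not field performance on any particular tissue or platform; on real
data the score clusters are broader and boundary-adjacent samples
(possible mosaics) occur, which is why predictions carry near-boundary
annotations.

## Numerical choices

* Beta values are strictly < 1 (the +100 offset guarantees it for
  finite intensities); readers clamp values within 1e-6 of [0, 1] and
  reject anything further out as misfed data.
* Missing values are an explicit mask end to end; text sentinels
  (`NA`, `null`, blank, `.`) are recognized on ingest and never coerced
  to 0.
* Per-sample statistics (Z-score mean/sd) and axis projections are
  computed per column over contiguous copies, so a sample's scores are
  bit-identical whether it is predicted alone or inside a batch
  (2-D reductions in the underlying numerics would otherwise change
  summation order with batch width).
* The model file stores floats via shortest-round-trip decimal
  representation, so write → read reproduces the model exactly; the
  file is versioned and validated (unit-norm loadings, disjoint probe
  sets) on read.
* Degenerate t-tests (zero pooled variance) resolve to t=0, p=1 when
  the group means agree, and p=0 when they differ.
* The training PCA centers probes on their training means; those means
  are the stored `center` vectors, which is why a sample sitting exactly
  at the training centroid scores (0, 0).

## Problem sizes

The test suite and the acceptance script run cohorts of 200–857 samples
by 2460 probes (probe counts scaled down from array scale with the X:Y
geometry preserved), 20 replicate seeds for the recovery properties, and
a 10^4-point grid for the beta formula; the full suite completes in a
few seconds on one CPU.

## Known limitations

* Text tables only; IDAT parsing is out of scope.
* No detection p-values, background or dye-bias correction, or
  between-array normalization — the method needs none of them, but the
  package will not fix pathological arrays either.
* Mosaic fraction estimation is out of scope; near-boundary annotation
  is the only mosaicism signal.
* The 0-on-both-axes decision boundary is a documented convention of
  this implementation; other implementations of the same idea may place
  boundaries differently.
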