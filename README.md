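# methylsex

Sex prediction and sex-chromosome-aneuploidy flagging from Illumina DNA
methylation arrays (450K / EPIC), using beta values only.

Public methylation datasets frequently carry missing or wrong sex
annotations, and many are deposited as plain text (beta matrices or
signal-intensity tables) rather than raw IDATs, which rules out tools
that need raw intensities. `methylsex` calls sex — and flags 45,XO
(Turner) and 47,XXY (Klinefelter) karyotypes — from nothing but a beta
matrix and a probe→chromosome annotation, which makes it usable as a QC
step on almost any deposited dataset. It is aimed at EWAS analysts and
data curators checking sample identity before downstream analysis.

## Method

For a methylated intensity M and unmethylated intensity U, the beta
value of a probe is

    β = M / (M + U + 100),

a methylation ratio in [0, 1). X-chromosome inactivation leaves two-X
genomes (46,XX; 47,XXY) with intermediate ChrX betas (one methylated,
one unmethylated allele), while one-X genomes (46,XY; 45,XO) are
hypomethylated on ChrX; ChrY probes are highly methylated when a Y is
present and show only background signal when it is not.

Training proceeds as:

1. Two-sample pooled-variance t-tests on raw betas per probe, female vs
   male; keep probes with Bonferroni-corrected p < 0.01 and
   |mean difference| > 0.2. Probes passing on autosomes are reported but
   excluded — the classifier uses sex-chromosome probes only.
2. Per-sample Z-score normalization: every beta of a sample is
   standardized by the mean and SD of that sample's *autosomal* betas
   (a sex-independent reference that removes technical scale).
3. Two separate PCAs on the Z-scores of a sex-balanced training subset:
   one over selected ChrX probes, one over selected ChrY probes. Only
   each PC1's loading vector, the per-probe centering means, and an
   orientation sign are kept.

Prediction is then a centered matrix multiplication: each sample gets an
X score (positive ⇒ two X copies) and a Y score (positive ⇒ Y present),
and the quadrant gives the call — 46,XX (x>0, y≤0), 46,XY (x≤0, y>0),
45,XO (x≤0, y≤0), 47,XXY (x>0, y>0). Because normalization and
projection are per-sample, a cohort of one sample is handled identically
to a batch.

A synthetic-cohort generator reproduces the beta-value regimes that make
this work (including XCI-escape probes and ChrY background noise), so
the whole pipeline can be exercised and tested without any downloads.

## Worked example

```python
import methylsex as ms

# train on a synthetic cohort of 100 females / 100 males
train = ms.generate_cohort(ms.GeneratorConfig(
    n_samples=200, karyotype_proportions={"46,XX": 0.5, "46,XY": 0.5}, seed=1))
model, results = ms.train_sex_model(train.beta, train.sheet, train.annotation, seed=1)
print(f"selected probes: {model.metadata['n_selected_x']} ChrX, "
      f"{model.metadata['n_selected_y']} ChrY "
      f"(of {model.metadata['n_probes_tested']} tested)")
print(f"PC1 variance explained: X {model.metadata['x_variance_explained']:.1%}, "
      f"Y {model.metadata['y_variance_explained']:.1%}")

# predict a small mixed cohort containing aneuploid samples
cohort = ms.generate_cohort(ms.GeneratorConfig(n_samples=8, seed=99))
preds = ms.estimate_sex(cohort.beta, cohort.annotation, model, cohort.sheet)
for p in preds:
    print(f"{p.sample_id}  x={p.x_score:+7.2f}  y={p.y_score:+7.2f}  "
          f"{p.karyotype_call:7s} {p.predicted_sex:9s} truth={cohort.truth[p.sample_id]}")
```

prints

```
selected probes: 337 ChrX, 59 ChrY (of 2460 tested)
PC1 variance explained: X 98.5%, Y 98.3%
S0000  x=  +4.95  y=  -4.54  46,XX   female    truth=46,XX
S0001  x=  -6.89  y=  +3.32  46,XY   male      truth=46,XY
S0002  x=  -6.63  y=  +3.33  46,XY   male      truth=46,XY
S0003  x=  +5.06  y=  +3.35  47,XXY  aneuploid truth=47,XXY
S0004  x=  +4.95  y=  -4.63  46,XX   female    truth=46,XX
S0005  x=  -6.79  y=  -4.55  45,XO   aneuploid truth=45,XO
S0006  x=  -6.88  y=  +3.34  46,XY   male      truth=46,XY
S0007  x=  +4.87  y=  -4.53  46,XX   female    truth=46,XX
```

The selection step keeps most of the 400 simulated ChrX and 60 ChrY
probes (those whose between-sex difference exceeds 0.2); each axis's
first principal component captures ~98% of the variance; positive x
means two X copies, positive y means a Y is present, and the quadrant is
the karyotype call. Samples whose labelled sex contradicts a binary
prediction get `label_mismatch=True`; aneuploid calls are flagged by the
karyotype itself, never as plain mismatches.

The same pipeline is available from the shell:

```
methylsex simulate --n-samples 200 --seed 7 --out-dir data/
methylsex train --beta data/beta.tsv --annotation data/annotation.csv \
    --samples data/samples.csv --seed 7 --out-model model.txt --report selection.tsv
methylsex predict --beta data/beta.tsv --annotation data/annotation.csv \
    --model model.txt --samples data/samples.csv --out predictions.csv
```

Trained models are versioned human-readable text (probe IDs, centering
means, PC1 loadings per axis); `methylsex predict` needs only that file
and a beta matrix. IDAT decoding is out of scope — convert IDATs to
intensity or beta text tables first.

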