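"""Synthetic methylation cohorts with ground-truth karyotypes.

The generator emulates the beta-value geometry that makes sex calling
from methylation arrays possible:

* ChrX probes in two-X genomes (46,XX; 47,XXY) sit mid-range (X
  inactivation leaves one methylated and one unmethylated allele), while
  one-X genomes (46,XY; 45,XO) are hypomethylated. A minority of X
  probes model XCI escape and run the other way (higher in males).
* ChrY probes are highly methylated when a Y is present; without a Y the
  measured signal is background/cross-hybridisation, modelled as a
  truncated normal around 0.35.
* Autosomal probes follow the usual bimodal beta distribution (peaks
  near 0.1 and 0.9), identical across karyotypes.

Per-probe class means are drawn once per cohort; each sample's betas are
its class means plus Gaussian noise, clipped into [0, 0.999]. Everything
is a fixed function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .datamodel import (
    BetaMatrix,
    DataError,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
)

KARYOTYPE_KEYS = ("46,XX", "46,XY", "45,XO", "47,XXY")
_KARYOTYPE_ALIASES = {"46XX": "46,XX", "46XY": "46,XY", "45XO": "45,XO", "47XXY": "47,XXY"}

#: upper clip for generated betas; keeps the strict beta < 1 invariant and
#: makes the intensity-table inversion (U >= 0) feasible at finite totals
BETA_CLIP_HIGH = 0.999

TWO_X = {"46,XX", "47,XXY"}
HAS_Y = {"46,XY", "47,XXY"}


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the observed beta regimes of blood methylation
    arrays: female ChrX betas mostly in 0.2-0.8, male ChrX below 0.2,
    male ChrY above 0.6, Y-absent background around mean 0.35 (sd 0.07),
    and about 7% of X probes escaping inactivation (more methylated in
    males). Probe counts 400 X / 60 Y scale down the ~14:1 ratio of
    sex-associated X to Y sites at array scale.
    """

    n_samples: int
    karyotype_proportions: Dict[str, float] = field(
        default_factory=lambda: {"46,XX": 0.4, "46,XY": 0.4, "45,XO": 0.1, "47,XXY": 0.1}
    )
    n_autosomal: int = 2000
    n_x: int = 400
    n_y: int = 60
    x_female_range: Tuple[float, float] = (0.2, 0.8)
    x_male_upper: float = 0.2
    y_male_lower: float = 0.6
    y_absent_mean: float = 0.35
    y_absent_sd: float = 0.07
    escape_fraction: float = 0.07
    noise_sd: float = 0.03
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.karyotype_proportions = {
            _KARYOTYPE_ALIASES.get(k, k): v
            for k, v in self.karyotype_proportions.items()
        }
        unknown = set(self.karyotype_proportions) - set(KARYOTYPE_KEYS)
        if unknown:
            raise DataError(f"unknown karyotypes: {sorted(unknown)}")
        total = sum(self.karyotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"karyotype proportions sum to {total!r}, not 1")
        if min(self.n_samples, self.n_autosomal, self.n_x, self.n_y) < 1:
            raise DataError("all counts must be >= 1")
        for name in ("escape_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.x_female_range
        if not (0 <= lo < hi <= 1):
            raise DataError(f"invalid x_female_range {self.x_female_range}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    sheet: SampleSheet
    truth: Dict[str, str]  # sample_id -> karyotype
    config: GeneratorConfig


def _karyotype_counts(n: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment of n samples over karyotypes."""
    keys = [k for k in KARYOTYPE_KEYS if proportions.get(k, 0.0) > 0]
    exact = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort; fully reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counts = _karyotype_counts(config.n_samples, config.karyotype_proportions)
    karyotypes: List[str] = []
    for k in KARYOTYPE_KEYS:
        karyotypes.extend([k] * counts.get(k, 0))
    karyotypes = [karyotypes[i] for i in rng.permutation(len(karyotypes))]

    auto_ids = [f"cgA{i:05d}" for i in range(config.n_autosomal)]
    x_ids = [f"cgX{i:05d}" for i in range(config.n_x)]
    y_ids = [f"cgY{i:05d}" for i in range(config.n_y)]
    probe_ids = auto_ids + x_ids + y_ids
    chrom = {p: str(1 + i % 22) for i, p in enumerate(auto_ids)}
    chrom.update({p: "X" for p in x_ids})
    chrom.update({p: "Y" for p in y_ids})
    annotation = ProbeAnnotation(chrom)

    # autosomal: bimodal mixture, identical across karyotypes
    comp = rng.random(config.n_autosomal) < 0.5
    auto_mean = np.where(
        comp,
        rng.normal(0.1, 0.05, config.n_autosomal),
        rng.normal(0.9, 0.05, config.n_autosomal),
    )
    auto_mean = np.clip(auto_mean, 0.02, 0.98)

    # ChrX: per-probe two-X and one-X regime means; escape probes invert
    lo, hi = config.x_female_range
    two_x_mean = rng.uniform(lo, hi, config.n_x)
    one_x_mean = rng.uniform(0.02, config.x_male_upper, config.n_x)
    n_escape = int(round(config.escape_fraction * config.n_x))
    escape_idx = rng.choice(config.n_x, size=n_escape, replace=False)
    # escape probes: one methylated allele in two-X cells (intermediate),
    # fully methylated on the silenced gene in one-X cells (high)
    two_x_mean[escape_idx] = rng.uniform(0.2, 0.5, n_escape)
    one_x_mean[escape_idx] = rng.uniform(0.65, 0.95, n_escape)

    # ChrY: present vs background regimes
    y_present_mean = rng.uniform(config.y_male_lower, 0.95, config.n_y)
    y_absent_mean = np.clip(
        rng.normal(config.y_absent_mean, config.y_absent_sd, config.n_y), 0.0, 1.0
    )

    n_probes = len(probe_ids)
    values = np.empty((n_probes, config.n_samples))
    a, x0, y0 = config.n_autosomal, config.n_autosomal + config.n_x, n_probes
    for j, k in enumerate(karyotypes):
        col = np.empty(n_probes)
        col[:a] = auto_mean
        col[a:x0] = two_x_mean if k in TWO_X else one_x_mean
        col[x0:y0] = y_present_mean if k in HAS_Y else y_absent_mean
        values[:, j] = col
    values = values + rng.normal(0.0, config.noise_sd, values.shape)
    values = np.clip(values, 0.0, BETA_CLIP_HIGH)

    missing = np.zeros(values.shape, dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random(values.shape) < config.missing_rate
        values = np.where(missing, np.nan, values)

    sample_ids = [f"S{j:04d}" for j in range(config.n_samples)]
    sexes = ["female" if k in ("46,XX", "45,XO") else "male" for k in karyotypes]
    beta = BetaMatrix(probe_ids, sample_ids, values, missing)
    sheet = SampleSheet(sample_ids, sexes)
    truth = dict(zip(sample_ids, karyotypes))
    return SyntheticCohort(beta, annotation, sheet, truth, config)


def generate_planted_cohort(
    n_per_sex: int = 100,
    n_autosomal: int = 2000,
    n_x: int = 400,
    n_y: int = 60,
    delta: float = 0.5,
    within_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticCohort:
    """Cohort with a fixed planted effect on every sex-chromosome probe.

    Every ChrX probe differs between the sexes by exactly ``delta`` in
    mean beta (females higher) and every ChrY probe by ``delta`` (males
    higher); autosomal probes are identical across sexes. This is the
    benchmark input for probe-selection sensitivity/specificity: planted
    probes should all be recovered, autosomes never.
    """
    rng = np.random.default_rng(seed)
    auto_ids = [f"cgA{i:05d}" for i in range(n_autosomal)]
    x_ids = [f"cgX{i:05d}" for i in range(n_x)]
    y_ids = [f"cgY{i:05d}" for i in range(n_y)]
    probe_ids = auto_ids + x_ids + y_ids
    chrom = {p: str(1 + i % 22) for i, p in enumerate(auto_ids)}
    chrom.update({p: "X" for p in x_ids})
    chrom.update({p: "Y" for p in y_ids})

    n = 2 * n_per_sex
    sexes = ["female"] * n_per_sex + ["male"] * n_per_sex
    base = (1.0 - delta) / 2  # symmetric around 0.5 so clipping is negligible
    means = np.empty((len(probe_ids), n))
    auto_mean = rng.uniform(0.2, 0.8, n_autosomal)
    means[:n_autosomal, :] = auto_mean[:, None]
    for j, sex in enumerate(sexes):
        means[n_autosomal : n_autosomal + n_x, j] = base + (delta if sex == "female" else 0.0)
        means[n_autosomal + n_x :, j] = base + (delta if sex == "male" else 0.0)
    values = np.clip(means + rng.normal(0, within_sd, means.shape), 0.001, BETA_CLIP_HIGH)

    sample_ids = [f"S{j:04d}" for j in range(n)]
    beta = BetaMatrix(probe_ids, sample_ids, values, np.zeros(values.shape, bool))
    sheet = SampleSheet(sample_ids, sexes)
    truth = {s: ("46,XX" if sex == "female" else "46,XY") for s, sex in zip(sample_ids, sexes)}
    config = GeneratorConfig(
        n_samples=n,
        karyotype_proportions={"46,XX": 0.5, "46,XY": 0.5},
        n_autosomal=n_autosomal,
        n_x=n_x,
        n_y=n_y,
        noise_sd=within_sd,
        seed=seed,
    )
    return SyntheticCohort(beta, ProbeAnnotation(chrom), sheet, truth, config)


def generate_intensity_tables(
    cohort: SyntheticCohort,
    total_intensity_scale: float = 10000.0,
    seed: Optional[int] = None,
) -> IntensityMatrix:
    """Invert betas into paired (M, U) intensities.

    Per cell a total T ~ Uniform(0.8, 1.2) x scale is drawn, raised where
    necessary so U stays nonnegative, and M = beta x (T + 100),
    U = T - M — so ``compute_beta`` recovers beta to within 1e-9.
    ChrY totals of Y-absent samples are scaled to ~11% of the Y-present
    level, mimicking the background-only signal of females on ChrY.
    """
    if seed is None:
        seed = cohort.config.seed + 1_000_003
    rng = np.random.default_rng(seed)
    beta = cohort.beta
    n_probes, n_samples = beta.shape
    T = total_intensity_scale * rng.uniform(0.8, 1.2, (n_probes, n_samples))

    y_rows = np.array(
        [cohort.annotation.chromosome_of(p) == "Y" for p in beta.probe_ids]
    )
    no_y_cols = np.array(
        [cohort.truth[s] not in HAS_Y for s in beta.sample_ids]
    )
    T[np.ix_(y_rows, no_y_cols)] *= 0.11

    vals = np.where(beta.missing_mask, 0.0, beta.values)
    with np.errstate(divide="ignore"):
        t_min = np.where(vals < 1, 100.0 * vals / (1.0 - vals), np.inf)
    T = np.maximum(T, t_min)
    M = vals * (T + 100.0)
    U = np.maximum(T - M, 0.0)  # guard fp rounding at the T = t_min boundary
    M = np.where(beta.missing_mask, np.nan, M)
    U = np.where(beta.missing_mask, np.nan, U)
    return IntensityMatrix(
        beta.probe_ids, beta.sample_ids, M, U, beta.missing_mask.copy()
    )


def scramble_labels(
    sheet: SampleSheet, n_swaps: int, seed: int
) -> Tuple[SampleSheet, List[str]]:
    """Flip the labelled sex of ``n_swaps`` randomly chosen samples.

    Returns the new sheet and the IDs whose labels were flipped (the
    ground truth for mislabel-detection tests).
    """
    labelled = [
        s for s, lab in zip(sheet.sample_ids, sheet.labelled_sex)
        if lab in ("female", "male")
    ]
    if n_swaps > len(labelled):
        raise DataError(
            f"cannot swap {n_swaps} labels; only {len(labelled)} labelled samples"
        )
    rng = np.random.default_rng(seed)
    swapped = sorted(rng.choice(labelled, size=n_swaps, replace=False).tolist())
    flip = {"female": "male", "male": "female"}
    swapped_set = set(swapped)
    new_labels = [
        flip[lab] if s in swapped_set else lab
        for s, lab in zip(sheet.sample_ids, sheet.labelled_sex)
    ]
    return SampleSheet(list(sheet.sample_ids), new_labels), swapped
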