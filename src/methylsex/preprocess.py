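"""Beta computation, sample QC, imputation, and per-sample Z-scoring.

The pipeline from a raw intensity table to a model-ready matrix is:

1. ``compute_beta``: beta = M / (M + U + 100). The +100 offset stabilizes
   low-intensity probes and bounds beta strictly below 1.
2. ``filter_samples_by_missingness``: drop samples with more than 10%
   missing probes (strict inequality).
3. ``impute_missing``: replace each missing cell by its probe's mean
   across samples; probes missing everywhere are dropped.
4. ``zscore_normalize``: standardize every probe value of a sample by the
   mean and standard deviation of that sample's *autosomal* betas. Using
   autosomes only makes the per-sample statistics sex-independent, so ChrX
   and ChrY probes carry their sex signal into the standardized values.
"""

from __future__ import annotations

import warnings
from typing import List, Tuple

import numpy as np

from .datamodel import (
    BetaMatrix,
    DataError,
    IntensityMatrix,
    ProbeAnnotation,
    ZScoreMatrix,
)

#: offset in the beta-value denominator (array-intensity units)
BETA_OFFSET = 100.0


def compute_beta(intens: IntensityMatrix, offset: float = BETA_OFFSET) -> BetaMatrix:
    """Compute beta = M / (M + U + offset) elementwise.

    Missing entries in M or U stay missing in the result. With nonnegative
    finite intensities every output lies in [0, 1).
    """
    m, u = intens.methylated, intens.unmethylated
    missing = intens.missing_mask.copy()
    with np.errstate(invalid="ignore"):
        values = m / (m + u + offset)
    values = np.where(missing, np.nan, values)
    return BetaMatrix(intens.probe_ids, intens.sample_ids, values, missing)


def filter_samples_by_missingness(
    beta: BetaMatrix, max_frac: float = 0.10
) -> Tuple[BetaMatrix, List[str]]:
    """Drop samples whose missing fraction exceeds ``max_frac`` (strict >).

    A sample with exactly ``max_frac`` missing is retained. Returns the
    filtered matrix and the list of removed sample IDs.
    """
    if not 0 <= max_frac < 1:
        raise DataError(f"max_frac must be in [0, 1), got {max_frac}")
    frac = beta.missing_mask.mean(axis=0)
    keep = frac <= max_frac
    removed = [s for s, k in zip(beta.sample_ids, keep) if not k]
    if not keep.any():
        raise DataError(
            f"all {len(beta.sample_ids)} samples exceed the missingness "
            f"threshold of {max_frac:.0%}"
        )
    if not removed:
        return beta, []
    kept_ids = [s for s, k in zip(beta.sample_ids, keep) if k]
    return beta.select_samples(kept_ids), removed


def impute_missing(beta: BetaMatrix) -> BetaMatrix:
    """Replace each missing cell by its probe's mean over observed samples.

    Probes with no observed value in any sample cannot be imputed and are
    dropped with a warning.
    """
    if not beta.sample_ids:
        raise DataError("cannot impute an empty matrix")
    if beta.n_missing == 0:
        return beta
    obs = ~beta.missing_mask
    n_obs = obs.sum(axis=1)
    all_missing = n_obs == 0
    values = np.where(obs, beta.values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probe_means = values.sum(axis=1) / n_obs
    filled = np.where(obs, beta.values, probe_means[:, None])
    if all_missing.any():
        dropped = [p for p, a in zip(beta.probe_ids, all_missing) if a]
        warnings.warn(
            f"{len(dropped)} probes with all values missing were dropped "
            f"(e.g. {dropped[:3]})",
            stacklevel=2,
        )
        keep = ~all_missing
        kept_ids = [p for p, k in zip(beta.probe_ids, keep) if k]
        filled = filled[keep]
        return BetaMatrix(
            kept_ids, beta.sample_ids, filled, np.zeros_like(filled, dtype=bool)
        )
    return BetaMatrix(
        beta.probe_ids, beta.sample_ids, filled, np.zeros_like(filled, dtype=bool)
    )


def zscore_normalize(
    beta: BetaMatrix, annotation: ProbeAnnotation, ddof: int = 0
) -> ZScoreMatrix:
    """Standardize each sample by its autosomal beta mean and sd.

    Every probe value x of sample s (autosomal and sex-chromosomal alike)
    maps to ``(x - mu_s) / sigma_s`` where mu_s and sigma_s are computed
    over sample s's autosomal probes only. The default ``ddof=0``
    (population sd) matches the numpy convention; the choice is recorded
    in model metadata because it shifts z-values at small probe counts.

    Requires a fully observed matrix (run :func:`impute_missing` first).
    """
    if beta.n_missing:
        raise DataError(
            f"{beta.n_missing} missing values present; impute before Z-scoring"
        )
    parts = annotation.partition([p for p in beta.probe_ids if p in annotation])
    auto = parts["autosomal"]
    if len(auto) < 2:
        raise DataError("need at least 2 autosomal probes for Z-scoring")
    index = {p: i for i, p in enumerate(beta.probe_ids)}
    auto_rows = np.array([index[p] for p in auto])
    auto_vals = beta.values[auto_rows]
    # per-column reductions over contiguous 1-D copies: a sample's mu/sigma
    # must not depend on how many other samples share the batch, down to
    # the last bit (numpy's 2-D axis reductions change summation order
    # with the array's width)
    n = auto_vals.shape[1]
    mu = np.array([np.ascontiguousarray(auto_vals[:, j]).mean() for j in range(n)])
    sigma = np.array(
        [np.ascontiguousarray(auto_vals[:, j]).std(ddof=ddof) for j in range(n)]
    )
    degenerate = sigma == 0
    if degenerate.any():
        bad = [s for s, d in zip(beta.sample_ids, degenerate) if d]
        raise DataError(
            f"constant autosomal profile (sd=0) for samples {bad[:5]}; "
            "Z-scoring is undefined"
        )
    z = (beta.values - mu[None, :]) / sigma[None, :]
    return ZScoreMatrix(beta.probe_ids, beta.sample_ids, z)


def flag_abnormal_density(
    beta: BetaMatrix, mid_fraction_threshold: float = 0.5
) -> List[str]:
    """Flag samples whose beta density looks non-bimodal.

    Healthy methylation profiles are bimodal, with most probes near 0 or
    1; a sample with more than ``mid_fraction_threshold`` of its observed
    betas in the mid-range (0.3, 0.7) is flagged for inspection. This is
    an advisory check: callers get the IDs and decide, nothing is dropped.
    """
    flagged = []
    for j, s in enumerate(beta.sample_ids):
        vals = beta.values[:, j][~beta.missing_mask[:, j]]
        if vals.size == 0:
            continue
        mid = np.mean((vals > 0.3) & (vals < 0.7))
        if mid > mid_fraction_threshold:
            flagged.append(s)
    if flagged:
        warnings.warn(
            f"{len(flagged)} samples have an unusually flat beta density "
            f"(possible QC problem): {flagged[:5]}",
            stacklevel=2,
        )
    return flagged
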