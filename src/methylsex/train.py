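"""Sex-associated probe selection and the two-axis PCA classifier fit.

Selection runs pooled-variance two-sample t-tests on *raw* beta values,
Bonferroni-corrects over the probes actually tested, and keeps probes
with corrected p below the p threshold and an absolute between-sex mean
beta difference above the delta threshold. Probes passing on autosomes
are reported but excluded from the model: the classifier is built from
sex-chromosome probes only.

The model itself is two independent PCAs on per-sample Z-scored betas:
one over the selected ChrX probes (first principal component separates
one-X from two-X samples) and one over the selected ChrY probes (Y
present vs absent). Only the probe-mean centers, the unit-norm PC1
loadings and an orientation sign per axis are retained, so prediction
reduces to a centered matrix multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from . import __version__
from .datamodel import (
    CHR_X,
    CHR_Y,
    BetaMatrix,
    DataError,
    ProbeAnnotation,
    SampleSheet,
    SexModel,
    ZScoreMatrix,
    validate_aligned,
)
from .preprocess import filter_samples_by_missingness, impute_missing, zscore_normalize

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_DELTA_THRESHOLD = 0.2


@dataclass
class ProbeSelectionResult:
    """Per-probe differential-methylation test outcome."""

    probe_id: str
    chromosome: str
    t_statistic: float
    raw_p: float
    bonferroni_p: float
    mean_female: float
    mean_male: float
    delta: float  # mean_female - mean_male
    selected: bool


def select_sex_associated_probes(
    beta: BetaMatrix,
    sheet: SampleSheet,
    annotation: ProbeAnnotation,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> List[ProbeSelectionResult]:
    """Test every probe for differential methylation between the sexes.

    Pooled-variance (Student's) two-sample t-tests on raw beta values,
    one per probe; Bonferroni multiplicity equals the number of probes
    tested. A probe is selected iff ``bonferroni_p < p_threshold`` and
    ``|delta| > delta_threshold``. A probe with zero pooled variance and
    equal group means gets t = 0, p = 1 (never selected).
    """
    females = [s for s in sheet.samples_with_sex("female") if s in set(beta.sample_ids)]
    males = [s for s in sheet.samples_with_sex("male") if s in set(beta.sample_ids)]
    if len(females) < 2 or len(males) < 2:
        raise DataError(
            f"need at least 2 samples per sex; have {len(females)} female, "
            f"{len(males)} male"
        )
    col = {s: j for j, s in enumerate(beta.sample_ids)}
    vals = np.where(beta.missing_mask, np.nan, beta.values)
    f_vals = vals[:, [col[s] for s in females]]
    m_vals = vals[:, [col[s] for s in males]]

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant probes are resolved explicitly below; silence the
        # catastrophic-cancellation advisory they trigger inside the t-test
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(f_vals, m_vals, axis=1, equal_var=True, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        mean_f = np.nanmean(f_vals, axis=1)
        mean_m = np.nanmean(m_vals, axis=1)

    # zero pooled variance: equal means -> no evidence (t=0, p=1);
    # different means -> perfect separation (p=0)
    with np.errstate(invalid="ignore"):
        undefined = ~np.isfinite(t)
        equal_means = np.isclose(mean_f, mean_m)
        t = np.where(undefined & equal_means, 0.0, t)
        p = np.where(undefined & equal_means, 1.0, p)
        diff_means = undefined & ~equal_means
        t = np.where(diff_means, np.sign(mean_f - mean_m) * np.inf, t)
        p = np.where(diff_means, 0.0, p)

    m_tests = len(beta.probe_ids)
    bonf = np.minimum(1.0, p * m_tests)
    delta = mean_f - mean_m
    selected = (bonf < p_threshold) & (np.abs(delta) > delta_threshold)

    results = []
    for i, probe in enumerate(beta.probe_ids):
        results.append(
            ProbeSelectionResult(
                probe_id=probe,
                chromosome=annotation.chromosome_of(probe),
                t_statistic=float(t[i]),
                raw_p=float(p[i]),
                bonferroni_p=float(bonf[i]),
                mean_female=float(mean_f[i]),
                mean_male=float(mean_m[i]),
                delta=float(delta[i]),
                selected=bool(selected[i]),
            )
        )
    return results


def balance_by_sex(sheet: SampleSheet, n_per_sex: int, seed: int) -> SampleSheet:
    """Draw ``n_per_sex`` females and males without replacement.

    Reproducible under ``seed``; the returned sheet preserves the input
    sheet's sample order.
    """
    females = sheet.samples_with_sex("female")
    males = sheet.samples_with_sex("male")
    if len(females) < n_per_sex or len(males) < n_per_sex:
        raise DataError(
            f"cannot draw {n_per_sex} per sex: {len(females)} females and "
            f"{len(males)} males available"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(females, size=n_per_sex, replace=False))
    chosen |= set(rng.choice(males, size=n_per_sex, replace=False))
    keep = [s for s in sheet.sample_ids if s in chosen]
    return sheet.subset(keep)


@dataclass
class AxisFit:
    """One chromosome axis: PC1 of the centered training Z-scores."""

    center: np.ndarray
    loadings: np.ndarray
    orientation_sign: int
    variance_explained: float
    scores: np.ndarray  # oriented training scores, aligned to input samples


def fit_axis(z: ZScoreMatrix, sexes: Sequence[str], higher: str) -> AxisFit:
    """Fit PC1 on one chromosome's Z-scores and orient it.

    ``z`` is restricted to one chromosome's selected probes (probes x
    samples); ``sexes`` aligns with ``z.sample_ids``. The orientation
    sign is chosen so the mean score of the ``higher`` sex exceeds the
    other sex's (``higher="female"`` for the ChrX axis, ``"male"`` for
    ChrY).
    """
    n_probes, n_samples = z.values.shape
    if n_probes < 2 and n_samples < 3:
        raise DataError("axis fit needs >= 2 probes or >= 3 samples")
    if n_samples < 3:
        raise DataError(f"axis fit needs >= 3 samples, got {n_samples}")
    sexes = [str(s).lower() for s in sexes]
    if len(sexes) != n_samples:
        raise DataError("sexes length does not match samples")
    if "female" not in sexes or "male" not in sexes:
        raise DataError("axis orientation requires both sexes in training data")

    X = z.values.T  # samples x probes
    center = X.mean(axis=0)
    if n_probes == 1:
        loadings = np.array([1.0])
        scores = (X - center)[:, 0]
        var_explained = 1.0
    else:
        pca = PCA(n_components=1, svd_solver="full")
        scores = pca.fit_transform(X)[:, 0]
        loadings = pca.components_[0]
        var_explained = float(pca.explained_variance_ratio_[0])

    is_higher = np.array([s == higher for s in sexes])
    sign = 1 if scores[is_higher].mean() >= scores[~is_higher].mean() else -1
    return AxisFit(
        center=center,
        loadings=loadings,
        orientation_sign=sign,
        variance_explained=var_explained,
        scores=sign * scores,
    )


def train_sex_model(
    beta: BetaMatrix,
    sheet: SampleSheet,
    annotation: ProbeAnnotation,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    n_per_sex: Optional[int] = None,
    seed: int = 0,
    balance_before_selection: bool = False,
    zscore_ddof: int = 0,
    max_missing_frac: float = 0.10,
) -> Tuple[SexModel, List[ProbeSelectionResult]]:
    """Train the full classifier; returns the model and the selection table.

    Probe selection uses all labelled samples by default; the PCA fit
    uses a seeded sex-balanced subset (``n_per_sex`` per sex, defaulting
    to the size of the minority sex). Set ``balance_before_selection`` to
    run selection on the balanced subset as well.
    """
    beta, _dropped = validate_aligned(beta, annotation)
    if beta.n_missing:
        beta, _removed = filter_samples_by_missingness(beta, max_missing_frac)
        beta = impute_missing(beta)

    present = set(beta.sample_ids)
    labelled = [
        s
        for s, lab in zip(sheet.sample_ids, sheet.labelled_sex)
        if lab in ("female", "male") and s in present
    ]
    lab_sheet = sheet.subset(labelled)
    n_f = len(lab_sheet.samples_with_sex("female"))
    n_m = len(lab_sheet.samples_with_sex("male"))
    if n_per_sex is None:
        n_per_sex = min(n_f, n_m)
    balanced = balance_by_sex(lab_sheet, n_per_sex, seed)

    sel_sheet = balanced if balance_before_selection else lab_sheet
    sel_beta = beta.select_samples(sel_sheet.sample_ids)
    results = select_sex_associated_probes(
        sel_beta, sel_sheet, annotation, p_threshold, delta_threshold
    )
    x_probes = [r.probe_id for r in results if r.selected and r.chromosome == CHR_X]
    y_probes = [r.probe_id for r in results if r.selected and r.chromosome == CHR_Y]
    n_auto_sel = sum(
        r.selected and r.chromosome not in (CHR_X, CHR_Y) for r in results
    )
    if not x_probes or not y_probes:
        raise DataError(
            f"selection found {len(x_probes)} ChrX and {len(y_probes)} ChrY "
            "probes; the training data lacks a usable sex signal"
        )

    z = zscore_normalize(
        beta.select_samples(balanced.sample_ids), annotation, ddof=zscore_ddof
    )
    x_fit = fit_axis(z.select_probes(x_probes), balanced.labelled_sex, higher="female")
    y_fit = fit_axis(z.select_probes(y_probes), balanced.labelled_sex, higher="male")

    is_f = np.array([s == "female" for s in balanced.labelled_sex])
    metadata: Dict[str, object] = {
        "package_version": __version__,
        "schema": "methylsex two-axis PCA classifier",
        "n_female_train": int(n_per_sex),
        "n_male_train": int(n_per_sex),
        "n_female_labelled": int(n_f),
        "n_male_labelled": int(n_m),
        "p_threshold": float(p_threshold),
        "delta_threshold": float(delta_threshold),
        "seed": int(seed),
        "zscore_ddof": int(zscore_ddof),
        "balance_before_selection": bool(balance_before_selection),
        "n_probes_tested": len(results),
        "n_selected_total": sum(r.selected for r in results),
        "n_selected_x": len(x_probes),
        "n_selected_y": len(y_probes),
        "n_selected_autosomal_excluded": int(n_auto_sel),
        "x_variance_explained": float(x_fit.variance_explained),
        "y_variance_explained": float(y_fit.variance_explained),
        "x_score_mean_female": float(x_fit.scores[is_f].mean()),
        "x_score_mean_male": float(x_fit.scores[~is_f].mean()),
        "y_score_mean_female": float(y_fit.scores[is_f].mean()),
        "y_score_mean_male": float(y_fit.scores[~is_f].mean()),
    }
    model = SexModel(
        x_probe_ids=x_probes,
        y_probe_ids=y_probes,
        x_center=x_fit.center,
        y_center=y_fit.center,
        x_loadings=x_fit.loadings,
        y_loadings=y_fit.loadings,
        x_orientation_sign=x_fit.orientation_sign,
        y_orientation_sign=y_fit.orientation_sign,
        metadata=metadata,
    )
    return model, results


def selection_table(results: Sequence[ProbeSelectionResult]):
    """Selection results as a pandas DataFrame (for the TSV report)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "chromosome": [r.chromosome for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "raw_p": [r.raw_p for r in results],
            "bonferroni_p": [r.bonferroni_p for r in results],
            "mean_female": [r.mean_female for r in results],
            "mean_male": [r.mean_male for r in results],
            "delta": [r.delta for r in results],
            "selected": [r.selected for r in results],
        }
    )
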