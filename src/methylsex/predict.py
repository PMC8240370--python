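"""Projection of samples onto the trained axes and karyotype calling.

A sample's position in the (ChrX-score, ChrY-score) plane determines the
call: the X axis separates one-X from two-X genomes (females higher) and
the Y axis separates Y-present from Y-absent (males higher), so the four
quadrants map to the four karyotypes:

    x > 0, y <= 0  ->  46,XX  (female)
    x <= 0, y > 0  ->  46,XY  (male)
    x <= 0, y <= 0 ->  45,XO  (Turner syndrome; aneuploid)
    x > 0, y > 0   ->  47,XXY (Klinefelter syndrome; aneuploid)

Scores are centered on the training means, which puts the between-group
midline near zero on both axes; the decision boundaries sit at 0.
Prediction is a centered matrix multiplication, so it works identically
on a cohort of one sample or one thousand.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    BetaMatrix,
    DataError,
    ProbeAnnotation,
    SampleSheet,
    SexModel,
    SexPrediction,
    ZScoreMatrix,
    validate_aligned,
)
from .preprocess import impute_missing, zscore_normalize

#: maximum tolerated fraction of an axis's probes absent at prediction time
MAX_MISSING_PROBE_FRAC = 0.2

#: |score| below this fraction of the training-group separation is
#: annotated as near-boundary (possible low-level mosaicism)
NEAR_BOUNDARY_FRAC = 0.05


def _axis_scores(
    z: ZScoreMatrix,
    probe_ids: Sequence[str],
    center: np.ndarray,
    loadings: np.ndarray,
    sign: int,
    axis_name: str,
    max_missing_frac: float,
) -> np.ndarray:
    index = {p: i for i, p in enumerate(z.probe_ids)}
    avail = [k for k, p in enumerate(probe_ids) if p in index]
    n_total, n_avail = len(probe_ids), len(avail)
    if n_total - n_avail > max_missing_frac * n_total:
        raise DataError(
            f"{n_total - n_avail} of {n_total} {axis_name}-axis model probes "
            f"are absent from the input (> {max_missing_frac:.0%} tolerated)"
        )
    rows = [index[probe_ids[k]] for k in avail]
    zc = z.values[rows, :] - center[avail, None]
    w = np.ascontiguousarray(loadings[avail])
    # column-wise dot products: a sample's score is computed from its own
    # column alone, so batch composition can never perturb it (not even in
    # the last bit via a different BLAS accumulation order)
    raw = np.array([w @ np.ascontiguousarray(zc[:, j]) for j in range(zc.shape[1])])
    # proportional rescaling keeps the score scale comparable when some
    # model probes are absent from the input platform/export
    return sign * (n_total / n_avail) * raw


def project(
    z: ZScoreMatrix,
    model: SexModel,
    max_missing_frac: float = MAX_MISSING_PROBE_FRAC,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample (x_score, y_score) from the stored PC1 coefficients.

    For each axis: ``score = sign * sum_p loading[p] * (z[p] - center[p])``
    over the model probes present in ``z``, rescaled by
    ``total/available`` when some are absent (up to ``max_missing_frac``).
    A sample's scores never depend on which other samples share the batch.
    """
    x = _axis_scores(
        z, model.x_probe_ids, model.x_center, model.x_loadings,
        model.x_orientation_sign, "X", max_missing_frac,
    )
    y = _axis_scores(
        z, model.y_probe_ids, model.y_center, model.y_loadings,
        model.y_orientation_sign, "Y", max_missing_frac,
    )
    return x, y


def classify(x_score: float, y_score: float) -> Tuple[str, str]:
    """Map an oriented score pair to (karyotype_call, predicted_sex).

    Boundaries (score exactly 0) fall to the "lower" side of each axis,
    so (0, 0) is called 45,XO.
    """
    if not (math.isfinite(x_score) and math.isfinite(y_score)):
        raise DataError(f"non-finite score pair ({x_score}, {y_score})")
    two_x = x_score > 0
    has_y = y_score > 0
    if two_x and not has_y:
        return "46,XX", "female"
    if not two_x and has_y:
        return "46,XY", "male"
    if not two_x and not has_y:
        return "45,XO", "aneuploid"
    return "47,XXY", "aneuploid"


def _note_for(x: float, y: float, model: SexModel) -> str:
    notes = []
    if x == 0 or y == 0:
        notes.append("boundary")
    md = model.metadata
    for axis, score in (("x", x), ("y", y)):
        mf = md.get(f"{axis}_score_mean_female")
        mm = md.get(f"{axis}_score_mean_male")
        if isinstance(mf, (int, float)) and isinstance(mm, (int, float)):
            sep = abs(float(mf) - float(mm))
            if sep > 0 and 0 < abs(score) < NEAR_BOUNDARY_FRAC * sep:
                notes.append(f"near-boundary ({axis.upper()} axis) - possible mosaic")
    return "; ".join(notes)


def estimate_sex(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    model: SexModel,
    sheet: Optional[SampleSheet] = None,
    max_missing_frac: float = MAX_MISSING_PROBE_FRAC,
) -> List[SexPrediction]:
    """Full prediction pipeline: impute, Z-score, project, classify.

    ``label_mismatch`` is set only for samples with a labelled sex and a
    binary (female/male) prediction; aneuploid calls are never counted as
    simple mismatches — they are flagged by the karyotype call itself.
    """
    beta, _dropped = validate_aligned(beta, annotation)
    beta = impute_missing(beta)
    ddof = int(model.metadata.get("zscore_ddof", 0))
    z = zscore_normalize(beta, annotation, ddof=ddof)
    x_scores, y_scores = project(z, model, max_missing_frac)

    labels = {}
    if sheet is not None:
        labels = dict(zip(sheet.sample_ids, sheet.labelled_sex))

    preds = []
    for j, sample in enumerate(z.sample_ids):
        x, y = float(x_scores[j]), float(y_scores[j])
        karyotype, sex = classify(x, y)
        labelled = labels.get(sample)
        if labelled not in ("female", "male"):
            labelled = None
        mismatch = None
        if labelled is not None and sex in ("female", "male"):
            mismatch = sex != labelled
        preds.append(
            SexPrediction(
                sample_id=sample,
                x_score=x,
                y_score=y,
                karyotype_call=karyotype,
                predicted_sex=sex,
                labelled_sex=labelled,
                label_mismatch=mismatch,
                note=_note_for(x, y, model),
            )
        )
    return preds
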