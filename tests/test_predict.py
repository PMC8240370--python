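"""Projection, quadrant classification, and the end-to-end prediction path."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methylsex as ms
from methylsex.datamodel import ZScoreMatrix
from methylsex.predict import classify, project


def toy_model(**overrides):
    kwargs = dict(
        x_probe_ids=["x1"], y_probe_ids=["y1"],
        x_center=np.array([0.0]), y_center=np.array([0.0]),
        x_loadings=np.array([1.0]), y_loadings=np.array([1.0]),
        x_orientation_sign=1, y_orientation_sign=1,
    )
    kwargs.update(overrides)
    return ms.SexModel(**kwargs)


class TestProject:
    def test_sample_at_center_scores_zero(self, model):
        z = ZScoreMatrix(
            model.x_probe_ids + model.y_probe_ids,
            ["s"],
            np.concatenate([model.x_center, model.y_center])[:, None],
        )
        x, y = project(z, model)
        assert x[0] == pytest.approx(0.0, abs=1e-12)
        assert y[0] == pytest.approx(0.0, abs=1e-12)

    def test_scalar_projection_on_one_probe_model(self):
        m = toy_model()
        z = ZScoreMatrix(["x1", "y1"], ["s"], np.array([[2.5], [-1.0]]))
        x, y = project(z, m)
        assert x[0] == 2.5 and y[0] == -1.0

    def test_batch_invariance_bit_for_bit(self, model, mixed_cohort):
        beta = ms.impute_missing(mixed_cohort.beta)
        z = ms.zscore_normalize(beta, mixed_cohort.annotation)
        x_all, y_all = project(z, model)
        for j in (0, 57, 199):
            sample = z.sample_ids[j]
            z_one = ms.zscore_normalize(
                beta.select_samples([sample]), mixed_cohort.annotation
            )
            x_one, y_one = project(z_one, model)
            assert x_one[0] == x_all[j]  # exact equality, not approx
            assert y_one[0] == y_all[j]

    def test_missing_probes_rescaled_up_to_cap(self):
        m = toy_model(
            x_probe_ids=[f"x{i}" for i in range(10)],
            x_center=np.zeros(10),
            x_loadings=np.full(10, 1 / np.sqrt(10)),
        )
        # only 8 of 10 X probes present: still fine (20% cap), rescaled
        probes = [f"x{i}" for i in range(8)] + ["y1"]
        z = ZScoreMatrix(probes, ["s"], np.ones((9, 1)))
        x, _ = project(z, m)
        assert x[0] == pytest.approx((10 / 8) * 8 / np.sqrt(10))
        # 7 of 10 present exceeds the cap
        z_bad = ZScoreMatrix(probes[:7] + ["y1"], ["s"], np.ones((8, 1)))
        with pytest.raises(ms.DataError, match="X-axis"):
            project(z_bad, m)


class TestClassify:
    @pytest.mark.parametrize(
        "x,y,karyotype,sex",
        [
            (5.0, -5.0, "46,XX", "female"),
            (-5.0, 5.0, "46,XY", "male"),
            (-5.0, -5.0, "45,XO", "aneuploid"),
            (5.0, 5.0, "47,XXY", "aneuploid"),
            (0.0, 0.0, "45,XO", "aneuploid"),  # ties fall to the lower side
        ],
    )
    def test_quadrant_map(self, x, y, karyotype, sex):
        assert classify(x, y) == (karyotype, sex)

    @settings(max_examples=300, derandomize=True)
    @given(
        x=st.floats(allow_nan=False, allow_infinity=False),
        y=st.floats(allow_nan=False, allow_infinity=False),
    )
    def test_every_finite_pair_gets_exactly_one_call(self, x, y):
        karyotype, sex = classify(x, y)
        assert karyotype in ("46,XX", "46,XY", "45,XO", "47,XXY")
        assert sex in ("female", "male", "aneuploid")

    def test_non_finite_rejected(self):
        with pytest.raises(ms.DataError, match="non-finite"):
            classify(float("nan"), 0.0)


class TestEstimateSex:
    def test_karyotype_truth_recovered(self, model, mixed_cohort):
        preds = ms.estimate_sex(
            mixed_cohort.beta, mixed_cohort.annotation, model, mixed_cohort.sheet
        )
        for p in preds:
            assert p.karyotype_call == mixed_cohort.truth[p.sample_id]

    def test_aneuploid_calls_not_counted_as_mismatches(self, model, mixed_cohort):
        preds = ms.estimate_sex(
            mixed_cohort.beta, mixed_cohort.annotation, model, mixed_cohort.sheet
        )
        for p in preds:
            if p.predicted_sex == "aneuploid":
                assert p.label_mismatch is None
            else:
                assert p.label_mismatch is False

    def test_flipped_label_flags_mismatch(self, model, normal_cohort):
        scrambled, swapped = ms.scramble_labels(normal_cohort.sheet, 5, seed=9)
        preds = ms.estimate_sex(
            normal_cohort.beta, normal_cohort.annotation, model, scrambled
        )
        flagged = {p.sample_id for p in preds if p.label_mismatch}
        assert flagged == set(swapped)

    def test_unlabelled_samples_have_no_mismatch_field(self, model, mixed_cohort):
        preds = ms.estimate_sex(mixed_cohort.beta, mixed_cohort.annotation, model)
        assert all(p.label_mismatch is None and p.labelled_sex is None for p in preds)

    def test_y_score_monotone_in_y_betas(self, model, mixed_cohort):
        beta = ms.impute_missing(mixed_cohort.beta)
        sample = beta.sample_ids[0]
        one = beta.select_samples([sample])
        y_rows = [
            i for i, p in enumerate(one.probe_ids)
            if p in set(model.y_probe_ids)
        ]
        scores = []
        for bump in (0.0, 0.05, 0.10, 0.15):
            vals = one.values.copy()
            vals[y_rows, 0] = np.clip(vals[y_rows, 0] + bump, 0, 0.999)
            bumped = ms.BetaMatrix(one.probe_ids, [sample], vals)
            z = ms.zscore_normalize(bumped, mixed_cohort.annotation)
            _, y = project(z, model)
            scores.append(y[0])
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_boundary_note_on_zero_scores(self):
        m = toy_model()
        karyotype, sex = classify(0.0, 0.0)
        assert karyotype == "45,XO"
        from methylsex.predict import _note_for

        assert "boundary" in _note_for(0.0, 0.0, m)
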