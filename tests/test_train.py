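"""Probe selection, balanced subsampling, and the per-chromosome PCA fit."""

import numpy as np
import pytest
from scipy import stats

import methylsex as ms
from methylsex.datamodel import ZScoreMatrix
from methylsex.train import fit_axis


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (independent code path)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def _make_two_group_beta(f_vals, m_vals, chroms=None):
    """probes x (females+males) matrix from per-group per-probe values."""
    f_vals, m_vals = np.atleast_2d(f_vals), np.atleast_2d(m_vals)
    n_probes = f_vals.shape[0]
    probe_ids = [f"p{i}" for i in range(n_probes)]
    ids = [f"f{j}" for j in range(f_vals.shape[1])] + [
        f"m{j}" for j in range(m_vals.shape[1])
    ]
    sexes = ["female"] * f_vals.shape[1] + ["male"] * m_vals.shape[1]
    beta = ms.BetaMatrix(probe_ids, ids, np.hstack([f_vals, m_vals]))
    sheet = ms.SampleSheet(ids, sexes)
    ann = ms.ProbeAnnotation(
        {p: (chroms[i] if chroms else "1") for i, p in enumerate(probe_ids)}
    )
    return beta, sheet, ann


class TestSelection:
    def test_p_values_match_textbook_oracle(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 0.9, (200, 7))
        m = rng.uniform(0.1, 0.9, (200, 4))
        beta, sheet, ann = _make_two_group_beta(f, m)
        results = ms.select_sex_associated_probes(beta, sheet, ann)
        for i, r in enumerate(results):
            t_exp, p_exp = pooled_t_oracle(f[i], m[i])
            assert r.t_statistic == pytest.approx(t_exp, rel=1e-10)
            assert r.raw_p == pytest.approx(p_exp, rel=1e-10)

    def test_identical_groups_give_null_result(self):
        vals = np.full(5, 0.4)
        beta, sheet, ann = _make_two_group_beta(vals[None, :], vals[None, :])
        (r,) = ms.select_sex_associated_probes(beta, sheet, ann)
        assert r.t_statistic == 0.0 and r.raw_p == 1.0 and not r.selected

    def test_strong_effect_selected(self):
        rng = np.random.default_rng(1)
        f = rng.normal(0.8, 0.02, (1, 50))
        m = rng.normal(0.2, 0.02, (1, 50))
        beta, sheet, ann = _make_two_group_beta(
            np.clip(f, 0, 0.99), np.clip(m, 0, 0.99), chroms=["X"]
        )
        (r,) = ms.select_sex_associated_probes(beta, sheet, ann)
        assert r.selected and abs(r.t_statistic) > 100 and abs(r.delta) > 0.5

    def test_small_delta_not_selected_despite_tiny_p(self):
        rng = np.random.default_rng(2)
        f = np.clip(rng.normal(0.50, 0.005, (1, 100)), 0, 0.99)
        m = np.clip(rng.normal(0.35, 0.005, (1, 100)), 0, 0.99)
        beta, sheet, ann = _make_two_group_beta(f, m)
        (r,) = ms.select_sex_associated_probes(beta, sheet, ann)
        assert r.bonferroni_p < 1e-20 and abs(r.delta) < 0.2 and not r.selected

    def test_bonferroni_and_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 0.9, (100, 10))
        m = np.clip(f + rng.normal(0, 0.15, (100, 10)), 0.01, 0.99)
        beta, sheet, ann = _make_two_group_beta(f, m)
        base = ms.select_sex_associated_probes(beta, sheet, ann, 0.05, 0.1)
        assert all(r.bonferroni_p >= r.raw_p for r in base)
        assert all(r.bonferroni_p == min(1.0, r.raw_p * 100) for r in base)
        n_sel = sum(r.selected for r in base)
        stricter_p = ms.select_sex_associated_probes(beta, sheet, ann, 0.01, 0.1)
        stricter_d = ms.select_sex_associated_probes(beta, sheet, ann, 0.05, 0.3)
        assert sum(r.selected for r in stricter_p) <= n_sel
        assert sum(r.selected for r in stricter_d) <= n_sel

    def test_fewer_than_two_per_sex_rejected(self):
        beta, sheet, ann = _make_two_group_beta([[0.1]], [[0.2, 0.3]])
        with pytest.raises(ms.DataError, match="at least 2"):
            ms.select_sex_associated_probes(beta, sheet, ann)


class TestBalanceBySex:
    def _sheet(self, nf, nm):
        ids = [f"f{i}" for i in range(nf)] + [f"m{i}" for i in range(nm)]
        return ms.SampleSheet(ids, ["female"] * nf + ["male"] * nm)

    def test_exact_counts_and_determinism(self):
        sheet = self._sheet(826, 832)
        sub1 = ms.balance_by_sex(sheet, 800, seed=4)
        sub2 = ms.balance_by_sex(sheet, 800, seed=4)
        assert sub1.sample_ids == sub2.sample_ids
        assert len(sub1.samples_with_sex("female")) == 800
        assert len(sub1.samples_with_sex("male")) == 800

    def test_minority_boundary_uses_all(self):
        sheet = self._sheet(5, 9)
        sub = ms.balance_by_sex(sheet, 5, seed=0)
        assert sorted(sub.samples_with_sex("female")) == [f"f{i}" for i in range(5)]

    def test_insufficient_samples_reported(self):
        with pytest.raises(ms.DataError, match="3 females"):
            ms.balance_by_sex(self._sheet(3, 10), 5, seed=0)


class TestFitAxis:
    def test_rank_one_clusters_closed_form(self):
        # two clusters at +a and -a on every probe: PC1 captures everything
        a, n_probes = 2.0, 6
        z_vals = np.hstack([np.full((n_probes, 4), a), np.full((n_probes, 4), -a)])
        z = ZScoreMatrix([f"p{i}" for i in range(n_probes)],
                         [f"s{j}" for j in range(8)], z_vals)
        fit = fit_axis(z, ["female"] * 4 + ["male"] * 4, higher="female")
        assert fit.variance_explained == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(fit.scores), a * np.sqrt(n_probes))
        assert fit.scores[:4].mean() > fit.scores[4:].mean()

    def test_orientation_sign_flips_when_needed(self):
        rng = np.random.default_rng(6)
        base = np.hstack([np.full((5, 5), 1.0), np.full((5, 5), -1.0)])
        z_vals = base + rng.normal(0, 0.05, base.shape)
        z = ZScoreMatrix([f"p{i}" for i in range(5)], [f"s{j}" for j in range(10)], z_vals)
        sexes = ["female"] * 5 + ["male"] * 5
        fit_f = fit_axis(z, sexes, higher="female")
        fit_m = fit_axis(z, sexes, higher="male")
        assert fit_f.orientation_sign == -fit_m.orientation_sign
        assert fit_f.scores[:5].mean() > fit_f.scores[5:].mean()
        assert fit_m.scores[5:].mean() > fit_m.scores[:5].mean()

    def test_single_probe_degenerates_to_centered_value(self):
        z = ZScoreMatrix(["p0"], ["s0", "s1", "s2", "s3"],
                         np.array([[2.0, 1.0, -1.0, -2.0]]))
        fit = fit_axis(z, ["female", "female", "male", "male"], higher="female")
        assert np.abs(fit.loadings[0]) == 1.0
        np.testing.assert_allclose(fit.scores, [2.0, 1.0, -1.0, -2.0])

    def test_loadings_are_covariance_eigenvector(self, normal_cohort, trained):
        model, _ = trained
        beta = normal_cohort.beta
        balanced = ms.balance_by_sex(
            normal_cohort.sheet, int(model.metadata["n_female_train"]), seed=11
        )
        z = ms.zscore_normalize(
            beta.select_samples(balanced.sample_ids), normal_cohort.annotation
        )
        zx = z.select_probes(model.x_probe_ids)
        X = zx.values.T - model.x_center
        cov = np.cov(X, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        top = eigvecs[:, -1]
        dot = abs(float(top @ model.x_loadings))
        assert dot == pytest.approx(1.0, abs=1e-8)
        # PC1 variance matches the top eigenvalue's share
        assert model.metadata["x_variance_explained"] == pytest.approx(
            eigvals[-1] / eigvals.sum(), rel=1e-6
        )

    def test_single_sex_rejected(self):
        z = ZScoreMatrix(["p0", "p1"], ["s0", "s1", "s2"], np.zeros((2, 3)))
        with pytest.raises(ms.DataError, match="both sexes"):
            fit_axis(z, ["female"] * 3, higher="female")


class TestTrainSexModel:
    def test_self_prediction_separates_sexes(self, normal_cohort, trained):
        model, _ = trained
        preds = ms.estimate_sex(
            normal_cohort.beta, normal_cohort.annotation, model, normal_cohort.sheet
        )
        by_sex = {"female": [], "male": []}
        for p in preds:
            truth = normal_cohort.sheet.sex_of(p.sample_id)
            assert p.predicted_sex == truth
            by_sex[truth].append((p.x_score, p.y_score))
        fx = [x for x, _ in by_sex["female"]]
        mx = [x for x, _ in by_sex["male"]]
        fy = [y for _, y in by_sex["female"]]
        my = [y for _, y in by_sex["male"]]
        assert min(fx) > max(mx)  # disjoint X scores, females higher
        assert min(my) > max(fy)  # disjoint Y scores, males higher

    def test_retraining_is_bit_identical(self, normal_cohort, tmp_path):
        from methylsex import io as msio

        paths = []
        for tag in ("a", "b"):
            model, _ = ms.train_sex_model(
                normal_cohort.beta, normal_cohort.sheet, normal_cohort.annotation, seed=3
            )
            path = tmp_path / f"model_{tag}.txt"
            msio.write_model(model, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_single_sex_training_rejected(self, normal_cohort):
        all_female = ms.SampleSheet(
            normal_cohort.sheet.sample_ids,
            ["female"] * len(normal_cohort.sheet.sample_ids),
        )
        with pytest.raises(ms.DataError):
            ms.train_sex_model(
                normal_cohort.beta, all_female, normal_cohort.annotation
            )

    def test_autosomal_selections_reported_but_excluded(self, trained, normal_cohort):
        model, results = trained
        sel_auto = [
            r.probe_id
            for r in results
            if r.selected and r.chromosome not in ("X", "Y")
        ]
        assert model.metadata["n_selected_autosomal_excluded"] == len(sel_auto)
        assert not set(sel_auto) & set(model.x_probe_ids + model.y_probe_ids)
        for r in results:
            assert r.selected == (
                r.bonferroni_p < 0.01 and abs(r.delta) > 0.2
            )
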