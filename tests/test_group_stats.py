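import itertools
import warnings

import numpy as np
import pytest

from lipidmsi.group_stats import (
    LMMConfig,
    LMMResult,
    TreatmentConfig,
    bh_adjust,
    call_significant,
    call_treatment_markers,
    fit_lmm,
    iterative_lmm,
    pca_scores,
    pixel_roc_auc,
    subsample_pixels,
    wilcoxon_rank_sum,
)

from conftest import make_section


class TestSubsample:
    def test_one_percent_of_400(self):
        rng = np.random.default_rng(0)
        out = subsample_pixels({"tumor": np.arange(400)}, 0.01, rng)
        assert out["tumor"].size == 4

    def test_at_least_one(self):
        rng = np.random.default_rng(0)
        out = subsample_pixels({"necrosis": np.arange(30)}, 0.01, rng)
        assert out["necrosis"].size == 1

    def test_deterministic_given_seed(self):
        a = subsample_pixels({"t": np.arange(1000)}, 0.05, np.random.default_rng(9))
        b = subsample_pixels({"t": np.arange(1000)}, 0.05, np.random.default_rng(9))
        np.testing.assert_array_equal(a["t"], b["t"])

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError):
            subsample_pixels({"t": np.array([])}, 0.01, np.random.default_rng(0))

    def test_draw_frequencies_near_fraction(self):
        # over many draws each pixel appears about `fraction` of the time
        n, draws, frac = 10_000, 100, 0.01
        rng = np.random.default_rng(123)
        counts = np.zeros(n)
        for _ in range(draws):
            counts[subsample_pixels({"t": np.arange(n)}, frac, rng)["t"]] += 1
        freq = counts / draws
        assert freq.mean() == pytest.approx(frac, rel=0.02)
        se = np.sqrt(frac * (1 - frac) / draws)
        assert np.mean(np.abs(freq - frac) > 3 * se) < 0.05


class TestFitLMM:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(21)
        for _ in range(15):
            n_g, per = 6, 12
            groups = np.repeat(np.arange(n_g), per)
            x = np.tile(np.r_[np.ones(7), np.zeros(5)], n_g)
            y = 0.8 * x + np.repeat(rng.normal(0, 1.0, n_g), per) + rng.normal(0, 1, x.size)
            beta, p, _ = fit_lmm(y, x, groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = MixedLM(y, sm.add_constant(x), groups=groups).fit(reml=True)
            assert beta == pytest.approx(ref.fe_params[1], abs=1e-4)
            assert p == pytest.approx(ref.pvalues[1], abs=5e-3)

    def test_single_group_ols_fallback(self):
        rng = np.random.default_rng(0)
        x = np.r_[np.ones(10), np.zeros(10)]
        y = x + rng.normal(0, 1, 20)
        _, _, flag = fit_lmm(y, x, np.zeros(20))
        assert flag

    def test_requires_both_levels(self):
        with pytest.raises(ValueError):
            fit_lmm(np.ones(5), np.ones(5), np.zeros(5))

    def test_type_one_error_calibrated(self):
        # null simulations: rejection rate at alpha 0.05 within [0.03, 0.07]
        rng = np.random.default_rng(42)
        n_g, per = 8, 20
        groups = np.repeat(np.arange(n_g), per)
        x = np.tile(np.r_[np.ones(10), np.zeros(10)], n_g)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = np.repeat(rng.normal(0, 0.7, n_g), per) + rng.normal(0, 1, x.size)
            _, p, _ = fit_lmm(y, x, groups)
            rej += p < 0.05
        assert 0.03 <= rej / n_sim <= 0.07

    def test_power_at_two_sigma_shift(self):
        rng = np.random.default_rng(7)
        groups = np.repeat(np.arange(5), 20)
        x = np.tile(np.r_[np.ones(10), np.zeros(10)], 5)
        rej = 0
        for _ in range(200):
            y = 2.0 * x + np.repeat(rng.normal(0, 0.5, 5), 20) + rng.normal(0, 1, 100)
            _, p, _ = fit_lmm(y, x, groups)
            rej += p < 0.05
        assert rej / 200 > 0.9


class TestBH:
    def test_closed_form_example(self):
        # step-up: q(4)=0.5, q(3)=0.03*4/3=0.04, then cummin caps q(2), q(1)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
        )

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 20)
        m = p.size
        order = np.argsort(p)
        manual = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            manual[i] = prev
        np.testing.assert_allclose(bh_adjust(p), manual, atol=1e-12)


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 1, 1], [1, 1, 1]) == 1.0

    def test_four_vs_four(self):
        assert wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)

    def test_enumeration_oracle(self):
        # exact p equals the permutation tail probability of the rank sum
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.permutation(np.arange(1.0, 11.0))[:4]
            b = rng.permutation(np.arange(20.0, 30.0))[:5]
            p = wilcoxon_rank_sum(a, b)
            pooled = np.concatenate([a, b])
            ranks = pooled.argsort().argsort() + 1.0
            obs = ranks[: a.size].sum()
            n = pooled.size
            mu = a.size * (n + 1) / 2
            count = 0
            total = 0
            for comb in itertools.combinations(range(n), a.size):
                s = ranks[list(comb)].sum()
                total += 1
                if abs(s - mu) >= abs(obs - mu) - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_minimum_sizes(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 2], [3, 4, 5])


class TestPixelROC:
    def test_perfect_separation(self):
        assert pixel_roc_auc(np.arange(100, 200.0), np.arange(100.0)) == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20000)
        b = rng.normal(0, 1, 20000)
        auc = pixel_roc_auc(a, b, subset_n=15000, rng=np.random.default_rng(1))
        assert auc == pytest.approx(0.5, abs=0.01)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.exponential(2, 500), rng.exponential(1, 500)
        r1 = pixel_roc_auc(a, b, subset_n=500)
        r2 = pixel_roc_auc(np.log1p(a), np.log1p(b), subset_n=500)
        assert r1 == r2

    def test_small_groups_used_in_full_with_warning(self):
        with pytest.warns(UserWarning):
            auc = pixel_roc_auc(np.ones(10) * 2, np.ones(10), subset_n=15000)
        assert auc == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            pixel_roc_auc(np.array([]), np.ones(5))


def _two_region_sections(effect_log2=1.0, n_samples=4, noise=0.0, seed=0):
    axis = np.arange(500.0, 520.0, 0.1)
    rng = np.random.default_rng(seed)
    sections = []
    j = np.searchsorted(axis, 510.0)
    for s in range(n_samples):
        n_px = 40
        labels = ["tumor"] * 20 + ["necrosis"] * 20
        inten = np.zeros((n_px, axis.size))
        base = 10.0 * (1 + 0.1 * s)
        inten[:20, j] = base * 2 ** effect_log2
        inten[20:, j] = base
        if noise:
            inten[:, j] *= np.exp(rng.normal(0, noise, n_px))
        sections.append(
            make_section(inten, axis, labels=labels, bio_sample=f"B{s}",
                         tech_rep=1, section_id=f"B{s}_r1")
        )
    return sections


class TestIterativeLMM:
    def test_noiseless_fold_change_exact(self):
        sections = _two_region_sections(effect_log2=1.0)
        res = iterative_lmm(sections, [510.0], LMMConfig(fraction=0.1, iterations=5, seed=0))
        assert res[0].mean_log2fc == pytest.approx(1.0, abs=1e-9)

    def test_full_fraction_single_iteration_equals_full_fit(self):
        sections = _two_region_sections(effect_log2=0.5, noise=0.3, seed=4)
        res = iterative_lmm(sections, [510.0], LMMConfig(fraction=1.0, iterations=1, seed=0))
        # oracle: direct full-data fit on the same pixels
        ys, xs, gs = [], [], []
        from lipidmsi.preprocess import pixel_mass_intensities

        for ds in sections:
            labels = ds.pixel_labels()
            mat = pixel_mass_intensities(ds, [510.0])[:, 0]
            sel = labels != "off_tissue"
            ys.append(mat[sel])
            xs.append((labels[sel] == "tumor").astype(float))
            gs.append(np.full(sel.sum(), ds.meta.bio_sample, dtype=object))
        _, p_full, _ = fit_lmm(np.concatenate(ys), np.concatenate(xs), np.concatenate(gs))
        assert res[0].mean_adj_p == pytest.approx(p_full, abs=1e-9)
        assert res[0].p_range[0] == res[0].p_range[1]

    def test_range_contains_mean(self):
        sections = _two_region_sections(effect_log2=1.0, noise=0.4, seed=8)
        (res,) = iterative_lmm(sections, [510.0], LMMConfig(fraction=0.2, iterations=10, seed=1))
        assert res.log2fc_range[0] <= res.mean_log2fc <= res.log2fc_range[1]
        assert res.p_range[0] <= res.mean_adj_p <= res.p_range[1]


class TestCallSignificant:
    def _res(self, mz, fc, p, rep):
        return LMMResult(mz, rep, fc, (fc, fc), p, (p, p))

    def test_reference_style_mass_called(self):
        results = {r: [self._res(790.6, 1.01, 0.011, r)] for r in (1, 2, 3)}
        calls = call_significant(results)
        row = calls.iloc[0]
        assert row.significant and row.direction == "tumor_up"

    def test_effect_size_gate(self):
        results = {r: [self._res(700.0, 0.4, 0.001, r)] for r in (1, 2, 3)}
        assert not call_significant(results).iloc[0].significant

    def test_single_replicate_not_called(self):
        results = {
            1: [self._res(700.0, 1.0, 0.01, 1)],
            2: [self._res(700.0, 0.1, 0.9, 2)],
            3: [self._res(700.0, 0.2, 0.8, 3)],
        }
        assert not call_significant(results).iloc[0].significant

    def test_conflicting_signs_flagged(self):
        results = {
            1: [self._res(700.0, 1.0, 0.01, 1)],
            2: [self._res(700.0, -1.0, 0.01, 2)],
            3: [self._res(700.0, 0.0, 0.9, 3)],
        }
        row = call_significant(results).iloc[0]
        assert not row.significant and row.sign_conflict


class TestCallTreatmentMarkers:
    def _analysis(self, pvals_by_rep, auc_value, fc=0.5):
        samples = [f"T{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 5)]
        arm_of = {s: ("treated" if s.startswith("T") else "control") for s in samples}
        return {
            "mzs": [700.0],
            "tech_reps": [1, 2, 3],
            "wilcoxon_p": {r: np.array([p]) for r, p in pvals_by_rep.items()},
            "log2fc": {r: np.array([fc]) for r in pvals_by_rep},
            "auc": {(s, r): np.array([auc_value]) for s in samples for r in (1, 2, 3)},
            "arm_of": arm_of,
        }

    def test_marker_called(self):
        a = self._analysis({1: 0.01, 2: 0.02, 3: 0.3}, 0.75)
        row = call_treatment_markers(a).iloc[0]
        assert row.marker and row.direction == "treated_up"
        assert row.auc == pytest.approx(0.75)

    def test_borderline_p_everywhere_fails(self):
        a = self._analysis({1: 0.06, 2: 0.06, 3: 0.06}, 0.9)
        assert not call_treatment_markers(a).iloc[0].wilcoxon_ok

    def test_auc_below_threshold_fails(self):
        a = self._analysis({1: 0.01, 2: 0.01, 3: 0.01}, 0.69)
        row = call_treatment_markers(a).iloc[0]
        assert not row.auc_ok and not row.marker

    def test_missing_replicate_adjusts_denominator(self):
        a = self._analysis({1: 0.01, 2: 0.02}, 0.75)
        a["tech_reps"] = [1, 2]
        a["auc"] = {k: v for k, v in a["auc"].items() if k[1] != 3}
        assert call_treatment_markers(a).iloc[0].marker


class TestPCA:
    def test_perfectly_correlated_variables(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        X = np.column_stack([x, 2 * x])
        _, _, evr = pca_scores(X)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_equal_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(5000, 2))
        _, _, evr = pca_scores(X)
        assert evr[0] == pytest.approx(0.5, abs=0.03)
        assert evr[1] == pytest.approx(0.5, abs=0.03)

    def test_scores_reproduce_projected_distances(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(20, 6)) @ rng.normal(0, 1, size=(6, 6))
        scores, _, _ = pca_scores(X, n_components=2)
        # oracle: full eigendecomposition of the covariance
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        proj = Xc @ V[:, ::-1][:, :2]
        d_scores = np.linalg.norm(scores[:, None] - scores[None], axis=-1)
        d_proj = np.linalg.norm(proj[:, None] - proj[None], axis=-1)
        np.testing.assert_allclose(d_scores, d_proj, atol=1e-8)

    def test_constant_column_dropped(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.warns(UserWarning):
            _, loadings, _ = pca_scores(X, n_components=1)
        assert loadings.shape[1] == 1

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(30, 4))
        _, loadings, _ = pca_scores(X)
        for comp in loadings:
            assert comp[np.argmax(np.abs(comp))] > 0
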