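"""Exhaustive pair search: pool enumeration, fits, streaming aggregates."""

import math
from itertools import combinations

import numpy as np
import pytest

from decliner import (
    build_design_matrix,
    count_models,
    enumerate_pool,
    fit_hclr_model,
    fit_pwl_pair,
    frequency_table,
    max_f1_threshold,
    pwl_eligible,
    run_pair_search,
)
from decliner.errors import DegenerateFeatureError, DomainError
from decliner.pairsearch import (
    HandcraftedFeature,
    PairModelResult,
    PairSearchAggregate,
    PWLPairConfig,
    handcrafted_values,
    pool_size,
    rank_auc,
)


class TestPoolEnumeration:
    def test_two_features_with_raw(self):
        pool = enumerate_pool(["A", "B"], include_raw=True)
        assert len(pool) == 7  # 2 raw + 5 combinations

    def test_closed_form_matches_enumeration(self):
        for n in (2, 3, 5, 8):
            names = [f"F{i}" for i in range(n)]
            for raw in (True, False):
                assert len(enumerate_pool(names, raw)) == pool_size(n, raw)

    def test_distinct_column_oracle_n10(self, rng):
        # brute force: materialise all six ordered-op columns per pair on
        # random data and count collinearity classes; A-B and B-A merge,
        # the two quotients stay distinct -> 5 per pair = 225
        names = [f"F{i}" for i in range(10)]
        cols = {n: rng.standard_normal(40) for n in names}
        seen = []
        for a, b in combinations(names, 2):
            for col in (
                cols[a] + cols[b], cols[a] - cols[b], cols[b] - cols[a],
                cols[a] * cols[b], cols[a] / cols[b], cols[b] / cols[a],
            ):
                u = col / np.linalg.norm(col)
                if not any(abs(abs(u @ v)) > 1 - 1e-9 for v in seen):
                    seen.append(u)
        assert len(seen) == len(enumerate_pool(names, include_raw=False)) == 225

    def test_model_count_formula(self):
        assert count_models(2, True) == math.comb(7, 2) == 21
        pool = enumerate_pool([f"F{i}" for i in range(5)], include_raw=False)
        assert count_models(5, False) == math.comb(len(pool), 2) == math.comb(50, 2)

    def test_cohort_scale_count_three_sig_figs(self):
        v = count_models(3388, include_raw=True)
        assert round(v / 1e14, 2) == 4.12

    def test_too_few_features(self):
        with pytest.raises(DomainError):
            enumerate_pool(["A"])
        with pytest.raises(DomainError):
            count_models(1)

    def test_quotients_are_guarded(self, rng):
        cols = {"A": rng.standard_normal(50), "B": rng.standard_normal(50)}
        cols["B"][0] = 0.0  # exact zero denominator
        v = handcrafted_values(HandcraftedFeature("div_ab", ("A", "B")), cols)
        assert np.all(np.isfinite(v))


class TestPwlPair:
    def _xor(self, rng, n=40):
        pts, ys = [], []
        for cx, cy, lab in [(2, 2, 1), (-2, -2, 1), (2, -2, 0), (-2, 2, 0)]:
            pts.append(np.column_stack([rng.normal(cx, 0.4, n), rng.normal(cy, 0.4, n)]))
            ys += [lab] * n
        P = np.vstack(pts)
        return P[:, 0], P[:, 1], np.array(ys)

    def test_xor_needs_multiple_lines(self, rng):
        x1, x2, y = self._xor(rng)
        res = fit_pwl_pair(x1, x2, y, seed=0)
        assert res.auc >= 0.95
        assert res.params["n_lines"] >= 2

    def test_linearly_separable_perfect_at_every_k(self, rng):
        y = (rng.random(60) < 0.5).astype(int)
        x1 = y * 3.0 + rng.normal(0, 0.1, 60)
        x2 = rng.standard_normal(60)
        for k in (2, 3, 4):
            res = fit_pwl_pair(x1, x2, y, n_lines=k, seed=0)
            assert res.auc == 1.0

    def test_determinism(self, rng):
        x1, x2, y = self._xor(rng, n=15)
        r1 = fit_pwl_pair(x1, x2, y, seed=4)
        r2 = fit_pwl_pair(x1, x2, y, seed=4)
        assert r1.auc == r2.auc
        assert r1.params == r2.params

    def test_flag_column_ineligible(self, rng):
        x = rng.standard_normal(20)
        flag = np.sign(rng.standard_normal(20))
        y = (rng.random(20) < 0.5).astype(int)
        with pytest.raises(DomainError, match="eligible"):
            fit_pwl_pair(x, flag, y, kinds=("continuous", "flag"), names=("x", "f"))


class TestHclr:
    def test_perfect_marker_auc_one(self, rng):
        y = (rng.random(50) < 0.3).astype(int)
        f1 = y + rng.normal(0, 0.01, 50)
        res = fit_hclr_model(f1, rng.standard_normal(50), y)
        assert res.auc == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coefficients_match_reference_fit(self, seed):
        # oracle: statsmodels unpenalised ML logistic (IRLS)
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 120
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * f1 - 0.5 * f2)))).astype(int)
        res = fit_hclr_model(f1, f2, y)
        ref = sm.Logit(y, sm.add_constant(np.column_stack([f1, f2]))).fit(disp=0, tol=1e-12)
        got = np.r_[res.params["coef"], res.params["intercept"]]
        want = np.r_[ref.params[1], ref.params[2], ref.params[0]]
        assert np.max(np.abs(got - want)) < 1e-6

    def test_swap_symmetry(self, rng):
        y = (rng.random(40) < 0.4).astype(int)
        f1, f2 = rng.standard_normal(40), rng.standard_normal(40)
        assert fit_hclr_model(f1, f2, y).auc == pytest.approx(
            fit_hclr_model(f2, f1, y).auc, abs=1e-10
        )

    def test_constant_input_skipped(self, rng):
        y = (rng.random(20) < 0.5).astype(int)
        with pytest.raises(DegenerateFeatureError):
            fit_hclr_model(np.ones(20), rng.standard_normal(20), y)


@pytest.fixture(scope="module")
def tiny_matrix(small_cohort):
    cohort, _, _ = small_cohort
    em = build_design_matrix(cohort, dataset_tag="metabolomic")
    names = pwl_eligible(em)[:4]
    return em.select(names + [f"Missing flag for {n}" for n in names[:1]])


class TestRunSearch:
    def test_pwl_pair_count(self, tiny_matrix, rapid_y):
        agg = run_pair_search(tiny_matrix, rapid_y, "PWL",
                              pwl_config=PWLPairConfig(epochs=40, restarts=1, n_lines=(2,)))
        assert agg.evaluated == math.comb(4, 2)  # the flag column is ineligible

    def test_hclr_candidate_count(self, small_cohort, rapid_y):
        cohort, _, _ = small_cohort
        em = build_design_matrix(cohort, dataset_tag="metabolomic")
        sub = em.select(em.feature_names[:6])
        agg = run_pair_search(sub, rapid_y, "HCLR")
        assert agg.evaluated == count_models(6, True) == math.comb(81, 2) == 3240

    def test_model_ceiling_enforced(self, tiny_matrix, rapid_y):
        with pytest.raises(DomainError, match="ceiling"):
            run_pair_search(tiny_matrix, rapid_y, "HCLR", model_ceiling=10)

    def test_streaming_mean_matches_two_pass(self, tiny_matrix, rapid_y):
        agg = run_pair_search(tiny_matrix, rapid_y, "PWL",
                              pwl_config=PWLPairConfig(epochs=40, restarts=1, n_lines=(2,)))
        # two-pass recomputation from the per-pair AUC map
        for feat, fa in agg.per_feature.items():
            aucs = [a for pair, a in agg.pwl_pair_auc.items() if feat in pair]
            assert fa.auc_sum / fa.model_count == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_hierarchy_pwl_at_least_linear(self, rng):
        # K>=2 hinges subsume a single linear boundary, so the PWL AUC on
        # a pair cannot fall far below the plain logistic AUC on the same
        # raw pair
        n = 80
        y = (rng.random(n) < 0.4).astype(int)
        x1 = y + rng.normal(0, 0.8, n)
        x2 = rng.standard_normal(n)
        hclr = fit_hclr_model(x1, x2, y)
        pwl = fit_pwl_pair(x1, x2, y, seed=0)
        assert hclr.auc <= pwl.auc + 0.02


class TestFrequencyTable:
    def _pwl_agg_all_high(self):
        agg = PairSearchAggregate("PWL", high_auc_threshold=0.5)
        for (a, b), auc in [(("A", "B"), 0.9), (("A", "C"), 0.8), (("B", "C"), 0.7)]:
            agg.record(PairModelResult("PWL", (a, b), auc, {}, (a, b)))
        return agg

    def test_every_feature_in_two_of_three_pairs(self):
        ft = frequency_table(self._pwl_agg_all_high())
        assert list(ft["single_frequency"]) == [2, 2, 2]

    def test_pwl_mean_over_all_models(self):
        ft = frequency_table(self._pwl_agg_all_high()).set_index("feature")
        assert ft.loc["A", "mean_auc"] == pytest.approx((0.9 + 0.8) / 2)
        assert ft.loc["A", "diff_from_overall_mean"] == pytest.approx(0.85 - 0.8)

    def test_hclr_top_decile_mean(self):
        agg = PairSearchAggregate("HCLR", high_auc_threshold=0.99)
        aucs = np.linspace(0.5, 0.9, 20)
        f = HandcraftedFeature("raw", ("A",))
        g = HandcraftedFeature("raw", ("B",))
        for a in aucs:
            agg.record(PairModelResult("HCLR", (f, g), float(a), {}, ("A", "B")))
        ft = frequency_table(agg).set_index("feature")
        k = math.ceil(0.1 * 20)
        assert ft.loc["A", "mean_auc"] == pytest.approx(np.sort(aucs)[-k:].mean())

    def test_absent_feature_listed_with_zero_frequency(self):
        ft = frequency_table(self._pwl_agg_all_high(), feature_names=["A", "B", "C", "D"])
        assert ft.set_index("feature").loc["D", "single_frequency"] == 0


class TestMaxF1Threshold:
    def test_separated_returns_lowest_positive_probability(self):
        p = np.array([0.1, 0.2, 0.7, 0.9])
        y = np.array([0, 0, 1, 1])
        assert max_f1_threshold(p, y) == 0.7

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(30)
        y = (rng.random(30) < 0.4).astype(int)

        def f1_at(t):
            pred = p >= t
            tp = np.sum(pred & (y == 1))
            denom = 2 * tp + np.sum(pred & (y == 0)) + np.sum(~pred & (y == 1))
            return 2 * tp / denom if denom else 0.0

        cands = np.unique(p)
        best = max(f1_at(t) for t in cands)
        t_got = max_f1_threshold(p, y)
        assert f1_at(t_got) == pytest.approx(best)
        # ties resolve to the lowest threshold
        winners = [t for t in cands if f1_at(t) == pytest.approx(best)]
        assert t_got == pytest.approx(min(winners))

    def test_all_identical_probabilities(self):
        y = np.array([1, 0, 1])
        assert max_f1_threshold(np.full(3, 0.4), y) == 0.4

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            max_f1_threshold(np.array([]), np.array([]))
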