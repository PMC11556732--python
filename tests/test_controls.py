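"""Factorial ANOVA, marginal-means contrasts, FDR, and control analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraltrace.controls import (
    fdr_adjust,
    label_saturation,
    light_dark_validation,
    marginal_means_contrasts,
    two_way_anova,
)


def projection_anova_oracle(y, a, b):
    """Brute-force sequential ANOVA for a balanced two-factor design via
    explicit projection matrices."""
    y = np.asarray(y, float)
    n = len(y)

    def dummies(f):
        f = np.asarray(f)
        levels = sorted(set(f))
        return np.column_stack([(f == l).astype(float) for l in levels[1:]])

    def hat(X):
        return X @ np.linalg.pinv(X.T @ X) @ X.T

    one = np.ones((n, 1))
    A, B = dummies(a), dummies(b)
    AB = np.column_stack([A[:, i] * B[:, j]
                          for i in range(A.shape[1]) for j in range(B.shape[1])])
    h0 = hat(one)
    h1 = hat(np.hstack([one, A]))
    h2 = hat(np.hstack([one, A, B]))
    h3 = hat(np.hstack([one, A, B, AB]))
    ss = [y @ (h1 - h0) @ y, y @ (h2 - h1) @ y, y @ (h3 - h2) @ y]
    ss_res = y @ (np.eye(n) - h3) @ y
    return ss, ss_res


class TestTwoWayAnova:
    def test_constant_response_has_zero_effect_ss(self):
        table = two_way_anova([5.0] * 8, ["x", "x", "y", "y"] * 2,
                              ["u"] * 4 + ["v"] * 4)
        assert (table.terms["ss"] < 1e-12).all()

    def test_balanced_interaction_closed_form(self):
        # 2x2 cells with means (0,0,0,delta), r replicates, no noise:
        # interaction SS = r * delta^2 / 4
        delta, r = 2.0, 3
        y, fa, fb = [], [], []
        for ai, av in enumerate(["x", "y"]):
            for bi, bv in enumerate(["u", "v"]):
                mean = delta if (ai, bi) == (1, 1) else 0.0
                y += [mean] * r
                fa += [av] * r
                fb += [bv] * r
        table = two_way_anova(y, fa, fb)
        inter = table.terms.set_index("term").loc["a:b", "ss"]
        assert inter == pytest.approx(r * delta**2 / 4)

    def test_matches_projection_oracle_on_random_balanced_designs(self, rng):
        for _ in range(5):
            r = 4
            fa = ["x"] * (2 * r) + ["y"] * (2 * r)
            fb = (["u"] * r + ["v"] * r) * 2
            y = rng.normal(size=4 * r)
            table = two_way_anova(y, fa, fb)
            ss_oracle, ss_res_oracle = projection_anova_oracle(y, fa, fb)
            got = table.terms.set_index("term")["ss"]
            # balanced design: Type II equals the sequential decomposition
            assert got["a"] == pytest.approx(ss_oracle[0], abs=1e-8)
            assert got["b"] == pytest.approx(ss_oracle[1], abs=1e-8)
            assert got["a:b"] == pytest.approx(ss_oracle[2], abs=1e-8)
            assert table.residual_ss == pytest.approx(ss_res_oracle, abs=1e-8)

    def test_df_sum_to_n_minus_one(self, rng):
        y = rng.normal(size=12)
        fa = ["x", "y", "z"] * 4
        fb = ["u"] * 6 + ["v"] * 6
        table = two_way_anova(y, fa, fb)
        assert table.terms["df"].sum() + table.residual_df == 11

    def test_type_one_error_calibrated_under_null(self):
        # null model: no effects; rejection rate of each term ~ alpha
        rng = np.random.default_rng(77)
        rej = 0
        reps = 200
        for _ in range(reps):
            y = rng.normal(size=16)
            fa = ["x"] * 8 + ["y"] * 8
            fb = (["u"] * 4 + ["v"] * 4) * 2
            table = two_way_anova(y, fa, fb)
            rej += table.terms.set_index("term").loc["a", "p"] <= 0.05
        lo, hi = 4, 18  # exact binomial 95% band for Binomial(200, 0.05)
        assert lo <= rej <= hi

    def test_empty_cell_with_interaction_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0, 3.0], ["x", "x", "y"], ["u", "v", "u"])


class TestMarginalMeans:
    def test_equal_cell_means_give_zero_estimate_p_one(self):
        y = [1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0]
        by = ["m1"] * 4 + ["m2"] * 4
        con = ["l", "l", "d", "d"] * 2
        results = marginal_means_contrasts(y, by, con, adjust="none")
        for r in results:
            assert r.estimate == pytest.approx(0.0)
            assert r.p == pytest.approx(1.0)

    def test_reduces_to_pooled_t_test_for_single_stratum(self, rng):
        from scipy import stats

        y1, y2 = rng.normal(size=6), rng.normal(loc=1.0, size=6)
        y = np.concatenate([y1, y2])
        con = ["a"] * 6 + ["b"] * 6
        res = marginal_means_contrasts(y, ["only"] * 12, con, adjust="none")[0]
        t_ref, p_ref = stats.ttest_ind(y1, y2)
        assert abs(res.t) == pytest.approx(abs(t_ref), rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    @pytest.mark.parametrize("adjust", ["tukey", "sidak", "bonferroni", "none"])
    def test_adjusted_p_never_below_raw(self, rng, adjust):
        y = rng.normal(size=27)
        by = ["m1", "m2", "m3"] * 9
        con = ["a"] * 9 + ["b"] * 9 + ["c"] * 9
        for r in marginal_means_contrasts(y, by, con, adjust=adjust):
            if r.estimable:
                assert r.p_adj >= r.p - 1e-12
                assert r.p_adj <= 1.0

    def test_empty_cell_flagged_not_dropped(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        by = ["m1", "m1", "m1", "m2", "m2"]
        con = ["a", "a", "b", "a", "a"]  # m2 has no "b" cell
        results = marginal_means_contrasts(y, by, con, adjust="none")
        flagged = [r for r in results if not r.estimable]
        assert len(flagged) == 1
        assert flagged[0].by_level == "m2"


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_brute_force_and_is_monotone(self, pvals):
        ours = fdr_adjust(pvals)
        ref = brute_force_bh(pvals)
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-12).all()
        # rejection set of the step-up rule is preserved at alpha = 0.05
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= 0.05 * i / m:
                k = i
        stepup_reject = np.zeros(m, bool)
        stepup_reject[order[:k]] = True
        np.testing.assert_array_equal(ours <= 0.05, stepup_reject)


class TestLightDark:
    def _table(self, light_vals, dark_vals, met="glucose"):
        rows = []
        for i, v in enumerate(light_vals):
            rows.append({"metabolite": met, "sample": f"L{i}", "enrichment": v})
        for i, v in enumerate(dark_vals):
            rows.append({"metabolite": met, "sample": f"D{i}", "enrichment": v})
        enr = pd.DataFrame(rows)
        meta = pd.DataFrame({
            "light": ["light"] * len(light_vals) + ["dark"] * len(dark_vals)},
            index=[f"L{i}" for i in range(len(light_vals))] +
                  [f"D{i}" for i in range(len(dark_vals))])
        return enr, meta

    def test_percent_excess_matches_reported_style_values(self):
        enr, meta = self._table([0.19, 0.19], [0.001, 0.001])
        out = light_dark_validation(enr, meta)
        assert out.iloc[0]["percent_excess"] == pytest.approx((0.19 - 0.001) / 0.19 * 100,
                                                              abs=1e-9)
        assert out.iloc[0]["percent_excess"] == pytest.approx(99.47, abs=0.01)

    def test_boundary_cases(self):
        enr, meta = self._table([0.2, 0.2], [0.2, 0.2])
        assert light_dark_validation(enr, meta).iloc[0]["percent_excess"] == pytest.approx(0.0)
        enr, meta = self._table([0.2, 0.2], [0.0, 0.0])
        assert light_dark_validation(enr, meta).iloc[0]["percent_excess"] == pytest.approx(100.0)

    def test_nonpositive_light_mean_flagged(self):
        enr, meta = self._table([0.0, 0.0], [0.1, 0.1])
        out = light_dark_validation(enr, meta)
        assert out.iloc[0]["flagged"]
        assert np.isnan(out.iloc[0]["percent_excess"])

    def test_requires_both_conditions(self):
        enr, meta = self._table([0.2, 0.3], [])
        with pytest.raises(ValueError):
            light_dark_validation(enr, meta)

    def test_dark_controls_average_to_full_excess_on_synthetic_data(self, small_dataset):
        from coraltrace.pipeline import correct_dataset

        spectra, meta, _ = small_dataset
        enr, _ = correct_dataset(spectra)
        labeled = meta[meta["isotope"] == "13C"]
        out = light_dark_validation(enr[enr["sample"].isin(labeled.index)], labeled)
        # labeling probability 0 in the dark: post-correction enrichment ~ 0,
        # so percent excess approaches 100
        assert out["percent_excess"].mean() > 95.0
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestLabelSaturation:
    def _series(self, values, times=(1, 3, 6, 12, 24)):
        rows = [{"metabolite": "m", "time": t, "enrichment": v}
                for t, v in zip(times, values)]
        return np.asarray(times, float), pd.DataFrame(rows)

    def test_interior_peak_bracketed_by_larger_neighbor(self):
        times, enr = self._series([0.05, 0.2, 0.21, 0.15, 0.1])
        out = label_saturation(times, enr).iloc[0]
        assert (out["t_lo"], out["t_hi"]) == (3, 6)
        assert out["flag"] == ""

    def test_monotone_series_flagged_terminal_window(self):
        times, enr = self._series([0.1, 0.2, 0.3, 0.4, 0.5])
        out = label_saturation(times, enr).iloc[0]
        assert (out["t_lo"], out["t_hi"]) == (12, 24)
        assert out["flag"] == "no_interior_peak"

    def test_constant_series_flagged_degenerate(self):
        times, enr = self._series([0.2] * 5)
        out = label_saturation(times, enr).iloc[0]
        assert out["flag"] == "degenerate_constant"

    def test_requires_three_timepoints(self):
        times, enr = self._series([0.1, 0.2], times=(1, 3))
        with pytest.raises(ValueError):
            label_saturation(times, enr)
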