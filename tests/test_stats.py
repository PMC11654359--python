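"""Gated comparisons, rank tests, FDR adjustment, agreement, regressions."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from roachtrack.stats import (
    ConfusionRates,
    GroupSample,
    agreement,
    bh_adjust,
    confusion_metrics,
    daily_trend,
    gated_compare,
    mann_whitney,
    mann_whitney_exact_enumeration,
)


def bh_stepup_oracle(pvals):
    """Literal Benjamini-Hochberg step-up: sort, scale by m/rank, cummin."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3) extreme arrangements

    def test_identical_multisets_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 2.5], [3.0, 4.0, 0.5, 6.0]
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == len(a) * len(b)
        assert p_ab == pytest.approx(p_ba)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (2, 4), (3, 3), (4, 4)])
    def test_exact_p_matches_exhaustive_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
            a, b = pooled[:n_a], pooled[n_a:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(
                mann_whitney_exact_enumeration(a, b), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_on_grid(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.9, 1.0]
        rng = np.random.default_rng(0)
        for m in range(1, 7):
            for _ in range(20):
                p = rng.choice(grid, size=m)
                np.testing.assert_allclose(
                    bh_adjust(p), bh_stepup_oracle(p), atol=1e-12
                )

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=10)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestGatedCompare:
    def test_identical_groups_null_result(self):
        g = [1.0, 2.0, 3.0]
        rep = gated_compare([GroupSample("a", g), GroupSample("b", g),
                             GroupSample("c", g)])
        assert rep.omnibus_p > 0.99
        assert not rep.significant_pairs()

    def test_normal_data_mostly_parametric(self):
        """Under exact normality the gates pass ~0.95^4 of the time."""
        rng = np.random.default_rng(42)
        parametric = 0
        for _ in range(100):
            samples = [
                GroupSample(lbl, rng.normal(10, 2, size=20))
                for lbl in ("a", "b", "c")
            ]
            rep = gated_compare(samples)
            parametric += rep.branch == "parametric"
        assert parametric >= 70

    def test_skewed_data_takes_nonparametric_branch(self):
        rng = np.random.default_rng(7)
        nonpar = 0
        for _ in range(20):
            samples = [
                GroupSample(lbl, rng.exponential(5, size=20))
                for lbl in ("a", "b", "c")
            ]
            nonpar += gated_compare(samples).branch == "nonparametric"
        assert nonpar >= 18

    def test_nonparametric_branch_contents(self):
        rng = np.random.default_rng(3)
        samples = [
            GroupSample("a", rng.exponential(1, 15)),
            GroupSample("b", rng.exponential(1, 15) + 5),
            GroupSample("c", rng.exponential(1, 15)),
        ]
        rep = gated_compare(samples)
        assert rep.branch == "nonparametric"
        assert rep.omnibus_test == "Kruskal-Wallis"
        assert len(rep.pairwise) == 3
        assert all(p.method == "Mann-Whitney" for p in rep.pairwise)
        assert all(p.p_adj >= p.p_raw - 1e-12 for p in rep.pairwise)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n=2"):
            gated_compare(
                [GroupSample("a", [1.0, 2.0]), GroupSample("b", [1, 2, 3])]
            )

    def test_dunnett_compares_against_control(self):
        rng = np.random.default_rng(0)
        samples = [
            GroupSample("air", rng.normal(0, 1, 15)),
            GroupSample("vehicle", rng.normal(0, 1, 15)),
            GroupSample("nicotine", rng.normal(3, 1, 15)),
        ]
        rep = gated_compare(samples, posthoc="dunnett", control="air")
        if rep.branch == "parametric":
            assert len(rep.pairwise) == 2
            assert all(p.pair[1] == "air" for p in rep.pairwise)

    def test_mixed_anova_branch(self):
        rng = np.random.default_rng(5)
        # 6 subjects x 2 within-levels per group, mild level effect
        samples, within = [], []
        for lbl in ("a", "b"):
            level1 = rng.normal(10, 1, 6)
            level2 = level1 + rng.normal(1, 0.3, 6)
            samples.append(GroupSample(lbl, np.concatenate([level1, level2])))
            within.append(np.array([1] * 6 + [2] * 6))
        rep = gated_compare(samples, paired_within=within)
        if rep.branch == "parametric":
            assert "mixed" in rep.omnibus_test
        assert 0 <= rep.omnibus_p <= 1


class TestAgreement:
    @staticmethod
    def _table(offset=0.0):
        rows = []
        for s in range(3):
            for q in range(1, 5):
                rows.append(
                    {"session": f"s{s}", "quadrant": q,
                     "seconds": 30.0 + 2 * s + q + offset}
                )
        return pd.DataFrame(rows)

    def test_identity_gives_zero_error(self):
        t = self._table()
        rep = agreement(t, t.copy())
        assert rep.mean_abs_error_pct == 0.0
        assert (rep.cells["norm_diff_pct"] == 0).all()

    def test_uniform_offset_is_one_percent(self):
        rep = agreement(self._table(), self._table(offset=1.2),
                        duration_s=120.0)
        np.testing.assert_allclose(rep.cells["norm_diff_pct"], 1.0)
        assert rep.mean_abs_error_pct == pytest.approx(1.0)

    def test_key_mismatch_names_offenders(self):
        hand = self._table()
        machine = self._table()
        machine.loc[0, "quadrant"] = 9
        with pytest.raises(ValueError, match="9"):
            agreement(hand, machine)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="seconds"):
            agreement(self._table().drop(columns="seconds"), self._table())


class TestConfusionMetrics:
    def test_reported_validation_rates(self):
        out = confusion_metrics(ConfusionRates(6.8, 2.0, 84.0, 7.2))
        assert out["recall_pct"] == 97.7
        assert out["precision_pct"] == 92.5

    def test_perfect_classifier(self):
        out = confusion_metrics(ConfusionRates(0.0, 0.0, 100.0, 0.0))
        assert out == {"recall_pct": 100.0, "precision_pct": 100.0,
                       "accuracy_pct": 100.0}

    def test_half_false_positives(self):
        out = confusion_metrics(ConfusionRates(50.0, 0.0, 50.0, 0.0))
        assert out["precision_pct"] == 50.0
        assert out["recall_pct"] == 100.0

    def test_undefined_metrics_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionRates(50.0, 0.0, 0.0, 50.0))

    def test_rates_must_sum_to_hundred(self):
        with pytest.raises(ValueError):
            ConfusionRates(10.0, 10.0, 10.0, 10.0)


class TestDailyTrend:
    def test_exact_line(self):
        pts = [(d, 2 * d + 1) for d in range(1, 8)]
        out = daily_trend(pts)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_constant_response(self):
        out = daily_trend([(1, 5.0), (2, 5.0), (3, 5.0)])
        assert out["slope"] == 0.0
        assert out["r_squared"] == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        days = np.arange(1, 6, dtype=float)
        values = rng.normal(10, 3, size=5)
        out = daily_trend(list(zip(days, values)))
        x = np.column_stack([np.ones(5), days])
        beta = np.linalg.solve(x.T @ x, x.T @ values)
        assert out["intercept"] == pytest.approx(beta[0])
        assert out["slope"] == pytest.approx(beta[1])

    def test_constant_day_rejected(self):
        with pytest.raises(ValueError):
            daily_trend([(3, 1.0), (3, 2.0)])
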