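"""Aggregation, correlation/error metrics and nonparametric tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nirscart import evaluate as ev


class TestAggregateByLocation:
    def test_equal_repeats(self):
        assert ev.aggregate_by_location([3.2, 3.2, 3.2]) == pytest.approx(3.2)

    def test_outlier_repeats_excluded(self):
        out = ev.aggregate_by_location([1.0, 2.0, 3.0], [True, False, True])
        assert out == pytest.approx(2.0)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.standard_normal(15)
            f = rng.random(15) > 0.3
            if not f.any():
                continue
            assert ev.aggregate_by_location(p, f) == pytest.approx(p[f].mean())

    def test_all_outliers_yields_missing(self, caplog):
        with caplog.at_level("WARNING"):
            out = ev.aggregate_by_location([1.0, 2.0], [False, False])
        assert math.isnan(out)
        assert "outliers" in caplog.text


def spearman_bruteforce(x, y):
    """Rank by hand (mid-ranks for ties), then Pearson."""
    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ev.spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ev.spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_pearson(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        assert ev.spearman(x, y) == pytest.approx(spearman_bruteforce(x, y),
                                                  abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.integers(0, 6, size=12).astype(float)  # ties likely
            b = rng.standard_normal(12)
            assert ev.spearman(a, b) == pytest.approx(spearman_bruteforce(a, b),
                                                      abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 30))
        base = ev.spearman(x, y)
        assert ev.spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert ev.spearman(x, 3 * y - 7) == pytest.approx(base, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        # well-separated values so affine maps cannot round distinct inputs
        # into float ties, which would legitimately change the ranks
        xs=st.lists(st.integers(-1000, 1000), min_size=4, max_size=20,
                    unique=True),
        scale=st.floats(0.1, 10),
        shift=st.floats(-100, 100),
    )
    def test_monotone_invariance_property(self, xs, scale, shift):
        x = np.array(xs, dtype=float) / 7.0
        y = np.sin(x) + 0.3 * x  # arbitrary, non-constant companion
        if np.ptp(y) == 0:
            return
        base = ev.spearman(x, y)
        assert ev.spearman(scale * x + shift, y) == pytest.approx(base, abs=1e-9)
        assert ev.spearman(np.arctan(x), y) == pytest.approx(base, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ev.UndefinedCorrelationError):
            ev.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_missing_pairs_dropped(self):
        x = [1.0, np.nan, 2.0, 3.0]
        y = [1.0, 5.0, 2.0, 3.0]
        assert ev.spearman(x, y) == pytest.approx(1.0)


class TestErrors:
    def test_perfect_prediction(self):
        p = np.arange(5.0)
        assert ev.rmse(p, p) == 0.0
        assert ev.nrmse(0.0, 0.0, 1.0) == 0.0

    def test_nrmse_reconstruction_superficial_pg(self):
        # printed calibration RMSE 0.174 OD over the 0.04-1.17 OD range
        assert round(ev.nrmse(0.174, 0.04, 1.17), 1) == 15.4

    def test_zero_range_rejected(self):
        with pytest.raises(ev.DegenerateNormalizationError):
            ev.nrmse(1.0, 2.0, 2.0)


def mannwhitney_enumeration(x, y):
    """Full enumeration over group assignments, coded independently."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestGroupComparisons:
    def test_identical_groups_p_one(self):
        assert ev.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == \
            pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = ev.compare_groups(x, y)
        # U = 0; 2 of the 20 assignments are as extreme (both tails)
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(mannwhitney_enumeration(x, y))

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(5)
            y = rng.standard_normal(4) + rng.random()
            assert ev.compare_groups(x, y) == pytest.approx(
                mannwhitney_enumeration(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6) + 0.5
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue
        assert ev.compare_groups(x, y) == pytest.approx(float(expected), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(5)
        x = np.round(rng.standard_normal(30), 1)
        y = np.round(rng.standard_normal(25) + 0.3, 1)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert ev.compare_groups(x, y) == pytest.approx(float(expected))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_groups([], [1.0])


class TestPairedComparison:
    def test_all_zero_differences_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            p = ev.compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0
        assert "degenerate" in caplog.text

    def test_matches_scipy_wilcoxon(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal(12)
        pvals = m + 0.4 + 0.1 * rng.standard_normal(12)
        expected = stats.wilcoxon(m - pvals, alternative="two-sided").pvalue
        assert ev.compare_paired(m, pvals) == pytest.approx(float(expected))


class TestEvaluateSets:
    def _tables(self, rho_perfect=True):
        rng = np.random.default_rng(7)
        rows, refs = [], []
        for target in ("t1", "t2"):
            ref = rng.random(12)
            for i, r in enumerate(ref):
                refs.append(dict(target=target, location_id=i, reference=r))
                for set_name in ("calibration", "validation", "test"):
                    rows.append(dict(target=target, set=set_name, fold=i % 5,
                                     location_id=i,
                                     prediction=r if rho_perfect else rng.random()))
        return pd.DataFrame(rows), pd.DataFrame(refs)

    def test_perfect_predictor(self):
        preds, refs = self._tables()
        report = ev.evaluate_sets(preds, refs)
        assert len(report) == 2 * 3
        assert np.allclose(report["spearman_rho"], 1.0)
        assert np.allclose(report["nrmse"], 0.0)

    def test_duplicate_validation_location_rejected(self):
        preds, refs = self._tables()
        dup = preds[preds["set"] == "validation"].iloc[[0]]
        with pytest.raises(ev.ProvenanceError):
            ev.evaluate_sets(pd.concat([preds, dup]), refs)


class TestSweep:
    def _setup(self):
        rng = np.random.default_rng(8)
        n_loc, n_rep = 10, 6
        m2 = rng.random(n_loc * n_rep) * 2.0
        refs, reps = [], []
        for t in ("a", "b"):
            ref = rng.random(n_loc)
            for i in range(n_loc):
                refs.append(dict(target=t, location_id=i, reference=ref[i]))
                for j in range(n_rep):
                    reps.append(dict(target=t, location_id=i,
                                     repeat_row=i * n_rep + j,
                                     prediction=ref[i] + 0.05 * rng.standard_normal()))
        ranges = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        return m2, pd.DataFrame(reps), pd.DataFrame(refs), ranges

    def test_infinite_radius_equals_plain_aggregation(self):
        m2, reps, refs, ranges = self._setup()
        out = ev.sweep_performance([1e6], m2, reps, refs, ranges)
        assert out["n_outliers"].iloc[0] == 0
        agg = reps[reps["target"] == "a"].groupby("location_id")["prediction"].mean()
        ref = refs[refs["target"] == "a"].set_index("location_id")["reference"]
        expected_rho_a = ev.spearman(agg, ref.reindex(agg.index))
        # average over the two targets must involve this exact aggregation
        out_small = ev.sweep_performance([1e6], m2 * 0, reps, refs, ranges)
        assert out["avg_spearman_rho"].iloc[0] == pytest.approx(
            out_small["avg_spearman_rho"].iloc[0])
        assert np.isfinite(expected_rho_a)

    def test_outlier_count_non_increasing(self):
        m2, reps, refs, ranges = self._setup()
        out = ev.sweep_performance([50, 75, 100, 125, 150], m2, reps, refs, ranges)
        counts = out["n_outliers"].to_numpy()
        assert np.all(counts[:-1] >= counts[1:])
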