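"""Rank statistics against enumeration oracles, plus the comparison table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from ighrep.stats import (
    StatsError,
    _bh_adjust,
    compare_features,
    correlate_features,
    mann_whitney_u,
    spearman,
    wilcoxon_signed_rank,
)


def mwu_permutation_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    mid = nx * ny / 2

    def u_of(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_of(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        mask = np.zeros(nx + ny, dtype=bool)
        mask[list(idx)] = True
        u = u_of(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_sign_oracle(diff):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    ranks = sps.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    mid = ranks.sum() / 2
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(diff))
    ]
    return np.mean([abs(w - mid) >= abs(w_obs - mid) - 1e-12 for w in ws])


class TestMannWhitney:
    def test_identical_multisets_midpoint_u(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == 4.5
        assert p > 0.9

    def test_fully_separated_extreme_u(self):
        u, _p = mann_whitney_u([1, 2, 3], [10, 20, 30])
        assert u == 0.0

    def test_constant_pooled_values_give_p_one(self):
        u, p = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
        assert (u, p) == (3.0, 1.0)

    def test_exact_p_equals_permutation_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            x, y = rng.random(5), rng.random(5)
            _u, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mwu_permutation_oracle(x, y), abs=1e-9)

    def test_empty_group_is_an_error(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences_n6(self):
        _w, p = wilcoxon_signed_rank(np.zeros(6), np.arange(1.0, 7.0))
        assert p == pytest.approx(2 / 64, abs=1e-12)

    def test_sign_enumeration_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            before = rng.random(6)
            after = before + rng.standard_normal(6)
            _w, p = wilcoxon_signed_rank(before, after)
            assert p == pytest.approx(wilcoxon_sign_oracle(after - before), abs=1e-9)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(StatsError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_and_approximate_agree_at_boundary(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            d = rng.standard_normal(25)
            exact = sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            approx = sps.wilcoxon(
                d, alternative="two-sided", method="approx", correction=True
            ).pvalue
            assert abs(exact - approx) < 0.01


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 5, 9])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x ** 3))[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            rho, _p = spearman(x, y)
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(StatsError, match="rank variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRankInvariance:
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_transform_leaves_tests_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(6), rng.random(7)
        base = mann_whitney_u(x, y)
        for f in (np.exp, lambda v: v ** 3, lambda v: 10 * v + 2):
            assert mann_whitney_u(f(x), f(y)) == pytest.approx(base)
        rho, p = spearman(x[:6], y[:6])
        rho2, p2 = spearman(np.exp(x[:6]), np.exp(y[:6]))
        assert (rho2, p2) == pytest.approx((rho, p))


class TestCompareFeatures:
    @staticmethod
    def _frame(rng, n_per_group=8, n_features=5, shift=None):
        samples = [f"s{i}" for i in range(2 * n_per_group)]
        data = rng.normal(size=(2 * n_per_group, n_features))
        if shift is not None:
            data[n_per_group:, 0] += shift
        frame = pd.DataFrame(
            data, index=samples, columns=[f"f{i}" for i in range(n_features)]
        )
        meta = pd.DataFrame({
            "sample_id": samples,
            "group": ["A"] * n_per_group + ["B"] * n_per_group,
            "pair_id": list(range(n_per_group)) * 2,
        })
        return frame, meta

    def test_constant_feature_has_p_one(self):
        rng = np.random.default_rng(41)
        frame, meta = self._frame(rng)
        frame["flat"] = 3.14
        table = compare_features(frame, meta)
        row = table[table["feature"] == "flat"].iloc[0]
        assert row["p_value"] == 1.0

    def test_planted_shift_is_top_ranked(self):
        rng = np.random.default_rng(43)
        frame, meta = self._frame(rng, n_per_group=15, n_features=8, shift=2.5)
        table = compare_features(frame, meta)
        assert table.iloc[0]["feature"] == "f0"
        assert table["p_value"].is_monotonic_increasing

    def test_bh_adjustment_dominates_raw_p(self):
        rng = np.random.default_rng(47)
        frame, meta = self._frame(rng)
        table = compare_features(frame, meta, adjust="bh")
        assert (table["adjusted_p"] >= table["p_value"] - 1e-15).all()
        expected = sps.false_discovery_control(table["p_value"].to_numpy())
        assert table["adjusted_p"].to_numpy() == pytest.approx(expected)

    def test_paired_design_uses_signed_rank(self):
        rng = np.random.default_rng(53)
        frame, meta = self._frame(rng, n_per_group=6)
        # distinct, all-positive pair differences -> exact one-tail mass 1/64
        frame["f0"] = list(range(6)) + [v + 0.1 * (v + 1) for v in range(6)]
        table = compare_features(frame, meta, design="paired")
        row = table[table["feature"] == "f0"].iloc[0]
        assert row["p_value"] == pytest.approx(2 / 64)
        assert row["direction"] == -1

    def test_paired_orphans_rejected(self):
        rng = np.random.default_rng(59)
        frame, meta = self._frame(rng)
        meta.loc[meta.index[-1], "pair_id"] = 99
        with pytest.raises(StatsError, match="unmatched pair ids"):
            compare_features(frame, meta, design="paired")

    def test_correlations_report_rho_and_n(self):
        rng = np.random.default_rng(61)
        frame, meta = self._frame(rng)
        meta["titer"] = frame["f1"].to_numpy() * 2 + rng.normal(0, 1e-6, len(frame))
        out = correlate_features(frame, meta, "titer")
        top = out.iloc[0]
        assert top["feature"] == "f1"
        assert top["rho"] == pytest.approx(1.0)
        assert top["n"] == len(frame)
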