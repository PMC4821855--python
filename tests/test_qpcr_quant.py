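"""Efficiency-corrected qPCR chain and its nonparametric statistics."""

import itertools
import math

import numpy as np
import pytest

from flaxsrna import qpcr_quant as q
from flaxsrna import synthetic_data


def mw_enumeration_oracle(a, b):
    """Two-sided exact p from value-level enumeration (independent of ranks).

    U for a subset is counted by pairwise comparisons with 0.5 for ties.
    """
    pooled = list(a) + list(b)
    na = len(a)

    def u_of(subset):
        rest = list(pooled)
        chosen = []
        for i in sorted(subset, reverse=True):
            chosen.append(rest.pop(i))
        return sum(
            1.0 if x > y_ else 0.5 if x == y_ else 0.0
            for x in chosen
            for y_ in rest
        )

    u_obs = sum(
        1.0 if x > y_ else 0.5 if x == y_ else 0.0 for x in a for y_ in b
    )
    mu = na * (len(pooled) - na) / 2.0
    us = [u_of(s) for s in itertools.combinations(range(len(pooled)), na)]
    return sum(abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us) / len(us)


class TestCteff:
    def test_perfect_doubling_identity(self):
        assert q.cteff(30.0, 1.0) == pytest.approx(30.0)

    def test_hand_value(self):
        assert q.cteff(30.0, 0.9) == pytest.approx(30 * math.log2(1.9))
        assert q.cteff(30.0, 0.9) == pytest.approx(27.780, abs=1e-3)

    def test_zero_ct(self):
        assert q.cteff(0.0, 0.5) == 0.0

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError):
            q.cteff(30.0, 0.0)
        with pytest.raises(ValueError):
            q.cteff(30.0, 1.5)


class TestDeltas:
    def test_target_equals_reference(self):
        d, sd = q.delta_cteff((25.0, 0.1), [(25.0, 0.1)])
        assert d == 0.0
        assert sd == pytest.approx(math.sqrt(0.01 + 0.01))

    def test_two_references_hand_value(self):
        d, _ = q.delta_cteff((27.78, 0.0), [(25.0, 0.0), (26.0, 0.0)])
        assert d == pytest.approx(2.28)

    def test_global_shift_cancels(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            t = float(rng.uniform(20, 30))
            refs = [(float(rng.uniform(18, 28)), 0.1) for _ in range(3)]
            shift = float(rng.uniform(-2, 2))
            d1, _ = q.delta_cteff((t, 0.1), refs)
            d2, _ = q.delta_cteff(
                (t + shift, 0.1), [(c + shift, s) for c, s in refs]
            )
            assert d2 == pytest.approx(d1)

    def test_delta_delta(self):
        dd, _ = q.delta_delta_cteff((1.0, 0.0), (-0.4, 0.0))
        assert dd == pytest.approx(1.4)
        dd_swapped, _ = q.delta_delta_cteff((-0.4, 0.0), (1.0, 0.0))
        assert dd_swapped == pytest.approx(-1.4)
        assert q.delta_delta_cteff((0.7, 0.1), (0.7, 0.2))[0] == 0.0

    def test_sd_quadrature(self):
        _, sd = q.delta_delta_cteff((1.0, 0.3), (-0.4, 0.4))
        assert sd == pytest.approx(0.5)


class TestEfficiency:
    def test_perfect_tenfold_series(self):
        series = [(c, 30 - 3.3219280948873626 * c) for c in (0.0, 1.0, 2.0, 3.0)]
        assert q.estimate_efficiency(series) == pytest.approx(1.0, abs=1e-9)

    def test_slope_minus_3_6(self):
        series = [(c, 30 - 3.6 * c) for c in (0.0, 1.0, 2.0)]
        assert q.estimate_efficiency(series) == pytest.approx(
            10 ** (1 / 3.6) - 1, abs=1e-9
        )

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            q.estimate_efficiency([(0.0, 30.0), (1.0, 27.0)])

    def test_positive_slope_invalid(self):
        with pytest.raises(ValueError):
            q.estimate_efficiency([(0.0, 30.0), (1.0, 31.0), (2.0, 33.0)])


class TestMannWhitney:
    def test_small_separated_groups(self):
        _, p = q.mann_whitney([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_three_vs_three(self):
        _, p = q.mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = q.mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_exact_equals_enumeration_oracle(self):
        rng = np.random.default_rng(62)
        for na in (2, 3, 4):
            for nb in (2, 3, 4):
                for _ in range(5):
                    a = list(rng.integers(0, 6, size=na))
                    b = list(rng.integers(0, 6, size=nb))
                    u, p = q.mann_whitney(a, b)
                    assert p == pytest.approx(mw_enumeration_oracle(a, b))

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(63)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        _, p = q.mann_whitney(a, b)
        from scipy import stats

        expected = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(float(expected))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            q.mann_whitney([], [1, 2])


class TestSpearman:
    def test_monotone_increasing(self):
        rs, _ = q.spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rs == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rs, _ = q.spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rs == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        rs, p = q.spearman([1, 2, 3, 4], [7, 7, 7, 7])
        assert math.isnan(rs) and math.isnan(p)

    def test_tied_example_matches_permutation_oracle(self):
        from scipy import stats

        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        rs, p = q.spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rs_expected = float(np.corrcoef(rx, ry)[0, 1])
        assert rs == pytest.approx(rs_expected)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        rs_all = [
            float(rxc @ ryc[list(perm)]) / denom
            for perm in itertools.permutations(range(6))
        ]
        p_expected = np.mean([abs(r) >= abs(rs) - 1e-9 for r in rs_all])
        assert p == pytest.approx(float(p_expected))

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(64)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        rs, p = q.spearman(x, y)
        assert 0 < p < 0.01 and rs > 0.7


class TestPercentileSummary:
    def test_median_only(self):
        s = q.percentile_summary([-1, 0, 2])
        assert s.median == 0.0

    def test_linear_interpolation(self):
        s = q.percentile_summary([1, 2, 3, 4])
        assert (s.q25, s.median, s.q75) == (1.75, 2.5, 3.25)

    def test_single_value(self):
        s = q.percentile_summary([3.5])
        assert s.median == s.q25 == s.q75 == s.min == s.max == 3.5

    def test_ordering_invariant(self):
        rng = np.random.default_rng(65)
        s = q.percentile_summary(rng.normal(size=50))
        assert s.min <= s.q25 <= s.median <= s.q75 <= s.max

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            q.percentile_summary([])


class TestFullChain:
    def test_e_one_reduces_to_classical_ddct(self):
        """With perfect efficiencies the corrected chain is plain ddCt."""
        rng = np.random.default_rng(66)
        for _ in range(20):
            ct_t_n, ct_t_s = rng.uniform(20, 30, 2)
            ct_r_n, ct_r_s = rng.uniform(18, 26, 2)
            d_n, _ = q.delta_cteff((q.cteff(ct_t_n, 1.0), 0), [(q.cteff(ct_r_n, 1.0), 0)])
            d_s, _ = q.delta_cteff((q.cteff(ct_t_s, 1.0), 0), [(q.cteff(ct_r_s, 1.0), 0)])
            dd, _ = q.delta_delta_cteff((d_n, 0), (d_s, 0))
            classical = (ct_t_n - ct_r_n) - (ct_t_s - ct_r_s)
            assert dd == pytest.approx(classical)

    def test_planted_effect_recovery(self):
        """ddCteff = 1.4 planted in simulated Ct data is recovered."""
        design = [
            synthetic_data.TranscriptDesign("REF1", 1.0, 21.0, {}, 0.08),
            synthetic_data.TranscriptDesign("REF2", 1.0, 22.0, {}, 0.08),
            synthetic_data.TranscriptDesign("TGT", 0.97, 24.0, {"P": 1.4}, 0.10),
        ]
        rng = np.random.default_rng(67)
        ct_df = synthetic_data.make_qpcr_dataset(
            design, {"N": 12, "P": 12}, replicate_sd=0.15, rng=rng
        )
        res = q.analyze_targets(ct_df, ["TGT"], ["REF1", "REF2"], "N", ["P"])
        assert len(res) == 1
        assert res.at[0, "delta_delta_cteff"] == pytest.approx(1.4, abs=0.2)
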