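"""Non-inferiority tests: formulas, exact signed-rank distribution, sample sizes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pulmotrunk.noninferiority import (
    PairedBinaryTable,
    noninf_distance_test,
    noninf_paired_binary,
    noninf_paired_shifted_wilcoxon,
    sample_size_noninf_t,
    sample_size_paired_binary,
    signed_rank_upper_pvalue,
    simulated_power_paired_binary,
)


class TestPairedBinary:
    def test_documented_wald_formula(self):
        # d = 0, se^2 = 40/200^2, z = 0.1 / sqrt(0.001)
        res = noninf_paired_binary(PairedBinaryTable(80, 20, 20, 80), margin=0.1)
        assert res.statistic == pytest.approx(0.1 / np.sqrt(0.001))
        assert res.p_value == pytest.approx(stats.norm.sf(res.statistic))
        assert res.decision

    def test_identical_perfect_raters_flagged_degenerate(self):
        res = noninf_paired_binary(PairedBinaryTable(100, 0, 0, 0), margin=0.1)
        assert res.degenerate and res.decision and res.p_value == 0.0

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            PairedBinaryTable(0, 0, 0, 0)
        with pytest.raises(ValueError):
            PairedBinaryTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            noninf_paired_binary(PairedBinaryTable(1, 1, 1, 1), margin=0.0)

    @given(
        st.tuples(*[st.integers(0, 60)] * 4).filter(lambda t: sum(t) > 0 and t[1] + t[2] > 0),
        st.floats(0.01, 0.3),
        st.floats(0.01, 0.3),
    )
    def test_larger_margin_never_increases_p(self, cells, m1, m2):
        lo, hi = sorted((m1, m2))
        table = PairedBinaryTable(*cells)
        assert noninf_paired_binary(table, hi).p_value <= noninf_paired_binary(table, lo).p_value


class TestShiftedWilcoxon:
    def test_equal_methods_give_most_extreme_one_sided_outcome(self):
        res = noninf_paired_shifted_wilcoxon(np.ones(10), np.ones(10), margin=0.25)
        assert res.p_value == pytest.approx(2.0**-10)
        assert res.decision

    def test_symmetric_differences_with_zero_margin_near_half(self):
        a = np.array([1.0, -1.0] * 5)
        res = noninf_paired_shifted_wilcoxon(a, np.zeros(10), margin=0.0)
        assert 0.4 <= res.p_value <= 0.7
        assert not res.decision

    def test_minimum_pairs_and_length_mismatch(self):
        with pytest.raises(ValueError):
            noninf_paired_shifted_wilcoxon([1.0] * 3, [1.0] * 3, margin=0.25)
        with pytest.raises(ValueError):
            noninf_paired_shifted_wilcoxon([1.0] * 8, [1.0] * 7, margin=0.25)

    def test_all_zero_shifted_differences_flagged(self):
        a = np.zeros(8)
        res = noninf_paired_shifted_wilcoxon(a, a, margin=0.0)
        assert res.degenerate and res.p_value == 1.0

    def test_exact_pvalue_matches_full_sign_enumeration(self, rng):
        """2^n enumeration over signed midranks, n <= 10, tied magnitudes included."""
        for _ in range(150):
            n = int(rng.integers(1, 11))
            d = rng.integers(-3, 4, size=n).astype(float)
            d = d[d != 0]
            if d.size == 0:
                continue
            w_obs, p = signed_rank_upper_pvalue(d)
            ranks = stats.rankdata(np.abs(d))
            m = d.size
            count = sum(
                1
                for mask in range(2**m)
                if sum(ranks[i] for i in range(m) if (mask >> i) & 1) >= w_obs - 1e-9
            )
            assert p == pytest.approx(count / 2**m, abs=1e-12)

    def test_normal_approximation_continuous_with_exact_regime(self, rng):
        d = rng.normal(0.3, 1.0, 40)  # n > 25 -> normal path
        _, p = signed_rank_upper_pvalue(d)
        res = stats.wilcoxon(d, alternative="greater", correction=False, mode="approx")
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_larger_margin_never_increases_p(self, m1, m2):
        lo, hi = sorted((m1, m2))
        a = np.array([0.2, -0.4, 0.7, -0.1, 0.3, -0.6, 0.5, 0.05])
        b = np.zeros(8)
        p_lo = noninf_paired_shifted_wilcoxon(a, b, lo).p_value
        p_hi = noninf_paired_shifted_wilcoxon(a, b, hi).p_value
        assert p_hi <= p_lo + 1e-12


class TestDistanceTest:
    def test_identical_methods_degenerate_non_inferior(self):
        a = np.full(50, 7.0)
        res = noninf_distance_test(a, a, margin_mm=5.0)
        assert res.degenerate and res.decision

    def test_matches_one_sided_t_on_shifted_differences(self, rng):
        a = rng.normal(8, 3, 30)
        b = rng.normal(8, 3, 30)
        res = noninf_distance_test(a, b, margin_mm=5.0)
        ref = stats.ttest_1samp(b - a + 5.0, 0.0, alternative="greater")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            noninf_distance_test([1.0], [2.0])


class TestSampleSizeT:
    def test_normal_approximation_then_t_correction(self):
        # effect (true_diff+margin)/sd = 0.5: normal formula gives 25, t-corrected 27
        assert sample_size_noninf_t(0.8, 0.05, margin=5.0, sd=10.0, true_diff=0.0) == 27

    @pytest.mark.parametrize("margin,sd,true_diff", [(5, 10, 0), (2, 6, 1), (0.25, 1.0, 0.1)])
    def test_agrees_with_noncentral_t_power_bisection(self, margin, sd, true_diff):
        """Independent oracle: scan n upward on the exact noncentral-t power curve."""
        effect = (true_diff + margin) / sd
        n = 2
        while True:
            crit = stats.t.ppf(0.95, n - 1)
            power = stats.nct.sf(crit, n - 1, effect * np.sqrt(n))
            if power >= 0.8:
                break
            n += 1
        assert sample_size_noninf_t(0.8, 0.05, margin, sd, true_diff) == pytest.approx(n, abs=1)

    def test_more_power_needs_more_samples(self):
        n80 = sample_size_noninf_t(0.8, 0.05, 5.0, 10.0)
        n999 = sample_size_noninf_t(0.999, 0.05, 5.0, 10.0)
        assert n999 > n80

    def test_non_positive_effect_is_impossible_design(self):
        with pytest.raises(ValueError):
            sample_size_noninf_t(0.8, 0.05, margin=5.0, sd=10.0, true_diff=-5.0)


class TestSampleSizePairedBinary:
    def test_margin_and_power_monotonicity(self):
        base = dict(alpha=0.05, assumed_accuracy_a=0.9, assumed_accuracy_b=0.9, discordance=0.1)
        assert sample_size_paired_binary(0.8, margin=0.2, **base) <= sample_size_paired_binary(
            0.8, margin=0.1, **base
        )
        assert sample_size_paired_binary(0.9, margin=0.1, **base) > sample_size_paired_binary(
            0.8, margin=0.1, **base
        )

    def test_inconsistent_design_rejected(self):
        with pytest.raises(ValueError):
            sample_size_paired_binary(0.8, 0.05, 0.1, 0.99, 0.5, discordance=0.01)
        with pytest.raises(ValueError):
            sample_size_paired_binary(0.8, 0.05, 0.05, 0.7, 0.9, discordance=0.3)

    def test_simulated_size_matches_independent_power_scan(self):
        """Brute-force scan over n (step 1) with the same per-n seed derivation."""
        kwargs = dict(power=0.8, alpha=0.05, margin=0.1,
                      assumed_accuracy_a=0.9, assumed_accuracy_b=0.9, discordance=0.1)
        got = sample_size_paired_binary(**kwargs, method="simulate", n_sims=3000, seed=17)
        n = max(1, sample_size_paired_binary(**kwargs) // 2)
        while True:
            pw = simulated_power_paired_binary(
                n, 0.9, 0.9, 0.1, margin=0.1, alpha=0.05, n_sims=3000, seed=17 + 1000003 * n
            )
            if pw >= 0.8:
                break
            n += 1
        assert got == n
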