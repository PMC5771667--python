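"""Closed-form population genetics: worked examples and consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupfate.popgen import (
    PopGenParams,
    competition_dynamics,
    concurrence_and_global_fixation,
    duplication_balance,
    duplication_frequency_dynamics,
    effective_population_size,
    fixation_stats,
    mutant_supply,
    ratio_from_frequency,
    recurrent_mutant_dynamics,
    successive_fixation_time,
)


class TestCompetition:
    def test_neutral_is_constant(self):
        traj = competition_dynamics(0.3, 0.0, np.arange(100))
        np.testing.assert_allclose(traj.f, traj.f[0])

    def test_doubling_time(self):
        traj = competition_dynamics(1.0, 0.001, [1000.0])
        assert traj.r[0] == pytest.approx(2.0)
        assert traj.f[0] == pytest.approx(2.0 / 3.0)

    @given(st.floats(min_value=1e-4, max_value=0.999))
    @settings(max_examples=30, deadline=None)
    def test_frequency_ratio_inverse(self, f):
        r = ratio_from_frequency(f)
        assert r / (1 + r) == pytest.approx(f, rel=1e-9)

    def test_invalid_r0(self):
        with pytest.raises(ValueError):
            competition_dynamics(0.0, 0.1, [1.0])


class TestFixationStats:
    def test_neutral_probability(self):
        st_ = fixation_stats(0.0, 2e8, "neutral")
        assert st_.P_fix == pytest.approx(5e-9)
        assert st_.t_fix == pytest.approx(4e8)

    def test_punctual(self):
        st_ = fixation_stats(0.0019, 2e8, "punctual")
        assert st_.P_fix == pytest.approx(0.0038)
        assert st_.t_half == pytest.approx(st_.t_fix / 2)
        assert st_.t_half == pytest.approx(math.log2(2e8) / 0.0019)

    def test_duplication_effective_selection(self):
        st_ = fixation_stats(0.0019, 2e8, "duplication", mu_d=4.1e-4)
        assert st_.P_fix == pytest.approx(2 * (0.0019 - 4.1e-4))
        assert st_.P_fix == pytest.approx(0.00298, abs=1e-5)

    def test_duplication_reduces_to_punctual_without_deletion(self):
        a = fixation_stats(0.002, 1e8, "duplication", mu_d=0.0)
        b = fixation_stats(0.002, 1e8, "punctual")
        assert a.P_fix == b.P_fix and a.t_fix == b.t_fix

    def test_duplication_not_fixable_below_deletion_rate(self):
        st_ = fixation_stats(1e-4, 1e8, "duplication", mu_d=4.4e-2)
        assert not st_.fixable and st_.P_fix == 0.0

    def test_recurrent_regime(self):
        st_ = fixation_stats(0.01, 1e4, "recurrent", mu_b=1e-5)
        assert st_.P_fix == 1.0
        assert st_.t_fix == pytest.approx(math.log2(1e4 * 0.01 / 1e-5) / 0.01)

    def test_invalid(self):
        with pytest.raises(ValueError):
            fixation_stats(-0.1, 1e4, "punctual")
        with pytest.raises(ValueError):
            fixation_stats(0.1, 1e4, "unknown")


class TestRecurrentDynamics:
    def test_large_supply_intercept(self):
        """At S*t = 0 the ratio equals the supply-selection balance mu_b/S."""
        traj = recurrent_mutant_dynamics(1e-4, 1e5, 100.0, 0.01, [0.0])
        assert traj.r[0] == pytest.approx(1e-4 / 0.01)
        assert traj.delay is None

    def test_small_supply_delay(self):
        traj = recurrent_mutant_dynamics(1e-7, 1e5, 100.0, 0.01, [0.0])
        assert traj.delay == pytest.approx(math.log2(100) / 1e-2, rel=1e-6)
        assert traj.delay == pytest.approx(664, abs=1)

    def test_branches_agree_at_boundary(self):
        """At mu_b*N = 1 the two branches give the same order of magnitude."""
        mu_b, N, D, S = 1e-5, 1e5, 100.0, 0.01
        t = 2000.0
        large = mu_b * 2 ** (S * t) / S
        T = math.log2(D) / (mu_b * N)
        small = 2 ** (S * (t - T)) / (N / math.sqrt(D))
        # within an order of magnitude (the ratio is ~ 2^(S T)/(S sqrt(D)))
        assert 0.05 < large / small < 15

    def test_invalid_selection(self):
        with pytest.raises(ValueError):
            recurrent_mutant_dynamics(1e-5, 1e5, 100.0, 0.0, [1.0])


class TestSuccessiveFixation:
    def test_single_mutation(self):
        st_ = fixation_stats(0.01, 1e4, "punctual")
        assert successive_fixation_time([0.01], 1e4) == pytest.approx(st_.t_fix)

    def test_stacked_equal_mutations(self):
        st_ = fixation_stats(0.01, 1e4, "punctual")
        assert successive_fixation_time([0.01] * 2, 1e4) == pytest.approx(
            st_.t_fix + st_.t_half
        )
        assert successive_fixation_time([0.01] * 3, 1e4) == pytest.approx(
            st_.t_fix + 2 * st_.t_half
        )

    def test_empty(self):
        assert successive_fixation_time([], 1e4) == 0.0


class TestDuplicationBalance:
    def test_neutral_frequencies_both_deletion_rates(self):
        assert duplication_balance(3e-4, 4.4e-2).f_eq == pytest.approx(
            0.0068, abs=2e-4
        )
        assert duplication_balance(3e-4, 4.1e-4).f_eq == pytest.approx(
            0.42, abs=0.01
        )

    def test_equilibration_time(self):
        assert duplication_balance(3e-4, 4.4e-2).t_eq == pytest.approx(68, abs=0.5)

    def test_deleterious_frequency(self):
        f_lo = duplication_balance(3e-4, 4.4e-2, S=-0.28).f_eq
        f_hi = duplication_balance(3e-4, 4.1e-4, S=-0.28).f_eq
        assert f_lo == pytest.approx(0.0009, abs=5e-5)
        assert f_hi == pytest.approx(0.0011, abs=5e-5)

    def test_runaway_selection_flagged(self):
        bal = duplication_balance(3e-4, 4.1e-4, S=0.0019)
        assert not bal.is_equilibrium


class TestDuplicationDynamics:
    def test_neutral_fixed_point_exact(self):
        traj = duplication_frequency_dynamics(3e-4, 4.4e-2, 0.0, 0.0, 1500)
        assert traj.f[-1] == pytest.approx(
            duplication_balance(3e-4, 4.4e-2).f_eq, rel=1e-9
        )

    def test_deleterious_fixed_point_first_order(self):
        mu_c, mu_d, S = 1e-4, 1e-2, -1e-3
        traj = duplication_frequency_dynamics(mu_c, mu_d, S, 0.0, 3000)
        assert traj.f[-1] == pytest.approx(
            duplication_balance(mu_c, mu_d, S).f_eq, rel=0.01
        )

    def test_positive_selection_escapes_balance(self):
        """S = 10% >> mu_d drives the duplicate to near fixation (a residual
        singleton class of order mu_d/S is constantly regenerated by
        deletion)."""
        traj = duplication_frequency_dynamics(3e-4, 4.1e-4, 0.10, 0.0, 2000)
        assert traj.f[-1] > 0.99

    def test_reduces_to_competition_without_rearrangements(self):
        S = 0.05
        traj = duplication_frequency_dynamics(0.0, 0.0, S, 0.5, 200)
        ref = competition_dynamics(1.0, math.log2(1 + S), traj.t)
        np.testing.assert_allclose(traj.f, ref.f, rtol=1e-9)

    def test_equilibration_timescale(self):
        """The transient dies out on the 3/mu_d timescale."""
        mu_c, mu_d = 3e-4, 4.4e-2
        traj = duplication_frequency_dynamics(mu_c, mu_d, 0.0, 0.0, 300)
        f_eq = duplication_balance(mu_c, mu_d).f_eq
        t_eq = int(3 / mu_d)
        assert traj.f[t_eq] > 0.9 * f_eq
        assert traj.f[t_eq // 4] < 0.75 * f_eq


class TestScalingAndArithmetic:
    def test_effective_population_size(self):
        assert effective_population_size(1.0) == pytest.approx(3e9)
        assert effective_population_size(5.0) == pytest.approx(3e9 / 5**1.44)
        assert effective_population_size(5.0) == pytest.approx(3.0e8, rel=0.05)
        assert effective_population_size(10.0) < effective_population_size(5.0)

    def test_concurrence_worked_example(self):
        p, P, ok = concurrence_and_global_fixation(0.2, 1e-3, 0.0019, 4.1e-4)
        assert p == pytest.approx(1e-4)
        assert P == pytest.approx(3e-7, rel=0.05)
        assert ok

    def test_concurrence_fly_parameters(self):
        # 0.05 mutants/generation; 1e5 duplicants in a population of 1e6
        p, _, _ = concurrence_and_global_fixation(0.05, 1e5 / 1e6, 0.0, 0.0)
        assert p == pytest.approx(2.5e-3)

    def test_not_fixable_when_deletion_dominates(self):
        _, P, ok = concurrence_and_global_fixation(0.2, 1e-3, 1e-4, 4.4e-2)
        assert P == 0.0 and not ok

    def test_mutant_supply(self):
        mu_b, supply = mutant_supply(1e-10, 10, 2e8)
        assert mu_b == pytest.approx(1e-9)
        assert supply == pytest.approx(0.2)
        assert mutant_supply(1e-10, 1, 2e8)[1] == pytest.approx(0.02)
        assert mutant_supply(1e-10, 0, 2e8)[1] == 0.0


class TestParams:
    def test_effective_size_default(self):
        p = PopGenParams(N=1e5, D=100.0)
        assert p.N_eff == pytest.approx(1e4)
        assert p.S_eff == pytest.approx(p.S - p.mu_d)

    def test_validation(self):
        with pytest.raises(ValueError):
            PopGenParams(N=0)
        with pytest.raises(ValueError):
            PopGenParams(mu_c=-1e-4)
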