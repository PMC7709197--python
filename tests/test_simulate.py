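"""Simulator: rate laws, stepping, mass balance, and the two execution paths."""

import math

import numpy as np
import pytest

from xtalplan.constants import MG_PER_G, ML_PER_UM3
from xtalplan.errors import CapExceededError, StepSizeError, ValidationError
from xtalplan.estimate import KineticParameters
from xtalplan.simulate import (
    CrystalHabit,
    SimulationConfig,
    SimulationState,
    growth_rate,
    nucleation_curve,
    nucleation_rate,
    simulate,
    step,
)


class TestRateLaws:
    def test_growth_zero_at_and_below_solubility(self, bench_params):
        assert growth_rate(4.51, bench_params) == 0.0
        assert growth_rate(2.0, bench_params) == 0.0  # no dissolution branch

    def test_growth_linear_above_solubility(self, bench_params):
        assert growth_rate(12.0, bench_params) == pytest.approx(0.8239, rel=1e-12)

    def test_nucleation_zero_at_and_below_solubility(self, bench_params):
        assert nucleation_rate(4.51, bench_params) == 0.0
        assert nucleation_rate(1.0, bench_params) == 0.0

    def test_nucleation_benchmark_value(self, bench_params):
        # hand arithmetic: 8.47*12*exp(-1.49/ln(12/4.51)^2) = 21.45
        assert nucleation_rate(12.0, bench_params) == pytest.approx(21.45, rel=1e-3)

    def test_nucleation_continuous_at_solubility(self, bench_params):
        """The barrier diverges as C -> C_e+, so the limit is 0."""
        assert nucleation_rate(4.51 * (1 + 1e-9), bench_params) < 1e-200

    def test_barrier_free_limit(self):
        p = KineticParameters(c_e=4.51, a1=0.11, a2=8.47, a3=0.0)
        assert nucleation_rate(12.0, p) == pytest.approx(8.47 * 12.0, rel=1e-12)

    def test_curve_matches_pointwise_rate(self, bench_params):
        grid = np.linspace(1.0, 15.0, 40)
        df = nucleation_curve(bench_params, grid)
        assert (df["nucleation_rate_per_ml_h"][grid <= 4.51] == 0.0).all()
        assert df["nucleation_rate_per_ml_h"].iloc[-1] == pytest.approx(
            nucleation_rate(15.0, bench_params), rel=1e-12
        )

    def test_curve_monotone_above_solubility(self, bench_params):
        # just above C_e the barrier exponential underflows to exactly 0.0,
        # so strict monotonicity is checked where the rate is representable
        grid = np.linspace(5.0, 30.0, 2000)
        rates = nucleation_curve(bench_params, grid)["nucleation_rate_per_ml_h"]
        assert (np.diff(rates) > 0).all()
        near = nucleation_curve(bench_params, np.linspace(4.511, 5.0, 100))
        assert (near["nucleation_rate_per_ml_h"] >= 0).all()


def seeded_state(length_um, conc, n=1):
    return SimulationState(
        t_h=0.0, conc_mg_ml=conc,
        birth_times_h=[0.0] * n, lengths_um=[length_um] * n,
        expected_nuclei=0.0,
    )


class TestStep:
    def test_subsaturated_state_only_advances_time(self, bench_params):
        config = SimulationConfig(conc0_mg_ml=4.0, volume_ml=0.003)
        s0 = SimulationState(t_h=0.0, conc_mg_ml=4.0)
        s1 = step(s0, config, bench_params)
        assert s1.t_h == pytest.approx(0.1)
        assert s1.conc_mg_ml == 4.0
        assert s1.n_crystals == 0

    def test_no_nucleation_when_a2_zero(self):
        p = KineticParameters(c_e=4.51, a1=0.11, a2=0.0, a3=1.49)
        config = SimulationConfig(conc0_mg_ml=12.0, volume_ml=0.003)
        s = SimulationState(t_h=0.0, conc_mg_ml=12.0)
        for _ in range(50):
            s = step(s, config, p)
        assert s.n_crystals == 0
        assert s.conc_mg_ml == 12.0

    def test_mass_conservation_seeded_crystal(self, bench_params):
        """C·V + C_s·abc·L³ is invariant while a seeded crystal grows."""
        p = KineticParameters(c_e=4.51, a1=0.11, a2=0.0, a3=1.49)
        config = SimulationConfig(conc0_mg_ml=12.0, volume_ml=0.002)
        abc = config.habit.volume_factor
        s = seeded_state(50.0, 12.0)
        total0 = (
            s.conc_mg_ml * config.volume_ml
            + config.c_s_g_ml * MG_PER_G * abc * s.lengths_um[0] ** 3 * ML_PER_UM3
        )
        for _ in range(500):
            s = step(s, config, p)
            total = (
                s.conc_mg_ml * config.volume_ml
                + config.c_s_g_ml * MG_PER_G * abc * s.lengths_um[0] ** 3 * ML_PER_UM3
            )
            assert total == pytest.approx(total0, rel=1e-10)
        assert s.lengths_um[0] > 50.0
        assert s.conc_mg_ml < 12.0

    def test_agrees_with_brute_force_euler(self, bench_params):
        """Ten steps match an independent, naive Euler re-implementation."""
        config = SimulationConfig(conc0_mg_ml=15.0, volume_ml=0.0017, dt_h=1e-3)
        s = SimulationState(t_h=0.0, conc_mg_ml=15.0)
        # naive oracle, written from the model equations directly
        C = 15.0
        acc = 0.0
        lengths: list[float] = []
        p = bench_params
        for istep in range(10):
            if C > p.c_e:
                acc += p.a2 * C * math.exp(-p.a3 / math.log(C / p.c_e) ** 2) \
                    * config.volume_ml * config.dt_h
            while len(lengths) + 1 <= acc:
                lengths.append(0.0)
            g = p.a1 * max(0.0, C - p.c_e) * config.dt_h
            dv = 0.0
            for k in range(len(lengths)):
                dv += (lengths[k] + g) ** 3 - lengths[k] ** 3
                lengths[k] += g
            C -= (
                config.c_s_g_ml * MG_PER_G * config.habit.volume_factor
                * dv * ML_PER_UM3 / config.volume_ml
            )
            s = step(s, config, p)
        assert s.conc_mg_ml == pytest.approx(C, rel=1e-9)
        assert s.n_crystals == len(lengths)
        for a, b in zip(s.lengths_um, lengths):
            assert a == pytest.approx(b, rel=1e-9)

    def test_step_size_error_on_overshoot(self, bench_params):
        # a huge seeded crystal in a tiny volume at a coarse step
        config = SimulationConfig(conc0_mg_ml=12.0, volume_ml=1e-5, dt_h=10.0)
        s = seeded_state(500.0, 12.0)
        with pytest.raises(StepSizeError):
            step(s, config, bench_params)

    def test_cap_exceeded(self, bench_params):
        config = SimulationConfig(conc0_mg_ml=25.0, volume_ml=0.0035, max_crystals=3)
        with pytest.raises(CapExceededError):
            simulate(config, bench_params)


class TestSimulate:
    def test_matches_step_composition(self, bench_params):
        """The O(1)-per-step path equals the explicit per-crystal path."""
        config = SimulationConfig(
            conc0_mg_ml=15.0, volume_ml=0.0017, dt_h=0.1, t_max_h=300.0,
            equil_rel_tol=0.0,
        )
        res = simulate(config, bench_params)
        s = SimulationState(t_h=0.0, conc_mg_ml=15.0)
        for _ in range(3000):
            s = step(s, config, bench_params)
        assert res.n_crystals == s.n_crystals
        assert res.final_conc_mg_ml == pytest.approx(s.conc_mg_ml, rel=1e-9)
        np.testing.assert_allclose(res.final_lengths_um, s.lengths_um, rtol=1e-9)

    def test_stochastic_matches_step_composition(self, bench_params):
        config = SimulationConfig(
            conc0_mg_ml=15.0, volume_ml=0.0017, dt_h=0.1, t_max_h=200.0,
            mode="stochastic", seed=123, equil_rel_tol=0.0,
        )
        res = simulate(config, bench_params)
        rng = np.random.default_rng(123)
        s = SimulationState(t_h=0.0, conc_mg_ml=15.0)
        for _ in range(2000):
            s = step(s, config, bench_params, rng=rng)
        assert res.n_crystals == s.n_crystals
        assert res.final_conc_mg_ml == pytest.approx(s.conc_mg_ml, rel=1e-9)

    def test_subsaturated_terminates_immediately(self, bench_params):
        config = SimulationConfig(conc0_mg_ml=4.0, volume_ml=0.003)
        res = simulate(config, bench_params)
        assert res.termination_reason == "subsaturated"
        assert res.n_crystals == 0

    def test_metastable_gives_no_crystals_in_six_months(self, bench_params):
        """At 5 mg/ml the nucleation barrier keeps the container empty."""
        res = simulate(
            SimulationConfig(conc0_mg_ml=5.0, volume_ml=0.003), bench_params
        )
        assert res.n_crystals == 0
        assert res.termination_reason == "horizon"
        assert res.final_conc_mg_ml == 5.0

    def test_trajectory_monotonicity(self, bench_params):
        config = SimulationConfig(conc0_mg_ml=15.0, volume_ml=0.0017)
        res = simulate(config, bench_params)
        assert (np.diff(res.trajectory["conc_mg_ml"]) <= 1e-12).all()
        assert (np.diff(res.trajectory["n_crystals"]) >= 0).all()
        assert (np.diff(res.birth_times_h) >= 0).all()
        # earlier-born crystals end up at least as large
        assert (np.diff(res.final_lengths_um) <= 1e-9).all()

    def test_final_state_mass_balance(self, bench_params):
        config = SimulationConfig(conc0_mg_ml=15.0, volume_ml=0.0017)
        res = simulate(config, bench_params)
        abc = config.habit.volume_factor
        crystal_mass = (
            config.c_s_g_ml * MG_PER_G * abc
            * float(np.sum(res.final_lengths_um**3)) * ML_PER_UM3
        )
        total = res.final_conc_mg_ml * config.volume_ml + crystal_mass
        assert total == pytest.approx(15.0 * config.volume_ml, rel=1e-6)

    def test_dt_halving_stability(self, bench_params):
        """Halving dt leaves the count unchanged and sizes within 0.5%."""
        kw = dict(conc0_mg_ml=15.0, volume_ml=0.0017)
        a = simulate(SimulationConfig(dt_h=0.1, **kw), bench_params)
        b = simulate(SimulationConfig(dt_h=0.05, **kw), bench_params)
        assert a.n_crystals == b.n_crystals
        assert a.first_crystal_length_um == pytest.approx(
            b.first_crystal_length_um, rel=5e-3
        )

    def test_count_nondecreasing_in_concentration(self, bench_params):
        """Over the single-crystal window the count rises with C0."""
        counts = []
        for c0 in (6.55, 6.6, 6.8, 7.0):
            res = simulate(
                SimulationConfig(
                    conc0_mg_ml=c0, volume_ml=0.4, dt_h=0.5, t_max_h=60000.0
                ),
                bench_params,
            )
            counts.append(res.n_crystals)
        assert counts == sorted(counts)

    def test_stochastic_seed_determinism(self, bench_params):
        kw = dict(conc0_mg_ml=15.0, volume_ml=0.0017, mode="stochastic")
        a = simulate(SimulationConfig(seed=7, **kw), bench_params)
        b = simulate(SimulationConfig(seed=7, **kw), bench_params)
        c = simulate(SimulationConfig(seed=8, **kw), bench_params)
        assert a.n_crystals == b.n_crystals
        np.testing.assert_array_equal(a.birth_times_h, b.birth_times_h)
        assert (a.n_crystals != c.n_crystals) or not np.array_equal(
            a.birth_times_h, c.birth_times_h
        )

    def test_stochastic_requires_seed(self):
        with pytest.raises(ValidationError):
            SimulationConfig(conc0_mg_ml=10.0, volume_ml=0.003, mode="stochastic")

    def test_habit_validation(self):
        with pytest.raises(ValidationError):
            CrystalHabit(a=1.0, b=0.5, c=0.8)
        with pytest.raises(ValidationError):
            CrystalHabit(a=2.0, b=1.0, c=0.5)
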