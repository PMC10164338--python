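"""Core dynamics: initial conditions, inhibition, LQ kill, impulses and
the exactness of the trajectory propagator."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.linalg import expm

from radtse import (
    ConfigurationError,
    ModelParameters,
    Regimen,
    apply_radiation_impulse,
    fraction_killed,
    inhibition,
    initial_state,
    mon_fri_regimen,
    simulate,
    system_matrix,
    total_dose_regimen,
    total_volume_derivative,
)
from radtse.model import TumorState, _Batch, _propagate_segment, _simulate_batch, _simulate_batch_numpy

from conftest import random_parameters


class TestInitialState:
    @pytest.mark.parametrize(
        "v0, total",
        [(44.0, 108.40081), (26.0, 64.05503)],
    )
    def test_geometric_composition_sums(self, v0, total):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.027, v0=v0)
        s = initial_state(p)
        r = 0.3 / 0.44
        assert s.v1 == v0
        assert s.v2 == pytest.approx(v0 * r)
        assert s.v3 == pytest.approx(v0 * r**2)
        assert s.v4 == pytest.approx(v0 * r**3)
        assert s.u1 == s.u2 == 0.0
        assert s.total == pytest.approx(total, rel=1e-5)

    def test_no_natural_death_puts_all_mass_in_v1(self):
        p = ModelParameters(kg=0.44, kk=0.0, alpha=0.06, gamma=0.02, v0=50.0)
        s = initial_state(p)
        assert (s.v1, s.v2, s.v3, s.v4) == (50.0, 0.0, 0.0, 0.0)


class TestInhibition:
    def test_worked_percentages_at_60_gy(self, pop):
        """Growth-rate inhibition at 60 Gy: 16.2% / 26.4% per study 1/2."""
        i1 = inhibition(60.0, 0.0, pop.median_parameters(1))
        i2 = inhibition(60.0, 0.0, pop.median_parameters(2))
        assert 100 * (1 - i1) == pytest.approx(16.2, abs=0.05)
        assert 100 * (1 - i2) == pytest.approx(26.4, abs=0.05)

    def test_radiosensitizer_scales_accumulated_dose(self, pop):
        i = inhibition(60.0, 1.0, pop.median_parameters(1, "Rs1"))
        assert 100 * (1 - i) == pytest.approx(20.412, abs=0.01)

    @pytest.mark.parametrize("kind, kwargs", [
        ("linear", {}),
        ("exponential", {}),
        ("saturating", {"id50": 30.0}),
    ])
    def test_no_dose_means_no_inhibition(self, kind, kwargs):
        p = ModelParameters(
            kg=0.44, kk=0.3, alpha=0.06, gamma=0.05, v0=20.0,
            inhibition_kind=kind, **kwargs,
        )
        assert inhibition(0.0, 5.0, p) == 1.0

    def test_linear_variant_may_go_negative(self):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.05, v0=20.0)
        assert inhibition(400.0, 0.0, p) < 0.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError, match="inhibition_kind"):
            ModelParameters(
                kg=0.4, kk=0.1, alpha=0.06, gamma=0.02, v0=20.0,
                inhibition_kind="quadratic",
            )

    def test_saturating_requires_id50(self):
        with pytest.raises(ConfigurationError, match="id50"):
            ModelParameters(
                kg=0.4, kk=0.1, alpha=0.06, gamma=0.02, v0=20.0,
                inhibition_kind="saturating",
            )


class TestFractionKilled:
    def test_two_gray_kill_fraction(self):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0)
        assert fraction_killed(2.0, 0.0, p) == pytest.approx(0.13416, abs=1e-4)

    def test_radiosensitizer_boosts_kill(self):
        p = ModelParameters(
            kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0, a=0.65
        )
        assert fraction_killed(2.0, 7.0, p) == pytest.approx(0.55032, abs=1e-4)

    def test_zero_dose_kills_nothing(self):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0)
        assert fraction_killed(0.0, 9.0, p) == 0.0

    def test_monotone_in_dose_and_concentration(self):
        p = ModelParameters(
            kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0, a=0.2
        )
        doses = np.linspace(0.0, 12.0, 30)
        f = fraction_killed(doses, 0.0, p)
        assert np.all(np.diff(f) > 0)
        concs = np.linspace(0.0, 10.0, 30)
        f = fraction_killed(2.0, concs, p)
        assert np.all(np.diff(f) > 0)


class TestImpulse:
    def test_killed_mass_moves_to_u1(self):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0)
        s = TumorState(v1=100.0, v2=1.0, v3=2.0, v4=3.0, u1=4.0, u2=5.0)
        out = apply_radiation_impulse(s, 2.0, 0.0, p)
        f = fraction_killed(2.0, 0.0, p)
        assert out.v1 == pytest.approx(100.0 * (1 - f))
        assert out.u1 == pytest.approx(4.0 + 100.0 * f)
        assert out.d_acc == pytest.approx(2.0)

    @given(
        dose=st.floats(0.0, 15.0),
        conc=st.floats(0.0, 10.0),
        v1=st.floats(0.0, 1e4),
    )
    @hsettings(max_examples=50, deadline=None)
    def test_total_volume_conserved(self, dose, conc, v1):
        p = ModelParameters(
            kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0, a=0.3, b=0.1
        )
        s = TumorState(v1=v1, v2=1.0, v3=2.0, v4=3.0, u1=4.0, u2=5.0)
        out = apply_radiation_impulse(s, dose, conc, p)
        assert out.total == pytest.approx(s.total, rel=1e-12)

    def test_zero_dose_only_books_dose(self):
        p = ModelParameters(kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=20.0)
        s = TumorState(v1=10.0, v2=1.0, v3=1.0, v4=1.0, u1=0.0, u2=0.0)
        out = apply_radiation_impulse(s, 0.0, 0.0, p)
        assert out.v1 == s.v1 and out.u1 == s.u1


class TestSimulate:
    def test_untreated_growth_is_exactly_exponential(self, median1):
        """No treatment: V_tot(t) = V_tot(0) e^((kg-kk) t), compartments
        keep their initial proportions."""
        horizon = 20.0
        traj = simulate(median1, Regimen.untreated(horizon), np.linspace(0, horizon, 9))
        tot0 = initial_state(median1).total
        expected = tot0 * np.exp((median1.kg - median1.kk) * traj.times)
        assert np.allclose(traj.total_volume, expected, rtol=1e-6)
        frac = traj.states / traj.total_volume[:, None]
        assert np.allclose(frac, frac[0], atol=1e-9)

    def test_untreated_doubling_time_near_five_days(self, median1):
        td = np.log(2) / (median1.kg - median1.kk)
        assert td == pytest.approx(4.951, abs=0.01)

    def test_huge_sensitized_dose_empties_v1(self):
        p = ModelParameters(
            kg=0.44, kk=0.3, alpha=0.06, gamma=0.02, v0=50.0, a=100.0
        )
        reg = Regimen(times=(5.0,), doses=(10.0,), concentrations=(50.0,), horizon=6.0)
        traj = simulate(p, reg, [5.0])
        assert traj.states[0, 0] < 1e-8 * 50.0

    def test_event_time_output_is_post_impulse(self, median1):
        reg = Regimen(times=(3.0,), doses=(2.0,), concentrations=(0.0,), horizon=10.0)
        traj = simulate(median1, reg, [3.0])
        assert np.allclose(traj.states[0], traj.post_event_states[0])
        assert traj.pre_event_states[0, 0] > traj.post_event_states[0, 0]

    def test_impulse_conserves_total_volume_in_trajectory(self, median3):
        reg = mon_fri_regimen(2, 2.0, horizon=30.0)
        traj = simulate(median3, reg, [29.0])
        pre = traj.pre_event_states.sum(axis=1)
        post = traj.post_event_states.sum(axis=1)
        assert np.allclose(pre, post, rtol=1e-12)

    def test_analytic_path_matches_stiff_integrator(self, pop):
        p = pop.median_parameters(1, "Rs1")
        reg = total_dose_regimen(60.0, concentration=1.0, horizon=60.0)
        t = np.arange(0.0, 61.0, 3.5)
        a = simulate(p, reg, t)
        b = simulate(p, reg, t, method="ivp", rtol=1e-11, atol=1e-13)
        rel = np.abs(a.total_volume - b.total_volume) / b.total_volume
        assert rel.max() < 1e-8

    def test_segment_propagator_matches_matrix_exponential(self):
        """Random impulse-free segments against scipy expm, including the
        stasis resonance kg*I ~ 0."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for k in range(60):
            p = random_parameters(rng)
            i_val = 0.0 if k % 10 == 0 else rng.uniform(-2.0, 1.0)
            tau = rng.uniform(0.01, 30.0)
            x0 = rng.uniform(0.0, 100.0, 6)  # (v1, u1, u2, v2, v3, v4)
            ref = expm(system_matrix(p, i_val) * tau) @ x0
            batch = _Batch(p)
            v1, s = _propagate_segment(
                batch, x0[:1].copy(), x0[None, 1:].copy(), np.array([i_val]), tau
            )
            got = np.concatenate([v1, s[0]])
            worst = max(worst, np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-30)))
        assert worst < 1e-8

    def test_fast_batch_path_matches_numpy_path(self, pop):
        p = pop.median_parameters(2, "Rs1")
        rng = np.random.default_rng(3)
        n = 17
        batch = _Batch(
            p,
            gamma=p.gamma * np.exp(rng.normal(0, 0.6, n)),
            alpha=p.alpha * np.exp(rng.normal(0, 0.5, n)),
            v0=p.v0 * np.exp(rng.normal(0, 0.4, n)),
        )
        reg = mon_fri_regimen(6, 2.0, concentration=2.0, horizon=90.0)
        ev = (
            np.asarray(reg.times),
            np.asarray(reg.doses),
            np.asarray(reg.concentrations),
        )
        t = np.arange(0.0, 91.0, 3.5)
        fast = _simulate_batch(batch, *ev, t)[0]
        slow = _simulate_batch_numpy(batch, *ev, t)[0]
        assert np.allclose(fast, slow, rtol=1e-12, atol=1e-12)

    @given(data=st.data())
    @hsettings(max_examples=20, deadline=None)
    def test_non_negative_and_monotone_in_exposure(self, data):
        """Compartments stay non-negative; more drug or dose never gives a
        larger tumor at any time from the first fraction on."""
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        p = random_parameters(rng)
        t = np.arange(0.0, 40.0, 2.0)
        lo = simulate(p, mon_fri_regimen(2, 1.0, concentration=0.5, horizon=40.0), t)
        assert (lo.states >= -1e-12).all()
        hi_dose = simulate(p, mon_fri_regimen(2, 2.0, concentration=0.5, horizon=40.0), t)
        hi_conc = simulate(p, mon_fri_regimen(2, 1.0, concentration=3.0, horizon=40.0), t)
        after = t >= 0.0
        assert (hi_dose.total_volume[after] <= lo.total_volume[after] * (1 + 1e-9)).all()
        assert (hi_conc.total_volume[after] <= lo.total_volume[after] * (1 + 1e-9)).all()


class TestDerivative:
    def test_untreated_derivative_is_net_growth(self, median3):
        reg = Regimen.untreated(30.0)
        d = total_volume_derivative(median3, reg, 25.0)
        traj = simulate(median3, reg, [25.0])
        expected = (median3.kg - median3.kk) * traj.total_volume[0]
        assert d == pytest.approx(expected, rel=1e-9)
        assert d > 0

    def test_derivative_decreases_with_concentration(self, pop):
        """More drug always lowers the stasis derivative while the tumor
        is still growing (beyond stasis it saturates towards zero from
        below as the tumor burns out, so monotonicity is asserted on the
        growth side)."""
        p = pop.median_parameters(3, "Rs1")
        vals = [
            total_volume_derivative(
                p, total_dose_regimen(60.0, concentration=c, horizon=60.0), 60.0
            )
            for c in (0.0, 0.5, 1.0, 1.5)
        ]
        assert vals[0] > 0
        assert np.all(np.diff(vals) < 0)

    def test_t_star_beyond_horizon_rejected(self, median3):
        with pytest.raises(ValueError, match="horizon"):
            total_volume_derivative(median3, Regimen.untreated(30.0), 31.0)


class TestRegimenValidation:
    def test_event_times_must_increase(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            Regimen(times=(1.0, 1.0), doses=(1.0, 1.0),
                    concentrations=(0.0, 0.0), horizon=5.0)

    def test_horizon_must_cover_events(self):
        with pytest.raises(ConfigurationError, match="horizon"):
            Regimen(times=(5.0,), doses=(1.0,), concentrations=(0.0,), horizon=4.0)
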