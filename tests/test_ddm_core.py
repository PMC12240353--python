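"""Wiener first-passage density, simulator and state modulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from breathdm.ddm_core import (
    DDMParameters,
    RespiratoryDeltas,
    StimulusCoding,
    RDM_CODING,
    absorption_probability,
    apply_state_modulation,
    simulate_ddm,
    trial_loglik,
    wiener_fpt_density,
    wfpt_sum_loglik,
)

PARAM_SETS = [
    (1.0, 2.0, 0.5, 0.3),
    (-0.8, 1.2, 0.4, 0.2),
    (0.0, 1.5, 0.6, 0.0),
    (2.5, 0.8, 0.3, 0.4),
]


@pytest.mark.parametrize("v,a,z,t", PARAM_SETS)
def test_density_normalises_to_one(v, a, z, t):
    total = sum(
        quad(lambda x: wiener_fpt_density(x, b, v, a, z, t), t, 80, limit=300)[0]
        for b in ("upper", "lower")
    )
    assert abs(total - 1.0) < 1e-6


@pytest.mark.parametrize("v,a,z,t", PARAM_SETS)
def test_reflection_symmetry_exact(v, a, z, t):
    rt = np.linspace(t + 0.01, t + 5, 50)
    up = wiener_fpt_density(rt, "upper", v, a, z, t)
    lo = wiener_fpt_density(rt, "lower", -v, a, 1 - z, t)
    np.testing.assert_array_equal(up, lo)


def test_zero_drift_central_start_is_symmetric():
    rt = np.linspace(0.31, 5, 40)
    up = wiener_fpt_density(rt, "upper", 0.0, 2.0, 0.5, 0.3)
    lo = wiener_fpt_density(rt, "lower", 0.0, 2.0, 0.5, 0.3)
    np.testing.assert_allclose(up, lo, rtol=1e-12)


def test_density_zero_at_or_below_nondecision_time():
    assert wiener_fpt_density(0.3, "upper", 1, 2, 0.5, 0.3) == 0.0
    assert wiener_fpt_density(0.1, "lower", 1, 2, 0.5, 0.3) == 0.0


def test_density_invalid_parameters_raise():
    with pytest.raises(ValueError):
        wiener_fpt_density(1.0, "upper", 1, -1, 0.5, 0.3)
    with pytest.raises(ValueError):
        wiener_fpt_density(1.0, "sideways", 1, 1, 0.5, 0.3)


def test_absorption_probability_limits():
    assert absorption_probability(0.0, 2.0, 0.5) == 0.5
    assert absorption_probability(0.0, 2.0, 0.3) == 0.3
    assert absorption_probability(50.0, 2.0, 0.5) == pytest.approx(1.0, abs=1e-12)
    assert absorption_probability(-50.0, 2.0, 0.5) == pytest.approx(0.0, abs=1e-12)


def test_absorption_probability_matches_density_mass():
    # P(upper) must equal the integrated upper-boundary density
    for v, a, z, t in PARAM_SETS:
        mass = quad(lambda x: wiener_fpt_density(x, "upper", v, a, z, t), t, 80, limit=300)[0]
        assert mass == pytest.approx(absorption_probability(v, a, z), abs=2e-6)


@given(
    v=st.floats(-3, 3),
    a=st.floats(0.5, 3),
    z=st.floats(0.1, 0.9),
    rt=st.floats(0.05, 8),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_density_nonnegative_and_reflection_property(v, a, z, rt):
    up = wiener_fpt_density(rt, "upper", v, a, z, 0.0)
    assert up >= 0.0
    assert up == wiener_fpt_density(rt, "lower", -v, a, 1 - z, 0.0)


def test_numba_kernel_matches_vectorised_density(rng):
    v, a, z, t = 1.2, 1.6, 0.45, 0.25
    rt = t + rng.uniform(0.05, 3.0, size=200)
    upper = rng.random(200) < 0.5
    direct = sum(
        np.log(wiener_fpt_density(r, "upper" if u else "lower", v, a, z, t))
        for r, u in zip(rt, upper)
    )
    assert wfpt_sum_loglik(rt, upper, v, a, z, t) == pytest.approx(direct, rel=1e-10)


def test_kernel_invalid_inputs_give_minus_inf(rng):
    rt = np.array([0.5, 0.2])
    upper = np.array([True, False])
    assert wfpt_sum_loglik(rt, upper, 1.0, 1.5, 0.5, 0.3) == -np.inf  # rt <= t
    assert wfpt_sum_loglik(rt, upper, 1.0, -1.0, 0.5, 0.1) == -np.inf  # bad a


class TestSimulator:
    def test_reproducible_and_rts_above_nondecision_time(self):
        c1, r1 = simulate_ddm(1.0, 1.5, 0.5, 0.3, n=500, dt=1e-3, seed=42)
        c2, r2 = simulate_ddm(1.0, 1.5, 0.5, 0.3, n=500, dt=1e-3, seed=42)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(r1, r2)
        assert np.all(r1[c1 >= 0] >= 0.3)

    def test_choice_proportions_match_closed_form(self):
        v, a, z = 1.0, 2.0, 0.5
        ch, _ = simulate_ddm(v, a, z, 0.0, n=100_000, dt=1e-4, seed=7)
        p_hat = float(np.mean(ch == 1))
        p = absorption_probability(v, a, z)
        se = np.sqrt(p * (1 - p) / ch.size)
        # allow 4 binomial SEs plus a small discretisation margin
        assert abs(p_hat - p) < 4 * se + 0.003

    def test_wider_boundary_slows_and_improves_accuracy(self):
        ch1, rt1 = simulate_ddm(1.0, 1.0, 0.5, 0.0, n=20_000, dt=1e-3, seed=1)
        ch2, rt2 = simulate_ddm(1.0, 2.0, 0.5, 0.0, n=20_000, dt=1e-3, seed=2)
        assert np.nanmean(rt2[ch2 >= 0]) > np.nanmean(rt1[ch1 >= 0])
        assert np.mean(ch2 == 1) > np.mean(ch1 == 1)

    def test_simulated_rt_distribution_matches_analytic_cdf(self):
        # Kolmogorov-Smirnov distance between simulated upper-boundary RTs
        # and the analytic conditional CDF
        from scipy.integrate import cumulative_trapezoid

        v, a, z, t = 1.0, 2.0, 0.5, 0.3
        ch, rt = simulate_ddm(v, a, z, t, n=100_000, dt=1e-4, seed=3)
        rt_up = np.sort(rt[ch == 1])
        grid = np.linspace(t + 1e-4, 15, 3000)
        dens = wiener_fpt_density(grid, "upper", v, a, z, t)
        cdf = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= absorption_probability(v, a, z)
        emp = np.searchsorted(rt_up, grid) / rt_up.size
        assert np.max(np.abs(emp - cdf)) < 0.01


class TestStateModulation:
    BASE = DDMParameters(v={"up": 2.0, "down": -2.0}, a=1.0, z=0.5, t=0.3)

    def test_zero_deltas_are_identity(self):
        deltas = RespiratoryDeltas.zeros(("up", "down"))
        for state in ("inspiration", "expiration"):
            eff = apply_state_modulation(self.BASE, deltas, state)
            assert eff == self.BASE

    def test_expiration_is_reference_state(self):
        deltas = RespiratoryDeltas(dv={"up": 1.0, "down": 1.0}, da=0.5, dz=0.1, dt=0.1)
        assert apply_state_modulation(self.BASE, deltas, "expiration") == self.BASE

    def test_inspiration_adds_deltas(self):
        deltas = RespiratoryDeltas(dv={"up": 0.0, "down": 0.0}, da=-0.05, dz=0.0, dt=0.0)
        eff = apply_state_modulation(self.BASE, deltas, "inspiration")
        assert eff.a == pytest.approx(0.95)

    def test_out_of_range_modulation_names_parameter(self):
        deltas = RespiratoryDeltas(dv={}, da=0.0, dz=0.6, dt=0.0)
        with pytest.raises(ValueError, match="z"):
            apply_state_modulation(self.BASE, deltas, "inspiration")

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            apply_state_modulation(self.BASE, RespiratoryDeltas.zeros(("up",)), "apnoea")


class TestTrialLoglik:
    BASE = DDMParameters(v={"up": 1.5, "down": -1.5}, a=1.4, z=0.5, t=0.3)
    DELTAS = RespiratoryDeltas(dv={"up": 0.0, "down": 0.0}, da=-0.04, dz=0.0, dt=0.0)

    def trial(self, **kw):
        d = dict(stimulus_class="up", choice="up", rt_s=0.8, state="expiration")
        d.update(kw)
        return d

    def test_rt_below_nondecision_time_gives_minus_inf(self):
        assert trial_loglik(self.trial(rt_s=0.2), self.BASE, self.DELTAS, RDM_CODING) == -np.inf

    def test_coding_swap_with_negated_drifts_is_invariant(self):
        flipped = StimulusCoding(upper="down", lower="up")
        base_neg = DDMParameters(
            v={k: -v for k, v in self.BASE.v.items()},
            a=self.BASE.a, z=1 - self.BASE.z, t=self.BASE.t,
        )
        deltas_neg = RespiratoryDeltas(
            dv={k: -v for k, v in self.DELTAS.dv.items()},
            da=self.DELTAS.da, dz=-self.DELTAS.dz, dt=self.DELTAS.dt,
        )
        for state in ("inspiration", "expiration"):
            t1 = trial_loglik(self.trial(state=state), self.BASE, self.DELTAS, RDM_CODING)
            t2 = trial_loglik(self.trial(state=state), base_neg, deltas_neg, flipped)
            assert t1 == pytest.approx(t2, rel=1e-12)

    def test_unlabelled_state_rejected(self):
        with pytest.raises(ValueError):
            trial_loglik(self.trial(state="transition"), self.BASE, self.DELTAS, RDM_CODING)

    def test_loglik_peaks_near_generating_parameters(self):
        ch, rt = simulate_ddm(1.5, 1.4, 0.5, 0.3, n=4000, dt=1e-3, seed=9)
        ok = ch >= 0
        upper = ch[ok] == 1
        ll_true = wfpt_sum_loglik(rt[ok], upper, 1.5, 1.4, 0.5, 0.3)
        for v_alt, a_alt in [(0.8, 1.4), (1.5, 2.0), (2.5, 1.0)]:
            assert ll_true > wfpt_sum_loglik(rt[ok], upper, v_alt, a_alt, 0.5, 0.3)


def test_parameter_validation():
    with pytest.raises(ValueError):
        DDMParameters(v={"up": 1.0}, a=0.0, z=0.5, t=0.1)
    with pytest.raises(ValueError):
        DDMParameters(v={"up": 1.0}, a=1.0, z=1.0, t=0.1)
    with pytest.raises(ValueError):
        DDMParameters(v={"up": np.inf}, a=1.0, z=0.5, t=0.1)
    with pytest.raises(ValueError):
        StimulusCoding(upper="up", lower="up")
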