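"""Exclusion rules, signal-detection criterion, summaries and paired tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from breathdm.behav_stats import (
    compute_criterion,
    exclude_trials,
    paired_ttest_bf,
    phase_binned_summary,
    summarize_by_state,
)
from breathdm.resp_preproc import EventLabel


def toy_trials(n=10, missed=(), fast=(), domain="RDM"):
    rows = []
    for i in range(n):
        rt = np.nan if i in missed else (50.0 if i in fast else 600.0 + i)
        rows.append(dict(
            subject_id="s00", domain=domain, block=0, trial=i,
            stimulus_class="up" if i % 2 == 0 else "down",
            choice=None if i in missed else ("up" if i % 2 == 0 else "down"),
            rt_ms=rt, missed=i in missed,
        ))
    return pd.DataFrame(rows)


class TestExclusions:
    def test_toy_counts(self):
        trials = toy_trials(10, missed=(0, 1), fast=(2,))
        kept, ledger = exclude_trials(trials)
        assert len(kept) == 7
        assert ledger["excluded_missed"] == 2
        assert ledger["excluded_fast_rt"] == 1

    def test_all_valid_is_identity(self):
        trials = toy_trials(8)
        kept, ledger = exclude_trials(trials)
        assert len(kept) == 8
        assert ledger["retained"] == 8

    def test_ledger_conserves_row_count(self, rng):
        trials = toy_trials(20, missed=(3, 4, 5), fast=(7,))
        trials["state"] = rng.choice(
            ["inspiration", "expiration", "transition", "unlabelled"], size=20
        )
        kept, ledger = exclude_trials(trials)
        excluded = sum(v for k, v in ledger.items() if k.startswith("excluded_"))
        assert ledger["presented"] == excluded + ledger["retained"]
        assert ledger["retained"] == len(kept)


def phi_inv_bisect(p, tol=1e-12):
    """Independent normal quantile via bisection on the error function."""
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if 0.5 * (1 + math.erf(mid / math.sqrt(2))) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def criterion_table(h_up, f_up, n=100):
    """Table with P(respond up | up) = h_up and P(respond up | down) = f_up."""
    rows = []
    for cls, p in (("up", h_up), ("down", f_up)):
        k = int(round(p * n))
        for i in range(n):
            rows.append(dict(stimulus_class=cls, choice="up" if i < k else "down"))
    return pd.DataFrame(rows)


class TestCriterion:
    def test_unbiased_observer_has_zero_criterion(self):
        assert compute_criterion(criterion_table(0.5, 0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_rates_cancel(self):
        assert compute_criterion(criterion_table(0.69, 0.31)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_quantile_oracle(self):
        c = compute_criterion(criterion_table(0.9, 0.4))
        expected = -0.5 * (phi_inv_bisect(0.9) + phi_inv_bisect(0.4))
        assert c == pytest.approx(expected, abs=1e-9)

    def test_extreme_rates_clipped_to_finite_value(self):
        c = compute_criterion(criterion_table(1.0, 0.0))
        assert np.isfinite(c)
        # 1/(2N) rule with N=100 per class
        expected = -0.5 * (phi_inv_bisect(1 - 1 / 200) + phi_inv_bisect(1 / 200))
        assert c == pytest.approx(expected, abs=1e-9)

    def test_label_swap_flips_sign(self, rng):
        for _ in range(5):
            h, f = rng.uniform(0.2, 0.8, 2)
            tab = criterion_table(h, f)
            swapped = tab.assign(choice=tab.choice.map({"up": "down", "down": "up"}))
            # swapping responses turns H -> 1-H, F -> 1-F
            assert compute_criterion(swapped) == pytest.approx(-compute_criterion(tab), abs=1e-9)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            compute_criterion(criterion_table(0.7, 0.3).query("stimulus_class == 'up'"))


def labels_for(trials, states):
    return [
        EventLabel(event_time_s=0.0, state=s, circular_phase=None, in_artefact=False)
        for s in states
    ]


class TestSummaries:
    def test_all_correct_gives_unit_hit_rate_both_states(self):
        trials = toy_trials(10)
        states = ["inspiration"] * 5 + ["expiration"] * 5
        out = summarize_by_state(trials, labels_for(trials, states), "stimulus")
        assert (out.value == 1.0).all()
        assert out.attrs["measure"] == "hit_rate"

    def test_state_with_no_trials_flagged(self):
        trials = toy_trials(6)
        out = summarize_by_state(trials, labels_for(trials, ["inspiration"] * 6), "stimulus")
        exp_row = out[out.state == "expiration"].iloc[0]
        assert exp_row.flagged and np.isnan(exp_row.value)

    def test_invalid_locking_rejected(self):
        trials = toy_trials(4)
        with pytest.raises(ValueError):
            summarize_by_state(trials, labels_for(trials, ["inspiration"] * 4), "onset")


def jzs_bf_quadrature(t, n, r=math.sqrt(2) / 2):
    """Independent JZS Bayes factor by numerical integration of the
    Zellner-Siow mixture (Cauchy prior on effect size)."""
    nu = n - 1

    def h0(tval):
        return (1 + tval**2 / nu) ** (-(nu + 1) / 2)

    def integrand(g):
        return (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * math.pi) ** -0.5
            * g ** -1.5
            * math.exp(-1 / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    return num / h0(t)


class TestPairedTest:
    A = np.array([0.71, 0.68, 0.75, 0.80, 0.66, 0.73, 0.69, 0.77, 0.72, 0.70])
    B = np.array([0.69, 0.70, 0.71, 0.78, 0.65, 0.70, 0.70, 0.74, 0.69, 0.68])

    def test_fixture_matches_scipy_t_and_quadrature_bayes_factor(self):
        res = paired_ttest_bf(self.A, self.B)
        t_ref, p_ref = stats.ttest_rel(self.A, self.B)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.bf10 == pytest.approx(jzs_bf_quadrature(t_ref, len(self.A)), rel=1e-3)
        assert res.bf01 == pytest.approx(1 / res.bf10)

    def test_ci_contains_mean_difference(self):
        res = paired_ttest_bf(self.A, self.B)
        assert res.ci95[0] <= res.mean_difference <= res.ci95[1]

    def test_constant_shift_degenerate(self):
        a = np.arange(10, dtype=float)
        with pytest.raises(ValueError):
            paired_ttest_bf(a, a + 0.5)

    def test_type_one_error_near_nominal_under_null(self, rng):
        n_rep, n = 1000, 40
        a = rng.standard_normal((n_rep, n))
        b = rng.standard_normal((n_rep, n))
        t, p = stats.ttest_rel(a, b, axis=1)
        rate = float(np.mean(p < 0.05))
        assert 0.03 < rate < 0.075  # 99% binomial band around 0.05 at 1000 reps

    def test_bayes_factor_favours_null_on_average_under_null(self, rng):
        bf01s = []
        for _ in range(40):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30)
            bf01s.append(paired_ttest_bf(a, b).bf01)
        assert np.median(bf01s) > 1.0


class TestPhaseBins:
    def test_edges_partition_circle_into_eight(self):
        trials = toy_trials(16)
        phases = np.linspace(-np.pi, np.pi, 16, endpoint=False)
        out = phase_binned_summary(trials, phases)
        assert len(out) == 8
        assert out.lo.iloc[0] == pytest.approx(-np.pi)
        assert out.hi.iloc[-1] == pytest.approx(np.pi)
        np.testing.assert_allclose(out.hi - out.lo, np.pi / 4)

    def test_constant_behaviour_gives_identical_bin_values(self, rng):
        trials = toy_trials(400)
        phases = rng.uniform(-np.pi, np.pi, 400)
        out = phase_binned_summary(trials, phases)
        assert np.allclose(out.value, 1.0)  # all responses correct by construction

    def test_event_frequency_tracks_time_in_phase_bin(self):
        # events spread uniformly in time land in each phase bin in
        # proportion to the time that bin occupies within the cycle
        from breathdm.resp_preproc import assign_circular_phase, detect_extrema, preprocess_trace
        from breathdm.synthetic_data import default_subject, generate_respiration
        from dataclasses import replace

        sub = replace(default_subject("RDM"), noise_sd=0.0, cycle_cv=0.0, inspiratory_fraction=0.4)
        tr = generate_respiration(sub, 400.0, seed=0)
        series = detect_extrema(preprocess_trace(tr))
        lo, hi = series.span
        times = np.linspace(lo + 0.01, hi - 0.01, 4000)
        phases = np.array([assign_circular_phase(t, series) for t in times])
        trials = toy_trials(4000)
        out = phase_binned_summary(trials, phases)
        # inspiration (negative phases, 40% of the cycle) spans bins 0-3
        insp_freq = out.rel_freq[:4].sum()
        assert insp_freq == pytest.approx(0.4, abs=0.03)
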