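"""Synthetic respiration, trial schedules and diffusion-model behaviour.

Every downstream stage of the pipeline (respiratory labelling, behavioural
statistics, hierarchical model fitting) is validated against data generated
here with known ground truth.  The generator emulates the structure of a
breathing-belt psychophysics session:

* quasi-periodic breathing — consecutive cycles with log-normally distributed
  durations, a distinct inspiratory (trough-to-peak) fraction, piecewise
  half-cosine waveform and additive Gaussian sensor noise, sampled at 10 Hz;
* a trial schedule of 4 blocks x 80 trials per domain, class-balanced within
  aligned sets (5 up + 5 down per 10 for random dot motion, 2 per emotion
  level per 8 for face affect discrimination), 400 ms stimuli, a response
  window to 2000 ms after offset and inter-trial intervals drawn uniformly
  from 500-2500 ms;
* choices and reaction times drawn from a drift-diffusion process whose
  parameters shift additively with the respiratory state at stimulus onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm_core import (
    DDMParameters,
    RespiratoryDeltas,
    StimulusCoding,
    RDM_CODING,
    FAD_CODING,
    apply_state_modulation,
    simulate_ddm,
)
from .psi_staircase import PsychometricFunction

__all__ = [
    "RespirationTrace",
    "TrialSchedule",
    "GroundTruthSubject",
    "RDM_CLASSES",
    "FAD_CLASSES",
    "generate_respiration",
    "generate_trial_schedule",
    "simulate_session",
    "simulate_psychometric_response",
    "default_subject",
    "write_trace",
    "read_trace",
]

RDM_CLASSES = ("up", "down")
FAD_CLASSES = ("AL", "AH", "HH", "HL")

STIMULUS_MS = 400.0
RESPONSE_WINDOW_MS = 2000.0
ITI_RANGE_MS = (500.0, 2500.0)
N_BLOCKS = 4
TRIALS_PER_BLOCK = 80
SET_SIZE = {"RDM": 10, "FAD": 8}

# which boundary each stimulus class favours in the generator: the correct
# response for RDM, the generating valence for FAD
_UPPER_CLASS = {"up": True, "down": False, "HL": True, "HH": True, "AH": False, "AL": False}


@dataclass
class RespirationTrace:
    """Breathing-belt force series.

    ``samples`` are force values in arbitrary units at ``sample_rate`` Hz.
    ``true_peak_times`` / ``true_trough_times`` (seconds) are present only for
    synthetic traces; ``artefact_mask`` lists half-open [start_s, end_s)
    intervals flagged invalid.
    """

    samples: np.ndarray
    sample_rate: float = 10.0
    true_peak_times: np.ndarray | None = None
    true_trough_times: np.ndarray | None = None
    artefact_mask: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        dur = self.samples.size / self.sample_rate
        for lo, hi in self.artefact_mask:
            if not (0 <= lo < hi <= dur):
                raise ValueError(f"artefact interval [{lo}, {hi}) outside trace span")
        if self.true_peak_times is not None and self.true_trough_times is not None:
            ext = np.concatenate([self.true_trough_times, self.true_peak_times])
            kinds = np.array([0] * len(self.true_trough_times) + [1] * len(self.true_peak_times))
            order = np.argsort(ext)
            if not np.all(np.diff(kinds[order]) != 0):
                raise ValueError("ground-truth peaks and troughs must alternate")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class GroundTruthSubject:
    """Everything needed to generate one subject and later check recovery."""

    base_params: DDMParameters
    deltas: RespiratoryDeltas
    psychometric: PsychometricFunction | None = None
    mean_cycle_s: float = 4.0
    inspiratory_fraction: float = 0.4
    cycle_cv: float = 0.15
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.inspiratory_fraction < 1.0):
            raise ValueError("inspiratory_fraction must be in (0, 1)")
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be >= 0")
        if not (self.mean_cycle_s > 0 and math.isfinite(self.mean_cycle_s)):
            raise ValueError("mean_cycle_s must be positive and finite")
        if not (self.noise_sd >= 0 and math.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be >= 0 and finite")


def default_subject(
    domain: str = "RDM",
    deltas: RespiratoryDeltas | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruthSubject:
    """A subject with decision parameters typical of near-threshold
    discrimination (median RTs around 0.6-0.8 s, ~70-80 % accuracy) and a
    resting breathing rate of ~15 cycles/min with expiration longer than
    inspiration.  ``rng`` adds mild between-subject variation.
    """
    classes = RDM_CLASSES if domain == "RDM" else FAD_CLASSES
    if domain == "RDM":
        v = {"up": 2.2, "down": -2.2}
    else:
        # drifts ordered with morph level: angry classes negative
        v = {"AL": -2.8, "AH": -1.0, "HH": 1.0, "HL": 2.8}
    a, z, t = 1.4, 0.5, 0.35
    if rng is not None:
        v = {c: vv + 0.25 * rng.standard_normal() for c, vv in v.items()}
        a = float(np.clip(a + 0.12 * rng.standard_normal(), 0.8, 2.5))
        z = float(np.clip(z + 0.03 * rng.standard_normal(), 0.35, 0.65))
        t = float(np.clip(t + 0.04 * rng.standard_normal(), 0.15, 0.6))
    if deltas is None:
        deltas = RespiratoryDeltas.zeros(classes)
    return GroundTruthSubject(
        base_params=DDMParameters(v=v, a=a, z=z, t=t),
        deltas=deltas,
        mean_cycle_s=4.0 if rng is None else float(np.clip(4.0 + 0.5 * rng.standard_normal(), 2.5, 6.0)),
        inspiratory_fraction=0.4,
        cycle_cv=0.15,
        noise_sd=0.05,
    )


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def generate_respiration(
    subject: GroundTruthSubject, duration_s: float, seed: int
) -> RespirationTrace:
    """Generate a quasi-periodic breathing trace of at least ``duration_s``.

    Cycle durations are log-normal around ``mean_cycle_s`` with coefficient
    of variation ``cycle_cv``; each cycle rises trough-to-peak as a half
    cosine over ``inspiratory_fraction`` of its duration and falls back over
    the remainder.  Gaussian noise with sd ``noise_sd`` is added, and the
    exact trough/peak times are recorded as ground truth.
    """
    if not math.isfinite(duration_s) or duration_s < subject.mean_cycle_s:
        raise ValueError("duration_s must cover at least one full breathing cycle")
    rng = np.random.default_rng(seed)
    fs = 10.0

    # draw cycles until they cover the requested duration
    cycles = []
    total = 0.0
    if subject.cycle_cv == 0:
        n = int(np.ceil(duration_s / subject.mean_cycle_s))
        cycles = [subject.mean_cycle_s] * n
        total = n * subject.mean_cycle_s
    else:
        sigma2 = math.log(1.0 + subject.cycle_cv**2)
        mu = math.log(subject.mean_cycle_s) - sigma2 / 2.0
        while total < duration_s:
            d = float(rng.lognormal(mu, math.sqrt(sigma2)))
            cycles.append(d)
            total += d

    starts = np.concatenate([[0.0], np.cumsum(cycles)])
    trough_times = starts  # every cycle starts at a trough, incl. final one
    peak_times = starts[:-1] + subject.inspiratory_fraction * np.asarray(cycles)

    n_samples = int(np.floor(total * fs)) + 1
    tt = np.arange(n_samples) / fs
    cyc_idx = np.clip(np.searchsorted(starts, tt, side="right") - 1, 0, len(cycles) - 1)
    local = tt - starts[cyc_idx]
    dur = np.asarray(cycles)[cyc_idx]
    rise = subject.inspiratory_fraction * dur
    # -1 at trough, +1 at peak
    x = np.where(
        local < rise,
        -np.cos(np.pi * local / rise),
        np.cos(np.pi * (local - rise) / (dur - rise)),
    )
    if subject.noise_sd > 0:
        x = x + rng.normal(0.0, subject.noise_sd, size=x.shape)

    keep_peaks = peak_times <= tt[-1]
    keep_troughs = trough_times <= tt[-1]
    return RespirationTrace(
        samples=x,
        sample_rate=fs,
        true_peak_times=peak_times[keep_peaks],
        true_trough_times=trough_times[keep_troughs],
    )


def true_state_at(trace: RespirationTrace, time_s: float) -> str:
    """Ground-truth respiratory state at a time point (synthetic traces)."""
    if trace.true_peak_times is None or trace.true_trough_times is None:
        raise ValueError("trace carries no ground truth")
    last_trough = _last_at_or_before(trace.true_trough_times, time_s)
    last_peak = _last_at_or_before(trace.true_peak_times, time_s)
    if last_trough is None and last_peak is None:
        raise ValueError(f"time {time_s} precedes the first extremum")
    if last_peak is None or (last_trough is not None and last_trough > last_peak):
        return "inspiration"
    return "expiration"


def _last_at_or_before(times: np.ndarray, t: float) -> float | None:
    i = np.searchsorted(times, t, side="right") - 1
    return None if i < 0 else float(times[i])


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

@dataclass
class TrialSchedule:
    """Per-trial timing and stimulus classes for one session."""

    domain: str
    table: pd.DataFrame  # block, trial, stimulus_class, onset_time_s, iti_ms

    @property
    def duration_s(self) -> float:
        last = self.table.iloc[-1]
        return float(last.onset_time_s + (STIMULUS_MS + RESPONSE_WINDOW_MS) / 1000.0)


def generate_trial_schedule(domain: str, seed: int) -> TrialSchedule:
    """4 blocks x 80 trials, class-balanced within each aligned set
    (shuffled within sets of 10 for RDM, 8 for FAD), ITIs ~ U(500, 2500) ms,
    onsets laid out sequentially from the ITIs and response windows."""
    if domain not in SET_SIZE:
        raise ValueError(f"domain must be one of {tuple(SET_SIZE)}, got {domain!r}")
    rng = np.random.default_rng(seed)
    classes = RDM_CLASSES if domain == "RDM" else FAD_CLASSES
    set_size = SET_SIZE[domain]
    per_class = set_size // len(classes)

    rows = []
    onset = 0.0
    trial_idx = 0
    for block in range(N_BLOCKS):
        for _ in range(TRIALS_PER_BLOCK // set_size):
            batch = list(classes) * per_class
            rng.shuffle(batch)
            for cls in batch:
                iti = float(rng.uniform(*ITI_RANGE_MS))
                rows.append(
                    dict(
                        block=block,
                        trial=trial_idx,
                        stimulus_class=cls,
                        onset_time_s=onset,
                        stimulus_duration_ms=STIMULUS_MS,
                        response_deadline_ms=STIMULUS_MS + RESPONSE_WINDOW_MS,
                        iti_ms=iti,
                    )
                )
                onset += (STIMULUS_MS + RESPONSE_WINDOW_MS + iti) / 1000.0
                trial_idx += 1
    return TrialSchedule(domain=domain, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def simulate_session(
    subject: GroundTruthSubject,
    schedule: TrialSchedule,
    trace: RespirationTrace,
    seed: int,
    subject_id: str = "s00",
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate choices and RTs for every scheduled trial.

    The ground-truth respiratory state *at stimulus onset* selects the
    effective DDM parameters (this is a generator convention: the analysis
    pipeline labels trials independently by onset and by response).  Trials
    whose RT exceeds the response deadline are marked missed with NaN RT,
    never dropped.  Returns a trial table with one row per trial.
    """
    if trace.duration_s < schedule.duration_s:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) does not cover the schedule "
            f"({schedule.duration_s:.1f} s)"
        )
    coding = RDM_CODING if schedule.domain == "RDM" else FAD_CODING
    rng = np.random.default_rng(seed)

    tab = schedule.table
    states = np.array([true_state_at(trace, t) for t in tab.onset_time_s])

    # simulate per (state, class) batch for speed, then scatter back
    rt_s = np.empty(len(tab))
    choice = np.empty(len(tab), dtype=object)
    for state in ("inspiration", "expiration"):
        eff = apply_state_modulation(subject.base_params, subject.deltas, state)
        for cls in subject.base_params.v:
            sel = np.flatnonzero((states == state) & (tab.stimulus_class == cls).to_numpy())
            if sel.size == 0:
                continue
            ch, rt = simulate_ddm(
                eff.v[cls], eff.a, eff.z, eff.t, n=sel.size, dt=dt,
                seed=int(rng.integers(2**31 - 1)),
            )
            rt_s[sel] = rt
            choice[sel] = np.where(ch == 1, coding.upper, np.where(ch == 0, coding.lower, None))

    deadline_s = (STIMULUS_MS + RESPONSE_WINDOW_MS) / 1000.0
    missed = np.isnan(rt_s) | (rt_s > deadline_s)
    rt_ms = np.where(missed, np.nan, rt_s * 1000.0)

    out = tab[["block", "trial", "stimulus_class", "onset_time_s"]].copy()
    out.insert(0, "subject_id", subject_id)
    out.insert(1, "domain", schedule.domain)
    out = out.rename(columns={"onset_time_s": "onset_s"})
    out["rt_ms"] = rt_ms
    out["choice"] = [c if not m else None for c, m in zip(choice, missed)]
    out["missed"] = missed
    out["response_s"] = out.onset_s + rt_s  # NaN-free; only meaningful when not missed
    out.loc[missed, "response_s"] = np.nan
    out["true_state_onset"] = states
    return out


def simulate_psychometric_response(
    psychometric: PsychometricFunction, intensity: float, seed: int | np.random.Generator
) -> int:
    """One Bernoulli draw with success probability ``psi(intensity)``."""
    lo, hi = psychometric.domain
    if not (lo <= intensity <= hi):
        raise ValueError(f"intensity {intensity} outside domain [{lo}, {hi}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.random() < psychometric(intensity))


def simulate_labelled_cohort(
    domain: str,
    n_subjects: int,
    deltas: RespiratoryDeltas,
    seed: int,
    n_trials: int | None = None,
    locking: str = "stimulus",
    labelling: str = "pipeline",
    dt: float = 2e-4,
) -> pd.DataFrame:
    """Simulate a cohort and attach respiratory-state labels.

    Each subject gets individual decision/breathing parameters (see
    :func:`default_subject`), a fresh schedule and respiration trace, and a
    simulated session.  With ``labelling='pipeline'`` trials are labelled
    through the actual preprocessing chain (filter, peak detection, event
    labelling) at the requested locking; with ``labelling='truth'`` the
    generator's own onset-state ground truth is used, which isolates
    estimator behaviour from labelling noise in recovery studies.
    ``n_trials`` truncates the 320-trial schedule for reduced designs.
    Returns the concatenated trial table with a ``state`` column.
    """
    from .resp_preproc import preprocess_trace, detect_extrema, label_events

    if labelling not in ("pipeline", "truth"):
        raise ValueError("labelling must be 'pipeline' or 'truth'")
    ss = np.random.SeedSequence(seed)
    frames = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        s1, s2, s3, s4 = (int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in child.spawn(4))
        rng = np.random.default_rng(s1)
        subject = default_subject(domain, deltas=deltas, rng=rng)
        schedule = generate_trial_schedule(domain, seed=s2)
        if n_trials is not None:
            schedule = TrialSchedule(domain=domain, table=schedule.table.iloc[:n_trials].copy())
        trace = generate_respiration(subject, schedule.duration_s + 10.0, seed=s3)
        tab = simulate_session(subject, schedule, trace, seed=s4, subject_id=f"s{i:02d}", dt=dt)
        if labelling == "truth":
            tab["state"] = tab.true_state_onset
            tab["phase"] = np.nan
        else:
            series = detect_extrema(preprocess_trace(trace))
            times = tab.onset_s if locking == "stimulus" else tab.response_s
            labels = label_events(times.to_numpy(), series)
            tab["state"] = [l.state for l in labels]
            tab["phase"] = [l.circular_phase for l in labels]
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_trace(trace: RespirationTrace, csv_path, json_path) -> None:
    """Two-column CSV (time_s, force) plus a JSON sidecar with sample rate,
    artefact intervals and, when present, ground-truth extrema."""
    pd.DataFrame({"time_s": trace.times, "force": trace.samples}).to_csv(csv_path, index=False)
    meta = {
        "sample_rate": trace.sample_rate,
        "artefact_mask": [list(iv) for iv in trace.artefact_mask],
    }
    if trace.true_peak_times is not None:
        meta["true_peak_times"] = list(map(float, trace.true_peak_times))
        meta["true_trough_times"] = list(map(float, trace.true_trough_times))
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trace(csv_path, json_path) -> RespirationTrace:
    df = pd.read_csv(csv_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    return RespirationTrace(
        samples=df["force"].to_numpy(),
        sample_rate=float(meta["sample_rate"]),
        true_peak_times=np.asarray(meta["true_peak_times"]) if "true_peak_times" in meta else None,
        true_trough_times=np.asarray(meta["true_trough_times"]) if "true_trough_times" in meta else None,
        artefact_mask=[tuple(iv) for iv in meta.get("artefact_mask", [])],
    )
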