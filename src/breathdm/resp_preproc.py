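"""Respiratory-trace preprocessing and event labelling.

A raw breathing-belt force trace is low-pass filtered (5th-order Butterworth
at 1 Hz, applied forward-backward so extremum timing is not shifted) and
z-scored.  Peaks are detected on the standardised signal (topographic
prominence >= 0.2 z-units, minimum separation 10 samples, width >= 2 samples
at half prominence); the minimum between each consecutive pair of peaks is a
trough, plus a leading trough before the first peak.  The trace is then
binarised into inspiratory (trough-to-peak) and expiratory (peak-to-trough)
half-open segments.

Behavioural events (stimulus onsets, responses) are labelled by their
containing segment; an event falling on an extremum sample is a respiratory
*transition* and is excluded from state analyses, and events outside the
detected-extrema span or inside annotated artefact intervals are left
unlabelled.  A continuous circular phase maps inspiration to [-pi, 0) and
expiration to [0, pi) by linear interpolation within each segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic_data import RespirationTrace

__all__ = [
    "StateSeries",
    "EventLabel",
    "preprocess_trace",
    "detect_extrema",
    "binarize_states",
    "label_events",
    "assign_circular_phase",
]

FILTER_ORDER = 5
CUTOFF_HZ = 1.0
PEAK_PROMINENCE = 0.2
PEAK_DISTANCE = 10    # samples
PEAK_WIDTH = 2        # samples at half prominence


@dataclass
class StateSeries:
    """Alternating extrema and the respiratory state segments they induce."""

    extrema_times: np.ndarray          # seconds, strictly increasing
    extrema_kinds: np.ndarray          # 'peak' / 'trough', alternating
    sample_rate: float
    artefact_mask: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.extrema_times, dtype=float)
        k = np.asarray(self.extrema_kinds)
        if t.size != k.size:
            raise ValueError("extrema times and kinds must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("extrema must be strictly increasing in time")
        if t.size >= 2 and np.any(k[1:] == k[:-1]):
            raise ValueError("extrema kinds must alternate")
        self.extrema_times = t
        self.extrema_kinds = k

    @property
    def span(self) -> tuple[float, float]:
        return float(self.extrema_times[0]), float(self.extrema_times[-1])


@dataclass(frozen=True)
class EventLabel:
    event_time_s: float
    state: str                       # inspiration / expiration / transition / unlabelled
    circular_phase: float | None     # radians in [-pi, pi), None when unlabelled
    in_artefact: bool


def preprocess_trace(trace: RespirationTrace) -> RespirationTrace:
    """Low-pass filter (Butterworth, zero-phase) and z-score a trace.

    The forward-backward application doubles the effective attenuation but
    keeps extrema where they are — the quantity the whole pipeline is about.
    A constant trace (sd 0) cannot be z-scored and raises.
    """
    if trace.sample_rate <= 2 * CUTOFF_HZ:
        raise ValueError(
            f"sample rate {trace.sample_rate} Hz too low for a {CUTOFF_HZ} Hz cutoff"
        )
    sos = signal.butter(FILTER_ORDER, CUTOFF_HZ, btype="low", fs=trace.sample_rate, output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    sd = x.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("constant trace cannot be standardised")
    z = (x - x.mean()) / sd
    return RespirationTrace(
        samples=z,
        sample_rate=trace.sample_rate,
        true_peak_times=trace.true_peak_times,
        true_trough_times=trace.true_trough_times,
        artefact_mask=list(trace.artefact_mask),
    )


def detect_extrema(trace: RespirationTrace) -> StateSeries:
    """Detect peaks and the troughs between them on a preprocessed trace."""
    x = trace.samples
    peaks, _ = signal.find_peaks(
        x, prominence=PEAK_PROMINENCE, distance=PEAK_DISTANCE, width=PEAK_WIDTH
    )
    if peaks.size < 2:
        raise ValueError("no respiratory cycles: fewer than 2 peaks detected")

    troughs = []
    # leading trough: minimum of the segment before the first peak
    lead = int(np.argmin(x[: peaks[0]])) if peaks[0] > 0 else None
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        troughs.append(p0 + 1 + int(np.argmin(x[p0 + 1 : p1])))

    idx = list(peaks)
    kinds = ["peak"] * len(idx)
    idx += troughs
    kinds += ["trough"] * len(troughs)
    if lead is not None:
        idx.append(lead)
        kinds.append("trough")
    order = np.argsort(idx)
    idx = np.asarray(idx)[order]
    kinds = np.asarray(kinds, dtype=object)[order]
    return StateSeries(
        extrema_times=idx / trace.sample_rate,
        extrema_kinds=kinds,
        sample_rate=trace.sample_rate,
        artefact_mask=list(trace.artefact_mask),
    )


def binarize_states(series: StateSeries) -> list[tuple[float, float, str]]:
    """Half-open [start_s, end_s) segments labelled by respiratory state.

    A segment starting at a trough is inspiration, at a peak expiration;
    time before the first and after the last extremum carries no state.
    """
    out = []
    for t0, t1, k in zip(series.extrema_times[:-1], series.extrema_times[1:], series.extrema_kinds[:-1]):
        out.append((float(t0), float(t1), "inspiration" if k == "trough" else "expiration"))
    return out


def _in_artefact(t: float, mask) -> bool:
    return any(lo <= t < hi for lo, hi in mask)


def label_events(event_times, series: StateSeries) -> list[EventLabel]:
    """Label each event time by respiratory state and circular phase.

    'Exactly at a peak or trough' is resolved at sample resolution: an event
    whose sample index equals an extremum's sample index is a transition.
    Events outside the extrema span or inside an artefact interval are
    unlabelled (and excluded from state analyses downstream).
    """
    fs = series.sample_rate
    ext_idx = np.round(series.extrema_times * fs).astype(int)
    lo, hi = series.span
    segments = binarize_states(series)
    starts = np.array([s[0] for s in segments])

    out = []
    for t in np.atleast_1d(np.asarray(event_times, dtype=float)):
        if not np.isfinite(t):  # e.g. missed trials have no response time
            out.append(EventLabel(float(t), "unlabelled", None, False))
            continue
        art = _in_artefact(t, series.artefact_mask)
        if art or t < lo or t >= hi:
            out.append(EventLabel(float(t), "unlabelled", None, art))
            continue
        if int(round(t * fs)) in ext_idx:
            out.append(EventLabel(float(t), "transition", None, False))
            continue
        seg = segments[int(np.searchsorted(starts, t, side="right") - 1)]
        out.append(EventLabel(float(t), seg[2], assign_circular_phase(t, series), False))
    return out


def assign_circular_phase(event_time: float, series: StateSeries) -> float:
    """Circular respiratory phase of an event, in radians.

    Linear interpolation within the containing segment: inspiration maps
    [trough, peak) onto [-pi, 0), expiration maps [peak, trough) onto
    [0, pi).  A trough is -pi, a peak 0.
    """
    lo, hi = series.span
    if not (lo <= event_time < hi):
        raise ValueError(f"event time {event_time} outside the labelled span [{lo}, {hi})")
    segments = binarize_states(series)
    starts = np.array([s[0] for s in segments])
    t0, t1, state = segments[int(np.searchsorted(starts, event_time, side="right") - 1)]
    frac = (event_time - t0) / (t1 - t0)
    return float(-np.pi + np.pi * frac) if state == "inspiration" else float(np.pi * frac)
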