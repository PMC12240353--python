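"""Behavioural exclusions, state-wise summaries and paired tests.

Exclusion rules: missed trials and reaction times below 100 ms are dropped
first; trials whose respiratory label is a transition or unlabelled are
dropped from state analyses; subjects with an absolute signal-detection
criterion above 0.6 in the motion task are flagged for exclusion from
motion analyses.  An exclusion ledger accounts for every presented trial.

State-wise summaries per subject give hit rate (motion), proportion of
'happy' responses (faces) and median reaction time, separately for
stimulus-locked and response-locked labelling.  Group comparisons use
two-sided paired t-tests with a JZS Bayes factor (Cauchy prior scale
sqrt(2)/2 on the standardised effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "TTestResult",
    "exclude_trials",
    "compute_criterion",
    "summarize_by_state",
    "paired_ttest_bf",
    "phase_binned_summary",
]

RT_FLOOR_MS = 100.0
CRITERION_CUTOFF = 0.6
BF_PRIOR_SCALE = np.sqrt(2) / 2


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    ci95: tuple[float, float]
    t: float
    dof: int
    p: float
    bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def exclude_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop missed trials and RTs below 100 ms; if a ``state`` column is
    present, additionally drop transition/unlabelled trials.

    Returns the retained table and a ledger whose counts sum to the input
    row count.
    """
    ledger = {"presented": len(trials)}
    missed = trials["missed"].fillna(False).astype(bool) if "missed" in trials else trials["rt_ms"].isna()
    fast = (~missed) & (trials["rt_ms"] < RT_FLOOR_MS)
    keep = ~(missed | fast)
    ledger["excluded_missed"] = int(missed.sum())
    ledger["excluded_fast_rt"] = int(fast.sum())
    out = trials[keep]
    if "state" in out.columns:
        transition = out["state"] == "transition"
        unlabelled = out["state"] == "unlabelled"
        ledger["excluded_transition"] = int(transition.sum())
        ledger["excluded_unlabelled"] = int(unlabelled.sum())
        out = out[~(transition | unlabelled)]
    ledger["retained"] = len(out)
    assert ledger["presented"] == ledger["retained"] + sum(
        v for k, v in ledger.items() if k.startswith("excluded_")
    )
    return out.copy(), ledger


def compute_criterion(trials: pd.DataFrame) -> float:
    """Signal-detection criterion c for the motion task.

    c = -0.5 * [Phi^-1(H) + Phi^-1(F)] with H the proportion of 'up'
    responses to upward stimuli and F the proportion of 'up' responses to
    downward stimuli.  Proportions of exactly 0 or 1 are adjusted by the
    1/(2N) rule so the quantiles stay finite.  |c| > 0.6 flags the subject
    for exclusion from motion analyses.
    """
    up = trials[trials.stimulus_class == "up"]
    down = trials[trials.stimulus_class == "down"]
    if len(up) == 0 or len(down) == 0:
        raise ValueError("criterion needs trials of both stimulus classes")

    def rate(sub: pd.DataFrame) -> float:
        p = float((sub.choice == "up").mean())
        n = len(sub)
        return min(max(p, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    return float(-0.5 * (stats.norm.ppf(rate(up)) + stats.norm.ppf(rate(down))))


def _correct(trials: pd.DataFrame) -> pd.Series:
    # motion: the correct response equals the stimulus class
    return trials.choice == trials.stimulus_class


def summarize_by_state(
    trials: pd.DataFrame, labels: list, locking: str
) -> pd.DataFrame:
    """Per-state behavioural summary for one subject.

    ``labels`` are EventLabels aligned row-for-row with ``trials`` for the
    chosen locking ('stimulus' or 'response').  Exclusion rules are applied
    internally.  Returns one row per respiratory state with hit rate (RDM)
    or proportion 'happy' (FAD), median RT and trial count; a state with no
    trials yields a row of NaNs with ``flagged=True``.
    """
    if locking not in ("stimulus", "response"):
        raise ValueError("locking must be 'stimulus' or 'response'")
    if len(labels) != len(trials):
        raise ValueError("labels must align with trials")
    df = trials.copy()
    df["state"] = [l.state for l in labels]
    df["phase"] = [l.circular_phase for l in labels]
    df, _ = exclude_trials(df)

    domain = df.domain.iloc[0] if len(df) else "RDM"
    rows = []
    for state in ("inspiration", "expiration"):
        sub = df[df.state == state]
        if len(sub) == 0:
            rows.append(dict(state=state, locking=locking, value=np.nan,
                             median_rt_ms=np.nan, n_trials=0, flagged=True))
            continue
        if domain == "RDM":
            value = float(_correct(sub).mean())
        else:
            value = float((sub.choice == "happy").mean())
        rows.append(dict(
            state=state, locking=locking, value=value,
            median_rt_ms=float(sub.rt_ms.median()), n_trials=len(sub), flagged=False,
        ))
    out = pd.DataFrame(rows)
    out.attrs["measure"] = "hit_rate" if domain == "RDM" else "proportion_happy"
    return out


def paired_ttest_bf(values_a, values_b) -> TTestResult:
    """Two-sided paired t-test with a JZS Bayes factor.

    The Bayes factor uses the Cauchy prior with scale sqrt(2)/2 on the
    standardised effect size (the conventional default).  Differences with
    zero variance are degenerate and raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    n = d.size
    t_stat, p = stats.ttest_rel(a, b)
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    bf10 = float(pg.bayesfactor_ttest(float(t_stat), n, paired=True, r=BF_PRIOR_SCALE))
    return TTestResult(
        mean_difference=float(d.mean()),
        ci95=(float(d.mean() - tcrit * se), float(d.mean() + tcrit * se)),
        t=float(t_stat),
        dof=n - 1,
        p=float(p),
        bf10=bf10,
    )


def phase_binned_summary(trials: pd.DataFrame, phases, n_bins: int = 8) -> pd.DataFrame:
    """Behaviour in equal-width circular phase bins over [-pi, pi).

    Returns, per bin: the response measure (hit rate or proportion 'happy'),
    median RT, trial count and relative event frequency.  Bins with no
    trials carry NaN measures.
    """
    phases = np.asarray(
        [p if p is not None else np.nan for p in phases], dtype=float
    )
    if len(phases) != len(trials):
        raise ValueError("phases must align with trials")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    df = trials.copy()
    df["phase"] = phases
    df = df[np.isfinite(df.phase)]
    idx = np.clip(np.digitize(df.phase, edges) - 1, 0, n_bins - 1)
    df["bin"] = idx

    domain = df.domain.iloc[0] if len(df) else "RDM"
    rows = []
    total = len(df)
    for b in range(n_bins):
        sub = df[df.bin == b]
        if domain == "RDM":
            value = float(_correct(sub).mean()) if len(sub) else np.nan
        else:
            value = float((sub.choice == "happy").mean()) if len(sub) else np.nan
        rows.append(dict(
            bin=b, lo=edges[b], hi=edges[b + 1], value=value,
            median_rt_ms=float(sub.rt_ms.median()) if len(sub) else np.nan,
            n_trials=len(sub),
            rel_freq=len(sub) / total if total else np.nan,
        ))
    return pd.DataFrame(rows)
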