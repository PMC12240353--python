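"""Psi adaptive staircase for psychometric threshold estimation.

The Psi method maintains a grid posterior over psychometric threshold
(alpha) and slope (beta) and, on every trial, presents the stimulus
intensity that minimises the expected posterior entropy, averaged over the
two possible responses weighted by their predictive probabilities.  After a
run, thresholds are read from the psychometric function evaluated at the
posterior-mean parameters.

The psychometric family is a cumulative normal core with fixed asymptotes:

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - alpha) / beta)

where ``gamma`` is the lower asymptote (0.5 for a two-alternative motion
task, 0 for a happy/angry morph judgement), ``lambda`` the lapse rate and
``beta`` the standard deviation of the core (larger = shallower).

Two presets mirror the configurations used for random dot motion (RDM:
coherence 0-1) and face affect discrimination (FAD: 201 morph levels, i.e.
0-200 in 0.5 %-happy steps); they ship as YAML files under ``presets/``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "PsychometricFunction",
    "PsiConfig",
    "PsiState",
    "load_preset",
    "psi_init",
    "psi_next_intensity",
    "psi_update",
    "estimate_threshold",
    "select_stimulus_levels",
    "run_staircase",
    "FAD_LEVEL_TARGETS",
]

FAD_LEVEL_TARGETS = (0.35, 0.45, 0.55, 0.65)
FAD_LEVEL_NAMES = ("AL", "AH", "HH", "HL")


@dataclass(frozen=True)
class PsychometricFunction:
    """Cumulative-normal psychometric function with fixed asymptotes."""

    alpha: float
    beta: float
    gamma: float  # lower asymptote ("expected minimum")
    lam: float    # lapse rate ("guess rate" shortfall of the upper asymptote)
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("slope parameter beta must be positive")
        if not (0 <= self.gamma < 1 and 0 <= self.lam < 1 and self.gamma + self.lam < 1):
            raise ValueError("asymptotes must satisfy gamma + lambda < 1")

    def __call__(self, x) -> np.ndarray | float:
        return self.gamma + (1.0 - self.gamma - self.lam) * norm.cdf(
            (np.asarray(x, dtype=float) - self.alpha) / self.beta
        )


@dataclass(frozen=True)
class PsiConfig:
    intensity_grid: np.ndarray
    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    gamma: float
    lam: float

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.intensity_grid[0]), float(self.intensity_grid[-1])


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    g = lo + step * np.arange(n + 1)
    return g[g <= hi + 1e-12]


def load_preset(name: str) -> PsiConfig:
    """Load the 'rdm' or 'fad' YAML preset shipped with the package."""
    with resources.files("breathdm.presets").joinpath(f"{name.lower()}.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return PsiConfig(
        intensity_grid=_grid(*cfg["intensity_range"], cfg["intensity_precision"]),
        alpha_grid=_grid(*cfg["threshold_range"], cfg["threshold_precision"]),
        beta_grid=_grid(*cfg["slope_range"], cfg["slope_precision"]),
        gamma=float(cfg["expected_minimum"]),
        lam=float(cfg["guess_rate"]),
    )


@dataclass
class PsiState:
    """Grid posterior over (alpha, beta) plus the trial log."""

    config: PsiConfig
    posterior: np.ndarray            # (n_alpha * n_beta,), sums to 1
    psi_table: np.ndarray            # (n_intensity, n_alpha * n_beta)
    trial_log: list = field(default_factory=list)

    @property
    def alpha_beta(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = np.meshgrid(self.config.alpha_grid, self.config.beta_grid, indexing="ij")
        return a.ravel(), b.ravel()

    def posterior_mean(self) -> tuple[float, float]:
        a, b = self.alpha_beta
        return float(self.posterior @ a), float(self.posterior @ b)

    def mean_function(self) -> PsychometricFunction:
        am, bm = self.posterior_mean()
        return PsychometricFunction(
            alpha=am, beta=bm, gamma=self.config.gamma, lam=self.config.lam,
            domain=self.config.domain,
        )


def psi_init(config: PsiConfig) -> PsiState:
    """Uniform prior over the (alpha, beta) grid; precomputes the response
    probability lookup table used by the entropy rule."""
    if config.intensity_grid.size == 0 or config.alpha_grid.size == 0 or config.beta_grid.size == 0:
        raise ValueError("empty Psi grid")
    a, b = np.meshgrid(config.alpha_grid, config.beta_grid, indexing="ij")
    a, b = a.ravel(), b.ravel()
    x = config.intensity_grid[:, None]
    table = config.gamma + (1.0 - config.gamma - config.lam) * norm.cdf((x - a[None, :]) / b[None, :])
    n = a.size
    return PsiState(config=config, posterior=np.full(n, 1.0 / n), psi_table=table)


def psi_next_intensity(state: PsiState) -> float:
    """Intensity minimising expected posterior entropy over (alpha, beta).

    Deterministic given the state; ties broken to the lowest intensity
    index so runs replay exactly.
    """
    post = state.posterior
    tab = state.psi_table
    p1 = tab @ post                      # predictive P(response=1 | x)
    p1 = np.clip(p1, 1e-300, 1.0)
    p0 = np.clip(1.0 - p1, 1e-300, 1.0)

    # unnormalised posteriors for each response; entropy via sum p log p
    w1 = tab * post[None, :]
    w0 = (1.0 - tab) * post[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = -np.sum(np.where(w1 > 0, w1 * np.log(w1 / p1[:, None]), 0.0), axis=1) / p1
        h0 = -np.sum(np.where(w0 > 0, w0 * np.log(w0 / p0[:, None]), 0.0), axis=1) / p0
    expected_h = p1 * h1 + p0 * h0
    return float(state.config.intensity_grid[int(np.argmin(expected_h))])


def psi_update(state: PsiState, intensity: float, response: int) -> PsiState:
    """Bayes update of the grid posterior after observing ``response`` in
    {0, 1} at ``intensity`` (which must be on the intensity grid)."""
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    xi = int(np.argmin(np.abs(state.config.intensity_grid - intensity)))
    if abs(state.config.intensity_grid[xi] - intensity) > 1e-9:
        raise ValueError(f"intensity {intensity} not on the grid")
    like = state.psi_table[xi] if response == 1 else 1.0 - state.psi_table[xi]
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior mass vanished: response inconsistent with model")
    new = PsiState(
        config=state.config,
        posterior=post / total,
        psi_table=state.psi_table,
        trial_log=state.trial_log + [(float(intensity), int(response))],
    )
    return new


def estimate_threshold(state: PsiState, target_probability: float) -> float:
    """Intensity at which the posterior-mean psychometric function equals
    ``target_probability``, by monotone interpolation on the intensity grid."""
    cfg = state.config
    attain_lo, attain_hi = cfg.gamma, 1.0 - cfg.lam
    if not (attain_lo < target_probability < attain_hi):
        raise ValueError(
            f"target {target_probability} outside attainable range ({attain_lo}, {attain_hi})"
        )
    f = state.mean_function()
    vals = np.asarray(f(cfg.intensity_grid))
    if target_probability < vals[0] or target_probability > vals[-1]:
        raise ValueError(
            f"target {target_probability} not reached on the intensity domain "
            f"[{vals[0]:.3f}, {vals[-1]:.3f}]"
        )
    return float(np.interp(target_probability, vals, cfg.intensity_grid))


def select_stimulus_levels(
    state: PsiState, targets=FAD_LEVEL_TARGETS
) -> dict[str, float]:
    """Map response-probability targets to test-stimulus intensities.

    With the default targets this returns the four face-affect levels:
    35 % (angry, low ambiguity), 45 % (angry, high), 55 % (happy, high) and
    65 % (happy, low ambiguity)."""
    levels = [estimate_threshold(state, p) for p in targets]
    grid = state.config.intensity_grid
    step = float(grid[1] - grid[0]) if grid.size > 1 else 0.0
    if max(levels) - min(levels) <= step:
        warnings.warn("degenerate slope: selected stimulus levels collapse together")
    names = FAD_LEVEL_NAMES if len(targets) == 4 else [f"L{i}" for i in range(len(targets))]
    return dict(zip(names, levels))


def run_staircase(
    config: PsiConfig,
    observer: PsychometricFunction,
    n_trials: int = 50,
    seed: int = 0,
    miss_prob: float = 0.0,
) -> PsiState:
    """Run a staircase against a simulated observer.

    A missed trial (probability ``miss_prob``) is repeated at the same
    intensity without updating the posterior, so the posterior always
    reflects exactly ``n_trials`` responses.
    """
    from .synthetic_data import simulate_psychometric_response

    rng = np.random.default_rng(seed)
    state = psi_init(config)
    done = 0
    while done < n_trials:
        x = psi_next_intensity(state)
        if miss_prob > 0 and rng.random() < miss_prob:
            continue  # repeat the same intensity; no update
        r = simulate_psychometric_response(observer, x, rng)
        state = psi_update(state, x, r)
        done += 1
    return state
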