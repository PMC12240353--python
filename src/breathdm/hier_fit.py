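"""Hierarchical Bayesian estimation of the respiratory-state DDM.

Model.  Choice/RT data from one task domain are fit with a stimulus-coded
drift-diffusion model: one drift rate per stimulus class, plus boundary
separation ``a``, relative starting point ``z`` and non-decision time ``t``
per subject.  Subject-level parameters theta_s are partially pooled through
group normals, theta_s ~ N(mu_theta, sigma_theta).  Respiratory state enters
as group-level fixed effects: a single delta per parameter, shared by all
subjects, added to the subject's parameter on inspiration trials (expiration
is the reference state).  A random-dot-motion model therefore has 5 deltas
(dv_up, dv_down, da, dz, dt) and a face-affect model 7 (four drift deltas
plus da, dz, dt).

Priors are flat: wide uniforms on every base parameter, delta and group sd
(bounds below), chosen so that posterior mass at the bounds is negligible at
the parameter scales this kind of data produces.

Sampling.  Adaptive Metropolis-within-Gibbs: component-wise random-walk
updates for subject parameters and deltas (proposal scales adapted toward
~35 % acceptance during burn-in only, so detailed balance holds afterwards),
a Gibbs draw for each group mean (truncated normal) and a log-scale
random-walk update for each group sd.  Multiple chains run independently
from jittered moment-based starting values; convergence is checked with the
Gelman-Rubin statistic at the conventional 1.02 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm_core import (
    RDM_CODING,
    FAD_CODING,
    A_MIN,
    A_MAX,
    Z_MIN,
    Z_MAX,
    T_MIN,
    T_MAX,
    V_ABS_MAX,
    wfpt_sum_loglik,
    simulate_ddm,
)
from .synthetic_data import RDM_CLASSES, FAD_CLASSES
from .behav_stats import exclude_trials

__all__ = [
    "HierarchicalModelSpec",
    "MCMCChains",
    "ConvergenceReport",
    "SamplingProfile",
    "FULL_PROFILE",
    "DESK_PROFILE",
    "build_model",
    "run_mcmc",
    "gelman_rubin",
    "posterior_predictive",
]

# flat-prior bounds; subject-level supports match ddm_core validation
BASE_BOUNDS = {"v": (-V_ABS_MAX, V_ABS_MAX), "a": (A_MIN, A_MAX), "z": (Z_MIN, Z_MAX), "t": (T_MIN, T_MAX)}
DELTA_BOUNDS = {"v": (-10.0, 10.0), "a": (-2.0, 2.0), "z": (-0.5, 0.5), "t": (-0.5, 0.5)}
SIGMA_BOUNDS = (1e-4, 3.0)

_INIT_SCALES = {"v": 0.30, "a": 0.12, "z": 0.04, "t": 0.02}
_DELTA_SCALES = {"v": 0.10, "a": 0.03, "z": 0.012, "t": 0.008}


@dataclass(frozen=True)
class SamplingProfile:
    n_chains: int = 4
    n_samples: int = 10_000
    burn_in: int = 2_000
    thin: int = 2
    # group/delta blocks repeated per subject sweep: they are cheap relative
    # to the subject updates and extra repeats cut group-level autocorrelation
    group_reps: int = 4


FULL_PROFILE = SamplingProfile(4, 10_000, 2_000, 2)
DESK_PROFILE = SamplingProfile(4, 3_000, 600, 2, group_reps=3)


@dataclass
class HierarchicalModelSpec:
    """Prepared data and parameter layout for one domain's fit."""

    domain: str
    locking: str
    classes: tuple[str, ...]
    subject_ids: list[str]
    # cells[s][c][state] = (rt_seconds, upper_bool); state 0 expiration, 1 inspiration
    cells: list[list[list[tuple[np.ndarray, np.ndarray]]]]

    @property
    def param_names(self) -> list[str]:
        return [f"v_{c}" for c in self.classes] + ["a", "z", "t"]

    @property
    def param_kinds(self) -> list[str]:
        return ["v"] * len(self.classes) + ["a", "z", "t"]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def min_rt(self, s: int) -> float:
        rts = [rt for cls in self.cells[s] for (rt, _) in cls if rt.size]
        return float(min(r.min() for r in rts if r.size))


@dataclass
class MCMCChains:
    """Post burn-in, thinned samples: name -> (n_chains, n_kept) array."""

    samples: dict[str, np.ndarray]
    profile: SamplingProfile
    seeds: list[int]
    param_names: list[str]

    @property
    def group_parameter_names(self) -> list[str]:
        return [k for k in self.samples if k.startswith(("mu_", "sigma_", "delta_"))]

    def pooled(self, name: str) -> np.ndarray:
        return self.samples[name].ravel()


@dataclass
class ConvergenceReport:
    grs: dict[str, float]
    threshold: float = 1.02

    @property
    def passed(self) -> bool:
        return all(v < self.threshold for v in self.grs.values())

    @property
    def flagged(self) -> list[str]:
        return [k for k, v in self.grs.items() if v >= self.threshold]


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

def build_model(trials: pd.DataFrame, domain: str, locking: str = "response") -> HierarchicalModelSpec:
    """Turn a state-labelled trial table into a fit-ready model spec.

    ``trials`` must carry subject_id, stimulus_class, choice, rt_ms and a
    ``state`` column ('inspiration'/'expiration'/'transition'/'unlabelled')
    for the chosen locking.  Missed/fast/transition/unlabelled trials are
    excluded here.  Requires >= 2 subjects, both states per subject, and
    every stimulus class present.
    """
    if domain not in ("RDM", "FAD"):
        raise ValueError("domain must be 'RDM' or 'FAD'")
    classes = RDM_CLASSES if domain == "RDM" else FAD_CLASSES
    coding = RDM_CODING if domain == "RDM" else FAD_CODING
    missing = set(classes) - set(trials.stimulus_class.unique())
    if missing:
        raise ValueError(f"missing stimulus classes: {sorted(missing)}")

    kept, _ = exclude_trials(trials)
    subject_ids = sorted(kept.subject_id.unique())
    if len(subject_ids) < 2:
        raise ValueError("hierarchical model needs at least 2 subjects")

    cells = []
    for sid in subject_ids:
        sub = kept[kept.subject_id == sid]
        for state in ("inspiration", "expiration"):
            if not (sub.state == state).any():
                raise ValueError(f"subject {sid} has no {state} trials")
        per_class = []
        for cls in classes:
            per_state = []
            for state in ("expiration", "inspiration"):
                cell = sub[(sub.stimulus_class == cls) & (sub.state == state)]
                rt = cell.rt_ms.to_numpy(dtype=float) / 1000.0
                upper = (cell.choice == coding.upper).to_numpy()
                per_state.append((np.ascontiguousarray(rt), np.ascontiguousarray(upper)))
            per_class.append(per_state)
        cells.append(per_class)
    return HierarchicalModelSpec(
        domain=domain, locking=locking, classes=classes,
        subject_ids=subject_ids, cells=cells,
    )


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)


def _mh_step(x: float, scale: float, logpost, rng, lo=-np.inf, hi=np.inf):
    """One random-walk Metropolis step on a scalar with hard bounds.

    Returns (new_x, new_logpost, accepted); ``logpost`` is called only for
    in-bounds proposals.
    """
    prop = x + scale * rng.standard_normal()
    if not (lo < prop < hi):
        return x, None, False
    lp_x = logpost(x)
    lp_p = logpost(prop)
    if math.log(rng.random() + 1e-300) < lp_p - lp_x:
        return prop, lp_p, True
    return x, lp_x, False


def _cell_loglik(cell, v, a, z, t) -> float:
    rt, upper = cell
    if rt.size == 0:
        return 0.0
    return wfpt_sum_loglik(rt, upper, v, a, z, t)


def _subject_loglik_cells(spec, s, theta, delta, n_class):
    """Log-likelihood of every (class, state) cell of subject ``s``."""
    out = np.empty((n_class, 2))
    a, z, t = theta[n_class], theta[n_class + 1], theta[n_class + 2]
    for c in range(n_class):
        out[c, 0] = _cell_loglik(spec.cells[s][c][0], theta[c], a, z, t)
        out[c, 1] = _cell_loglik(
            spec.cells[s][c][1], theta[c] + delta[c],
            a + delta[n_class], z + delta[n_class + 1], t + delta[n_class + 2],
        )
    return out


def _initial_values(spec: HierarchicalModelSpec, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Moment-based starting values: t near the fastest RT, z central, a
    moderate, drifts from the logistic transform of each class's
    upper-boundary choice fraction (exact for z = 0.5)."""
    S, C = spec.n_subjects, len(spec.classes)
    P = C + 3
    subj = np.empty((S, P))
    for s in range(S):
        a0 = 1.5
        for c in range(C):
            rt0, up0 = spec.cells[s][c][0]
            rt1, up1 = spec.cells[s][c][1]
            n = up0.size + up1.size
            p = (up0.sum() + up1.sum() + 0.5) / (n + 1.0)
            subj[s, c] = np.clip(math.log(p / (1 - p)) / a0, -4, 4)
        subj[s, C] = a0
        subj[s, C + 1] = 0.5
        subj[s, C + 2] = 0.9 * spec.min_rt(s)
    # chain jitter
    subj[:, :C] += 0.2 * rng.standard_normal((S, C))
    subj[:, C] = np.clip(subj[:, C] * np.exp(0.1 * rng.standard_normal(S)), A_MIN + 0.05, A_MAX - 0.5)
    subj[:, C + 1] = np.clip(subj[:, C + 1] + 0.02 * rng.standard_normal(S), 0.3, 0.7)
    subj[:, C + 2] = np.clip(subj[:, C + 2] * (1 - 0.1 * rng.random(S)), 0.02, T_MAX - 0.05)
    mu = subj.mean(axis=0)
    sigma = np.clip(subj.std(axis=0, ddof=1), 0.08, 1.0)
    delta = np.zeros(P)
    return subj, mu, sigma, delta


def run_mcmc(
    spec: HierarchicalModelSpec,
    profile: SamplingProfile = DESK_PROFILE,
    seed: int = 0,
) -> MCMCChains:
    """Sample the hierarchical posterior with independent adaptive
    Metropolis-within-Gibbs chains.  Reproducible: the same seed gives
    identical chains.  Proposal-scale adaptation runs during burn-in only.
    """
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(profile.n_chains)]
    per_chain = [_run_single_chain(spec, profile, cs) for cs in chain_seeds]

    names = list(per_chain[0].keys())
    samples = {k: np.stack([pc[k] for pc in per_chain]) for k in names}
    return MCMCChains(samples=samples, profile=profile, seeds=chain_seeds,
                      param_names=spec.param_names)


def _run_single_chain(spec, profile, seed) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    C = len(spec.classes)
    P = C + 3
    S = spec.n_subjects
    kinds = spec.param_kinds
    names = spec.param_names

    subj, mu, sigma, delta = _initial_values(spec, rng)
    ll = np.empty((S, C, 2))
    for s in range(S):
        ll[s] = _subject_loglik_cells(spec, s, subj[s], delta, C)
        tries = 0
        while not np.all(np.isfinite(ll[s])):
            # jittered re-initialisation for zero-likelihood starts
            subj[s, C + 2] *= 0.8
            subj[s, :C] *= 0.7
            ll[s] = _subject_loglik_cells(spec, s, subj[s], delta, C)
            tries += 1
            if tries > 20:
                raise RuntimeError(f"cannot initialise subject {spec.subject_ids[s]}")

    subj_scale = np.tile([_INIT_SCALES[k] for k in kinds], (S, 1))
    delta_scale = np.array([_DELTA_SCALES[k] for k in kinds])
    sigma_scale = np.full(P, 0.25)
    shift_scale = np.array([0.3 * _INIT_SCALES[k] for k in kinds])
    scale_scale = np.full(P, 0.15)
    acc = {"subj": np.zeros((S, P)), "delta": np.zeros(P), "sigma": np.zeros(P),
           "shift": np.zeros(P), "scale": np.zeros(P)}
    window = 25
    acc_windows = {"delta": profile.group_reps * window, "sigma": profile.group_reps * window}

    n_kept = (profile.n_samples - profile.burn_in) // profile.thin
    kept = {f"{g}_{n}": np.empty(n_kept) for g in ("mu", "sigma", "delta") for n in names}
    for n in names:
        for s in range(S):
            kept[f"{n}[{spec.subject_ids[s]}]"] = np.empty(n_kept)
    k_idx = 0

    bounds = [BASE_BOUNDS[k] for k in kinds]
    dbounds = [DELTA_BOUNDS[k] for k in kinds]

    for it in range(profile.n_samples):
        # --- subject-level updates ---
        for s in range(S):
            theta = subj[s]
            for j in range(P):
                lo, hi = bounds[j]
                prop = theta[j] + subj_scale[s, j] * rng.standard_normal()
                if not (lo < prop < hi):
                    continue
                theta_new = theta.copy()
                theta_new[j] = prop
                if j < C:  # drift: only cells of class j change
                    a_, z_, t_ = theta[C], theta[C + 1], theta[C + 2]
                    new0 = _cell_loglik(spec.cells[s][j][0], prop, a_, z_, t_)
                    new1 = _cell_loglik(spec.cells[s][j][1], prop + delta[j],
                                        a_ + delta[C], z_ + delta[C + 1], t_ + delta[C + 2])
                    d_ll = new0 + new1 - ll[s, j, 0] - ll[s, j, 1]
                else:
                    new_cells = _subject_loglik_cells(spec, s, theta_new, delta, C)
                    d_ll = new_cells.sum() - ll[s].sum()
                d_prior = _norm_logpdf(prop, mu[j], sigma[j]) - _norm_logpdf(theta[j], mu[j], sigma[j])
                if math.log(rng.random() + 1e-300) < d_ll + d_prior:
                    subj[s, j] = prop
                    if j < C:
                        ll[s, j, 0], ll[s, j, 1] = new0, new1
                    else:
                        ll[s] = new_cells
                    acc["subj"][s, j] += 1

        # Group blocks are cheap relative to the subject sweep, so they are
        # repeated a few times per iteration to reduce autocorrelation of
        # the group-level quantities the analysis reports.
        for _rep in range(profile.group_reps):
            # group means: Gibbs (flat prior, truncated to bounds)
            for j in range(P):
                lo, hi = bounds[j]
                m, sd = subj[:, j].mean(), sigma[j] / math.sqrt(S)
                for _ in range(100):
                    draw = m + sd * rng.standard_normal()
                    if lo < draw < hi:
                        mu[j] = draw
                        break

            # group sds: random walk on log sigma
            for j in range(P):
                th = subj[:, j]

                def lp(sg, th=th, j=j):
                    return float(np.sum(_norm_logpdf(th, mu[j], sg)))

                ls = math.log(sigma[j])
                prop = math.exp(ls + sigma_scale[j] * rng.standard_normal())
                if SIGMA_BOUNDS[0] < prop < SIGMA_BOUNDS[1]:
                    # Jacobian log(prop/sigma): log-scale walk, flat prior on sigma
                    if math.log(rng.random() + 1e-300) < lp(prop) - lp(sigma[j]) + math.log(prop / sigma[j]):
                        sigma[j] = prop
                        acc["sigma"][j] += 1

            # deltas: group-level fixed effects (inspiration cells only)
            for j in range(P):
                lo, hi = dbounds[j]
                prop = delta[j] + delta_scale[j] * rng.standard_normal()
                if not (lo < prop < hi):
                    continue
                delta_new = delta.copy()
                delta_new[j] = prop
                if j < C:
                    new_ll = np.array([
                        _cell_loglik(spec.cells[s][j][1], subj[s, j] + prop,
                                     subj[s, C] + delta[C], subj[s, C + 1] + delta[C + 1],
                                     subj[s, C + 2] + delta[C + 2])
                        for s in range(S)
                    ])
                    d_ll = new_ll.sum() - ll[:, j, 1].sum()
                else:
                    new_ll = np.empty((S, C))
                    for s in range(S):
                        for c in range(C):
                            new_ll[s, c] = _cell_loglik(
                                spec.cells[s][c][1], subj[s, c] + delta[c],
                                subj[s, C] + delta_new[C], subj[s, C + 1] + delta_new[C + 1],
                                subj[s, C + 2] + delta_new[C + 2],
                            )
                    d_ll = new_ll.sum() - ll[:, :, 1].sum()
                if math.log(rng.random() + 1e-300) < d_ll:
                    delta[j] = prop
                    if j < C:
                        ll[:, j, 1] = new_ll
                    else:
                        ll[:, :, 1] = new_ll
                    acc["delta"][j] += 1

        # --- joint reparameterisation moves ---
        # Translation: shift a whole parameter column and its group mean
        # together (subject-prior terms cancel); decorrelates mu from the
        # subject block.  Scale: contract/expand subject deviations around
        # mu together with sigma (flat prior on sigma leaves an extra
        # Jacobian factor c); decorrelates sigma.
        for j in range(P):
            lo, hi = bounds[j]
            eps = shift_scale[j] * rng.standard_normal()
            if lo < mu[j] + eps < hi and np.all((subj[:, j] + eps > lo) & (subj[:, j] + eps < hi)):
                subj_new = subj.copy()
                subj_new[:, j] += eps
                if j < C:
                    new_ll = np.empty((S, 2))
                    for s in range(S):
                        th = subj_new[s]
                        new_ll[s, 0] = _cell_loglik(spec.cells[s][j][0], th[j], th[C], th[C + 1], th[C + 2])
                        new_ll[s, 1] = _cell_loglik(spec.cells[s][j][1], th[j] + delta[j],
                                                    th[C] + delta[C], th[C + 1] + delta[C + 1],
                                                    th[C + 2] + delta[C + 2])
                    d_ll = new_ll.sum() - ll[:, j, :].sum()
                else:
                    new_ll = np.empty((S, C, 2))
                    for s in range(S):
                        new_ll[s] = _subject_loglik_cells(spec, s, subj_new[s], delta, C)
                    d_ll = new_ll.sum() - ll.sum()
                if math.log(rng.random() + 1e-300) < d_ll:
                    subj[:, j] += eps
                    mu[j] += eps
                    if j < C:
                        ll[:, j, :] = new_ll
                    else:
                        ll[:] = new_ll
                    acc["shift"][j] += 1

        for j in range(P):
            lo, hi = bounds[j]
            c_fac = math.exp(scale_scale[j] * rng.standard_normal())
            sig_new = sigma[j] * c_fac
            cand = mu[j] + c_fac * (subj[:, j] - mu[j])
            if SIGMA_BOUNDS[0] < sig_new < SIGMA_BOUNDS[1] and np.all((cand > lo) & (cand < hi)):
                subj_new = subj.copy()
                subj_new[:, j] = cand
                if j < C:
                    new_ll = np.empty((S, 2))
                    for s in range(S):
                        th = subj_new[s]
                        new_ll[s, 0] = _cell_loglik(spec.cells[s][j][0], th[j], th[C], th[C + 1], th[C + 2])
                        new_ll[s, 1] = _cell_loglik(spec.cells[s][j][1], th[j] + delta[j],
                                                    th[C] + delta[C], th[C + 1] + delta[C + 1],
                                                    th[C + 2] + delta[C + 2])
                    d_ll = new_ll.sum() - ll[:, j, :].sum()
                else:
                    new_ll = np.empty((S, C, 2))
                    for s in range(S):
                        new_ll[s] = _subject_loglik_cells(spec, s, subj_new[s], delta, C)
                    d_ll = new_ll.sum() - ll.sum()
                # acceptance includes the net Jacobian factor c
                if math.log(rng.random() + 1e-300) < d_ll + math.log(c_fac):
                    subj[:, j] = cand
                    sigma[j] = sig_new
                    if j < C:
                        ll[:, j, :] = new_ll
                    else:
                        ll[:] = new_ll
                    acc["scale"][j] += 1

        # --- adaptation (burn-in only) ---
        if it < profile.burn_in and (it + 1) % window == 0:
            subj_scale *= np.exp(0.6 * (acc["subj"] / window - 0.35))
            delta_scale *= np.exp(0.6 * (acc["delta"] / acc_windows["delta"] - 0.35))
            sigma_scale *= np.exp(0.6 * (acc["sigma"] / acc_windows["sigma"] - 0.35))
            shift_scale *= np.exp(0.6 * (acc["shift"] / window - 0.35))
            scale_scale *= np.exp(0.6 * (acc["scale"] / window - 0.35))
            for key in acc:
                acc[key][:] = 0

        # --- storage ---
        if it >= profile.burn_in and (it - profile.burn_in) % profile.thin == 0:
            for j, n in enumerate(names):
                kept[f"mu_{n}"][k_idx] = mu[j]
                kept[f"sigma_{n}"][k_idx] = sigma[j]
                kept[f"delta_{n}"][k_idx] = delta[j]
                for s in range(S):
                    kept[f"{n}[{spec.subject_ids[s]}]"][k_idx] = subj[s, j]
            k_idx += 1

    return kept


# ---------------------------------------------------------------------------
# Diagnostics and posterior predictive
# ---------------------------------------------------------------------------

def gelman_rubin(chains: MCMCChains | dict[str, np.ndarray]) -> ConvergenceReport:
    """Gelman-Rubin potential scale reduction per parameter.

    R = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B the between-chain variance of chain means (times n).
    """
    samples = chains.samples if isinstance(chains, MCMCChains) else chains
    out = {}
    for name, arr in samples.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"{name}: need >= 2 chains of equal length >= 2")
        m, n = arr.shape
        w = arr.var(axis=1, ddof=1).mean()
        if w == 0:
            raise ValueError(f"{name}: zero within-chain variance")
        b = n * arr.mean(axis=1).var(ddof=1)
        out[name] = float(math.sqrt(((n - 1) / n * w + b / n) / w))
    return ConvergenceReport(grs=out)


def posterior_predictive(
    chains: MCMCChains,
    spec: HierarchicalModelSpec,
    n_datasets: int = 100,
    seed: int = 0,
    bins: np.ndarray | None = None,
    warn_unconverged: bool = True,
):
    """Simulate datasets from joint posterior draws and summarise RT
    histograms per stimulus class with the signed-RT convention
    (lower-boundary responses counted as negative RTs).

    Each simulated dataset keeps the observed per-subject, per-class,
    per-state trial counts.  Returns (bin_edges, observed_hist,
    simulated_hists) with histogram arrays of shape (n_class, n_bins) and
    (n_datasets, n_class, n_bins).
    """
    if warn_unconverged:
        rep = gelman_rubin(
            {k: v for k, v in chains.samples.items() if k in chains.group_parameter_names}
        )
        if not rep.passed:
            import warnings

            warnings.warn(f"posterior predictive from unconverged chains: {rep.flagged}")
    rng = np.random.default_rng(seed)
    C = len(spec.classes)
    S = spec.n_subjects
    if bins is None:
        bins = np.linspace(-4.0, 4.0, 81)

    observed = np.zeros((C, len(bins) - 1))
    for s in range(S):
        for c in range(C):
            for state in (0, 1):
                rt, upper = spec.cells[s][c][state]
                signed = np.where(upper, rt, -rt)
                observed[c] += np.histogram(signed, bins=bins)[0]

    n_chains, n_kept = next(iter(chains.samples.values())).shape
    sims = np.zeros((n_datasets, C, len(bins) - 1))
    for d in range(n_datasets):
        ci = rng.integers(n_chains)
        ki = rng.integers(n_kept)
        delta = np.array([chains.samples[f"delta_{n}"][ci, ki] for n in spec.param_names])
        for s in range(S):
            sid = spec.subject_ids[s]
            theta = np.array([chains.samples[f"{n}[{sid}]"][ci, ki] for n in spec.param_names])
            for c in range(C):
                for state in (0, 1):
                    n_tr = spec.cells[s][c][state][0].size
                    if n_tr == 0:
                        continue
                    v = theta[c] + state * delta[c]
                    a = theta[C] + state * delta[C]
                    z = theta[C + 1] + state * delta[C + 1]
                    t = theta[C + 2] + state * delta[C + 2]
                    ch, rt = simulate_ddm(v, a, z, t, n=n_tr, dt=2e-3,
                                          seed=int(rng.integers(2**31 - 1)))
                    ok = ch >= 0
                    signed = np.where(ch[ok] == 1, rt[ok], -rt[ok])
                    sims[d, c] += np.histogram(signed, bins=bins)[0]
    return bins, observed, sims
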