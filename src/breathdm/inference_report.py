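"""Posterior summarisation and reporting.

Each respiratory delta parameter is summarised by its 95 % highest posterior
density interval (the shortest contiguous interval holding the requested
mass) and a two-sided Bayesian P value: twice the smaller of the posterior
masses above and below zero, floored at 2/n so Monte-Carlo estimates are
never reported as exactly zero.  Parameters with P < 0.05 are starred.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hier_fit import MCMCChains

__all__ = ["PosteriorSummary", "hpdi", "bayesian_p", "summarize_deltas", "write_report"]

ALPHA = 0.05


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    hpdi_low: float
    hpdi_high: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def hpdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` posterior mass.

    Sorted-sample sliding window; on width ties the window with the lowest
    start wins, so the result is deterministic.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an HPDI")
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[i]), float(x[i + k - 1])


def bayesian_p(samples) -> float:
    """Two-sided Bayesian P: 2 x min(P(x > 0), P(x < 0)), floored at 2/n."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 samples")
    p_pos = float(np.mean(x > 0))
    p_neg = float(np.mean(x < 0))
    return float(max(2.0 * min(p_pos, p_neg), 2.0 / x.size))


def summarize_deltas(chains: MCMCChains, mass: float = 0.95) -> pd.DataFrame:
    """Table of respiratory-delta posteriors: one row per delta parameter
    with HPDI bounds, two-sided Bayesian P and a significance star, computed
    on the samples pooled across chains."""
    rows = []
    delta_names = [k for k in chains.samples if k.startswith("delta_")]
    if not delta_names:
        raise ValueError("chains contain no delta parameters")
    for name in delta_names:
        pooled = chains.pooled(name)
        lo, hi = hpdi(pooled, mass)
        p = bayesian_p(pooled)
        rows.append({
            "Delta parameter": name.removeprefix("delta_"),
            "HPDI low": lo,
            "HPDI high": hi,
            "P": p,
            "sig": "*" if p < ALPHA else "",
        })
    return pd.DataFrame(rows)


def write_report(
    summaries: pd.DataFrame,
    out_dir,
    behavioural: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the delta-posterior table as CSV and JSON (plus optional
    behavioural test results), each carrying a run-metadata block with the
    software version and a config hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta.setdefault("software_version", __version__)
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]

    paths = {}
    csv_path = out / "table1.csv"
    with open(csv_path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        summaries.to_csv(fh, index=False)
    paths["table1.csv"] = csv_path

    json_path = out / "table1.json"
    with open(json_path, "w") as fh:
        json.dump({"metadata": meta, "rows": summaries.to_dict(orient="records")}, fh, indent=1)
    paths["table1.json"] = json_path

    if behavioural is not None:
        bpath = out / "behavioural_tests.csv"
        with open(bpath, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            behavioural.to_csv(fh, index=False)
        paths["behavioural_tests.csv"] = bpath
    return paths
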