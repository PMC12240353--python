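"""Shared fixtures.

The expensive hierarchical fit used by the convergence acceptance check is
session-scoped so posterior-predictive and stationarity tests can reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

from breathdm.ddm_core import RespiratoryDeltas
from breathdm.synthetic_data import RDM_CLASSES, simulate_labelled_cohort
from breathdm.hier_fit import DESK_PROFILE, build_model, run_mcmc


@pytest.fixture(scope="session")
def grs_cohort():
    """10-subject random-dot-motion cohort, 160 trials each, moderate
    respiratory deltas, labelled through the full preprocessing pipeline."""
    deltas = RespiratoryDeltas(
        dv={c: 0.0 for c in RDM_CLASSES}, da=-0.04, dz=0.014, dt=0.0
    )
    return simulate_labelled_cohort("RDM", 10, deltas, seed=11, n_trials=160)


@pytest.fixture(scope="session")
def grs_fit(grs_cohort):
    """Four-chain fit of the cohort at the reduced (desk) profile:
    4 x 3000 samples, burn-in 600, thin 2."""
    spec = build_model(grs_cohort, "RDM", "stimulus")
    chains = run_mcmc(spec, DESK_PROFILE, seed=5)
    return spec, chains


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
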