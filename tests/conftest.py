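"""Shared fixtures.

The heavy end-to-end fixture (`reduced_run`) executes the full pipeline at
the package's reduced experiment scale once per session; several acceptance
and pipeline tests read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

import spikeplex as sp
from spikeplex.pipeline import run_trial, trial_seeds


@pytest.fixture(scope="session")
def small_net():
    """Deterministic 100-neuron structural network at default parameters."""
    return sp.build_structural_network(sp.BuildParams(), rng=42)


@pytest.fixture(scope="session")
def reduced_run():
    """Reduced-profile experiment: both methods, kappa = 0.2, 5 trials.

    The first three trials back the aggregate sign-pattern checks; all five
    back the cross-method false-positive comparison.
    """
    cfg = sp.reduced_profile(seed=20240, kappas=(0.2,))
    cfg.n_trials = 5
    trials = [run_trial(cfg, ts) for ts in trial_seeds(cfg)]
    return cfg, trials
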