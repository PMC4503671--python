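"""Shared fixtures: hand-built trajectory tables and seeded simulator runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hitchclock.simulator import SimulationConfig, simulate_wright_fisher
from hitchclock.trajectories import TrajectoryTable


def make_table(
    freqs: dict[str, list[float]],
    generations: list[int],
    categories: dict[str, str] | None = None,
    censored_below: float | None = None,
) -> TrajectoryTable:
    """Build a TrajectoryTable from {mutation_id: frequency list}.

    With ``censored_below`` set, cells under that value are flagged censored.
    """
    ids = list(freqs)
    arr = np.array([freqs[m] for m in ids], dtype=float)
    cens = np.zeros_like(arr, dtype=bool)
    if censored_below is not None:
        cens = arr < censored_below
        arr = arr.copy()
    arr = np.where(cens, np.nan, arr)
    index = pd.Index(ids, name="mutation_id")
    meta = pd.DataFrame(
        {
            "gene": [f"gene_{m}" for m in ids],
            "category": [
                (categories or {}).get(m, "non-synonymous") for m in ids
            ],
            "cluster": [None] * len(ids),
        },
        index=index,
    )
    return TrajectoryTable(
        meta=meta,
        freq=pd.DataFrame(arr, index=index, columns=generations),
        censored=pd.DataFrame(cens, index=index, columns=generations),
    )


#: Sweep-separated study conditions: detection floor far above drift level,
#: sweeps resolved by the sampling grid.  Used for truth-recovery checks.
SEPARATED = dict(
    popsize=20000,
    mu=2.5e-6,
    ls=300,
    ln=700,
    alpha=1e-4,
    beta=0.4,
    s_adaptive=0.15,
    s_harmful=-0.02,
    generations=8000,
    sample_every=100,
)

#: Clonal-interference conditions scaled down from the headline run
#: (mu*(ls+ln) = 0.02 per genome, alpha = 0.005 of non-synonymous).
INTERFERENCE = dict(
    popsize=1000,
    mu=2e-5,
    ls=300,
    ln=700,
    alpha=0.005,
    beta=0.4,
    s_adaptive=0.05,
    s_harmful=-0.02,
    generations=4000,
    sample_every=100,
)

#: Sparse noisy observation akin to the experiment's Sanger time courses.
NOISY_SPARSE = dict(
    popsize=1000,
    mu=2e-5,
    ls=300,
    ln=700,
    alpha=0.001,
    beta=0.4,
    s_adaptive=0.08,
    s_harmful=-0.02,
    generations=6000,
    sample_every=400,
    obs_sd=0.062,
)


@pytest.fixture(scope="session")
def sim_separated():
    """Noise-free run with well-separated sweeps (truth recovery)."""
    return simulate_wright_fisher(
        SimulationConfig(**SEPARATED, obs_sd=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def sim_noisy():
    """Sparsely sampled run observed through the Sanger noise model."""
    return simulate_wright_fisher(SimulationConfig(**NOISY_SPARSE, seed=5))
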