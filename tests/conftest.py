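"""Shared fixtures: the default desk-scale simulation run and small helpers.

The expensive end-to-end simulation (2 x 5 Mb chromosomes, 250 origins,
2,000 cells x 500 fragments) is session-scoped so recovery-style tests
share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from okmap import io, simulate
from okmap.config import RunConfig
from okmap.core import StrandedTrack
from okmap.pipeline import call_origins_from_track


@pytest.fixture(scope="session")
def default_run():
    """Default desk-scale simulation plus the full origin-calling chain."""
    model = simulate.default_model(seed=1)
    frags = simulate.simulate_fragments(model, n_cells=2000,
                                        fragments_per_cell=500, seed=2)
    track = io.bin_fragments(frags, model.chrom_sizes, bin_size=100)
    calls, normalized = call_origins_from_track(track, RunConfig())
    recovery = simulate.score_recovery(calls, model)
    return {
        "model": model,
        "fragments": frags,
        "track": track,
        "calls": calls,
        "normalized": normalized,
        "recovery": recovery,
    }


@pytest.fixture(scope="session")
def small_model():
    """A single 1 Mb chromosome with 8 origins — small enough for the exact
    firing-combination enumeration oracle."""
    return simulate.simulate_genome_model(
        n_chrom=1, chrom_length=1_000_000, n_origins=8,
        efficiency_distribution=("beta", (2.0, 2.0)), seed=11,
    )


def make_track(watson: np.ndarray, crick: np.ndarray,
               bin_size: int = 100) -> StrandedTrack:
    """One-chromosome track from explicit per-bin counts."""
    watson = np.asarray(watson, dtype=float)
    return StrandedTrack(
        bin_size=bin_size,
        chrom_sizes={"chrT": len(watson) * bin_size},
        watson={"chrT": watson},
        crick={"chrT": np.asarray(crick, dtype=float)},
    )


@pytest.fixture
def toy_track():
    return make_track
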