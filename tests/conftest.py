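from __future__ import annotations

import numpy as np
import pytest

from hoxmap import align, profile as prof, simmap, simulate


@pytest.fixture(scope="session")
def scenario():
    """One frozen realization of the two-sister synthetic family."""
    return simulate.hox_parahox_scenario("paper_supported", 1.0, rng_seed=0)


@pytest.fixture(scope="session")
def calibrated_profile(scenario):
    model = prof.build_profile(scenario.seed_alignment())
    prof.calibrate_threshold(model, seed=0)
    return model


@pytest.fixture(scope="session")
def scenario_graph(scenario):
    """Report-cutoff similarity graph over the frozen scenario."""
    hits = align.all_against_all(scenario.sequences, align.ScoringScheme(), 1e-2)
    return simmap.SimilarityGraph(
        scenario.sequences, align.build_edges(hits, 1e-2), 1e-2
    )
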