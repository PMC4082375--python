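"""Shared fixtures: simulated study populations, computed once per run."""

import random

import pytest

from historygraph import sample_avgs, simulate_pair


@pytest.fixture(scope="session")
def sim_pairs():
    """100 (simple history, degraded seed graph) pairs from the forward
    simulation protocol (5 segments, 4 epochs, 10% degradation)."""
    return [simulate_pair(seed=s)[:2] for s in range(100)]


@pytest.fixture(scope="session")
def sampled_avgs(sim_pairs):
    """200 G-bounded AVG endpoints: ten walks from each of the first
    twenty seed graphs."""
    out = []
    for i, (_, g) in enumerate(sim_pairs[:20]):
        got, k = 0, 0
        while got < 10 and k < 40:
            rep = sample_avgs(g, n_starts=1,
                              rng=random.Random(1000 * i + k))
            k += 1
            if rep.best_graph is not None:
                out.append((g, rep.best_graph))
                got += 1
    return out
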