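import numpy as np
import pytest
from hypothesis import settings

from pstsim.models import IsolationModel, build_model_registry

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return build_model_registry()


@pytest.fixture(scope="session")
def panmictic_model():
    """Effectively a single panmictic population: both descendants and the
    ancestor share one size and the split is immediate."""
    return IsolationModel(
        "panmictic", 10_000, 10_000, 10_000,
        divergence_years=1e-3, generation_years=2.0,
    )


def random_unrooted_topology(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary topology as adjacency lists (test helper)."""
    adj = [[] for _ in range(n_leaves)]
    hub = len(adj)
    adj.append([0, 1, 2])
    for leaf in (0, 1, 2):
        adj[leaf] = [hub]
    for x in range(3, n_leaves):
        edges = [(u, v) for u in range(len(adj)) for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = len(adj)
        adj.append([u, v, x])
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[x] = [w]
    return adj


def brute_force_changes(adj, n_leaves: int, tip_states, n_states: int) -> int:
    """Minimum labelling changes by exhaustive enumeration over internal
    state assignments (oracle; exponential, tiny inputs only)."""
    import itertools

    internal = list(range(n_leaves, len(adj)))
    edges = [(u, v) for u in range(len(adj)) for v in adj[u] if u < v]
    best = None
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for i in range(n_leaves):
            state[i] = tip_states[i]
        cost = sum(1 for u, v in edges if state[u] != state[v])
        if best is None or cost < best:
            best = cost
    return best
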