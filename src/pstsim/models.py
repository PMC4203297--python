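"""Two-population isolation models and coalescent gene-tree simulation.

The demographic scenario is a clean species split: two descendant
populations of constant diploid effective size (``n_pop1``, ``n_pop2``)
diverge from a common ancestral population (``n_ancestor``) at time
``divergence_years`` with no post-divergence gene flow.  Optionally the
second descendant passes through a founder epoch -- a brief interval of
very small effective size anchored at the divergence event (the oldest
``founder_fraction`` of its branch) -- modelling speciation by a small
number of colonising individuals.

Gene trees are simulated under the standard neutral coalescent
(continuous time, pair-coalescence rate ``1/(2N)`` per generation for a
diploid population of size ``N``) using :mod:`msprime`.  Times are kept
in generations internally; years appear only at the interface and are
converted through ``generation_years``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterator, Optional

import msprime
import numpy as np

__all__ = [
    "POP1",
    "POP2",
    "IsolationModel",
    "GeneTree",
    "build_model_registry",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "registry_to_json",
    "registry_from_json",
]

#: population identifiers used for tip labels and population maps
POP1 = "pop1"
POP2 = "pop2"

# msprime wants seeds in [1, 2**32); we keep everything below 2**31 and
# derive per-tree seeds from a master seed by a fixed increment.
_SEED_MOD = 2**31 - 1


def _msprime_seed(seed: int) -> int:
    return int(seed) % _SEED_MOD + 1


@dataclass(frozen=True)
class IsolationModel:
    """A two-population isolation scenario with an optional founder epoch.

    Sizes are diploid effective sizes in individuals; the divergence time
    is in years and converted to generations via ``generation_years``.
    ``founder_size``/``founder_fraction`` describe the founder epoch of
    population 2: during the oldest ``founder_fraction`` of the time since
    divergence, population 2 has size ``founder_size`` instead of
    ``n_pop2``.
    """

    label: str
    n_pop1: float
    n_pop2: float
    n_ancestor: float
    divergence_years: float
    generation_years: float = 2.0
    founder_size: Optional[float] = None
    founder_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.n_pop1, self.n_pop2, self.n_ancestor) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.divergence_years <= 0:
            raise ValueError("divergence_years must be positive")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")
        if (self.founder_size is None) != (self.founder_fraction is None):
            raise ValueError(
                "founder_size and founder_fraction must be set together"
            )
        if self.founder_size is not None:
            if not (0.0 < self.founder_fraction < 1.0):
                raise ValueError("founder_fraction must lie in (0, 1)")
            if self.founder_size <= 0:
                raise ValueError("founder_size must be positive")
            if self.founder_size > self.n_pop2:
                raise ValueError("founder_size cannot exceed n_pop2")

    @property
    def has_founder_epoch(self) -> bool:
        return self.founder_size is not None

    @property
    def divergence_generations(self) -> float:
        return self.divergence_years / self.generation_years

    def demography(self) -> msprime.Demography:
        """msprime demography with times in generations.

        The founder epoch is expressed as a size change of population 2 at
        ``(1 - founder_fraction) * T`` generations, so the epoch covers the
        oldest ``founder_fraction`` of the branch, ending at the split.
        """
        t_gen = self.divergence_generations
        dem = msprime.Demography()
        dem.add_population(name=POP1, initial_size=self.n_pop1)
        dem.add_population(name=POP2, initial_size=self.n_pop2)
        dem.add_population(name="ancestor", initial_size=self.n_ancestor)
        if self.has_founder_epoch:
            dem.add_population_parameters_change(
                time=(1.0 - self.founder_fraction) * t_gen,
                population=POP2,
                initial_size=self.founder_size,
            )
        dem.add_population_split(
            time=t_gen, derived=[POP1, POP2], ancestral="ancestor"
        )
        return dem


def build_model_registry() -> dict[str, IsolationModel]:
    """The eight speciation models 1a--4b.

    Constant-size models (a) and founder-event models (b) share the same
    effective sizes (IM high-point estimates for the *U. notata* complex,
    *U. scoparia* and their ancestor) and differ in divergence time:
    0.054, 1.0, 2 and 6 Ma.  The b variants add a 241-individual founder
    epoch for species 2 lasting 5% of the divergence time.
    """
    n1, n2, na = 1_090_596.0, 121_955.0, 43_764.0
    divergences = {"1": 54_000.0, "2": 1_000_000.0, "3": 2_000_000.0, "4": 6_000_000.0}
    registry: dict[str, IsolationModel] = {}
    for tier, t in divergences.items():
        registry[tier + "a"] = IsolationModel(
            label=tier + "a", n_pop1=n1, n_pop2=n2, n_ancestor=na,
            divergence_years=t,
        )
        registry[tier + "b"] = IsolationModel(
            label=tier + "b", n_pop1=n1, n_pop2=n2, n_ancestor=na,
            divergence_years=t, founder_size=241.0, founder_fraction=0.05,
        )
    return registry


class GeneTree:
    """A rooted, ultrametric, binary coalescent genealogy.

    Stored as flat arrays: ``parent[i]`` is the parent node of node ``i``
    (-1 for the root) and ``time[i]`` its age in generations (tips at 0).
    Tips are nodes ``0 .. n_tips-1`` with labels like ``pop2_017``.
    """

    __slots__ = ("parent", "time", "n_tips", "labels", "tip_population")

    def __init__(self, parent, time, n_tips, labels, tip_population):
        self.parent = np.asarray(parent, dtype=np.int32)
        self.time = np.asarray(time, dtype=np.float64)
        self.n_tips = int(n_tips)
        self.labels = list(labels)
        self.tip_population = dict(tip_population)

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                ch[par].append(node)
        return ch

    def branch_length(self, node: int) -> float:
        par = self.parent[node]
        if par < 0:
            return 0.0
        return float(self.time[par] - self.time[node])

    def tip_populations_by_index(self) -> list[str]:
        return [self.tip_population[lab] for lab in self.labels]

    def validate(self, tol: float = 1e-6) -> None:
        if np.any(self.time[: self.n_tips] > tol):
            raise ValueError("tree is not ultrametric: tips not at time 0")
        ch = self.children()
        internal = [i for i in range(self.n_nodes) if ch[i]]
        if len(internal) != self.n_tips - 1:
            raise ValueError("binary tree must have n_tips - 1 internal nodes")
        for node, par in enumerate(self.parent):
            if par >= 0 and self.time[par] < self.time[node] - tol:
                raise ValueError("parent older than child violated")

    # -- output ----------------------------------------------------------
    def newick(self, precision: int = 6) -> str:
        ch = self.children()
        fmt = f"%.{precision}f"

        out: list[str] = []
        # iterative post-order formatting to avoid recursion limits
        stack: list[tuple[int, bool]] = [(self.root, False)]
        parts: dict[int, str] = {}
        while stack:
            node, done = stack.pop()
            if not done and ch[node]:
                stack.append((node, True))
                for c in reversed(ch[node]):
                    stack.append((c, False))
                continue
            if ch[node]:
                inner = ",".join(parts.pop(c) for c in ch[node])
                text = f"({inner})"
            else:
                text = self.labels[node]
            if self.parent[node] >= 0:
                text += ":" + (fmt % self.branch_length(node))
            parts[node] = text
        out.append(parts[self.root])
        return out[0] + ";"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick", preserve_underscores=True)


def _tree_from_tskit(ts, n1: int, n2: int) -> GeneTree:
    t = ts.first()
    n_tips = n1 + n2
    # nodes of the genealogy re-indexed tips-first, then by age
    order = list(t.nodes())
    remap: dict[int, int] = {}
    nxt = n_tips
    for u in sorted(order, key=lambda u: (ts.node(u).time, u)):
        if u < n_tips:  # samples are nodes 0 .. n_tips-1
            remap[u] = u
        else:
            remap[u] = nxt
            nxt += 1
    n_nodes = len(order)
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes, dtype=np.float64)
    for u in order:
        i = remap[u]
        time[i] = ts.node(u).time
        p = t.parent(u)
        if p != -1:
            parent[i] = remap[p]
    labels = [f"{POP1}_{i:03d}" for i in range(n1)] + [
        f"{POP2}_{i:03d}" for i in range(n2)
    ]
    tip_population = {lab: (POP1 if i < n1 else POP2) for i, lab in enumerate(labels)}
    return GeneTree(parent, time, n_tips, labels, tip_population)


def simulate_gene_tree(
    model: IsolationModel, n1: int, n2: int, seed: int
) -> GeneTree:
    """Simulate one gene tree: ``n1`` lineages from population 1 and
    ``n2`` from population 2, branch lengths in generations.

    Identical ``(model, n1, n2, seed)`` reproduce the identical tree.
    """
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages in total")
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")
    samples = []
    if n1:
        samples.append(msprime.SampleSet(n1, population=POP1, ploidy=1))
    if n2:
        samples.append(msprime.SampleSet(n2, population=POP2, ploidy=1))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=model.demography(),
        ploidy=2,
        random_seed=_msprime_seed(seed),
    )
    return _tree_from_tskit(ts, n1, n2)


def simulate_gene_trees(
    model: IsolationModel, n1: int, n2: int, n_trees: int, seed: int
) -> Iterator[GeneTree]:
    """Batch simulation; per-tree seeds are ``seed + i`` (fixed increment)."""
    for i in range(n_trees):
        yield simulate_gene_tree(model, n1, n2, seed + i)


# -- registry (de)serialisation ------------------------------------------

def registry_to_json(registry: dict[str, IsolationModel], path) -> None:
    data = {label: asdict(m) for label, m in registry.items()}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)


def registry_from_json(path) -> dict[str, IsolationModel]:
    with open(path) as fh:
        data = json.load(fh)
    return {label: IsolationModel(**fields) for label, fields in data.items()}
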