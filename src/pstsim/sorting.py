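"""Slatkin's s, the PST statistic, chi-square model tests and power.

Slatkin's s is the minimum number of character-state changes of the
population label on a gene tree (unordered parsimony).  s = 1 means at
least one population's tips form a clade -- the tree is "sorted", covering
both reciprocal monophyly and one population nested monophyletically
inside the other.  PST (percentage sorted trees) is the percentage of
gene trees in a set with s = 1; it is the test statistic used to confront
observed multilocus data with speciation models.

A model is tested by comparing the observed PST with the s = 1 proportion
of a simulated null distribution using a chi-square goodness-of-fit test
in which PST percentages are treated as counts out of 100 (1 df, critical
value 3.841 at alpha = 0.05).  ``rejection_interval`` scans integer
expected percentages for the non-rejection band; ``power_analysis``
estimates the probability that data generated under one model reject
another.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import GeneTree, IsolationModel, simulate_gene_tree
from .parsimony import ReconstructedTree, parsimony_search, _hartigan_score
from .seqsim import (
    CalibrationResult,
    ScalingFactor,
    SubstitutionModel,
    calibrate_scaling,
    evolve_sequences,
)

__all__ = [
    "SDistribution",
    "PSTTest",
    "PowerResult",
    "slatkins_s",
    "pst",
    "pst_chi_square",
    "rejection_interval",
    "tally_s_distribution",
    "power_analysis",
    "NullPipeline",
]


def _two_state_hartigan(adj, n_leaves: int, is_pop2: np.ndarray) -> int:
    """Minimum changes of a binary population character on a tree given as
    adjacency lists (leaves first)."""
    tip_states = np.zeros((n_leaves, 1, 2), dtype=bool)
    tip_states[np.arange(n_leaves), 0, is_pop2.astype(int)] = True
    return _hartigan_score(adj, n_leaves, tip_states, np.ones(1, dtype=np.int64))


def slatkins_s(tree, populations: Optional[dict[str, str]] = None) -> int:
    """Slatkin's s: parsimony count of the two-population label on a tree.

    ``tree`` may be a :class:`~pstsim.models.GeneTree` (its own population
    map is used), a :class:`~pstsim.parsimony.ReconstructedTree`, or a
    dendropy tree; ``populations`` maps tip labels to exactly two
    population identifiers.
    """
    if isinstance(tree, GeneTree):
        populations = populations or tree.tip_population
        labels = tree.labels
        ch = tree.children()
        adj: list[list[int]] = [[] for _ in range(tree.n_nodes)]
        for node, kids in enumerate(ch):
            for k in kids:
                adj[node].append(k)
                adj[k].append(node)
        n_leaves = tree.n_tips
    elif isinstance(tree, ReconstructedTree):
        if populations is None:
            raise ValueError("a population map is required")
        labels = tree.labels
        adj = tree.adjacency
        n_leaves = tree.n_tips
    else:  # dendropy tree
        if populations is None:
            raise ValueError("a population map is required")
        from .parsimony import _tree_from_dendropy

        labels = [
            nd.taxon.label for nd in tree.leaf_node_iter() if nd.taxon
        ]
        adj, labels = _tree_from_dendropy(tree, labels)
        n_leaves = len(labels)

    missing = [lab for lab in labels if lab not in populations]
    if missing:
        raise ValueError(f"unlabeled tips: {missing[:5]}")
    pops = sorted({populations[lab] for lab in labels})
    if len(pops) != 2:
        raise ValueError(
            f"exactly two populations required among the tips, got {pops}"
        )
    is_pop2 = np.array([populations[lab] == pops[1] for lab in labels])
    if n_leaves == 2:
        return 1
    return _two_state_hartigan(adj, n_leaves, is_pop2)


def pst(s_values: Iterable[int]) -> float:
    """Percentage of trees with s = 1."""
    vals = list(s_values)
    if not vals:
        raise ValueError("empty collection of s values")
    return 100.0 * sum(1 for v in vals if v == 1) / len(vals)


@dataclass
class PSTTest:
    observed_pst: float
    expected_proportion: float
    chi_square: float
    df: int
    p_value: float
    alpha: float
    rejected: bool


def pst_chi_square(
    observed_pst: float,
    expected_proportion: float,
    alpha: float = 0.05,
    n_null: int = 1000,
) -> PSTTest:
    """Chi-square test of an observed PST against a null proportion.

    PST percentages are treated as counts out of 100 (goodness of fit with
    1 df).  Null proportions of exactly 0 or 1 are clamped by half a count
    of the null simulation size so the statistic stays defined.
    """
    if not (0.0 <= observed_pst <= 100.0):
        raise ValueError("observed PST must lie in [0, 100]")
    if not (0.0 <= expected_proportion <= 1.0):
        raise ValueError("expected proportion must lie in [0, 1]")
    half_count = 1.0 / (2.0 * n_null)
    p = min(max(expected_proportion, half_count), 1.0 - half_count)
    o = observed_pst
    chi2 = (o - 100.0 * p) ** 2 / (100.0 * p * (1.0 - p))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return PSTTest(
        observed_pst=o,
        expected_proportion=expected_proportion,
        chi_square=chi2,
        df=1,
        p_value=p_value,
        alpha=alpha,
        rejected=p_value < alpha,
    )


def rejection_interval(
    observed_pst: float, alpha: float = 0.05, n_null: int = 1000
) -> tuple[int, int]:
    """Smallest and largest integer expected-PST percentages (inclusive)
    not rejected at ``alpha`` given the observed PST."""
    kept = [
        e
        for e in range(101)
        if not pst_chi_square(observed_pst, e / 100.0, alpha, n_null).rejected
    ]
    if not kept:
        raise ValueError("every expected percentage is rejected")
    return min(kept), max(kept)


@dataclass
class SDistribution:
    """Tally of Slatkin's s over a set of gene trees."""

    counts: Counter
    n_trees: int
    source: str = ""

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_trees:
            raise ValueError("counts must sum to n_trees")

    @property
    def s_max(self) -> int:
        return max(self.counts)

    @property
    def pst(self) -> float:
        return 100.0 * self.counts.get(1, 0) / self.n_trees

    @property
    def sorted_proportion(self) -> float:
        return self.counts.get(1, 0) / self.n_trees

    def percentages(self) -> dict[int, float]:
        return {
            s: 100.0 * c / self.n_trees for s, c in sorted(self.counts.items())
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("s\tcount\tpercent\n")
            for s, c in sorted(self.counts.items()):
                fh.write(f"{s}\t{c}\t{100.0 * c / self.n_trees:.2f}\n")

    @classmethod
    def from_s_values(cls, values: Iterable[int], source: str = "") -> "SDistribution":
        vals = list(values)
        return cls(Counter(vals), len(vals), source)

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "SDistribution":
        counts: Counter = Counter()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                s, c = line.split("\t")[:2]
                counts[int(s)] = int(c)
        return cls(counts, sum(counts.values()), source)


@dataclass
class NullPipeline:
    """Options for the simulate -> evolve -> reconstruct -> s pipeline.

    The default calibration target is the observed mean between-species
    pairwise divergence of the 14-locus study data (~0.88%), matched on
    cross-population pairs; ``calibration_pairs="all"`` with a total-
    diversity target reproduces the all-pairs alternative.
    """

    n1: int = 15
    n2: int = 70
    length: int = 500
    sub_model: SubstitutionModel = field(default_factory=SubstitutionModel)
    mode: str = "reconstructed"  # or "truetree"
    target_divergence: Optional[float] = None  # default: observed between-species
    calibration_pairs: str = "between"
    calibration_reps: int = 8
    restarts: int = 1

    def resolved_target(self) -> float:
        if self.target_divergence is not None:
            return self.target_divergence
        from .datasets import observed_between_divergence, observed_mean_diversity

        if self.calibration_pairs == "between":
            return observed_between_divergence()
        return observed_mean_diversity()


def _pipeline_s(
    model: IsolationModel,
    options: NullPipeline,
    scaling: Optional[ScalingFactor],
    seed: int,
) -> int:
    tree = simulate_gene_tree(model, options.n1, options.n2, seed)
    if options.mode == "truetree":
        return slatkins_s(tree)
    alignment = evolve_sequences(
        tree,
        options.length,
        options.sub_model,
        scaling,
        seed=(seed * 2654435761) % (2**31 - 1),
    )
    rec = parsimony_search(alignment, seed=seed, restarts=options.restarts)
    from .models import POP2

    is_pop2 = np.array(
        [tree.tip_population[lab] == POP2 for lab in rec.labels]
    )
    return _two_state_hartigan(rec.adjacency, rec.n_tips, is_pop2)


def tally_s_distribution(
    model: IsolationModel,
    n_trees: int = 1000,
    options: Optional[NullPipeline] = None,
    seed: int = 0,
    scaling: Optional[ScalingFactor] = None,
) -> SDistribution:
    """Null distribution of Slatkin's s under ``model``.

    In "reconstructed" mode (the standard procedure) each replicate
    simulates a gene tree, evolves a sequence matrix at a scaling
    calibrated to the target divergence, reconstructs the tree by
    parsimony, and computes s on the reconstruction.  "truetree" mode
    computes s directly on the simulated genealogy (diagnostics).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    options = options or NullPipeline()
    if options.mode not in ("reconstructed", "truetree"):
        raise ValueError("mode must be 'reconstructed' or 'truetree'")
    if options.mode == "reconstructed" and scaling is None:
        scaling = calibrate_scaling(
            model,
            options.resolved_target(),
            n1=options.n1,
            n2=options.n2,
            length=options.length,
            sub_model=options.sub_model,
            reps=options.calibration_reps,
            seed=seed + 10_007,
            pairs=options.calibration_pairs,
        ).scaling
    values = [
        _pipeline_s(model, options, scaling, seed + i) for i in range(n_trees)
    ]
    return SDistribution.from_s_values(values, source=model.label)


@dataclass
class PowerResult:
    generating_label: str
    null_label: str
    n_loci: int
    n_replicates: int
    n_null_trees: int
    alpha: float
    power: float  # percentage of replicates rejected
    expected_proportion: float


def power_analysis(
    generating: IsolationModel,
    null_model: IsolationModel,
    n_loci: int = 14,
    n_replicates: int = 100,
    n_null: int = 1000,
    alpha: float = 0.05,
    options: Optional[NullPipeline] = None,
    seed: int = 0,
    null_distribution: Optional[SDistribution] = None,
) -> PowerResult:
    """Probability that ``n_loci``-locus datasets drawn under
    ``generating`` reject ``null_model`` with the PST chi-square test.

    When the two models coincide the rejection rate estimates the test's
    type-I error and should sit near ``alpha``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    options = options or NullPipeline(mode="truetree")
    if null_distribution is None:
        null_distribution = tally_s_distribution(
            null_model, n_null, options, seed=seed + 500_009
        )
    p_null = null_distribution.sorted_proportion
    scaling = None
    if options.mode == "reconstructed":
        scaling = calibrate_scaling(
            generating,
            options.resolved_target(),
            n1=options.n1,
            n2=options.n2,
            length=options.length,
            sub_model=options.sub_model,
            reps=options.calibration_reps,
            seed=seed + 20_011,
            pairs=options.calibration_pairs,
        ).scaling
    rejections = 0
    for rep in range(n_replicates):
        s_vals = [
            _pipeline_s(
                generating, options, scaling, seed + rep * n_loci + k
            )
            for k in range(n_loci)
        ]
        test = pst_chi_square(pst(s_vals), p_null, alpha, n_null)
        rejections += test.rejected
    return PowerResult(
        generating_label=generating.label,
        null_label=null_model.label,
        n_loci=n_loci,
        n_replicates=n_replicates,
        n_null_trees=null_distribution.n_trees,
        alpha=alpha,
        power=100.0 * rejections / n_replicates,
        expected_proportion=p_null,
    )
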