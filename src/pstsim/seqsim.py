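"""HKY sequence evolution along gene trees and divergence calibration.

Alignments are fixed-length nucleotide matrices evolved site-independently
under the HKY substitution model (transition/transversion ratio ``kappa``,
arbitrary base frequencies).  Branch lengths of the input genealogy are in
generations; a scaling factor (expected substitutions per site per
generation) converts them to substitution units.  ``calibrate_scaling``
finds, by bisection on a fixed ladder of simulated gene trees, the scaling
that makes the average pairwise sequence divergence of simulated
alignments match an observed target -- the standard way of tuning
simulated sequence variability to a real dataset when the underlying
mutation rate is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import GeneTree, IsolationModel, simulate_gene_tree

__all__ = [
    "SubstitutionModel",
    "ScalingFactor",
    "LocusAlignment",
    "CalibrationResult",
    "CalibrationError",
    "evolve_sequences",
    "mean_pairwise_divergence",
    "expected_p_distance",
    "calibrate_scaling",
    "read_fasta",
    "write_fasta",
    "read_popmap",
    "write_popmap",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
#: column code for gaps / missing / ambiguous characters in user data
MISSING = 4


@dataclass(frozen=True)
class SubstitutionModel:
    """HKY85: one transition/transversion rate ratio, free base frequencies."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.min() < 0 or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must be non-negative and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix, normalised to one expected
        substitution per site per unit time."""
        pi = np.asarray(self.base_freqs, dtype=float)
        kappa = self.kappa
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def _eigen(self):
        """Eigendecomposition of Q via symmetrisation (reversible model)."""
        pi = np.asarray(self.base_freqs, dtype=float)
        # guard zero frequencies for the similarity transform
        d = np.sqrt(np.clip(pi, 1e-300, None))
        q = self.rate_matrix()
        sym = (q * d[:, None]) / d[None, :]
        sym = 0.5 * (sym + sym.T)
        w, v = np.linalg.eigh(sym)
        right = v / d[:, None]
        left = v.T * d[None, :]
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the parent state."""
        if t < 0:
            raise ValueError("negative branch duration")
        w, right, left = self._eigen()
        p = (right * np.exp(w * t)) @ left
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def expected_p_distance(sub_model: SubstitutionModel, t: float) -> float:
    """Expected proportion of differing sites between the two ends of a
    path of ``t`` expected substitutions/site (matrix-exponential form)."""
    pi = np.asarray(sub_model.base_freqs, dtype=float)
    p = sub_model.transition_matrix(t)
    return float((pi * (1.0 - np.diag(p))).sum())


@dataclass(frozen=True)
class ScalingFactor:
    """Expected substitutions per site per generation applied to branches."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("scaling rate must be non-negative")


@dataclass
class LocusAlignment:
    """Fixed-length nucleotide matrix with row labels and population map.

    ``matrix`` holds integer codes 0..3 for ACGT and 4 for anything else
    (gap, N, IUPAC ambiguity) in user-supplied data.
    """

    matrix: np.ndarray
    labels: list[str]
    populations: Optional[dict[str, str]] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per row required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("row labels must be unique")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(BASES[c] if c < 4 else "N" for c in self.matrix[i])

    def restrict(self, population: str) -> "LocusAlignment":
        """Rows belonging to one population (population map required)."""
        if self.populations is None:
            raise ValueError("alignment carries no population map")
        keep = [i for i, lab in enumerate(self.labels)
                if self.populations.get(lab) == population]
        labels = [self.labels[i] for i in keep]
        return LocusAlignment(
            self.matrix[keep], labels,
            {lab: population for lab in labels}, self.name,
        )


def evolve_sequences(
    tree: GeneTree,
    length: int = 500,
    sub_model: Optional[SubstitutionModel] = None,
    scaling: ScalingFactor | float = 0.0,
    seed: int = 0,
) -> LocusAlignment:
    """Evolve a ``length``-bp alignment along ``tree`` under HKY.

    The root sequence is drawn from the equilibrium base frequencies; each
    branch applies the HKY transition matrix for a duration of
    ``branch length (generations) x scaling.rate`` independently per site.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    sub_model = sub_model or SubstitutionModel()
    rate = scaling.rate if isinstance(scaling, ScalingFactor) else float(scaling)
    if rate < 0:
        raise ValueError("scaling rate must be non-negative")
    rng = np.random.default_rng(seed)
    pi = np.asarray(sub_model.base_freqs, dtype=float)
    w, right, left = sub_model._eigen()

    children = tree.children()
    root = tree.root
    states: dict[int, np.ndarray] = {
        root: rng.choice(4, size=length, p=pi).astype(np.uint8)
    }
    out = np.empty((tree.n_tips, length), dtype=np.uint8)
    # preorder: parents are always processed before children
    stack = [root]
    while stack:
        node = stack.pop()
        seq = states.pop(node)
        if node < tree.n_tips:
            out[node] = seq
            continue
        for child in children[node]:
            t = tree.branch_length(child) * rate
            if t < 0:
                raise ValueError("negative branch length")
            if t == 0.0:
                states[child] = seq.copy()
            else:
                p = (right * np.exp(w * t)) @ left
                p = np.clip(p, 0.0, None)
                p /= p.sum(axis=1, keepdims=True)
                child_seq = np.empty(length, dtype=np.uint8)
                for s in range(4):
                    idx = np.flatnonzero(seq == s)
                    if idx.size:
                        child_seq[idx] = rng.choice(4, size=idx.size, p=p[s])
                states[child] = child_seq
            stack.append(child)
    return LocusAlignment(
        out, list(tree.labels), dict(tree.tip_population), name="simulated"
    )


def mean_pairwise_divergence(
    alignment: LocusAlignment, between: Optional[tuple[str, str]] = None
) -> float:
    """Mean proportion of differing sites over sequence pairs.

    By default all pairs are averaged; ``between=(popA, popB)`` restricts
    the average to cross-population pairs (the divergence that carries the
    lineage-sorting signal).  Columns where either member of a pair is
    missing/ambiguous are excluded for that pair (only relevant for
    user-supplied data).
    """
    x = alignment.matrix
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    if between is not None:
        if alignment.populations is None:
            raise ValueError("between-population divergence needs a population map")
        pa, pb = between
        ia = [i for i, lab in enumerate(alignment.labels)
              if alignment.populations.get(lab) == pa]
        ib = [i for i, lab in enumerate(alignment.labels)
              if alignment.populations.get(lab) == pb]
        if not ia or not ib:
            raise ValueError("both populations must be present")
        xa, xb = x[ia], x[ib]
        both = (xa[:, None, :] < 4) & (xb[None, :, :] < 4)
        diffs = ((xa[:, None, :] != xb[None, :, :]) & both).sum()
        sites = both.sum()
        if sites == 0:
            raise ValueError("no comparable sites between any pair")
        return float(diffs / sites)
    valid = x < 4
    total_diff = 0.0
    total_sites = 0.0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diffs = ((x[i] != x[i + 1 :]) & both).sum(axis=1)
        sites = both.sum(axis=1)
        total_diff += diffs.sum()
        total_sites += sites.sum()
    if total_sites == 0:
        raise ValueError("no comparable sites between any pair")
    return total_diff / total_sites


@dataclass
class CalibrationResult:
    scaling: ScalingFactor
    achieved_divergence: float
    steps: int


class CalibrationError(RuntimeError):
    """Raised when no scaling rate can reach the target divergence; the
    closest achieved divergence is attached."""

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


def calibrate_scaling(
    model: IsolationModel,
    target_divergence: float,
    n1: int = 15,
    n2: int = 70,
    length: int = 500,
    sub_model: Optional[SubstitutionModel] = None,
    reps: int = 8,
    seed: int = 0,
    rel_tol: float = 0.10,
    max_steps: int = 30,
    pairs: str = "all",
) -> CalibrationResult:
    """Find the branch-scaling rate whose simulated mean pairwise
    divergence matches ``target_divergence`` within ``rel_tol`` (relative).

    ``pairs="all"`` averages every sequence pair; ``pairs="between"``
    averages only cross-population pairs, which is the divergence that
    controls how much phylogenetic signal separates the two groups.

    A fixed ladder of ``reps`` gene trees (seeds ``seed .. seed+reps-1``)
    is simulated once and reused across bisection steps, so the search is
    reproducible and effectively monotone in the rate.
    """
    if pairs not in ("all", "between"):
        raise ValueError("pairs must be 'all' or 'between'")
    if not (0.0 < target_divergence < 1.0):
        raise ValueError("target divergence must lie in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sub_model = sub_model or SubstitutionModel()
    trees = [simulate_gene_tree(model, n1, n2, seed + i) for i in range(reps)]
    seq_seeds = [(seed + 7919 * (i + 1)) % (2**31 - 1) for i in range(reps)]

    from .models import POP1, POP2

    between = (POP1, POP2) if pairs == "between" else None

    def achieved(rate: float) -> float:
        divs = [
            mean_pairwise_divergence(
                evolve_sequences(t, length, sub_model, rate, s), between
            )
            for t, s in zip(trees, seq_seeds)
        ]
        return float(np.mean(divs))

    # bracket the target by doubling; rates are substitutions/site/generation
    lo, f_lo = 0.0, 0.0
    hi = 1e-12
    f_hi = achieved(hi)
    doublings = 0
    while f_hi < target_divergence and doublings < 80:
        lo, f_lo = hi, f_hi
        hi *= 2.0
        f_hi = achieved(hi)
        doublings += 1
    if f_hi < target_divergence:
        raise CalibrationError(
            f"target divergence {target_divergence} unattainable; "
            f"saturation plateau near {f_hi:.6f}",
            achieved=f_hi,
        )
    best_rate, best_div = hi, f_hi
    steps = 0
    while steps < max_steps:
        if abs(best_div - target_divergence) <= rel_tol * target_divergence:
            break
        mid = 0.5 * (lo + hi)
        f_mid = achieved(mid)
        if abs(f_mid - target_divergence) < abs(best_div - target_divergence):
            best_rate, best_div = mid, f_mid
        if f_mid < target_divergence:
            lo = mid
        else:
            hi = mid
        steps += 1
    return CalibrationResult(ScalingFactor(best_rate), best_div, steps)


# -- FASTA / population-map I/O ------------------------------------------

def write_fasta(alignment: LocusAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(alignment.labels):
            fh.write(f">{label}\n")
            seq = alignment.sequence(i)
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_fasta(
    path,
    populations: Optional[dict[str, str]] = None,
    strict_acgt: bool = False,
    name: str = "",
) -> LocusAlignment:
    """Read an aligned FASTA.  With ``strict_acgt`` any non-ACGT character
    is an error (simulated-data paths); otherwise gaps/ambiguities are
    kept as missing and excluded from pairwise comparisons."""
    from Bio import SeqIO

    labels: list[str] = []
    rows: list[np.ndarray] = []
    for record in SeqIO.parse(str(path), "fasta"):
        labels.append(record.id)
        seq = str(record.seq).upper()
        codes = np.fromiter(
            (_CODE.get(c, MISSING) for c in seq), dtype=np.uint8, count=len(seq)
        )
        if strict_acgt and (codes == MISSING).any():
            raise ValueError(
                f"non-ACGT character in sequence {record.id!r} of {path}"
            )
        rows.append(codes)
    if not rows:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return LocusAlignment(np.vstack(rows), labels, populations, name=name)


def write_popmap(populations: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")


def read_popmap(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out
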