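"""Parsimony gene-tree reconstruction: Fitch scoring, neighbor joining,
and NNI hill climbing.

The reconstruction step mirrors the classic simulation pipeline: simulated
alignments are turned back into (unrooted) trees by unweighted parsimony
so that lineage-sorting statistics are measured on trees carrying
reconstruction error, exactly as they would be for real data.

Scoring uses the Fitch small-parsimony algorithm with per-pattern state
sets packed four bits per site pattern into Python big integers, so a
whole alignment is scored with a handful of bitwise operations per node.
Columns whose parsimony score cannot depend on the topology (constant
columns and columns where at most one state occurs more than once)
contribute a precomputed constant.  Polytomies in user-supplied trees are
handled by Hartigan's generalisation.

The search is deterministic: neighbor joining with lowest-index tie
breaking provides the start tree, then first-improvement
nearest-neighbor-interchange sweeps in a fixed edge order run until no
move lowers the score.  For seven or fewer taxa the search instead
enumerates every unrooted topology, so the returned score is the global
minimum by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqsim import LocusAlignment, MISSING

__all__ = [
    "ReconstructedTree",
    "parsimony_score",
    "neighbor_joining",
    "parsimony_search",
    "p_distance_matrix",
    "read_newick",
    "write_newick",
]

_STATE_MASK = (1, 2, 4, 8)  # A, C, G, T as bits
_FULL = 15


# ---------------------------------------------------------------------------
# pattern compression
# ---------------------------------------------------------------------------

def _compress_patterns(matrix: np.ndarray):
    """Split alignment columns into a topology-independent score offset and
    weighted parsimony-relevant patterns.

    Returns ``(offset, patterns, weights)`` where ``patterns`` is an array
    of shape (n_rows, P) of state codes.  A column is topology-independent
    when it contains no missing data and at most one state occurs more
    than once; its score is then ``n_rows - max state count`` on every
    tree.
    """
    cols, weights = np.unique(matrix, axis=1, return_counts=True)
    offset = 0
    keep: list[int] = []
    n = matrix.shape[0]
    for j in range(cols.shape[1]):
        col = cols[:, j]
        if (col >= 4).any():
            keep.append(j)  # missing data: no shortcut, let Fitch handle it
            continue
        counts = np.bincount(col, minlength=4)
        if (counts >= 2).sum() >= 2:
            keep.append(j)
        else:
            offset += int(weights[j]) * (n - int(counts.max()))
    return offset, cols[:, keep], weights[keep]


def _pack_tip_sets(patterns: np.ndarray) -> list[int]:
    """Per-row big-int bitsets: nibble ``j`` holds the state set of
    pattern ``j`` (missing data = full set)."""
    n, p = patterns.shape
    sets = []
    for i in range(n):
        acc = 0
        row = patterns[i]
        for j in range(p):
            c = row[j]
            mask = _FULL if c >= 4 else _STATE_MASK[c]
            acc |= mask << (4 * j)
        sets.append(acc)
    return sets


def _nibble_lsb(p: int) -> int:
    """0x111...1 with one bit per nibble over p nibbles."""
    acc = 0
    for j in range(p):
        acc |= 1 << (4 * j)
    return acc


class _FitchScorer:
    """Scores adjacency-represented unrooted binary trees against a fixed
    set of packed site patterns."""

    def __init__(self, matrix: np.ndarray):
        self.n = matrix.shape[0]
        self.offset, patterns, weights = _compress_patterns(matrix)
        self.n_patterns = patterns.shape[1]
        self.tip_sets = _pack_tip_sets(patterns)
        self.weights = [int(w) for w in weights]
        self._lsb = _nibble_lsb(self.n_patterns)

    def score(self, adj: list[list[int]]) -> int:
        if self.n_patterns == 0:
            return self.offset
        lsb = self._lsb
        weights = self.weights
        tip_sets = self.tip_sets
        n = self.n
        cost = 0
        # root at leaf 0; iterative post-order over (node, parent)
        sets: dict[int, int] = {}
        stack: list[tuple[int, int, bool]] = [(adj[0][0], 0, False)]
        while stack:
            node, parent, done = stack.pop()
            if node < n:
                sets[node] = tip_sets[node]
                continue
            if not done:
                stack.append((node, parent, True))
                for nb in adj[node]:
                    if nb != parent:
                        stack.append((nb, node, False))
                continue
            acc = -1
            for nb in adj[node]:
                if nb == parent:
                    continue
                child = sets.pop(nb)
                if acc == -1:
                    acc = child
                    continue
                inter = acc & child
                m = inter | (inter >> 1)
                m |= m >> 2
                zeros = lsb & ~m
                if zeros:
                    union = acc | child
                    acc = inter | (union & (zeros * 15))
                    z = zeros
                    while z:
                        low = z & -z
                        cost += weights[(low.bit_length() - 1) >> 2]
                        z ^= low
                else:
                    acc = inter
            sets[node] = acc
        # fold in the root leaf
        inter = sets[adj[0][0]] & tip_sets[0]
        m = inter | (inter >> 1)
        m |= m >> 2
        zeros = lsb & ~m
        z = zeros
        while z:
            low = z & -z
            cost += weights[(low.bit_length() - 1) >> 2]
            z ^= low
        return self.offset + cost

    # -- incremental machinery for stepwise addition ---------------------

    def _zero_weight(self, word: int) -> int:
        """Weighted count of empty nibbles in ``word``."""
        lsb = self._lsb
        m = word | (word >> 1)
        m |= m >> 2
        z = lsb & ~m
        total = 0
        while z:
            low = z & -z
            total += self.weights[(low.bit_length() - 1) >> 2]
            z ^= low
        return total

    @staticmethod
    def _combine(a: int, b: int, lsb: int) -> int:
        """Per-nibble Fitch combine: intersection where non-empty, union
        elsewhere."""
        inter = a & b
        m = inter | (inter >> 1)
        m |= m >> 2
        zeros = lsb & ~m
        if zeros:
            return inter | ((a | b) & (zeros * 15))
        return inter

    def edge_sets(self, adj: list[list[int]], root_leaf: int):
        """Fitch state sets seen from both sides of every directed edge.

        Returns ``(down, up)`` keyed by (parent, child) pairs oriented
        away from ``root_leaf``; the insertion cost of a new tip on an
        edge is the weighted count of patterns whose tip set misses
        ``combine(down, up)`` of that edge.
        """
        lsb = self._lsb
        tip_sets = self.tip_sets
        n = self.n
        root = adj[root_leaf][0]
        parent: dict[int, int] = {root: root_leaf}
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            for nb in adj[node]:
                if nb != parent[node]:
                    parent[nb] = node
                    stack.append(nb)
        down: dict[int, int] = {}
        for node in reversed(order):
            if node < n:
                down[node] = tip_sets[node]
            else:
                kids = [nb for nb in adj[node] if nb != parent[node]]
                acc = down[kids[0]]
                for k in kids[1:]:
                    acc = self._combine(acc, down[k], lsb)
                down[node] = acc
        up: dict[int, int] = {root: tip_sets[root_leaf]}
        for node in order:
            kids = [nb for nb in adj[node] if nb != parent[node]]
            for k in kids:
                acc = up[node]
                for sib in kids:
                    if sib != k:
                        acc = self._combine(acc, down[sib], lsb)
                up[k] = acc
        return parent, order, down, up

    def stepwise_addition(self, order=None, dist=None) -> list[list[int]]:
        """Greedy parsimony stepwise addition in a fixed taxon order.

        Taxa are added one at a time at the attachment edge with the
        smallest increase in parsimony score (Fitch edge sets give the
        exact single-leaf insertion cost).  Ties are broken by sequence
        similarity when a distance matrix is supplied -- among the
        minimum-cost edges the one adjacent to the leaf closest to the new
        taxon wins -- and then by a fixed traversal order.  This mirrors
        the starting-tree strategy of classic parsimony software and,
        importantly, places taxa the characters cannot resolve next to
        their most similar neighbours instead of at arbitrary positions.
        """
        n = self.n
        order = list(order) if order is not None else list(range(n))
        if n < 3:
            raise ValueError("need at least 3 taxa")
        adj: list[list[int]] = [[] for _ in range(n)]
        hub = len(adj)
        adj.append([order[0], order[1], order[2]])
        for leaf in order[:3]:
            adj[leaf] = [hub]
        root_leaf = order[0]
        inf = float("inf")
        for x in order[3:]:
            parent, trav, down, up = self.edge_sets(adj, root_leaf)
            x_set = self.tip_sets[x]
            drow = dist[x] if dist is not None else None
            best = None  # (cost, affinity, dfs index, edge)
            for idx, node in enumerate(trav):  # edge (parent[node], node)
                ctx = self._combine(down[node], up[node], self._lsb)
                cost = self._zero_weight(x_set & ctx)
                if drow is None:
                    affinity = 0.0
                else:
                    p = parent[node]
                    near = [
                        nb
                        for endpoint in (node, p)
                        for nb in ([endpoint] if endpoint < n else adj[endpoint])
                        if nb < n
                    ]
                    affinity = min((drow[l] for l in near), default=inf)
                key = (cost, affinity, idx)
                if best is None or key < best[0]:
                    best = (key, (parent[node], node))
            p, v = best[1]
            w = len(adj)
            adj.append([p, v, x])
            _replace(adj[p], v, w)
            _replace(adj[v], p, w)
            adj[x] = [w]
        return adj


# ---------------------------------------------------------------------------
# adjacency-tree helpers
# ---------------------------------------------------------------------------

def _internal_edges(adj: list[list[int]], n_leaves: int) -> list[tuple[int, int]]:
    edges = []
    for u in range(n_leaves, len(adj)):
        for v in adj[u]:
            if v >= n_leaves and u < v:
                edges.append((u, v))
    return sorted(edges)


def _replace(lst: list[int], old: int, new: int) -> None:
    lst[lst.index(old)] = new


def _nni_swap(adj: list[list[int]], u: int, a: int, v: int, c: int) -> None:
    """Exchange subtree ``a`` (neighbor of u) with subtree ``c``
    (neighbor of v) across the internal edge (u, v)."""
    _replace(adj[u], a, c)
    _replace(adj[v], c, a)
    _replace(adj[a], u, v)
    _replace(adj[c], v, u)


def _copy_adj(adj: list[list[int]]) -> list[list[int]]:
    return [list(x) for x in adj]


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(alignment: LocusAlignment) -> np.ndarray:
    """Pairwise p-distances with complete deletion of columns containing
    gaps or missing data."""
    x = alignment.matrix
    keep = (x < 4).all(axis=0)
    x = x[:, keep]
    if x.shape[1] == 0:
        return np.zeros((alignment.n_sequences, alignment.n_sequences))
    d = (x[:, None, :] != x[None, :, :]).mean(axis=2)
    np.fill_diagonal(d, 0.0)
    return d


def _nj_adjacency(dist: np.ndarray) -> list[list[int]]:
    """Neighbor joining on a distance matrix, returning the unrooted tree
    as adjacency lists (leaves 0..n-1 first).  Ties in the Q criterion are
    broken by the lowest (row-major) index pair, so the topology is a
    deterministic function of the matrix."""
    n = dist.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any() or np.abs(np.diag(dist)).max() > 0:
        raise ValueError("distances must be non-negative with zero diagonal")
    adj: list[list[int]] = [[] for _ in range(n)]
    active = list(range(n))  # node ids
    d = dist.astype(float).copy()
    while len(active) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        new = len(adj)
        adj.append([])
        adj[new].append(active[i])
        adj[new].append(active[j])
        adj[active[i]].append(new)
        adj[active[j]].append(new)
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d_new[keep]
        d2[:-1, -1] = d_new[keep]
        d2[-1, -1] = 0.0
        d = d2
        active = [active[k] for k in keep] + [new]
    hub = len(adj)
    adj.append([])
    for node in active:
        adj[hub].append(node)
        adj[node].append(hub)
    return adj


# ---------------------------------------------------------------------------
# exhaustive enumeration (small taxon counts)
# ---------------------------------------------------------------------------

def _enumerate_topologies(n_leaves: int) -> Iterable[list[list[int]]]:
    """All unrooted binary topologies on leaves 0..n-1 by stepwise
    addition, in a fixed deterministic order ((2n-5)!! trees)."""
    base: list[list[int]] = [[3], [3], [3], [0, 1, 2]]

    def edges_of(adj):
        out = []
        for u in range(len(adj)):
            for v in adj[u]:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def recurse(adj, next_leaf):
        if next_leaf == n_leaves:
            yield adj
            return
        for u, v in edges_of(adj):
            new_adj = _copy_adj(adj)
            hub = len(new_adj)
            new_adj.append([])
            _replace(new_adj[u], v, hub)
            _replace(new_adj[v], u, hub)
            new_adj[hub] = [u, v, next_leaf]
            new_adj[next_leaf] = [hub]
            yield from recurse(new_adj, next_leaf + 1)

    if n_leaves == 3:
        yield base
        return
    # re-index base so internal node ids start at n_leaves
    hub = n_leaves
    adj: list[list[int]] = [[] for _ in range(n_leaves)] + [[0, 1, 2]]
    for leaf in (0, 1, 2):
        adj[leaf] = [hub]
    yield from recurse(adj, 3)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class ReconstructedTree:
    """Unrooted tree topology over alignment rows.

    ``adjacency`` is the internal representation (leaves first); ``labels``
    map leaf indices to row labels.  ``score`` is the parsimony score under
    the alignment the tree was built from, when known.
    """

    adjacency: list[list[int]]
    labels: list[str]
    score: Optional[int] = None

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick", preserve_underscores=True)

    def newick(self) -> str:
        adj = self.adjacency
        n = self.n_tips
        if n == 2:
            return f"({self.labels[0]},{self.labels[1]});"
        root = adj[0][0] if adj[0] else 0
        parts: dict[int, str] = {}
        stack: list[tuple[int, int, bool]] = [(root, -1, False)]
        while stack:
            node, parent, done = stack.pop()
            kids = [nb for nb in adj[node] if nb != parent]
            if node < n:
                parts[node] = self.labels[node]
                continue
            if not done:
                stack.append((node, parent, True))
                for nb in kids:
                    stack.append((nb, node, False))
                continue
            parts[node] = "(" + ",".join(parts.pop(k) for k in kids) + ")"
        return parts[root] + ";"


def _tree_from_dendropy(tree, labels: Sequence[str]) -> tuple[list[list[int]], list[str]]:
    """Adjacency (possibly multifurcating) from a dendropy tree."""
    label_index = {lab: i for i, lab in enumerate(labels)}
    node_ids: dict = {}
    adj: list[list[int]] = [[] for _ in labels]
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon else nd.label
            if lab not in label_index:
                raise ValueError(f"tree tip {lab!r} not present in alignment")
            node_ids[nd] = label_index[lab]
        else:
            node_ids[nd] = len(adj)
            adj.append([])
    seen = set()
    for nd in tree.preorder_node_iter():
        lab = nd.taxon.label if (nd.is_leaf() and nd.taxon) else None
        if lab is not None:
            if lab in seen:
                raise ValueError(f"duplicate tip label {lab!r}")
            seen.add(lab)
        for child in nd.child_nodes():
            adj[node_ids[nd]].append(node_ids[child])
            adj[node_ids[child]].append(node_ids[nd])
    return adj, list(labels)


def _hartigan_score(adj: list[list[int]], n_leaves: int,
                    tip_states: np.ndarray, weights: np.ndarray) -> int:
    """Hartigan minimum-change count on an arbitrary (rooted or unrooted,
    possibly multifurcating) tree.  ``tip_states`` is a boolean array of
    shape (n_leaves, P, n_states)."""
    n_patterns = tip_states.shape[1]
    if n_patterns == 0:
        return 0
    # root at the node adjacent to leaf 0; leaf 0 is folded in at the end
    root = adj[0][0]
    cost = np.zeros(n_patterns, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    stack: list[tuple[int, int, bool]] = [(root, 0, False)]
    while stack:
        node, parent, done = stack.pop()
        if node < n_leaves:
            sets[node] = tip_states[node]
            continue
        kids = [nb for nb in adj[node] if nb != parent]
        if not done:
            stack.append((node, parent, True))
            for nb in kids:
                stack.append((nb, node, False))
            continue
        counts = np.zeros(tip_states.shape[1:], dtype=np.int64)
        for k in kids:
            counts += sets.pop(k)
        best = counts.max(axis=1)
        cost += np.int64(len(kids)) - best
        sets[node] = counts == best[:, None]
    final = sets[root] & tip_states[0]
    cost += (~final.any(axis=1)).astype(np.int64)
    return int((cost * weights).sum())


def parsimony_score(tree, alignment: LocusAlignment) -> int:
    """Minimum number of state changes of ``alignment`` on ``tree``
    (unordered 4-state Fitch; Hartigan at polytomies).

    ``tree`` may be a :class:`ReconstructedTree` or a dendropy tree whose
    tip labels match the alignment rows.  The score does not depend on
    where the tree is rooted.
    """
    if isinstance(tree, ReconstructedTree):
        if sorted(tree.labels) != sorted(alignment.labels):
            raise ValueError("tree tips do not match alignment rows")
        if tree.labels != alignment.labels:
            # permute rows to leaf order
            order = [alignment.labels.index(lab) for lab in tree.labels]
            matrix = alignment.matrix[order]
        else:
            matrix = alignment.matrix
        adj, n = tree.adjacency, tree.n_tips
    else:
        adj, labels = _tree_from_dendropy(tree, alignment.labels)
        if len({lab for lab in alignment.labels}) != alignment.n_sequences:
            raise ValueError("duplicate alignment labels")
        tips_in_tree = {
            nd.taxon.label for nd in tree.leaf_node_iter() if nd.taxon
        }
        if tips_in_tree != set(alignment.labels):
            raise ValueError("tree tips do not match alignment rows")
        matrix, n = alignment.matrix, alignment.n_sequences
    cols, weights = np.unique(matrix, axis=1, return_counts=True)
    p = cols.shape[1]
    tip_states = np.zeros((n, p, 4), dtype=bool)
    for s in range(4):
        tip_states[:, :, s] = (cols == s) | (cols >= 4)
    return _hartigan_score(adj, n, tip_states, weights)


def neighbor_joining(
    dist: np.ndarray, labels: Optional[Sequence[str]] = None
) -> ReconstructedTree:
    """Standard NJ agglomeration with deterministic lowest-index-pair tie
    breaking; returns the unrooted topology (no branch lengths)."""
    dist = np.asarray(dist, dtype=float)
    if labels is None:
        labels = [f"t{i}" for i in range(dist.shape[0])]
    adj = _nj_adjacency(dist)
    return ReconstructedTree(adj, list(labels))


def _nni_hill_climb(adj: list[list[int]], n: int, scorer: _FitchScorer) -> int:
    """First-improvement NNI in fixed edge order; mutates ``adj`` in
    place and returns the final score (never above the start score)."""
    score = scorer.score(adj)
    improved = True
    while improved:
        improved = False
        for u, v in _internal_edges(adj, n):
            a = min(nb for nb in adj[u] if nb != v)
            others_v = sorted(nb for nb in adj[v] if nb != u)
            for c in others_v:
                _nni_swap(adj, u, a, v, c)
                s = scorer.score(adj)
                if s < score:
                    score = s
                    improved = True
                    break
                _nni_swap(adj, u, c, v, a)  # revert
            if improved:
                break
    return score


def parsimony_search(
    alignment: LocusAlignment,
    seed: int = 0,
    restarts: int = 1,
    start: str = "stepwise",
) -> ReconstructedTree:
    """Reconstruct an unrooted tree by parsimony.

    Seven or fewer taxa: exhaustive enumeration of all unrooted topologies
    (global optimum).  More taxa: a greedy stepwise-addition starting tree
    (``start="nj"`` uses neighbor joining on p-distances instead) followed
    by first-improvement NNI hill climbing in a fixed edge order; the
    returned score never exceeds the start score.  The result is a
    deterministic function of the alignment (and ``seed``, which only
    varies the taxon addition order when ``restarts > 1``; the tree with
    the lowest score, first found, wins).
    """
    n = alignment.n_sequences
    if n < 4:
        raise ValueError("parsimony search needs at least 4 sequences")
    scorer = _FitchScorer(alignment.matrix)
    if n <= 7:
        best_adj, best_score = None, None
        for adj in _enumerate_topologies(n):
            s = scorer.score(adj)
            if best_score is None or s < best_score:
                best_adj, best_score = adj, s
        return ReconstructedTree(best_adj, list(alignment.labels), best_score)

    rng = np.random.default_rng(seed)
    dist = p_distance_matrix(alignment)
    best_adj, best_score = None, None
    for r in range(max(1, restarts)):
        if r == 0:
            if start == "nj":
                adj = _nj_adjacency(dist)
            else:
                adj = scorer.stepwise_addition(dist=dist)
        else:
            order = rng.permutation(n).tolist()
            adj = scorer.stepwise_addition(order, dist=dist)
        score = _nni_hill_climb(adj, n, scorer)
        if best_score is None or score < best_score:
            best_adj, best_score = adj, score
    return ReconstructedTree(best_adj, list(alignment.labels), best_score)


# -- newick I/O for user-supplied trees ----------------------------------

def read_newick(path_or_string, schema: str = "newick"):
    """Read a gene tree (e.g. an ML tree for the observed arm)."""
    import dendropy

    text = str(path_or_string)
    if "(" in text and ";" in text:
        return dendropy.Tree.get(
            data=text, schema=schema, preserve_underscores=True
        )
    return dendropy.Tree.get(path=text, schema=schema, preserve_underscores=True)


def write_newick(tree, path) -> None:
    if isinstance(tree, ReconstructedTree):
        text = tree.newick()
    else:
        text = tree.as_string(schema="newick")
    with open(path, "w") as fh:
        fh.write(text if text.endswith("\n") else text + "\n")
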