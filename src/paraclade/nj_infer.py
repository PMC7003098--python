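"""Distance-based draft gene trees: p-distances, Neighbor-Joining, bootstrap.

The screening stage of the pipeline needs quick draft trees rather than
full Bayesian inference, so gene trees are built from pairwise distances
with Saitou–Nei Neighbor-Joining. Determinism is part of the contract:
Q-criterion ties break toward the lowest (i, j) index pair, negative branch
lengths are clamped to zero (with the clamped deficit logged), and bootstrap
resampling is fully seeded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import Alignment, FormatError, GeneTree, Node

logger = logging.getLogger(__name__)

_MISSING = ("-", "X")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def __getitem__(self, pair):
        i, j = (self.ids.index(p) if isinstance(p, str) else p for p in pair)
        return self.values[i, j]


def _encode(aln: Alignment) -> np.ndarray:
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1")
    return arr.reshape(len(aln.rows), aln.n_columns)


def p_distance(aln: Alignment, gap_mode: str = "pairwise_deletion",
               column_indices=None) -> DistanceMatrix:
    """Proportion of differing residues per pair.

    ``pairwise_deletion`` compares, per pair, only columns where neither row
    has a gap or unknown; ``complete_deletion`` first drops every column
    containing a gap or unknown in any row. A pair with no comparable
    columns raises, naming the pair.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least two sequences")
    arr = _encode(aln)
    if column_indices is not None:
        arr = arr[:, column_indices]
    ok = ~np.isin(arr, [b"-", b"X"])
    if gap_mode == "complete_deletion":
        keep = ok.all(axis=0)
        arr, ok = arr[:, keep], ok[:, keep]
    elif gap_mode != "pairwise_deletion":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise FormatError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            d[i, j] = d[j, i] = float((arr[i, both] != arr[j, both]).sum()) / m
    return DistanceMatrix(list(aln.ids), d)


def poisson_correct(d: DistanceMatrix) -> DistanceMatrix:
    """Multiple-hit correction ``d' = -ln(1 - p)``; requires all p < 1."""
    p = d.values
    if np.any((p >= 1.0) & ~np.eye(len(d.ids), dtype=bool)):
        raise ValueError("cannot Poisson-correct a saturated distance (p >= 1)")
    return DistanceMatrix(list(d.ids), -np.log1p(-p))


def neighbor_joining(d: DistanceMatrix) -> GeneTree:
    """Saitou–Nei agglomeration; returns the canonical unrooted tree.

    Ties in the Q criterion break toward the lowest (i, j) index pair in the
    current (stable) node ordering; negative branch lengths are clamped to
    zero and the total clamped deficit logged.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least three taxa")
    D = d.values.copy()
    nodes = [Node(name) for name in d.ids]
    active = list(range(n))
    clamped = 0.0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties, scanning row-major over the active list
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ai, aj = divmod(int(flat), m)
        for i in range(m):
            done = False
            for j in range(i + 1, m):
                if q[i, j] == qmin:
                    ai, aj = i, j
                    done = True
                    break
            if done:
                break
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        for val, node in ((li, nodes[i_glob]), (lj, nodes[j_glob])):
            if val < 0:
                clamped += -val
                val = 0.0
            node.length = val
        new = Node(children=[nodes[i_glob], nodes[j_glob]])
        nodes.append(new)
        new_idx = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i_glob, j_glob):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (
                D[i_glob, k] + D[j_glob, k] - dij
            )
        active = [k for k in active if k not in (i_glob, j_glob)] + [new_idx]

    # terminal three-way join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for idx, val in ((a, la), (b, lb), (c, lc)):
        if val < 0:
            clamped += -val
            val = 0.0
        nodes[idx].length = val
        root.add(nodes[idx])
    if clamped > 0:
        logger.info("neighbor_joining clamped %.6g of negative branch length",
                    clamped)
    return GeneTree(root)


def _bipartitions(tree: GeneTree, reference: str) -> set:
    """Internal bipartitions, each encoded as the side not holding `reference`."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(l.name for l in node.leaves())
        if reference in side:
            side = all_leaves - side
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            out.add(side)
    return out


def bootstrap(aln: Alignment, n_reps: int, seed: int,
              gap_mode: str = "pairwise_deletion",
              correction: str = "none") -> GeneTree:
    """Point-estimate NJ tree with bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the point-estimate tree is the percentage
    of replicate trees containing it. Replicates in which some pair has no
    comparable columns are skipped (and excluded from the denominator).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    def infer(columns=None):
        d = p_distance(aln, gap_mode=gap_mode, column_indices=columns)
        if correction == "poisson":
            d = poisson_correct(d)
        elif correction != "none":
            raise ValueError(f"unknown correction {correction!r}")
        return neighbor_joining(d)

    point = infer()
    reference = sorted(aln.ids)[0]
    target = _bipartitions(point, reference)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        try:
            tree = infer(columns=cols)
        except (FormatError, ValueError):
            continue
        n_used += 1
        seen = _bipartitions(tree, reference)
        for bp in target & seen:
            counts[bp] += 1

    all_leaves = frozenset(aln.ids)
    for node in point.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(l.name for l in node.leaves())
        if reference in side:
            side = all_leaves - side
        if side in counts and n_used:
            node.support = 100.0 * counts[side] / n_used
    return point
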