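"""Alignment, distances, neighbor-joining trees and nearest-reference queries.

Everything here is deterministic: the global aligner breaks traceback ties in
a fixed order (diagonal, then up, then left), neighbor joining breaks Q-matrix
ties on the smallest index pair, and the bootstrap consumes a single seeded
NumPy generator.  Scores default to match +1 / mismatch -1 / gap -2 (linear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAP = "-"

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must share one length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal, nonnegative")
        self.matrix = m


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the NJ result has a trifurcating root."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{c._newick_node()}:{bl:.6g}" for c, bl in self.children
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


@dataclass
class Tree:
    root: TreeNode
    degenerate: bool = False
    clamped_lengths: list[tuple[str, float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every leaf pair (keys sorted)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, 0.0)]  # type: ignore[list-item]
            groups = []
            for child, bl in node.children:
                groups.append([(n, d + bl) for n, d in walk(child)])
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a, da in groups[i]:
                        for b, db in groups[j]:
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            return [pair for g in groups for pair in g]

        walk(self.root)
        return dists

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = set(self.root.leaves())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                clade = walk(child)
                if 1 < len(clade) < len(all_leaves) - 1:
                    side = clade if anchor not in clade else all_leaves - clade
                    parts.add(frozenset(side))
                below |= clade
            return below

        walk(self.root)
        return parts


# ---------------------------------------------------------------------------
# Pairwise alignment


def pairwise_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
    ids: tuple[str, str] = ("a", "b"),
) -> tuple[Alignment, float]:
    """Optimal global alignment (linear gap cost).

    Traceback ties are broken diagonal first, then up (gap in ``b``), then
    left (gap in ``a``), which pins a unique optimal alignment.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    M = np.empty((n + 1, m + 1))
    M[0, :] = np.arange(m + 1) * gap
    M[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1] + s, M[i - 1, j] + gap, M[i, j - 1] + gap)
    # Traceback.
    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if M[i, j] == M[i - 1, j - 1] + s:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and M[i, j] == M[i - 1, j] + gap:
            ra.append(a[i - 1])
            rb.append(GAP)
            i -= 1
            continue
        ra.append(GAP)
        rb.append(b[j - 1])
        j -= 1
    aln = Alignment(list(ids), ["".join(reversed(ra)), "".join(reversed(rb))])
    return aln, float(M[n, m])


def alignment_score(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> float:
    """Score-only global alignment, vectorized row by row.

    For linear gaps the row recurrence collapses to a prefix-max scan:
    a path enters row i at some column (via diagonal or up) and then only
    moves right, so M[i, j] = max_{j' <= j} (entry[j'] + (j - j') * gap).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    m = len(b)
    jj = np.arange(1, m + 1, dtype=float)
    prev = np.arange(m + 1, dtype=float) * gap
    for i in range(1, len(a) + 1):
        s = np.where(bb == ord(a[i - 1]), match, mismatch)
        entry = np.maximum(prev[:-1] + s, prev[1:] + gap)
        drift = np.maximum.accumulate(entry - jj * gap)
        cur = np.empty(m + 1)
        cur[0] = prev[0] + gap
        cur[1:] = np.maximum(drift + jj * gap, 0 * jj + cur[0] + jj * gap)
        # First column can also feed rightward moves:
        cur[1:] = np.maximum(cur[1:], cur[0] + jj * gap)
        prev = cur
    return float(prev[m])


def identity_and_coverage(aln: Alignment) -> tuple[float, float]:
    """Percent identical columns over alignment length, and percent columns
    aligned residue-to-residue over the longer input sequence."""
    r0, r1 = aln.rows
    length = len(r0)
    ident = sum(1 for x, y in zip(r0, r1) if x == y and x != GAP)
    both = sum(1 for x, y in zip(r0, r1) if x != GAP and y != GAP)
    longer = max(len(aln.degapped(0)), len(aln.degapped(1)))
    return 100.0 * ident / length, 100.0 * both / longer


# ---------------------------------------------------------------------------
# Multiple alignment (center star)


def progressive_align(
    sequences: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximizing the summed pairwise alignment
    scores (ties to the smallest index); all others are merged against it
    under "once a gap, always a gap".
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    names = list(ids) if ids is not None else [f"seq{i}" for i in range(len(seqs))]

    k = len(seqs)
    totals = np.zeros(k)
    for i in range(k):
        for j in range(i + 1, k):
            s = alignment_score(seqs[i], seqs[j], match, mismatch, gap)
            totals[i] += s
            totals[j] += s
    center = int(np.argmax(totals))

    # Master = current gapped center row; rows follow the master's gap pattern.
    master = seqs[center]
    rows: dict[int, str] = {center: master}
    order = [center] + [i for i in range(k) if i != center]
    for idx in order[1:]:
        aln, _ = pairwise_align(master, seqs[idx], match, mismatch, gap)
        new_master, new_row = aln.rows
        # Propagate gaps newly inserted into the master to finished rows.
        if new_master != master:
            gap_map = _gap_insertions(master, new_master)
            for done, row in rows.items():
                rows[done] = _insert_gaps(row, gap_map)
            master = new_master
        rows[center] = master
        rows[idx] = new_row
    width = len(master)
    return Alignment(names, [rows[i].ljust(width, GAP) for i in range(k)])


def _gap_insertions(old: str, new: str) -> list[int]:
    """Positions (in old-row coordinates) where ``new`` inserted gaps into
    ``old``; ``old`` with gaps inserted at these positions equals ``new``."""
    out: list[int] = []
    i = 0
    for ch in new:
        if i < len(old) and ch == old[i]:
            i += 1
        else:
            if ch != GAP:
                raise ValueError("rows disagree beyond gap insertions")
            out.append(i)
    if i != len(old):
        raise ValueError("rows disagree beyond gap insertions")
    return out


def _insert_gaps(row: str, positions: list[int]) -> str:
    out: list[str] = []
    prev = 0
    for p in positions:
        out.append(row[prev:p])
        out.append(GAP)
        prev = p
    out.append(row[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Distances


def p_distance(aln: Alignment, on_undefined: str = "error") -> DistanceMatrix:
    """Proportion of differing sites over sites where neither row is gapped.

    ``on_undefined`` controls pairs with zero comparable sites: ``"error"``
    raises, ``"max"`` assigns distance 1.0 (used by the bootstrap, where a
    resample can drop every shared column of a gappy pair).
    """
    k = len(aln.rows)
    if k < 2:
        raise ValueError("need at least two rows")
    arr = np.array([list(r) for r in aln.rows])
    gaps = arr == GAP
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~gaps[i] & ~gaps[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                if on_undefined == "max":
                    d[i, j] = d[j, i] = 1.0
                    continue
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            diff = int((arr[i][ok] != arr[j][ok]).sum())
            d[i, j] = d[j, i] = diff / n_ok
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with pinned tie-breaks.

    Q-matrix ties are broken on the smallest (i, j) index pair in the current
    node ordering; negative branch lengths are clamped to zero and recorded on
    the returned tree.  An all-zero matrix yields an arbitrary resolved
    topology flagged ``degenerate``.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    clamped: list[tuple[str, float]] = []
    degenerate = bool(np.allclose(dm.matrix, 0.0))

    def clamp(node_label: str, bl: float) -> float:
        if bl < 0:
            clamped.append((node_label, bl))
            return 0.0
        return bl

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # Smallest (i, j) pair among minima.
        best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best - 1e-12:
                    best, bi, bj = Q[i, j], i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = D[bi, bj] - li
        label_i = nodes[bi].name or f"node{bi}"
        label_j = nodes[bj].name or f"node{bj}"
        li = clamp(label_i, li)
        lj = clamp(label_j, lj)
        new = TreeNode(children=[(nodes[bi], li), (nodes[bj], lj)])
        d_new = 0.5 * (D[bi] + D[bj] - D[bi, bj])
        keep = [x for x in range(m) if x not in (bi, bj)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    # Join the final three nodes at a trifurcating root.
    (x, y, z) = (0, 1, 2)
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = TreeNode(
        children=[
            (nodes[x], clamp(nodes[x].name or "nodeX", lx)),
            (nodes[y], clamp(nodes[y].name or "nodeY", ly)),
            (nodes[z], clamp(nodes[z].name or "nodeZ", lz)),
        ]
    )
    return Tree(root, degenerate=degenerate, clamped_lengths=clamped)


def bootstrap(
    aln: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; the support
    of each original internal bipartition is the percentage of replicate trees
    containing it.  A single integer seed drives one NumPy generator.
    """
    if len(aln.rows) < 4:
        raise ValueError("bootstrap needs at least four rows")
    base_dm = p_distance(aln, on_undefined="max")
    base_tree = neighbor_joining(base_dm)
    targets = base_tree.bipartitions()
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    n_sites = aln.n_sites
    arr = np.array([list(r) for r in aln.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep = Alignment(list(aln.ids), rep_rows)
        rep_tree = neighbor_joining(p_distance(rep, on_undefined="max"))
        rep_bps = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(node: TreeNode, all_leaves: set[str], anchor: str) -> set[str]:
        if node.is_leaf:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            below |= annotate(child, all_leaves, anchor)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            key = frozenset(side)
            if key in counts:
                node.support = 100.0 * counts[key] / n_replicates
        return below

    leaves = set(base_tree.leaves())
    annotate(base_tree.root, leaves, min(leaves))
    return base_tree


# ---------------------------------------------------------------------------
# Nearest labeled reference


def nearest_reference(
    query: str,
    references: Sequence[tuple[str, str, str]],
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> tuple[str, float]:
    """Label of the reference minimizing pairwise p-distance to ``query``.

    ``references`` is a sequence of (ref_id, label, sequence).  Ties go to the
    lexicographically smallest reference id with margin 0; with a single
    reference the margin is +inf.  Returns (label, margin), margin being the
    runner-up distance minus the best distance.
    """
    if not references:
        raise ValueError("need at least one reference")
    scored: list[tuple[float, str, str]] = []
    for ref_id, label, seq in references:
        aln, _ = pairwise_align(query, seq, match, mismatch, gap)
        d = float(p_distance(aln, on_undefined="max").matrix[0, 1])
        scored.append((d, ref_id, label))
    scored.sort(key=lambda t: (t[0], t[1]))
    best = scored[0]
    if len(scored) == 1:
        return best[2], math.inf
    margin = scored[1][0] - best[0]
    if abs(margin) < 1e-12:
        margin = 0.0
    return best[2], margin
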