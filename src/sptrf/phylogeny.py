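"""Jukes-Cantor distances, neighbor-joining, bootstrap support, clade purity.

The published analysis built trees with external GUI software; this module
provides a deterministic in-repo replacement: pairwise Jukes-Cantor (JC)
distances with pairwise deletion of gap columns, canonical Saitou-Nei
neighbor joining (NJ) with lexicographic tie-breaking, nonparametric
bootstrap over alignment columns, and a monophyly ("clade purity") report
that asks whether sequences of one element pattern form a clade.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .elements import MosaicAlignment
from .errors import ContractError, SaturationError

__all__ = [
    "CladePurityReport",
    "DistanceMatrix",
    "PhyloTree",
    "bootstrap_support",
    "clade_purity",
    "jc_distance",
    "jc_matrix",
    "nj_tree",
]

#: Mismatch fraction beyond which the JC transform has no finite value.
_P_MAX = 0.75
#: Distance substituted for saturated pairs when saturation="clamp".
_D_CLAMP = 5.0


def _pairwise_p(row_a: str, row_b: str) -> tuple[int, int]:
    """(mismatches, shared non-gap columns) under pairwise deletion."""
    if len(row_a) != len(row_b):
        raise ContractError("rows differ in length")
    shared = mism = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        shared += 1
        if a != b:
            mism += 1
    return mism, shared


def jc_distance(row_a: str, row_b: str, saturation: str = "raise") -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) between two gapped rows.

    p is the mismatch fraction over columns where both rows have a residue
    (pairwise deletion).  For p >= 0.75 the transform diverges; by default
    this raises :class:`SaturationError`, with ``saturation="clamp"`` a
    large fixed distance is substituted (used inside bootstrap replicates,
    where resampling can transiently saturate a pair).
    """
    mism, shared = _pairwise_p(row_a, row_b)
    if shared == 0:
        if saturation == "clamp":
            return _D_CLAMP
        raise ContractError("no shared non-gap columns between rows")
    p = mism / shared
    if p >= _P_MAX:
        if saturation == "clamp":
            return _D_CLAMP
        raise SaturationError(f"mismatch fraction {p:.3f} >= 0.75; JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ContractError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ContractError("distance matrix diagonal must be zero")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ContractError("distance matrix must be symmetric")
        if (m < -1e-12).any():
            raise ContractError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.ids)


def jc_matrix(aln: MosaicAlignment, saturation: str = "raise") -> DistanceMatrix:
    """All-pairs JC distances for an alignment (pairwise deletion)."""
    n = len(aln)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jc_distance(aln.rows[i], aln.rows[j], saturation)
    return DistanceMatrix(tuple(r.id for r in aln.records), m)


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency with branch lengths, leaves labeled by taxon.

    ``supports`` maps canonical bipartitions (see :meth:`bipartitions`) to
    bootstrap percentages.
    """

    adjacency: dict  # node -> {neighbor: branch_length}
    leaf_labels: dict  # node -> taxon id
    supports: dict = field(default_factory=dict)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.taxa)
        return side if ref not in side else frozenset(self.taxa) - side

    def bipartitions(self) -> set:
        """Canonical internal-edge bipartitions as frozensets of taxon ids.

        Each internal edge splits the leaves in two; the canonical side is
        the one not containing the lexicographically smallest taxon.
        Trivial (leaf-edge) splits are excluded.
        """
        out = set()
        for side in self._edge_sides():
            if 1 < len(side) < len(self.leaf_labels) - 1:
                out.add(self._canonical(side))
        return out

    def _edge_sides(self):
        seen = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                yield frozenset(self._leaves_beyond(v, u))

    def _leaves_beyond(self, node, blocked):
        stack, leaves, visited = [node], [], {blocked, node}
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                leaves.append(self.leaf_labels[x])
            for y in self.adjacency[x]:
                if y not in visited:
                    visited.add(y)
                    stack.append(y)
        return leaves

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        ids = self.taxa
        node_of = {lab: n for n, lab in self.leaf_labels.items()}
        n = len(ids)
        m = np.zeros((n, n))
        for i, lab in enumerate(ids):
            dist = {node_of[lab]: 0.0}
            stack = [node_of[lab]]
            while stack:
                x = stack.pop()
                for y, bl in self.adjacency[x].items():
                    if y not in dist:
                        dist[y] = dist[x] + bl
                        stack.append(y)
            for j, lab2 in enumerate(ids):
                m[i, j] = dist[node_of[lab2]]
        np.fill_diagonal(m, 0.0)
        m = (m + m.T) / 2
        return DistanceMatrix(ids, m)

    def newick(self, include_support: bool = True, min_support: float | None = None) -> str:
        """Newick string, rooted for display at the last internal node.

        Supports are written as internal-node labels; when ``min_support``
        is given, values at or below it are suppressed (the data retain
        them regardless).
        """
        internal = [n for n in self.adjacency if n not in self.leaf_labels]
        root = max(internal) if internal else next(iter(self.adjacency))

        def fmt(node, parent, blen):
            if node in self.leaf_labels:
                core = self.leaf_labels[node]
            else:
                kids = [fmt(c, node, bl) for c, bl in sorted(self.adjacency[node].items())
                        if c != parent]
                label = ""
                if include_support and parent is not None:
                    side = frozenset(self._leaves_beyond(node, parent))
                    sup = self.supports.get(self._canonical(side))
                    if sup is not None and (min_support is None or sup > min_support):
                        label = f"{sup:g}"
                core = "(" + ",".join(kids) + ")" + label
            return core if blen is None else f"{core}:{blen:.6f}"

        return fmt(root, None, None) + ";"


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    At each step the pair minimising the Q criterion is joined; ties are
    broken by the lexicographically smallest (taxon, taxon) representative
    pair, making the result deterministic.  Negative branch lengths are
    clamped to zero with a warning.
    """
    n = len(d)
    if n < 3:
        raise ContractError("neighbor joining needs at least 3 taxa")
    adjacency: dict = {}
    leaf_labels = {i: d.ids[i] for i in range(n)}
    dist = {i: {j: float(d.matrix[i, j]) for j in range(n) if j != i} for i in range(n)}
    rep = {i: d.ids[i] for i in range(n)}  # smallest leaf label in cluster
    next_node = n
    for i in range(n):
        adjacency[i] = {}

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:.3g} clamped to 0")
            return 0.0
        return x

    active = set(range(n))
    while len(active) > 2:
        r = len(active)
        total = {i: sum(dist[i].values()) for i in active}
        best = None
        best_q = math.inf
        for i in active:
            for j in active:
                if j <= i:
                    continue
                q = (r - 2) * dist[i][j] - total[i] - total[j]
                key = tuple(sorted((rep[i], rep[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and best is not None
                                          and key < tuple(sorted((rep[best[0]], rep[best[1]])))):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = dist[i][j]
        li = 0.5 * dij + (total[i] - total[j]) / (2 * (r - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        adjacency[u] = {}
        adjacency[u][i] = adjacency[i][u] = clamp(li)
        adjacency[u][j] = adjacency[j][u] = clamp(lj)
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i][k] + dist[j][k] - dij)
            dist[u][k] = dist[k][u] = duk
        active.discard(i)
        active.discard(j)
        for k in active:
            dist[k].pop(i, None)
            dist[k].pop(j, None)
        active.add(u)
        rep[u] = min(rep[i], rep[j])
    i, j = sorted(active)
    adjacency[i][j] = adjacency[j][i] = clamp(dist[i][j])
    return PhyloTree(adjacency, leaf_labels)


def bootstrap_support(
    aln: MosaicAlignment, replicates: int, seed: int
) -> PhyloTree:
    """NJ tree of the full alignment with column-bootstrap edge supports.

    Columns are resampled with replacement; each replicate alignment is run
    through JC + NJ (saturated pairs clamped to a large distance) and every
    original internal bipartition's support is the percentage of replicate
    trees containing it.
    """
    if replicates < 1:
        raise ContractError("replicates must be >= 1")
    tree = nj_tree(jc_matrix(aln, saturation="clamp"))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncols = aln.ncols
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep_rows = ["".join(np.char.decode(row[cols])) for row in rows]
        rep_aln = MosaicAlignment(aln.records, rep_rows)
        rep_tree = nj_tree(jc_matrix(rep_aln, saturation="clamp"))
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return tree


@dataclass(frozen=True)
class CladePurityReport:
    monophyletic: dict  # group label -> bool
    violators: dict  # group label -> tuple of foreign leaf ids
    purity: float


def clade_purity(
    tree: PhyloTree,
    labels: dict,
    groups: list | None = None,
) -> CladePurityReport:
    """Monophyly of each element pattern (or declared pattern group) on a tree.

    ``labels`` maps every leaf taxon to its pattern name; ``groups`` may
    merge closely related patterns (e.g. the 01/02 pair) into one unit
    before testing.  A pattern is monophyletic iff its leaf set is one side
    of some edge of the unrooted tree (singletons trivially are).  Purity is
    the fraction of monophyletic patterns; for each failure the report lists
    the foreign leaves inside the smallest clan spanning the pattern.
    """
    taxa = set(tree.taxa)
    unlabeled = taxa - set(labels)
    if unlabeled:
        raise ContractError(f"unlabeled leaves: {sorted(unlabeled)}")
    merged: dict[str, str] = {}
    if groups:
        for grp in groups:
            name = "/".join(sorted(grp))
            for g in grp:
                merged[g] = name
    members: dict[str, set] = {}
    for leaf, pat in labels.items():
        if leaf not in taxa:
            continue
        members.setdefault(merged.get(pat, pat), set()).add(leaf)

    sides = [frozenset(s) for s in tree._edge_sides()]
    all_sides = set(sides) | {frozenset(taxa) - s for s in sides} | {frozenset(taxa)}
    mono: dict[str, bool] = {}
    violators: dict[str, tuple] = {}
    for name, leaves in members.items():
        if len(leaves) <= 1 or len(leaves) == len(taxa):
            mono[name] = True
            continue
        ok = frozenset(leaves) in all_sides
        mono[name] = ok
        if not ok:
            spanning = min(
                (s for s in all_sides if leaves <= s), key=len
            )
            violators[name] = tuple(sorted(spanning - leaves))
    purity = sum(mono.values()) / len(mono) if mono else 1.0
    return CladePurityReport(mono, violators, purity)
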