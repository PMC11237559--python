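"""Distance phylogeny of SoxY homologs: stacked profile alignment,
p/Poisson distances, neighbor joining, column bootstrap, clade assignment.

Tree inference is deliberately distance-based (Saitou-Nei NJ with the
Studier-Keppler Q criterion): the clade-level structure this pipeline
reports is robust to the choice of inference method, and an implemented
algorithm keeps every stage verifiable against exact oracles.  Bootstrap
support is the classical column-resampling bipartition frequency.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IncomparablePairError, InvalidInputError

GAP_BYTE = ord("-")


# ----------------------------------------------------------------------
# Stacked alignment in profile coordinates
# ----------------------------------------------------------------------

@dataclass
class StackedAlignment:
    """Sequences threaded onto profile match columns (insertions dropped)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InvalidInputError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidInputError("duplicate sequence ids")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise InvalidInputError("rows must be equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_bytes(self) -> np.ndarray:
        return np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                         for r in self.rows])


def stack_alignments(entries: list[tuple[str, str, np.ndarray]]) -> StackedAlignment:
    """Stack (id, sequence, profile-trace) triples into a fixed-width matrix.

    Residues map to match columns; deletions become gaps; insertions
    relative to the profile are discarded.  All traces must come from the
    same profile (equal column count).
    """
    if not entries:
        raise InvalidInputError("no alignment entries")
    m = len(entries[0][2])
    ids, rows = [], []
    for sid, seq, trace in entries:
        if len(trace) != m:
            raise InvalidInputError("traces from mixed profiles")
        rows.append("".join(seq[int(t)] if t >= 0 else "-" for t in trace))
        ids.append(sid)
    return StackedAlignment(ids=ids, rows=rows)


# ----------------------------------------------------------------------
# Distances
# ----------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    model: str = "p"  # "p" | "poisson"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise InvalidInputError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T):
            raise InvalidInputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0):
            raise InvalidInputError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("distances must be finite")

    def index(self, sid: str) -> int:
        return self.ids.index(sid)


def pairwise_distance(msa: StackedAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p-distance (optionally Poisson-corrected).

    p = mismatches / shared non-gap columns; poisson d = -ln(1 - p).
    A pair with no shared columns, or p >= 1 under the Poisson model, is an
    error.
    """
    if len(msa.ids) < 2:
        raise InvalidInputError("need >= 2 rows")
    if model not in ("p", "poisson"):
        raise InvalidInputError(f"unknown model {model!r}")
    A = msa.to_bytes()
    nongap = A != GAP_BYTE
    n = len(msa.ids)
    D = np.zeros((n, n))
    for i in range(n):
        shared = nongap[i] & nongap[i + 1:]
        mism = (A[i] != A[i + 1:]) & shared
        s = shared.sum(axis=1)
        if np.any(s == 0):
            j = i + 1 + int(np.argmax(s == 0))
            raise IncomparablePairError(
                f"{msa.ids[i]} and {msa.ids[j]} share no aligned columns")
        p = mism.sum(axis=1) / s
        if model == "poisson":
            if np.any(p >= 1):
                raise IncomparablePairError("p >= 1; Poisson distance undefined")
            p = -np.log1p(-p)
        D[i, i + 1:] = p
    D = D + D.T
    return DistanceMatrix(ids=list(msa.ids), data=D, model=model)


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------

@dataclass
class Node:
    name: str = ""
    length: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating root."""

    root: Node

    def tips(self) -> list[str]:
        return self.root.tips()

    @property
    def newick(self) -> str:
        return write_newick(self)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _node_newick(node: Node) -> str:
    if node.is_leaf():
        s = node.name
    else:
        s = "(" + ",".join(_node_newick(c) for c in node.children) + ")" + node.name
    if node.length is not None:
        s += f":{_fmt(node.length)}"
    return s


def write_newick(tree: Tree) -> str:
    return _node_newick(tree.root) + ";\n"


def read_newick(text: str) -> Tree:
    """Parse Newick via scikit-bio and convert to the internal node type."""
    import skbio

    sk = skbio.TreeNode.read(_io.StringIO(text), convert_underscores=False)

    def conv(n) -> Node:
        return Node(name=n.name or "",
                    length=None if n.length is None else float(n.length),
                    children=[conv(c) for c in n.children])

    return Tree(root=conv(sk))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining (Studier-Keppler Q criterion).

    Tie joins pick the smallest (i, j) index pair in the current working
    order; negative branch lengths are clamped to zero; the result is an
    unrooted tree with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise InvalidInputError("NJ requires >= 3 taxa")
    D = dm.data.copy()
    nodes = [Node(name=sid) for sid in dm.ids]
    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(k, 1)
        best = int(np.argmin(Q[iu, ju]))  # first minimum = smallest (i, j)
        i, j = int(iu[best]), int(ju[best])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        ci, cj = nodes[i], nodes[j]
        ci.length = max(0.0, li)
        cj.length = max(0.0, lj)
        parent = Node(children=[ci, cj])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.zeros((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        D = D2
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, (dab + dac - dbc) / 2)
    b.length = max(0.0, (dab + dbc - dac) / 2)
    c.length = max(0.0, (dac + dbc - dab) / 2)
    return Tree(root=Node(children=[a, b, c]))


# ----------------------------------------------------------------------
# Bipartitions, bootstrap, clades
# ----------------------------------------------------------------------

def bipartitions(tree: Tree, trivial: bool = False) -> set[frozenset]:
    """Splits of the unrooted tree, each normalized to the side that does
    not contain the lexicographically smallest tip."""
    all_tips = frozenset(tree.tips())
    ref = min(all_tips)
    splits = set()

    def walk(node: Node):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            sub = walk(c)
            if c is not None and 0 < len(sub) < len(all_tips):
                side = sub if ref not in sub else all_tips - sub
                if trivial or 1 < len(side) < len(all_tips) - 1:
                    splits.add(side)
            below = below | sub
        return below

    walk(tree.root)
    return splits


@dataclass
class BootstrapResult:
    supports: dict[frozenset, float]
    replicates: int

    def support_for(self, tips: frozenset, all_tips: frozenset) -> float:
        ref = min(all_tips)
        side = tips if ref not in tips else all_tips - tips
        return self.supports.get(frozenset(side), 0.0)


def bootstrap_support(msa: StackedAlignment, replicates: int = 100,
                      seed: int = 0, model: str = "p") -> BootstrapResult:
    """Column-resampling bootstrap: support = bipartition frequency over
    NJ trees of resampled alignments."""
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    m = msa.n_columns
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, m, size=m)
        rep = StackedAlignment(
            ids=list(msa.ids),
            rows=["".join(r[c] for c in cols) for r in msa.rows])
        tree = neighbor_joining(pairwise_distance(rep, model))
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    return BootstrapResult(
        supports={s: c / replicates for s, c in counts.items()},
        replicates=replicates)


@dataclass
class CladeAssignment:
    assignments: dict[str, object]  # id -> clade label
    monophyly: dict[object, bool | None]


def assign_clades(dm: DistanceMatrix, exemplars: dict[object, list[str]],
                  tree: Tree | None = None) -> CladeAssignment:
    """Assign every id to the clade of its nearest exemplar set (mean
    distance; ties to the lowest clade label) and, when a tree is given,
    flag whether each assigned clade is monophyletic on it."""
    labels = sorted(exemplars)
    for lab in labels:
        if not exemplars[lab]:
            raise InvalidInputError(f"clade {lab} has no exemplars")
        for sid in exemplars[lab]:
            if sid not in dm.ids:
                raise InvalidInputError(f"exemplar {sid} missing from matrix")
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    assignments: dict[str, object] = {}
    for sid in dm.ids:
        i = idx[sid]
        means = [(float(np.mean([dm.data[i, idx[e]] for e in exemplars[lab]])), lab)
                 for lab in labels]
        best = min(means, key=lambda t: (t[0], labels.index(t[1])))
        assignments[sid] = best[1]
    monophyly: dict[object, bool | None] = {}
    if tree is not None:
        all_tips = frozenset(tree.tips())
        splits = bipartitions(tree, trivial=True)
        ref = min(all_tips)
        for lab in labels:
            members = frozenset(s for s, l in assignments.items()
                                if l == lab and s in all_tips)
            if not members:
                monophyly[lab] = None
            elif len(members) in (1, len(all_tips)):
                monophyly[lab] = True
            else:
                side = members if ref not in members else all_tips - members
                monophyly[lab] = frozenset(side) in splits
    else:
        monophyly = {lab: None for lab in labels}
    return CladeAssignment(assignments=assignments, monophyly=monophyly)
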