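"""Independent brute-force oracles used by the tests.

These enumerate search spaces directly (alignment paths, tree topologies)
and never call the code paths they are checking.
"""

from __future__ import annotations

import itertools

import numpy as np

from soxyprof._dp import AA_INDEX

NEG = float("-inf")


# ----------------------------------------------------------------------
# Alignment-path enumeration
# ----------------------------------------------------------------------

def brute_profile_global(em: np.ndarray, seq: str, gap_open: float,
                         gap_ext: float) -> float:
    """Enumerate every alignment path of seq against profile columns:
    global across columns, affine internal gaps (a run costs
    open + (k-1)*ext; switching between insertion and deletion runs
    re-opens), and sequence residues before the first / after the last
    column are free."""
    L, m = len(seq), em.shape[0]
    idx = [AA_INDEX[c] for c in seq]
    best = [NEG]

    def rec(i, j, score, last):
        if j == m:  # all columns consumed; trailing residues are free
            best[0] = max(best[0], score)
            return
        if i < L:
            rec(i + 1, j + 1, score + em[j][idx[i]], "M")
        # delete column j
        cost = gap_ext if last == "D" else gap_open
        rec(i, j + 1, score - cost, "D")
        if i < L:  # insert residue i (free while no column consumed yet)
            cost = 0.0 if j == 0 else (gap_ext if last == "I" else gap_open)
            rec(i + 1, j, score - cost, "I" if j > 0 else last)

    rec(0, 0, 0.0, "")
    return best[0]


def brute_pair_global(a: str, b: str, submat, gap_open: float,
                      gap_ext: float) -> float:
    """Global affine alignment of two sequences by path enumeration."""
    La, Lb = len(a), len(b)
    best = [NEG]

    def rec(i, j, score, last):
        if i == La and j == Lb:
            best[0] = max(best[0], score)
            return
        if i < La and j < Lb:
            rec(i + 1, j + 1, score + submat[a[i], b[j]], "M")
        if j < Lb:
            cost = gap_ext if last == "D" else gap_open
            rec(i, j + 1, score - cost, "D")
        if i < La:
            cost = gap_ext if last == "I" else gap_open
            rec(i + 1, j, score - cost, "I")

    rec(0, 0, 0.0, "")
    return best[0]


def brute_pair_local(a: str, b: str, submat, gap_open: float,
                     gap_ext: float) -> float:
    """Optimal local alignment score by enumerating all substring pairs."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            s = brute_pair_global(a[i1:i2], b[j1:j2], submat, gap_open, gap_ext)
            best = max(best, s)
    return best


# ----------------------------------------------------------------------
# Unrooted binary trees: enumeration, random generation, path distances
# ----------------------------------------------------------------------

class EdgeTree:
    """Unrooted binary tree as an edge list over node ids; leaves 0..n-1."""

    def __init__(self, n_start: int = 3):
        # star over leaves 0,1,2 with center node 100
        self.edges: list[tuple[int, int]] = [(0, 100), (1, 100), (2, 100)]
        self.next_internal = 101
        self.n_leaves = n_start

    def insert_leaf(self, edge_index: int) -> None:
        u, v = self.edges.pop(edge_index)
        c = self.next_internal
        self.next_internal += 1
        leaf = self.n_leaves
        self.n_leaves += 1
        self.edges.extend([(u, c), (v, c), (leaf, c)])

    def copy(self) -> "EdgeTree":
        t = EdgeTree.__new__(EdgeTree)
        t.edges = list(self.edges)
        t.next_internal = self.next_internal
        t.n_leaves = self.n_leaves
        return t

    def adjacency(self):
        adj: dict[int, list[tuple[int, int]]] = {}
        for k, (u, v) in enumerate(self.edges):
            adj.setdefault(u, []).append((v, k))
            adj.setdefault(v, []).append((u, k))
        return adj

    def paths(self) -> dict[tuple[int, int], list[int]]:
        """Edge-index path between every leaf pair."""
        adj = self.adjacency()
        out = {}
        for a in range(self.n_leaves):
            stack = [(a, -1, [])]
            while stack:
                node, parent, path = stack.pop()
                if node < 100 and node != a:
                    if a < node:
                        out[(a, node)] = path
                for nxt, k in adj[node]:
                    if nxt != parent:
                        stack.append((nxt, node, path + [k]))
        return out

    def splits(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, sides normalized away from leaf 0."""
        adj = self.adjacency()
        splits = set()
        for k, (u, v) in enumerate(self.edges):
            # leaves on the v side of edge k
            seen = {u}
            stack = [v]
            side = set()
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                if node < 100:
                    side.add(node)
                for nxt, ek in adj[node]:
                    if ek != k:
                        stack.append(nxt)
            all_leaves = set(range(self.n_leaves))
            if 1 < len(side) < self.n_leaves - 1:
                norm = side if 0 not in side else all_leaves - side
                splits.add(frozenset(norm))
        return splits

    def distance_matrix(self, lengths: np.ndarray) -> np.ndarray:
        n = self.n_leaves
        D = np.zeros((n, n))
        for (a, b), path in self.paths().items():
            D[a, b] = D[b, a] = sum(lengths[k] for k in path)
        return D


def enumerate_topologies(n: int) -> list[EdgeTree]:
    """All unrooted binary topologies on n labelled leaves (3, 15, 105...)."""
    trees = [EdgeTree()]
    for _ in range(3, n):
        nxt = []
        for t in trees:
            for k in range(len(t.edges)):
                t2 = t.copy()
                t2.insert_leaf(k)
                nxt.append(t2)
        trees = nxt
    return trees


def random_tree(n: int, rng: np.random.Generator,
                min_len: float = 0.2, max_len: float = 1.5):
    """Random topology with positive branch lengths; returns (tree, D)."""
    t = EdgeTree()
    for _ in range(3, n):
        t.insert_leaf(int(rng.integers(len(t.edges))))
    lengths = rng.uniform(min_len, max_len, size=len(t.edges))
    return t, t.distance_matrix(lengths)


def least_squares_ssq(tree: EdgeTree, D: np.ndarray) -> float:
    """OLS fit of branch lengths to D for a fixed topology; returns SSQ."""
    pairs = sorted(tree.paths().items())
    A = np.zeros((len(pairs), len(tree.edges)))
    y = np.zeros(len(pairs))
    for r, ((a, b), path) in enumerate(pairs):
        A[r, path] = 1.0
        y[r] = D[a, b]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ x - y
    return float(resid @ resid)
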