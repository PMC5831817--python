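"""Independent reference implementations used only as test oracles.

These deliberately re-derive results from first principles (plain
three-matrix dynamic programming, exhaustive topology enumeration with
least-squares branch fitting) and share no code with the package paths
they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def reference_local_score(a: str, b: str, score: dict, gap_open: int, gap_extend: int) -> int:
    """Plain three-matrix local-alignment DP (no vectorization tricks).

    A gap of length k costs gap_open + k * gap_extend.  ``score`` maps
    residue pairs to substitution scores.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score[(a[i - 1], b[j - 1])]
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            Ix[i][j] = max(
                M[i - 1][j] - (gap_open + gap_extend),
                Ix[i - 1][j] - gap_extend,
            )
            Iy[i][j] = max(
                M[i][j - 1] - (gap_open + gap_extend),
                Iy[i][j - 1] - gap_extend,
            )
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return int(round(best))


# ---------------------------------------------------------------------------
# Exhaustive tree search for small distance matrices


def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies (as edge lists of frozensets).

    Built by sequential insertion of each taxon into every edge of every
    partial topology; returns each topology as the set of nontrivial
    bipartitions (frozenset of frozensets).
    """
    assert len(labels) >= 3

    def splits_of(tree):
        # tree: dict node -> neighbors; leaves are labels, internals ints
        out = set()
        for u, v in tree["edges"]:
            side = _component(tree, u, v)
            if 1 < len([x for x in side if isinstance(x, str)]) < len(labels) - 1:
                out.add(frozenset(x for x in side if isinstance(x, str)))
        # canonicalize: each split as the smaller-side frozenset is ambiguous;
        # store both orientations collapsed by min-size then lexicographic
        canon = set()
        full = frozenset(labels)
        for s in out:
            comp = full - s
            canon.add(min((s, comp), key=lambda f: (len(f), sorted(f))))
        return frozenset(canon)

    def _component(tree, start, blocked):
        seen = {blocked, start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in tree["adj"][x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        seen.discard(blocked)
        return seen

    # start with the unique 3-leaf star
    star = {
        "adj": {0: set(labels[:3]), **{l: {0} for l in labels[:3]}},
        "edges": [(l, 0) for l in labels[:3]],
        "next_internal": 1,
    }
    partial = [star]
    for leaf in labels[3:]:
        grown = []
        for tree in partial:
            for u, v in tree["edges"]:
                new = _insert_leaf(tree, u, v, leaf)
                grown.append(new)
        partial = grown
    return [(t, splits_of(t)) for t in partial]


def _insert_leaf(tree, u, v, leaf):
    import copy

    t = copy.deepcopy(tree)
    w = ("i", t["next_internal"])
    t["next_internal"] += 1
    t["adj"][u].discard(v)
    t["adj"][v].discard(u)
    t["adj"][w] = {u, v, leaf}
    t["adj"][u].add(w)
    t["adj"][v].add(w)
    t["adj"][leaf] = {w}
    t["edges"] = [e for e in t["edges"] if set(e) != {u, v}]
    t["edges"] += [(u, w), (v, w), (leaf, w)]
    return t


def _path_edges(tree, a, b):
    """Edge list on the unique path between two nodes."""
    parent = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        if x == b:
            break
        for y in tree["adj"][x]:
            if y not in parent:
                parent[y] = x
                stack.append(y)
    path = []
    x = b
    while parent[x] is not None:
        path.append(frozenset((x, parent[x])))
        x = parent[x]
    return path


def best_topology_by_least_squares(labels: list[str], D: np.ndarray):
    """Exhaustive search: the topology whose least-squares fit to D is best.

    For each topology, branch lengths are fit by unconstrained linear
    least squares on the path-incidence system; returns the bipartition
    set of the minimal-residual topology.
    """
    pairs = list(itertools.combinations(range(len(labels)), 2))
    d_vec = np.array([D[i, j] for i, j in pairs])
    best = None
    for tree, splits in enumerate_unrooted_topologies(labels):
        edges = [frozenset(e) for e in tree["edges"]]
        eidx = {e: k for k, e in enumerate(edges)}
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            for e in _path_edges(tree, labels[i], labels[j]):
                A[r, eidx[e]] = 1.0
        x, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        resid = float(np.sum((A @ x - d_vec) ** 2))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, splits)
    return best[1]


def random_additive_tree(labels: list[str], rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (distance matrix over labels, nontrivial bipartition set).
    """
    topos = None
    # build a random topology by random sequential insertion
    import copy

    tree = {
        "adj": {0: set(labels[:3]), **{l: {0} for l in labels[:3]}},
        "edges": [(l, 0) for l in labels[:3]],
        "next_internal": 1,
    }
    for leaf in labels[3:]:
        u, v = tree["edges"][rng.integers(len(tree["edges"]))]
        tree = _insert_leaf(tree, u, v, leaf)
    lengths = {frozenset(e): float(rng.uniform(0.1, 1.0)) for e in tree["edges"]}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in _path_edges(tree, labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    full = frozenset(labels)
    splits = set()
    for u, v in tree["edges"]:
        side = frozenset(
            x for x in _bfs_side(tree, u, v) if isinstance(x, str)
        )
        if 1 < len(side) < n - 1:
            splits.add(min((side, full - side), key=lambda f: (len(f), sorted(f))))
    return D, frozenset(splits)


def _bfs_side(tree, start, blocked):
    seen = {blocked, start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in tree["adj"][x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    seen.discard(blocked)
    return seen


def canonical_splits(bipartitions, labels) -> frozenset:
    """Normalize a collection of leaf-set bipartition sides for comparison."""
    full = frozenset(labels)
    out = set()
    for s in bipartitions:
        s = frozenset(s)
        if 1 < len(s) < len(full) - 1:
            out.add(min((s, full - s), key=lambda f: (len(f), sorted(f))))
    return frozenset(out)
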