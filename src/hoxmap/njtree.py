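"""Distance-based neighbor joining as the phylogenetic contrast.

The pipeline's point of comparison: classic NJ on uncorrected p-distances
over the extracted 60-column domain windows.  Uncorrected distances
saturate for fast-evolving groups, which is exactly the mechanism behind
long-branch attraction -- so a corrected-distance option exists but is
off by default.  Tie-breaking in the Q-minimization is deterministic
(lexicographically smallest label pair) and negative branch lengths are
clamped to zero by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotatedSequence
from .profile import ProfileModel, scan_sequence


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("p-distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def domain_distance(
    seqs: Sequence[AnnotatedSequence],
    profile: ProfileModel,
    corrected: bool = False,
) -> DistanceMatrix:
    """p-distance matrix over the best profile-hit window of each sequence.

    The fixed-length window extraction is an implicit alignment (no gaps,
    all windows are ``profile.length`` columns), matching how the only
    unambiguously alignable region of the family is used in practice.
    p-distances need not satisfy the triangle inequality; that is a
    property of the statistic, not an error.  ``corrected=True`` applies
    a Jukes-Cantor-style correction with 20 states (capped at the
    saturation bound).
    """
    windows = []
    for s in seqs:
        hits = scan_sequence(profile, s)
        if not hits:
            raise ValueError(f"sequence {s.seq_id!r} has no domain hit")
        best = max(hits, key=lambda h: h.score)
        windows.append(s.residues[best.start:best.end])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(windows[i], windows[j])
            if corrected:
                cap = 19.0 / 20.0
                p = min(p, cap - 1e-6)
                p = -cap * math.log(1.0 - p / cap)
            d[i, j] = d[j, i] = p
    return DistanceMatrix([s.seq_id for s in seqs], d)


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def rec(n: TreeNode) -> str:
            if not n.children:
                return f"{n.label}:{n.length:.6g}"
            return "(" + ",".join(rec(c) for c in n.children) + f"):{n.length:.6g}"
        inner = ",".join(rec(c) for c in self.children)
        return f"({inner});"


@dataclass
class InferredTree:
    """Unrooted NJ tree, represented with a trifurcating root node."""

    root: TreeNode
    labels: list[str]

    @property
    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> list[frozenset]:
        """Leaf set under every internal edge (one side per edge)."""
        out = []

        def rec(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.label])
            below = frozenset().union(*(rec(c) for c in node.children))
            if node is not self.root:
                out.append(below)
            return below

        rec(self.root)
        return out


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> InferredTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    At each step the pair (i, j) minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` is joined; ties break on the
    lexicographically smallest (label_i, label_j) pair, so the result is
    deterministic.  Negative branch lengths are clamped to zero unless
    ``clamp_negative`` is off.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in D.labels]
    names: list[str] = list(D.labels)

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            {tuple(sorted((int(i), int(j)))) for i, j in cand},
            key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))),
        )
        i, j = pairs[0]
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final 3-node star: closed-form branch lengths
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return InferredTree(root=root, labels=list(D.labels))


@dataclass
class AttractionDetail:
    attracted: bool
    clade: frozenset
    extras: frozenset


def attraction_check(
    tree: InferredTree, group_a: Iterable[str], group_b: Iterable[str]
) -> AttractionDetail:
    """Are two leaf groups pulled into an exclusive neighborhood?

    True iff the smallest bipartition side containing all of
    ``group_a + group_b`` contains no other leaf.  This is the formal
    version of "the least similar sequences artificially group together".
    """
    ga, gb = frozenset(group_a), frozenset(group_b)
    if ga & gb:
        raise ValueError("groups must be disjoint")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 leaves")
    all_leaves = frozenset(tree.labels)
    unknown = (ga | gb) - all_leaves
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    target = ga | gb
    sides = []
    for bp in tree.bipartitions():
        for side in (bp, all_leaves - bp):
            if target <= side:
                sides.append(side)
    sides.append(all_leaves)  # trivial side always contains the target
    best = min(sides, key=len)
    extras = best - target
    return AttractionDetail(attracted=not extras, clade=best, extras=extras)
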