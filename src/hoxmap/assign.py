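"""Quantified ParaHox -> Hox group assignment from graph connectivity.

The published judgement was visual: how many connections a ParaHox
cluster makes to each Hox paralog-group cluster and how dark (significant)
those lines are.  This module formalizes both cues into per-group-pair
statistics at each analysis cutoff:

    connection_density    = edge_count / possible_pairs
    mean_weight           = mean -log10(E) weight over existing edges
    density_weighted_score = sum of weights / possible_pairs

and ranks Hox bins per ParaHox group by the density-weighted score, with
a relative tie margin so that a "roughly equal in number and quality"
situation is reported as a tie rather than an arbitrary winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import Category, GroupLabel, assignment_bin
from .simmap import LayoutState, SimilarityGraph, apply_cutoff, center_distance

HOX_BINS = ["PG1", "PG2", "PG3", "central", "posterior", "anterior"]
PARAHOX_BINS = ["Gsx", "Pdx", "Cdx"]


@dataclass(frozen=True)
class PairStats:
    edge_count: int
    possible_pairs: int
    mean_weight: float | None  # None when no edges exist
    weight_sum: float

    @property
    def connection_density(self) -> float:
        return self.edge_count / self.possible_pairs

    @property
    def density_weighted_score(self) -> float:
        return self.weight_sum / self.possible_pairs


@dataclass
class GroupConnectivity:
    """Pairwise group statistics at one cutoff; symmetric in group order."""

    cutoff: float
    members: dict[str, list[str]]  # bin -> node ids
    stats: dict[frozenset, PairStats]

    def get(self, group_a: str, group_b: str) -> PairStats | None:
        return self.stats.get(frozenset((group_a, group_b)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, st in sorted(self.stats.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            rows.append({
                "group_a": a, "group_b": b, "cutoff": self.cutoff,
                "edge_count": st.edge_count, "possible_pairs": st.possible_pairs,
                "density": st.connection_density,
                "mean_weight": st.mean_weight,
                "score": st.density_weighted_score,
            })
        return pd.DataFrame(rows)


def connectivity(
    graph: SimilarityGraph,
    labels: Mapping[str, GroupLabel],
    cutoff: float,
) -> GroupConnectivity:
    """Group-to-group connectivity statistics at the given cutoff.

    Nodes without a label or binned to OTHER are excluded from pair
    counts.  A group with no members is simply absent from the result.
    """
    g = apply_cutoff(graph, cutoff)
    members: dict[str, list[str]] = {}
    bin_of: dict[str, str] = {}
    for sid in g.node_ids:
        label = labels.get(sid)
        if label is None:
            continue
        b = assignment_bin(label)
        if b is None:
            continue
        bin_of[sid] = b
        members.setdefault(b, []).append(sid)

    counts: dict[frozenset, int] = {}
    wsums: dict[frozenset, float] = {}
    for e in g.edges:
        ba, bb = bin_of.get(e.id_a), bin_of.get(e.id_b)
        if ba is None or bb is None or ba == bb:
            continue
        key = frozenset((ba, bb))
        counts[key] = counts.get(key, 0) + 1
        wsums[key] = wsums.get(key, 0.0) + e.weight

    stats: dict[frozenset, PairStats] = {}
    bins = sorted(members)
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            key = frozenset((a, b))
            possible = len(members[a]) * len(members[b])
            n = counts.get(key, 0)
            ws = wsums.get(key, 0.0)
            stats[key] = PairStats(
                edge_count=n,
                possible_pairs=possible,
                mean_weight=(ws / n) if n else None,
                weight_sum=ws,
            )
    return GroupConnectivity(cutoff=cutoff, members=members, stats=stats)


@dataclass
class RankedAssignment:
    """Hox bins ranked for one ParaHox group, with tie sets.

    ``tie_sets`` is an ordered partition of the ranked bins; the first
    set is the top assignment (more than one member = unresolved tie).
    """

    parahox: str
    cutoff: float
    scores: list[tuple[str, float]]  # (hox_bin, score) descending
    tie_sets: list[list[str]]
    tie_margin: float

    @property
    def top(self) -> list[str]:
        return self.tie_sets[0] if self.tie_sets else []

    @property
    def tied(self) -> bool:
        return len(self.top) > 1


def rank_hox(
    conn: GroupConnectivity,
    parahox: str,
    tie_margin: float = 0.25,
) -> RankedAssignment:
    """Rank Hox bins by density-weighted score for one ParaHox group.

    Adjacent bins whose scores sit within ``tie_margin`` (relative to the
    running maximum of the current tie set) are merged into one tie set.
    Deterministic: ties in score order break on bin name.
    """
    if parahox not in conn.members:
        raise ValueError(f"ParaHox group {parahox!r} has no members in the graph")
    hox_bins = [b for b in conn.members if b not in PARAHOX_BINS]
    scores = []
    for hb in hox_bins:
        st = conn.get(parahox, hb)
        scores.append((hb, st.density_weighted_score if st else 0.0))
    scores.sort(key=lambda t: (-t[1], t[0]))

    tie_sets: list[list[str]] = []
    set_max = None
    for hb, sc in scores:
        if set_max is not None and (
            (set_max == 0 and sc == 0)
            or (set_max > 0 and (set_max - sc) / set_max < tie_margin)
        ):
            tie_sets[-1].append(hb)
        else:
            tie_sets.append([hb])
            set_max = sc
    return RankedAssignment(parahox, conn.cutoff, scores, tie_sets, tie_margin)


@dataclass
class AssignmentReport:
    """Per-ParaHox rankings at every analysis cutoff plus divergence ranks."""

    cutoffs: list[float]
    rankings: dict[str, dict[float, RankedAssignment]]  # parahox -> cutoff -> ranking
    connectivity: dict[float, GroupConnectivity]
    divergence_ranks: list[tuple[str, float]]
    provenance: dict = field(default_factory=dict)

    def final_assignment(self, parahox: str) -> RankedAssignment:
        """Ranking at the most stringent cutoff where the group still connects.

        Mirrors the published procedure of tightening the cutoff for
        resolution until most connections are lost.
        """
        per = self.rankings[parahox]
        for c in sorted(self.cutoffs):  # most stringent first
            r = per[c]
            if any(sc > 0 for _, sc in r.scores):
                return r
        return per[max(self.cutoffs)]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [c.to_frame() for c in self.connectivity.values()], ignore_index=True
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_markdown(self) -> str:
        lines = ["# ParaHox -> Hox assignment report", ""]
        lines.append(
            "Scores are density-weighted connectivity (sum of -log10 E-value "
            "edge weights per possible sequence pair). Tie sets use a relative "
            f"margin of {self.provenance.get('tie_margin', 0.10):g}; the tie "
            "criterion is this package's formalization of 'roughly equal in "
            "number and quality', not a published threshold."
        )
        lines.append("")
        for ph in sorted(self.rankings):
            lines.append(f"## {ph}")
            final = self.final_assignment(ph)
            tie = " (tie)" if final.tied else ""
            lines.append(
                f"Final assignment at cutoff {final.cutoff:g}: "
                f"**{' + '.join(final.top)}**{tie}"
            )
            for c in sorted(self.cutoffs, reverse=True):
                r = self.rankings[ph][c]
                ranked = ", ".join(f"{hb}={sc:.2f}" for hb, sc in r.scores)
                lines.append(f"- cutoff {c:g}: {ranked}")
            lines.append("")
        if self.divergence_ranks:
            lines.append("## Distance from map center (most divergent first)")
            for g, d in self.divergence_ranks:
                lines.append(f"- {g}: {d:.3f}")
            lines.append("")
        if self.provenance:
            lines.append("## Provenance")
            for k, v in sorted(self.provenance.items()):
                lines.append(f"- {k}: {v}")
        return "\n".join(lines) + "\n"


def assignment_report(
    graph: SimilarityGraph,
    labels: Mapping[str, GroupLabel],
    cutoffs: Sequence[float],
    layout_state: LayoutState | None = None,
    tie_margin: float = 0.25,
    provenance: dict | None = None,
) -> AssignmentReport:
    """Full assignment analysis across the given E-value cutoffs."""
    if not cutoffs:
        raise ValueError("need at least one analysis cutoff")
    conns = {c: connectivity(graph, labels, c) for c in cutoffs}
    parahox_present = [
        p for p in PARAHOX_BINS if any(p in conns[c].members for c in cutoffs)
    ]
    rankings: dict[str, dict[float, RankedAssignment]] = {}
    for ph in parahox_present:
        rankings[ph] = {
            c: rank_hox(conns[c], ph, tie_margin) for c in cutoffs
        }
    div: list[tuple[str, float]] = []
    if layout_state is not None:
        import warnings
        if not layout_state.converged:
            warnings.warn("layout did not converge; center distances reported anyway")
        bins = {
            sid: b
            for sid, label in labels.items()
            if (b := assignment_bin(label)) is not None
        }
        div = center_distance(layout_state, bins)
    prov = dict(provenance or {})
    prov.setdefault("tie_margin", tie_margin)
    prov.setdefault("cutoffs", list(cutoffs))
    return AssignmentReport(
        cutoffs=list(cutoffs),
        rankings=rankings,
        connectivity=conns,
        divergence_ranks=div,
        provenance=prov,
    )
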