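"""Thresholded similarity graph and force-directed 2D/3D map.

The graph holds one node per sequence and one edge per reciprocal-hit
pair at a materialization cutoff; tightening the cutoff only removes
edges (never requires re-alignment as long as the new cutoff is at or
below the build cutoff).  The layout relaxes node coordinates under
linear attraction along edges (proportional to the normalized -log10 E
weight) and inverse-square all-pairs repulsion, with a multiplicative
cooling schedule.  Only the relative geometry matters downstream
(cluster adjacency, distance-from-center ranks), so the force constants
are package defaults, exposed in :class:`LayoutParams` and logged in the
map file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .annotations import AnnotatedSequence, Category, GroupLabel, canonical_group
from .align import SimilarityEdge


class MapParseError(ValueError):
    pass


@dataclass
class SimilarityGraph:
    """Nodes (sequences) + symmetric E-value edges at a given cutoff."""

    sequences: list[AnnotatedSequence]
    edges: list[SimilarityEdge]
    cutoff: float

    def __post_init__(self) -> None:
        ids = [s.seq_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate seq_ids in graph")
        idset = set(ids)
        seen = set()
        for e in self.edges:
            if e.id_a == e.id_b:
                raise ValueError(f"self-edge on {e.id_a}")
            if e.id_a not in idset or e.id_b not in idset:
                raise ValueError(f"edge endpoint not a node: {e.id_a}-{e.id_b}")
            key = (e.id_a, e.id_b)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def node_ids(self) -> list[str]:
        return [s.seq_id for s in self.sequences]

    def sequence(self, seq_id: str) -> AnnotatedSequence:
        return next(s for s in self.sequences if s.seq_id == seq_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_weighted_edges_from((e.id_a, e.id_b, e.weight) for e in self.edges)
        return g


def apply_cutoff(graph: SimilarityGraph, new_cutoff: float) -> SimilarityGraph:
    """Re-threshold the edge set at a more stringent cutoff.

    Directions with E > new_cutoff are dropped and weights recomputed over
    the survivors; edges losing both directions disappear.  Nodes are
    unchanged (isolated nodes remain part of the map).
    """
    if new_cutoff > graph.cutoff:
        raise ValueError(
            f"new cutoff {new_cutoff:g} is laxer than the build cutoff "
            f"{graph.cutoff:g}; re-run the all-against-all stage instead"
        )
    edges = []
    for e in graph.edges:
        eab = e.evalue_ab if (e.evalue_ab is not None and e.evalue_ab <= new_cutoff) else None
        eba = e.evalue_ba if (e.evalue_ba is not None and e.evalue_ba <= new_cutoff) else None
        if eab is None and eba is None:
            continue
        edges.append(SimilarityEdge.make(e.id_a, e.id_b, eab, eba))
    return SimilarityGraph(graph.sequences, edges, new_cutoff)


def connected_components(graph: SimilarityGraph) -> list[set[str]]:
    """Undirected components, largest first (ties: smallest member id)."""
    comps = list(nx.connected_components(graph.to_networkx()))
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def select_seed_clusters(components: Sequence[set[str]], seed_ids: set[str]) -> set[str]:
    """Union of every component containing at least one seed sequence."""
    if not seed_ids:
        raise ValueError("seed set is empty")
    out: set[str] = set()
    for comp in components:
        if comp & seed_ids:
            out |= comp
    return out


@dataclass
class LayoutParams:
    attraction_scale: float = 1.0
    repulsion_scale: float = 0.01
    step_size: float = 0.05
    cooling: float = 0.995
    max_iter: int = 1500
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        vals = (self.attraction_scale, self.repulsion_scale, self.step_size,
                self.cooling, self.max_iter, self.convergence_tol)
        if any(v <= 0 for v in vals):
            raise ValueError("all layout parameters must be positive")
        if not self.cooling < 1:
            raise ValueError("cooling must be < 1")


@dataclass
class LayoutState:
    dims: int
    coords: np.ndarray  # (n_nodes, dims)
    rng_seed: int
    iterations_run: int
    converged: bool
    node_ids: list[str]

    def index_of(self, seq_id: str) -> int:
        return self.node_ids.index(seq_id)


_EPS = 1e-9  # coincident-point threshold; jitter drawn from the layout RNG


def layout(
    graph: SimilarityGraph,
    params: LayoutParams | None = None,
    dims: int = 2,
    seed: int = 0,
) -> LayoutState:
    """Force-directed relaxation of the similarity graph.

    Initial coordinates are uniform in the unit cube.  Per iteration the
    net force on each node is

        sum over edges:      attraction_scale * (w / max_w) * (x_j - x_i)
        sum over node pairs: repulsion_scale * (x_i - x_j) / d^3

    and positions move by step * force, with the step multiplied by
    ``cooling`` each iteration.  Stops when the mean displacement drops
    below ``convergence_tol`` or at ``max_iter``.  Deterministic given
    the seed (coincident points are jittered from the same RNG stream).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if not graph.sequences:
        raise ValueError("layout needs at least one node")
    params = params or LayoutParams()
    rng = np.random.default_rng(seed)
    ids = graph.node_ids
    n = len(ids)
    pos = rng.uniform(0.0, 1.0, size=(n, dims))

    idx = {sid: i for i, sid in enumerate(ids)}
    if graph.edges:
        ea = np.array([idx[e.id_a] for e in graph.edges])
        eb = np.array([idx[e.id_b] for e in graph.edges])
        w = np.array([e.weight for e in graph.edges], dtype=float)
        max_w = w.max()
        w_norm = w / max_w if max_w > 0 else np.zeros_like(w)
    else:
        ea = eb = w_norm = None

    step = params.step_size
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        coincident = (dist < _EPS) & ~np.eye(n, dtype=bool)
        if coincident.any():
            jitter_nodes = np.unique(np.nonzero(coincident)[0])
            pos[jitter_nodes] += rng.normal(scale=1e-6, size=(len(jitter_nodes), dims))
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        force = params.repulsion_scale * (diff / dist[..., None] ** 3).sum(axis=1)
        if ea is not None:
            pull = params.attraction_scale * w_norm[:, None] * (pos[eb] - pos[ea])
            np.add.at(force, ea, pull)
            np.add.at(force, eb, -pull)
        delta = step * force
        pos += delta
        step *= params.cooling
        mean_disp = float(np.linalg.norm(delta, axis=1).mean())
        if mean_disp < params.convergence_tol:
            converged = True
            break
    return LayoutState(dims, pos, seed, it, converged, list(ids))


def center_distance(
    state: LayoutState, groups: Mapping[str, GroupLabel] | Mapping[str, str]
) -> list[tuple[str, float]]:
    """Per-group mean Euclidean distance from the global centroid.

    Groups are ranked descending (most divergent first).  Groups with no
    members among the laid-out nodes are omitted with a warning.
    """
    centroid = state.coords.mean(axis=0)
    d = np.linalg.norm(state.coords - centroid, axis=1)
    by_group: dict[str, list[float]] = {}
    for i, sid in enumerate(state.node_ids):
        g = groups.get(sid)
        if g is None:
            continue
        name = g.name if isinstance(g, GroupLabel) else str(g)
        by_group.setdefault(name, []).append(float(d[i]))
    requested = {g.name if isinstance(g, GroupLabel) else str(g) for g in groups.values()}
    for name in requested - by_group.keys():
        warnings.warn(f"group {name!r} has no members in the layout; omitted")
    ranked = sorted(((g, float(np.mean(v))) for g, v in by_group.items()),
                    key=lambda t: (-t[1], t[0]))
    return ranked


# ---------------------------------------------------------------------------
# Map file (plain-text, human-diffable, CLANS-like in spirit)


def write_map(graph: SimilarityGraph, state: LayoutState | None, path: str | Path) -> None:
    """Serialize graph (+ optional layout) to the plain-text map dialect.

    Sections: ``[params]``, ``[sequences]`` (FASTA-like), ``[groups]``,
    ``[coordinates]`` and ``[edges]`` (node_index_a node_index_b
    evalue_ab;evalue_ba with ``-`` for an absent direction).  Floats are
    printed with repr so the round trip is bit-exact.
    """
    if state is not None and state.node_ids != graph.node_ids:
        raise ValueError("layout nodes do not match graph nodes")
    idx = {sid: i for i, sid in enumerate(graph.node_ids)}
    with open(path, "w") as fh:
        fh.write("# hoxmap similarity map\n")
        fh.write("[params]\n")
        fh.write(f"cutoff={repr(graph.cutoff)}\n")
        if state is not None:
            fh.write(f"dims={state.dims}\n")
            fh.write(f"rng_seed={state.rng_seed}\n")
            fh.write(f"iterations_run={state.iterations_run}\n")
            fh.write(f"converged={state.converged}\n")
        fh.write("[sequences]\n")
        for s in graph.sequences:
            fh.write(f">{s.seq_id}|{s.common_name}|{s.species}\n{s.residues}\n")
        fh.write("[groups]\n")
        for s in graph.sequences:
            fh.write(f"{s.seq_id}\t{s.group.category.value}\t{s.group.name}\n")
        if state is not None:
            fh.write("[coordinates]\n")
            for sid, row in zip(graph.node_ids, state.coords):
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{sid}\t{vals}\n")
        fh.write("[edges]\n")
        for e in graph.edges:
            eab = "-" if e.evalue_ab is None else repr(e.evalue_ab)
            eba = "-" if e.evalue_ba is None else repr(e.evalue_ba)
            fh.write(f"{idx[e.id_a]}\t{idx[e.id_b]}\t{eab};{eba}\n")


def read_map(path: str | Path) -> tuple[SimilarityGraph, LayoutState | None]:
    """Parse a map file; raises :class:`MapParseError` with line numbers."""
    params: dict[str, str] = {}
    seqs: list[AnnotatedSequence] = []
    group_rows: dict[str, tuple[str, str]] = {}
    coords: list[tuple[str, list[float]]] = []
    edge_rows: list[tuple[int, int, float | None, float | None]] = []
    section = None
    pending_header: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                tag = line[1:-1]
                if tag not in ("params", "sequences", "groups", "coordinates", "edges"):
                    raise MapParseError(f"{path}:{lineno}: unknown section tag [{tag}]")
                section = tag
                continue
            try:
                if section == "params":
                    k, v = line.split("=", 1)
                    params[k] = v
                elif section == "sequences":
                    if line.startswith(">"):
                        pending_header = line[1:]
                    else:
                        if pending_header is None:
                            raise MapParseError(f"{path}:{lineno}: sequence data before header")
                        sid, common, species = (pending_header.split("|") + ["", ""])[:3]
                        seqs.append(AnnotatedSequence(sid, line, common, species,
                                                      canonical_group(common)))
                        pending_header = None
                elif section == "groups":
                    sid, cat, name = line.split("\t")
                    group_rows[sid] = (cat, name)
                elif section == "coordinates":
                    parts = line.split("\t")
                    coords.append((parts[0], [float(v) for v in parts[1:]]))
                elif section == "edges":
                    ia, ib, ev = line.split("\t")
                    eab_s, eba_s = ev.split(";")
                    edge_rows.append((
                        int(ia), int(ib),
                        None if eab_s == "-" else float(eab_s),
                        None if eba_s == "-" else float(eba_s),
                    ))
                else:
                    raise MapParseError(f"{path}:{lineno}: data outside any section")
            except MapParseError:
                raise
            except ValueError as exc:
                raise MapParseError(f"{path}:{lineno}: {exc}") from exc
    for s in seqs:
        if s.seq_id in group_rows:
            cat, name = group_rows[s.seq_id]
            s.group = GroupLabel(Category(cat), name)
    ids = [s.seq_id for s in seqs]
    edges = [
        SimilarityEdge.make(ids[ia], ids[ib], eab, eba)
        for ia, ib, eab, eba in edge_rows
    ]
    graph = SimilarityGraph(seqs, edges, float(params["cutoff"]))
    state = None
    if coords:
        arr = np.array([c for _, c in coords])
        state = LayoutState(
            dims=int(params.get("dims", arr.shape[1])),
            coords=arr,
            rng_seed=int(params.get("rng_seed", 0)),
            iterations_run=int(params.get("iterations_run", 0)),
            converged=params.get("converged", "False") == "True",
            node_ids=[sid for sid, _ in coords],
        )
    return graph, state


#: Color roles matching the published palette: anterior groups yellow/orange,
#: Hox3 red, central blue, posterior green, ParaHox grey.
GROUP_COLORS = {
    "PG1": "#f2c200", "PG2": "#f28c00", "PG3": "#d62728", "anterior": "#f2c200",
    "central": "#1f77b4", "posterior": "#2ca02c",
    "Gsx": "#666666", "Pdx": "#888888", "Cdx": "#444444",
    "other": "#cccccc",
}


def save_scatter(graph: SimilarityGraph, state: LayoutState, path: str | Path) -> None:
    """2D scatter export (SVG/PNG by extension) with per-group colors."""
    import matplotlib
    matplotlib.use("Agg")
    # fixed hash salt + no date metadata keep the export reproducible
    matplotlib.rcParams["svg.hashsalt"] = "hoxmap"
    import matplotlib.pyplot as plt
    from .annotations import assignment_bin

    fig, ax = plt.subplots(figsize=(6, 6))
    xy = state.coords[:, :2]
    for e in graph.edges:
        i, j = state.index_of(e.id_a), state.index_of(e.id_b)
        ax.plot(xy[[i, j], 0], xy[[i, j], 1], color="0.5",
                alpha=min(1.0, e.weight / 100.0 + 0.1), lw=0.5, zorder=1)
    for i, s in enumerate(graph.sequences):
        b = assignment_bin(s.group) or "other"
        color = GROUP_COLORS.get(b, GROUP_COLORS.get(s.group.name, "#cccccc"))
        marker = "s" if s.group.category is Category.PARAHOX else "o"
        ax.scatter(*xy[i], c=color, marker=marker, s=25, zorder=2)
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", metadata={"Date": None})
    plt.close(fig)
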