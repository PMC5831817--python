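"""Synthetic paralog families with a conserved domain and rate heterogeneity.

Each simulated protein is a conserved ~60-residue domain embedded between
variable flanks.  Groups of species-level sequences diverge along a rooted
guide topology (branch lengths in expected substitutions per flank site);
domain sites evolve at a reduced rate and never receive indels, so the
domain stays detectable and extractable -- the structure of a real
homeobox family.  Per-group rate multipliers allow two groups (a Cdx-like
and a posterior-Hox-like group) to evolve independently faster than the
rest, which is the regime that produces long-branch attraction in
distance trees while the similarity graph simply disconnects them.

The substitution process is a simple proportional-exchange model: a site
hit by substitution (probability 1 - exp(-t * rate)) redraws its residue
from the stationary background composition.  The published argument needs
rate heterogeneity between groups, not a realistic replacement process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .annotations import AnnotatedSequence, Category, GroupLabel
from .profile import ALPHABET

#: Stationary amino-acid frequencies (BLOSUM62 background), ALPHABET order.
BACKGROUND = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(ALPHABET), size=length, p=BACKGROUND)
    return "".join(ALPHABET[i] for i in idx)


def evolve_sequence(
    parent: str,
    branch_length: float,
    rate_profile: float | np.ndarray,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_mask: np.ndarray | None = None,
) -> tuple[str, int]:
    """Evolve a sequence along one branch; returns (child, changed_sites).

    Per site, a substitution event occurs with probability
    ``1 - exp(-branch_length * site_rate)``; the replacement is drawn from
    the stationary composition (and may silently equal the parent residue,
    so the expected fraction of *changed* sites carries the usual
    "resampling" correction).  Indels (geometric lengths, insertions drawn
    from the background) are applied only at positions allowed by
    ``indel_mask``; changed_sites counts substitutions only.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    n = len(parent)
    rates = np.broadcast_to(np.asarray(rate_profile, dtype=float), (n,))
    p_sub = 1.0 - np.exp(-branch_length * rates)
    hit = rng.random(n) < p_sub
    chars = list(parent)
    n_changed = 0
    if hit.any():
        draws = rng.choice(len(ALPHABET), size=int(hit.sum()), p=BACKGROUND)
        for pos, d in zip(np.flatnonzero(hit), draws):
            new = ALPHABET[d]
            if new != chars[pos]:
                n_changed += 1
            chars[pos] = new
    if indel_rate > 0:
        allowed = (
            np.ones(n, dtype=bool) if indel_mask is None else np.asarray(indel_mask, bool)
        )
        n_allowed = int(allowed.sum())
        n_events = rng.poisson(indel_rate * branch_length * n_allowed)
        for _ in range(n_events):
            positions = np.flatnonzero(allowed)
            if positions.size == 0:
                break
            pos = int(rng.choice(positions))
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5 and positions.size > length:  # deletion
                del_span = [p for p in range(pos, min(pos + length, n)) if allowed[p]]
                for p in sorted(del_span, reverse=True):
                    del chars[p]
                allowed = np.delete(allowed, del_span)
            else:  # insertion
                ins = random_protein(length, rng)
                chars[pos:pos] = list(ins)
                allowed = np.insert(allowed, pos, np.ones(length, dtype=bool))
            n = len(chars)
    return "".join(chars), n_changed


@dataclass(frozen=True)
class GroupSpec:
    name: str
    label: GroupLabel
    n_species: int = 6
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not np.isfinite(self.rate_multiplier) or self.rate_multiplier < 0:
            raise ValueError("rate_multiplier must be finite and >= 0")


@dataclass
class TreeNode:
    """Guide-topology node; leaves carry group names."""

    length: float = 0.0
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:g}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}):{node.length:g}"
        return rec(self) + ";"


@dataclass
class FamilyDesign:
    """Full specification of a simulated paralog family."""

    groups: list[GroupSpec]
    guide_topology: TreeNode
    domain_length: int = 60
    flank_length_range: tuple[int, int] = (80, 110)
    indel_rate: float = 0.03
    domain_rate: float = 0.2  # rate multiplier of domain sites vs flank sites
    species_branch: float = 0.05  # tip branch per species inside a group
    rng_seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        leaves = self.guide_topology.leaves()
        if sorted(leaves) != sorted(names):
            raise ValueError(
                f"guide topology leaves {sorted(leaves)} do not match "
                f"groups {sorted(names)}"
            )


@dataclass
class SimulatedDataset:
    sequences: list[AnnotatedSequence]
    truth: FamilyDesign
    #: per-sequence realized substitution count along its whole lineage
    lineage: dict[str, int]
    #: per-sequence 0-based half-open span of the true domain
    domain_spans: dict[str, tuple[int, int]]

    def seed_ids(self) -> list[str]:
        """First species of every group -- the curated-seed analogue."""
        return [f"{g.name}_1" for g in self.truth.groups]

    def seed_alignment(self) -> list[str]:
        """True domain segments of the seed sequences (gap-free, aligned)."""
        rows = []
        for sid in self.seed_ids():
            s, e = self.domain_spans[sid]
            seq = next(x for x in self.sequences if x.seq_id == sid)
            rows.append(seq.residues[s:e])
        return rows

    def labels(self) -> dict[str, GroupLabel]:
        return {s.seq_id: s.group for s in self.sequences}


@dataclass
class _Lineage:
    left: str
    domain: str
    right: str
    subs: int

    @property
    def residues(self) -> str:
        return self.left + self.domain + self.right


def _evolve_lineage(
    parent: _Lineage,
    branch_length: float,
    rate_scale: float,
    design: FamilyDesign,
    rng: np.random.Generator,
) -> _Lineage:
    """One branch of segment-wise evolution (indels confined to flanks)."""
    bl = branch_length * rate_scale
    left, n1 = evolve_sequence(parent.left, bl, 1.0, rng, design.indel_rate)
    domain, n2 = evolve_sequence(parent.domain, bl, design.domain_rate, rng)
    right, n3 = evolve_sequence(parent.right, bl, 1.0, rng, design.indel_rate)
    return _Lineage(left, domain, right, parent.subs + n1 + n2 + n3)


def simulate_family(design: FamilyDesign) -> SimulatedDataset:
    """Evolve one family down the guide topology; reproducible from the seed."""
    rng = np.random.default_rng(design.rng_seed)
    lo, hi = design.flank_length_range
    root = _Lineage(
        left=random_protein(int(rng.integers(lo, hi + 1)), rng),
        domain=random_protein(design.domain_length, rng),
        right=random_protein(int(rng.integers(lo, hi + 1)), rng),
        subs=0,
    )
    spec_of = {g.name: g for g in design.groups}
    sequences: list[AnnotatedSequence] = []
    lineage: dict[str, int] = {}
    spans: dict[str, tuple[int, int]] = {}

    def descend(node: TreeNode, state: _Lineage, scale: float) -> None:
        if node.is_leaf:
            g = spec_of[node.name]
            anc = _evolve_lineage(state, node.length, g.rate_multiplier, design, rng)
            for i in range(1, g.n_species + 1):
                tip = _evolve_lineage(
                    anc, design.species_branch, g.rate_multiplier, design, rng
                )
                sid = f"{g.name}_{i}"
                sequences.append(
                    AnnotatedSequence(
                        seq_id=sid,
                        residues=tip.residues,
                        common_name=g.name,
                        species=f"sp{i}",
                        group=g.label,
                    )
                )
                lineage[sid] = tip.subs
                spans[sid] = (len(tip.left), len(tip.left) + len(tip.domain))
        else:
            child_state = _evolve_lineage(state, node.length, scale, design, rng)
            for c in node.children:
                descend(c, child_state, scale)

    for child in design.guide_topology.children:
        descend(child, root, 1.0)
    if design.guide_topology.is_leaf:  # degenerate single-group design
        descend(design.guide_topology, root, 1.0)
    return SimulatedDataset(sequences, design, lineage, spans)


# ---------------------------------------------------------------------------
# Named Hox/ParaHox scenarios

_HOX = Category.HOX
_PARAHOX = Category.PARAHOX


def _groups(severity: float) -> list[GroupSpec]:
    return [
        GroupSpec("PG1", GroupLabel(_HOX, "PG1")),
        GroupSpec("PG2", GroupLabel(_HOX, "PG2")),
        GroupSpec("PG3", GroupLabel(_HOX, "PG3")),
        GroupSpec("central", GroupLabel(_HOX, "central")),
        GroupSpec("posterior", GroupLabel(_HOX, "posterior"), rate_multiplier=severity),
        GroupSpec("Gsx", GroupLabel(_PARAHOX, "Gsx")),
        GroupSpec("Pdx", GroupLabel(_PARAHOX, "Pdx")),
        GroupSpec("Cdx", GroupLabel(_PARAHOX, "Cdx"), rate_multiplier=severity),
    ]


def _leaf(name: str, length: float) -> TreeNode:
    return TreeNode(length=length, name=name)


def _paper_supported_topology() -> TreeNode:
    """Gsx sister to the PG2+(PG3,Pdx) clade, Cdx sister to central.

    Gsx sits at equal path distance from PG2 and PG3 (the two-way tie),
    Pdx pairs with PG3, and Cdx pairs with the central group while the
    posterior group branches separately.
    """
    return TreeNode(children=[
        TreeNode(length=0.25, children=[
            _leaf("PG1", 1.0),
            TreeNode(length=0.15, children=[
                _leaf("Gsx", 0.1),
                TreeNode(length=0.05, children=[
                    _leaf("PG2", 0.5),
                    TreeNode(length=0.35, children=[
                        _leaf("PG3", 0.15),
                        _leaf("Pdx", 0.15),
                    ]),
                ]),
            ]),
        ]),
        TreeNode(length=0.25, children=[
            TreeNode(length=0.25, children=[
                _leaf("central", 0.3),
                _leaf("Cdx", 0.4),
            ]),
            _leaf("posterior", 0.7),
        ]),
    ])


def _traditional_topology() -> TreeNode:
    """The traditional hypothesis: Gsx with PG1/PG2, Cdx with posterior."""
    return TreeNode(children=[
        TreeNode(length=0.3, children=[
            TreeNode(length=0.15, children=[
                _leaf("Gsx", 0.4),
                TreeNode(length=0.15, children=[
                    _leaf("PG1", 0.45),
                    _leaf("PG2", 0.45),
                ]),
            ]),
            TreeNode(length=0.3, children=[
                _leaf("PG3", 0.35),
                _leaf("Pdx", 0.35),
            ]),
        ]),
        TreeNode(length=0.3, children=[
            _leaf("central", 0.5),
            TreeNode(length=0.15, children=[
                _leaf("Cdx", 0.35),
                _leaf("posterior", 0.35),
            ]),
        ]),
    ])


PRESETS = {
    "paper_supported": _paper_supported_topology,
    "lba": _paper_supported_topology,
    "traditional": _traditional_topology,
}


def hox_parahox_scenario(
    preset: str, severity: float = 1.0, rng_seed: int = 0
) -> SimulatedDataset:
    """Simulate a named Hox/ParaHox hypothesis.

    ``paper_supported`` and ``lba`` share the Gsx~(PG2,PG3) / Pdx~PG3 /
    Cdx~central topology; ``severity`` independently scales the
    substitution rates of the Cdx-like and posterior-like groups (1 = no
    rate heterogeneity; large values produce the long-branch regime).
    ``traditional`` encodes the Gsx~PG1/2, Cdx~posterior alternative.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    if severity < 1:
        raise ValueError("severity must be >= 1")
    design = FamilyDesign(
        groups=_groups(severity),
        guide_topology=PRESETS[preset](),
        rng_seed=rng_seed,
    )
    return simulate_family(design)


def write_design(design: FamilyDesign, path: str | Path) -> None:
    """Serialize a design as a key-value config plus newick topology."""
    with open(path, "w") as fh:
        fh.write(f"domain_length={design.domain_length}\n")
        fh.write(f"flank_length_range={design.flank_length_range[0]},{design.flank_length_range[1]}\n")
        fh.write(f"indel_rate={design.indel_rate}\n")
        fh.write(f"domain_rate={design.domain_rate}\n")
        fh.write(f"species_branch={design.species_branch}\n")
        fh.write(f"rng_seed={design.rng_seed}\n")
        for g in design.groups:
            fh.write(
                f"group={g.name},{g.label.category.value},{g.label.name},"
                f"{g.n_species},{g.rate_multiplier}\n"
            )
        fh.write(f"topology={design.guide_topology.newick()}\n")
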