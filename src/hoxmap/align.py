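"""All-against-all local alignment and Karlin-Altschul E-values.

Exact Smith-Waterman (affine gaps, Gotoh) replaces heuristic database
search: at the scale this package targets (a few hundred proteins of a few
hundred residues) the full dynamic program is affordable and removes any
seeding nondeterminism.  Raw scores are converted to E-values with fixed
Karlin-Altschul parameters,

    E = K * m * n * exp(-lambda * S),

so E-values are used strictly comparatively: the ordering and the
-log10(E) edge weights are what the similarity map consumes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .annotations import AnnotatedSequence

#: Residues accepted in scored sequences (X scores 0 against everything).
SW_ALPHABET = "ARNDCQEGHILKMFPSTWYVX"

#: E-values are floored here before -log10 so weights stay finite.
EVALUE_FLOOR = 1e-300


def _default_matrix() -> np.ndarray:
    """BLOSUM62 over SW_ALPHABET with the X row/column zeroed."""
    b62 = substitution_matrices.load("BLOSUM62")
    n = len(SW_ALPHABET)
    m = np.zeros((n, n))
    for i, a in enumerate(SW_ALPHABET[:-1]):
        for j, b in enumerate(SW_ALPHABET[:-1]):
            m[i, j] = b62[a, b]
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (so the default
    11/1 matches the familiar BLOSUM62 gapped scheme).  ``lam``/``K`` are
    the fixed gapped-BLOSUM62 Karlin-Altschul parameters.
    """

    matrix: np.ndarray = field(default_factory=_default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not self.gap_open >= self.gap_extend >= 1:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._aligner = PairwiseAligner(
            mode="local",
            open_gap_score=-(self.gap_open + self.gap_extend),
            extend_gap_score=-self.gap_extend,
        )
        arr = substitution_matrices.Array(alphabet=SW_ALPHABET, dims=2)
        for i, a in enumerate(SW_ALPHABET):
            for j, b in enumerate(SW_ALPHABET):
                arr[a, b] = self.matrix[i, j]
        self._aligner.substitution_matrix = arr

    def provenance(self) -> dict:
        return {
            "matrix": "BLOSUM62 (X scores 0)",
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "lambda": self.lam,
            "K": self.K,
        }


def _validate(residues: str) -> None:
    bad = set(residues) - set(SW_ALPHABET)
    if bad:
        raise ValueError(f"unknown residue code(s) {sorted(bad)}")


def smith_waterman(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Maximal local alignment score under affine gaps; symmetric, >= 0."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    _validate(a)
    _validate(b)
    return int(round(scheme._aligner.score(a, b)))


def evalue(S: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expect value K*m*n*exp(-lambda*S)."""
    if S < 0:
        raise ValueError("raw score must be >= 0")
    return max(scheme.K * m * n * math.exp(-scheme.lam * S), EVALUE_FLOOR)


def neg_log10_evalue(E: float) -> float:
    return -math.log10(max(E, EVALUE_FLOOR))


@dataclass(frozen=True)
class DirectedHit:
    query_id: str
    subject_id: str
    score: int
    evalue: float


def all_against_all(
    seqs: Sequence[AnnotatedSequence],
    scheme: ScoringScheme | None = None,
    report_cutoff: float = 1e-2,
) -> list[DirectedHit]:
    """One DirectedHit per ordered pair with E <= report_cutoff.

    Scores are computed once per unordered pair (Smith-Waterman is
    symmetric) and expanded to both directions.  Self-hits are excluded.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids")
    scheme = scheme or ScoringScheme()
    hits: list[DirectedHit] = []
    for sa, sb in itertools.combinations(seqs, 2):
        S = smith_waterman(sa.residues, sb.residues, scheme)
        E = evalue(S, len(sa.residues), len(sb.residues), scheme)
        if E <= report_cutoff:
            hits.append(DirectedHit(sa.seq_id, sb.seq_id, S, E))
            hits.append(DirectedHit(sb.seq_id, sa.seq_id, S, E))
    return hits


@dataclass(frozen=True)
class SimilarityEdge:
    """Unordered sequence pair with its directional E-values.

    ``weight`` is the mean of -log10(E) over the directions present --
    the symmetric attraction value used by the layout and the
    connectivity statistics.
    """

    id_a: str
    id_b: str
    evalue_ab: float | None
    evalue_ba: float | None
    weight: float

    @staticmethod
    def make(id_a: str, id_b: str, evalue_ab: float | None, evalue_ba: float | None) -> "SimilarityEdge":
        if id_a > id_b:
            id_a, id_b = id_b, id_a
            evalue_ab, evalue_ba = evalue_ba, evalue_ab
        present = [e for e in (evalue_ab, evalue_ba) if e is not None]
        if not present:
            raise ValueError("edge requires at least one direction")
        weight = sum(neg_log10_evalue(e) for e in present) / len(present)
        return SimilarityEdge(id_a, id_b, evalue_ab, evalue_ba, weight)

    @property
    def best_evalue(self) -> float:
        return min(e for e in (self.evalue_ab, self.evalue_ba) if e is not None)


def build_edges(hits: Iterable[DirectedHit], cutoff: float) -> list[SimilarityEdge]:
    """Symmetrize directed hits into edges at an E-value cutoff (inclusive).

    An unordered pair yields an edge when at least one direction has
    E <= cutoff; only directions meeting the cutoff contribute to the
    weight.  Output sorted by (id_a, id_b).
    """
    directions: dict[tuple[str, str], dict[str, float]] = {}
    for h in hits:
        a, b = sorted((h.query_id, h.subject_id))
        d = directions.setdefault((a, b), {})
        key = "ab" if (h.query_id, h.subject_id) == (a, b) else "ba"
        d[key] = h.evalue
    edges = []
    for (a, b), d in sorted(directions.items()):
        eab = d.get("ab")
        eba = d.get("ba")
        if eab is not None and eab > cutoff:
            eab = None
        if eba is not None and eba > cutoff:
            eba = None
        if eab is None and eba is None:
            continue
        edges.append(SimilarityEdge.make(a, b, eab, eba))
    return edges


def write_hits_tsv(hits: Iterable[DirectedHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.score}\t{repr(h.evalue)}\n")


def read_hits_tsv(path: str | Path) -> list[DirectedHit]:
    hits = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            q, s, score, E = line.rstrip("\n").split("\t")
            hits.append(DirectedHit(q, s, int(score), float(E)))
    return hits
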