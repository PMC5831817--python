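"""FASTA / annotation-table I/O and CD-hit-style redundancy clustering.

Headers use the pipe convention ``>seq_id|common_name|species`` with all
fields after the first optional.  Redundancy clustering is greedy
longest-first on global-alignment identity, and the member->representative
map it returns can be reversed later to re-inflate a filtered dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import AnnotatedSequence, canonical_group


class FastaParseError(ValueError):
    pass


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    seq_id = parts[0].strip()
    common = parts[1].strip() if len(parts) > 1 else ""
    species = parts[2].strip() if len(parts) > 2 else ""
    return seq_id, common, species


def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read annotated protein sequences from a FASTA file.

    One record per entry, order preserved.  A record with an empty
    sequence raises :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    out: list[AnnotatedSequence] = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaParseError(
                f"{path}:{_header_line(path, rec.description)}: "
                f"record {rec.description!r} has an empty sequence"
            )
        seq_id, common, species = _parse_header(rec.description)
        out.append(
            AnnotatedSequence(
                seq_id=seq_id,
                residues=str(rec.seq),
                common_name=common,
                species=species,
                group=canonical_group(common),
            )
        )
    return out


def _header_line(path: Path, description: str) -> int:
    """Line number of the header whose description matches (1-based)."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].strip() == description:
                return i
    return 0


def write_fasta(seqs: Iterable[AnnotatedSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences with ``id|common_name|species`` headers."""
    records = []
    for s in seqs:
        header = s.seq_id
        if s.common_name or s.species:
            header += f"|{s.common_name}"
        if s.species:
            header += f"|{s.species}"
        records.append(SeqRecord(Seq(s.residues), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_annotation_table(seqs: Iterable[AnnotatedSequence], path: str | Path) -> None:
    """TSV: seq_id, common_name, species, canonical category, group name."""
    with open(path, "w") as fh:
        fh.write("seq_id\tcommon_name\tspecies\tcategory\tgroup\n")
        for s in seqs:
            fh.write(
                f"{s.seq_id}\t{s.common_name}\t{s.species}\t"
                f"{s.group.category.value}\t{s.group.name}\n"
            )


# ---------------------------------------------------------------------------
# Redundancy clustering


@dataclass
class RedundancyMap:
    """member seq_id -> representative seq_id at a given identity threshold.

    Every representative maps to itself, so composition is idempotent.
    """

    representative_of: dict[str, str] = field(default_factory=dict)
    identity_threshold: float = 0.95

    def representatives(self) -> set[str]:
        return {r for r in self.representative_of.values()}

    def members(self, rep: str) -> list[str]:
        return [m for m, r in self.representative_of.items() if r == rep]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("member\trepresentative\n")
            for m in sorted(self.representative_of):
                fh.write(f"{m}\t{self.representative_of[m]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, identity_threshold: float = 0.95) -> "RedundancyMap":
        rep_of: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("member"):
                raise ValueError(f"{path}: expected 'member\\trepresentative' header")
            for line in fh:
                m, r = line.rstrip("\n").split("\t")
                rep_of[m] = r
        return cls(rep_of, identity_threshold)


_identity_aligner = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment (linear gap cost)."""
    aln = _identity_aligner.align(a, b)[0]
    c = aln.counts()
    length = c.identities + c.mismatches + c.gaps
    return c.identities / length if length else 0.0


def cluster_redundant(
    seqs: Sequence[AnnotatedSequence], identity_threshold: float = 0.95
) -> RedundancyMap:
    """Greedy longest-first redundancy clustering.

    Sequences are visited longest first (ties on length broken by
    lexicographic seq_id); each joins the first accepted representative
    with global identity >= threshold, else becomes a representative
    itself.  Deterministic.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1.0]")
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids in input")
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))
    reps: list[AnnotatedSequence] = []
    rep_of: dict[str, str] = {}
    for s in order:
        assigned = None
        for r in reps:
            # identity is bounded by len(short)/alignment_len <= len(short)/len(long)
            if len(s.residues) / len(r.residues) < identity_threshold:
                continue
            if global_identity(s.residues, r.residues) >= identity_threshold:
                assigned = r.seq_id
                break
        if assigned is None:
            reps.append(s)
            assigned = s.seq_id
        rep_of[s.seq_id] = assigned
    return RedundancyMap(rep_of, identity_threshold)


def reinflate(
    kept: set[str],
    rmap: RedundancyMap,
    all_seqs: Sequence[AnnotatedSequence],
) -> list[AnnotatedSequence]:
    """Reverse the redundancy filtering for the kept representatives.

    Returns every sequence whose representative is in ``kept`` (the
    representatives themselves included), in the order of ``all_seqs``.
    """
    reps = rmap.representatives()
    bad = kept - reps
    if bad:
        raise ValueError(f"not representatives: {sorted(bad)}")
    return [s for s in all_seqs if rmap.representative_of.get(s.seq_id) in kept]
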