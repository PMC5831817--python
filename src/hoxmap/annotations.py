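"""Controlled vocabulary for Hox/ParaHox group labels and annotated sequences.

Hox paralog groups follow the vertebrate nomenclature (PG1..PG13, with
*Mus musculus* as the standard), with the usual collective bins: anterior
(PG1-2), Hox3 (PG3), central (PG4-8) and posterior (PG9-13).  Protostome
gene names (Lab, Pb, Dfd, Antp, Ubx, Abd-A, Abd-B ...) are translated into
that scheme.  The three ParaHox families are Gsx (a.k.a. ind/Gsh),
Pdx (a.k.a. Xlox) and Cdx (a.k.a. cad/caudal).  Any name outside the
synonym table maps to OTHER -- never silently to a Hox group.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class Category(enum.Enum):
    HOX = "HOX"
    PARAHOX = "PARAHOX"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GroupLabel:
    """Canonical group label: a category plus a controlled-vocabulary name.

    Valid HOX names are ``PG1``..``PG13`` and the collective bins
    ``anterior``, ``central``, ``posterior``.  Valid PARAHOX names are
    ``Gsx``, ``Pdx``, ``Cdx``.  OTHER carries the fixed name ``other``.
    """

    category: Category
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.category.value}:{self.name}"


OTHER = GroupLabel(Category.OTHER, "other")

#: ParaHox synonym table (lower-cased keys).
_PARAHOX_SYNONYMS = {
    "gsx": "Gsx",
    "gsh": "Gsx",
    "ind": "Gsx",
    "pdx": "Pdx",
    "xlox": "Pdx",
    "ipf1": "Pdx",
    "cdx": "Cdx",
    "cad": "Cdx",
    "caudal": "Cdx",
}

#: Protostome/common-name -> vertebrate paralog-group synonyms.
_HOX_SYNONYMS = {
    "lab": "PG1",
    "labial": "PG1",
    "pb": "PG2",
    "proboscipedia": "PG2",
    "zen": "PG3",
    "dfd": "PG4",
    "deformed": "PG4",
    "scr": "PG5",
    "antp": "PG7",
    "ubx": "central",
    "abd-a": "central",
    "abda": "central",
    "abd-b": "posterior",
    "abdb": "posterior",
    "anterior": "anterior",
    "central": "central",
    "posterior": "posterior",
}

_HOX_NUMBERED = re.compile(r"^(?:hox|pg)[-_ ]?(\d{1,2})[a-z]?$")


def canonical_group(name: str) -> GroupLabel:
    """Map a free-text group name onto the controlled vocabulary.

    Case-insensitive and deterministic.  ``Hox<k>`` / ``PG<k>`` forms with
    k in 1..13 map to the corresponding paralog group; known synonyms map
    through the tables above; anything else yields OTHER.
    """
    key = name.strip().lower()
    if not key:
        return OTHER
    if key in _PARAHOX_SYNONYMS:
        return GroupLabel(Category.PARAHOX, _PARAHOX_SYNONYMS[key])
    if key in _HOX_SYNONYMS:
        return GroupLabel(Category.HOX, _HOX_SYNONYMS[key])
    m = _HOX_NUMBERED.match(key)
    if m:
        k = int(m.group(1))
        if 1 <= k <= 13:
            return GroupLabel(Category.HOX, f"PG{k}")
    return OTHER


def assignment_bin(label: GroupLabel) -> str | None:
    """Collapse a Hox label onto the bins used for group assignment.

    PG1, PG2 and PG3 stay separate (the ParaHox questions hinge on them);
    PG4-8 collapse to ``central`` and PG9-13 to ``posterior``.  ParaHox
    labels pass through unchanged; OTHER yields None (excluded from
    connectivity statistics).
    """
    if label.category is Category.OTHER:
        return None
    if label.category is Category.PARAHOX:
        return label.name
    name = label.name
    if name.startswith("PG"):
        k = int(name[2:])
        if k <= 3:
            return f"PG{k}"
        if k <= 8:
            return "central"
        return "posterior"
    return name  # already a collective bin


@dataclass
class AnnotatedSequence:
    """A full-length protein with its identifier and annotations.

    ``residues`` is an uppercase string over the 20 amino-acid letters
    (X allowed for unknowns).  ``group`` is the canonical label derived
    from ``common_name`` unless set explicitly.
    """

    seq_id: str
    residues: str
    common_name: str = ""
    species: str = ""
    group: GroupLabel = field(default=OTHER)

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r} has no residues")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)
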