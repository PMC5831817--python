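"""Position-specific log-odds profile for homeodomain detection.

A fixed-length (no insert/delete state) log-odds profile built from a seed
multiple alignment of the ~60-residue homeodomain.  The pipeline only needs
the presence and count of the domain in each candidate protein, not a
per-residue alignment, so match columns with a calibrated score threshold
are sufficient.  The threshold is calibrated empirically against a null of
i.i.d. background-composition sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotatedSequence

#: Canonical residue order for all profile arrays.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP_CHARS = frozenset("-.")


def encode(residues: str) -> np.ndarray:
    """Encode residues as indices into ALPHABET; X encodes as 20 (scores 0)."""
    out = np.empty(len(residues), dtype=np.intp)
    for i, ch in enumerate(residues):
        if ch == "X":
            out[i] = len(ALPHABET)
        else:
            idx = _INDEX.get(ch)
            if idx is None:
                raise ValueError(f"unknown residue code {ch!r} at position {i}")
            out[i] = idx
    return out


@dataclass
class ProfileModel:
    """Per-column, per-residue natural-log odds over a background composition.

    ``log_odds`` has shape (length, 20); ``background`` sums to 1.
    ``score_threshold`` is None until :func:`calibrate_threshold` runs.
    """

    log_odds: np.ndarray
    background: np.ndarray
    score_threshold: float | None = None
    #: column frequency matrix retained for invariant checks / serialization
    frequencies: np.ndarray | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.log_odds, axis=1))

    def _padded(self) -> np.ndarray:
        """log-odds with an extra zero column so X scores 0 everywhere."""
        return np.hstack([self.log_odds, np.zeros((self.length, 1))])

    def window_scores(self, residues: str) -> np.ndarray:
        """Score of every length-L window of the sequence (empty if too short)."""
        if len(residues) < self.length:
            return np.empty(0)
        enc = encode(residues)
        windows = np.lib.stride_tricks.sliding_window_view(enc, self.length)
        lo = self._padded()
        return lo[np.arange(self.length)[None, :], windows].sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# background\t" + "\t".join(repr(float(b)) for b in self.background) + "\n")
            thr = "NA" if self.score_threshold is None else repr(float(self.score_threshold))
            fh.write(f"# score_threshold\t{thr}\n")
            fh.write("column\t" + "\t".join(ALPHABET) + "\n")
            for c in range(self.length):
                row = "\t".join(repr(float(v)) for v in self.log_odds[c])
                fh.write(f"{c}\t{row}\n")


def build_profile(
    seed_alignment: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | str = "from-alignment",
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from an aligned set of seed sequences.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are dropped
    from the match states.  Per kept column,

        log_odds[c][a] = ln( (count_a + pc * bg_a) / (n_eff + pc) / bg_a )

    with ``n_eff`` the number of counted residues in the column.  X is
    ignored in the counts.
    """
    rows = [r.upper() for r in seed_alignment]
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged seed alignment: rows differ in length")
    for r in rows:
        for ch in r:
            if ch not in _INDEX and ch != "X" and ch not in GAP_CHARS:
                raise ValueError(f"alphabet violation in seed alignment: {ch!r}")

    counts = np.zeros((width, len(ALPHABET)))
    gaps = np.zeros(width)
    for r in rows:
        for c, ch in enumerate(r):
            if ch in GAP_CHARS:
                gaps[c] += 1
            elif ch != "X":
                counts[c, _INDEX[ch]] += 1
    keep = gaps / len(rows) <= max_gap_fraction
    counts = counts[keep]
    if counts.shape[0] == 0:
        raise ValueError("no match columns left after the gap-fraction rule")

    if isinstance(background, str):
        if background != "from-alignment":
            raise ValueError(f"unknown background spec {background!r}")
        total = counts.sum(axis=0)
        bg = (total + 1.0) / (total.sum() + len(ALPHABET))  # Laplace floor
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (len(ALPHABET),) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 20 frequencies summing to 1")

    n_eff = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * bg) / (n_eff + pseudocount)
    log_odds = np.log(freqs / bg)
    return ProfileModel(log_odds=log_odds, background=bg, frequencies=freqs)


def read_seed_alignment(path: str | Path) -> list[str]:
    """Aligned FASTA -> list of equal-length rows (gaps '-' or '.')."""
    from Bio import SeqIO

    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: no alignment rows")
    return rows


def sample_background_sequence(background: np.ndarray, length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(ALPHABET), size=length, p=background)
    return "".join(ALPHABET[i] for i in idx)


def calibrate_threshold(
    profile: ProfileModel,
    n_samples: int = 1000,
    fpr: float = 1e-3,
    seed: int = 0,
    null_length: int = 500,
) -> float:
    """Empirical null calibration: (1 - fpr) quantile of best-window scores.

    The null draws ``n_samples`` i.i.d. sequences of ``null_length`` from
    the profile's background composition.  Sets and returns
    ``profile.score_threshold``.  Deterministic given ``seed``.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable quantile")
    if not 0.0 < fpr <= 0.5:
        raise ValueError("fpr must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    best = np.empty(n_samples)
    for i in range(n_samples):
        s = sample_background_sequence(profile.background, null_length, rng)
        best[i] = profile.window_scores(s).max()
    threshold = float(np.quantile(best, 1.0 - fpr))
    profile.score_threshold = threshold
    return threshold


@dataclass(frozen=True)
class DomainHit:
    """One non-overlapping profile hit; [start, end) is 0-based half-open."""

    seq_id: str
    start: int
    end: int
    score: float


def scan_sequence(profile: ProfileModel, seq: AnnotatedSequence) -> list[DomainHit]:
    """All non-overlapping windows scoring >= the calibrated threshold.

    Best-first greedy overlap resolution: repeatedly keep the highest-
    scoring remaining window (ties broken by smaller start) and discard
    windows overlapping it.  Hits are returned sorted by start.
    """
    if profile.score_threshold is None:
        raise ValueError("profile is not calibrated; run calibrate_threshold first")
    scores = profile.window_scores(seq.residues)
    cand = np.flatnonzero(scores >= profile.score_threshold)
    if cand.size == 0:
        return []
    order = sorted(cand, key=lambda i: (-scores[i], i))
    taken: list[int] = []
    for i in order:
        if all(abs(i - j) >= profile.length for j in taken):
            taken.append(i)
    return [
        DomainHit(seq.seq_id, int(i), int(i) + profile.length, float(scores[i]))
        for i in sorted(taken)
    ]


@dataclass
class FilterResult:
    kept: list[AnnotatedSequence]
    removed: list[AnnotatedSequence]
    zero_hit_ids: list[str]


def filter_multidomain(
    seqs: Iterable[AnnotatedSequence], profile: ProfileModel
) -> FilterResult:
    """Exclude sequences carrying more than a single homeodomain.

    Sequences with >= 2 hits go to ``removed`` (likely concatenations or
    mis-assemblies); sequences with 0 or 1 hits are kept, with zero-hit
    ids flagged separately since the candidate set is expected to stem
    from a domain search.
    """
    kept: list[AnnotatedSequence] = []
    removed: list[AnnotatedSequence] = []
    zero: list[str] = []
    for s in seqs:
        n = len(scan_sequence(profile, s))
        if n >= 2:
            removed.append(s)
        else:
            kept.append(s)
            if n == 0:
                zero.append(s.seq_id)
    return FilterResult(kept, removed, zero)


def write_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """TSV hit table with 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart_1based\tend_1based\tscore\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start + 1}\t{h.end}\t{repr(h.score)}\n")


def read_hit_table(path: str | Path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            seq_id, s1, e1, score = line.rstrip("\n").split("\t")
            hits.append(DomainHit(seq_id, int(s1) - 1, int(e1), float(score)))
    return hits
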