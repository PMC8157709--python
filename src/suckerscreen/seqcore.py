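"""Sequence primitives: FASTA I/O, affine-gap global alignment, percent identity.

Conventions used throughout the package
---------------------------------------
* DNA alphabet is ``{A, C, G, T, N}``.  ``N`` is an ambiguity placeholder and
  never counts as a match — not even against another ``N``.
* Coordinates are 0-based, half-open.
* FASTA headers follow ``id|subgenome|class`` where ``subgenome`` is ``S``,
  ``T`` or ``none`` (the two progenitor genomes of allotetraploid tobacco,
  *N. sylvestris* and *N. tomentosiformis*) and ``class`` is
  ``transcription_factor``, ``unknown`` or ``other``.  A bare header (no pipe)
  defaults to ``none``/``other`` and round-trips unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Subgenome",
    "AnnotationClass",
    "Transcript",
    "Scoring",
    "DEFAULT_SCORING",
    "PairwiseAlignment",
    "IdentityMode",
    "IdentityProfile",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "global_align",
    "percent_identity",
    "windowed_identity",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")
_ALPHABET = "ACGTN"
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences, FASTA records, or alignments."""


class Subgenome(str, enum.Enum):
    S = "S"
    T = "T"
    NONE = "none"


class AnnotationClass(str, enum.Enum):
    TRANSCRIPTION_FACTOR = "transcription_factor"
    UNKNOWN = "unknown"
    OTHER = "other"


def _validate_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(
            f"{name}: non-IUPAC characters {sorted(bad)} (allowed: A, C, G, T, N)"
        )
    return seq


@dataclass
class Transcript:
    """A transcript record with subgenome tag and annotation class."""

    id: str
    sequence: str
    subgenome: Subgenome = Subgenome.NONE
    annotation_class: AnnotationClass = AnnotationClass.OTHER

    def __post_init__(self) -> None:
        self.sequence = _validate_sequence(self.sequence, f"transcript {self.id!r}")

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


def _parse_header(header: str) -> tuple[str, Subgenome, AnnotationClass]:
    parts = header.split("|")
    name = parts[0]
    sub = Subgenome.NONE
    cls = AnnotationClass.OTHER
    if len(parts) >= 2 and parts[1]:
        try:
            sub = Subgenome(parts[1])
        except ValueError as exc:
            raise SequenceError(f"record {name!r}: unknown subgenome tag {parts[1]!r}") from exc
    if len(parts) >= 3 and parts[2]:
        try:
            cls = AnnotationClass(parts[2])
        except ValueError as exc:
            raise SequenceError(f"record {name!r}: unknown annotation class {parts[2]!r}") from exc
    return name, sub, cls


def _format_header(t: Transcript) -> str:
    if t.subgenome is Subgenome.NONE and t.annotation_class is AnnotationClass.OTHER:
        return t.id
    return f"{t.id}|{t.subgenome.value}|{t.annotation_class.value}"


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from a FASTA file (header convention ``id|subgenome|class``)."""
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        name, sub, cls = _parse_header(header)
        if name in seen:
            raise SequenceError(f"duplicate transcript id {name!r} in {path}")
        seen.add(name)
        try:
            seq = _validate_sequence(str(rec.seq), f"record {name!r}")
        except SequenceError:
            raise
        out.append(Transcript(name, seq, sub, cls))
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts wrapped at 60 columns; headers encode subgenome and class."""
    records = [
        SeqRecord(Seq(t.sequence), id=_format_header(t), description="")
        for t in transcripts
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement (``N`` maps to ``N``); an involution."""
    sequence = _validate_sequence(sequence)
    return sequence.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring. A gap of length L scores ``gap_open + L * gap_extend``.

    Defaults are megablast-style weights (match +2, mismatch -3, open -5,
    extend -2), a conventional choice for highly similar nucleotide pairs
    such as homoeologs.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


class IdentityMode(str, enum.Enum):
    """Denominator used when turning an alignment into a percent identity."""

    ALL_COLUMNS = "all_columns"
    EXCLUDE_TERMINAL_GAPS = "exclude_terminal_gaps"
    SHORTER_SEQUENCE = "shorter_sequence"


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two gapped strings of equal length."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceError("aligned strings must have equal length")

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identity_pct(self) -> float:
        return percent_identity(self)

    def ungapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    def ungapped_b(self) -> str:
        return self.aligned_b.replace("-", "")


def _column_is_match(ca: str, cb: str) -> bool:
    return ca == cb and ca != "-" and ca != "N"


def _build_aligner(scoring: Scoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            if x == y and x != "N":
                matrix[x, y] = scoring.match
            else:
                matrix[x, y] = scoring.mismatch
    aligner.substitution_matrix = matrix
    # biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; map our open + L*extend onto it.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of two DNA strings under affine gap scoring.

    The first optimal alignment in the aligner's deterministic traceback
    order is returned, so identical inputs always yield identical output.
    """
    a = _validate_sequence(a, "sequence a")
    b = _validate_sequence(b, "sequence b")
    if not a or not b:
        raise SequenceError("cannot align an empty sequence")
    aligner = _build_aligner(scoring)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score)


def _terminal_gap_span(aln: PairwiseAlignment) -> tuple[int, int]:
    """Columns [lo, hi) between the outermost columns where both rows have bases."""
    a, b = aln.aligned_a, aln.aligned_b
    n = len(a)
    lo = 0
    while lo < n and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    return lo, hi


def percent_identity(
    aln: PairwiseAlignment, mode: IdentityMode = IdentityMode.EXCLUDE_TERMINAL_GAPS
) -> float:
    """Identical columns / denominator, as a percentage in [0, 100].

    Modes: all alignment columns; columns excluding terminal gap runs
    (default); or the length of the shorter input sequence.
    """
    a, b = aln.aligned_a, aln.aligned_b
    if mode is IdentityMode.EXCLUDE_TERMINAL_GAPS:
        lo, hi = _terminal_gap_span(aln)
        denom = hi - lo
        matches = sum(_column_is_match(a[i], b[i]) for i in range(lo, hi))
    elif mode is IdentityMode.ALL_COLUMNS:
        denom = len(a)
        matches = sum(_column_is_match(x, y) for x, y in zip(a, b))
    elif mode is IdentityMode.SHORTER_SEQUENCE:
        denom = min(len(aln.ungapped_a()), len(aln.ungapped_b()))
        matches = sum(_column_is_match(x, y) for x, y in zip(a, b))
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise SequenceError("zero denominator in percent identity")
    return 100.0 * matches / denom


@dataclass
class IdentityProfile:
    """Window-start → identity, with window starts on the ungapped first sequence."""

    window_length: int
    step: int
    entries: list[tuple[int, float]] = field(default_factory=list)

    @property
    def starts(self) -> list[int]:
        return [s for s, _ in self.entries]

    @property
    def identities(self) -> list[float]:
        return [v for _, v in self.entries]


def windowed_identity(
    aln: PairwiseAlignment, window_length: int, step: int = 1
) -> IdentityProfile:
    """Sliding-window identity along sequence *a* of a global alignment.

    Each window covers ``window_length`` ungapped bases of sequence *a*;
    identity is identical columns over all alignment columns spanned by the
    window (so gap columns inside the span count in the denominator).
    """
    if window_length < 1 or step < 1:
        raise ValueError("window_length and step must be >= 1")
    a, b = aln.aligned_a, aln.aligned_b
    cols = [i for i, c in enumerate(a) if c != "-"]  # a-position -> column
    len_a = len(cols)
    if window_length > len_a:
        raise SequenceError(
            f"window length {window_length} exceeds sequence length {len_a}"
        )
    # cumulative match counts per column for O(1) window sums
    cum = [0]
    for x, y in zip(a, b):
        cum.append(cum[-1] + (1 if _column_is_match(x, y) else 0))
    entries: list[tuple[int, float]] = []
    for s in range(0, len_a - window_length + 1, step):
        c0 = cols[s]
        c1 = cols[s + window_length - 1] + 1
        matches = cum[c1] - cum[c0]
        entries.append((s, 100.0 * matches / (c1 - c0)))
    return IdentityProfile(window_length=window_length, step=step, entries=entries)


def format_alignment(aln: PairwiseAlignment) -> str:
    """3-line debug dump: sequence a, match bars, sequence b."""
    bars = "".join(
        "|" if _column_is_match(x, y) else " "
        for x, y in zip(aln.aligned_a, aln.aligned_b)
    )
    return f"{aln.aligned_a}\n{bars}\n{aln.aligned_b}\n"
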