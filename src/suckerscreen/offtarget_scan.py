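"""Exact off-target scan: maximal shared runs of >= k consecutive nucleotides.

A hairpin trigger can silence an unintended transcript when the two share a
long enough run of identical bases; 22 consecutive matching nucleotides is
the conventional risk threshold.  Because the criterion is literal sequence
identity, the scan is implemented as exact k-mer seeding plus maximal
extension rather than a heuristic aligner: every shared substring of length
>= k is found, each reported once as a maximal match (extending it one base
in either direction breaks identity or hits a sequence boundary).

Both strands are scanned by default — hairpin RNAi produces sense and
antisense small RNAs — and ``N`` never matches anything, including ``N``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqcore import SequenceError, Transcript, reverse_complement

__all__ = [
    "KmerIndex",
    "OffTargetHit",
    "Strand",
    "Verdict",
    "build_index",
    "scan_trigger",
    "classify_trigger",
    "write_hits_tsv",
    "write_verdicts_tsv",
    "DEFAULT_MATCH_LENGTH",
]

DEFAULT_MATCH_LENGTH = 22
_MIN_K = 8


class Strand(str, enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


class Verdict(str, enum.Enum):
    CLEAN = "clean"
    OFF_TARGET_RISK = "off_target_risk"


@dataclass(frozen=True)
class OffTargetHit:
    """A maximal exact match between a trigger and a non-target transcript.

    Coordinates are 0-based half-open.  ``trigger_start``/``trigger_end``
    always refer to the trigger in its given (sense) orientation; for an
    antisense hit the transcript substring equals the reverse complement of
    the trigger substring.
    """

    trigger_id: str
    transcript_id: str
    trigger_start: int
    trigger_end: int
    transcript_start: int
    transcript_end: int
    strand: Strand
    match_length_nt: int


class KmerIndex:
    """Exact k-mer index over a transcriptome: k-mer -> [(transcript_id, pos)].

    Transcripts shorter than k contribute nothing; k-mers containing ``N``
    are not indexed (N never matches).
    """

    def __init__(self, k: int):
        if k < _MIN_K:
            raise ValueError(f"k must be >= {_MIN_K}, got {k}")
        self.k = k
        self._map: dict[str, list[tuple[str, int]]] = {}

    def add(self, transcript: Transcript) -> None:
        seq = transcript.sequence
        k = self.k
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            self._map.setdefault(kmer, []).append((transcript.id, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._map.get(kmer, [])

    @property
    def n_kmers(self) -> int:
        return len(self._map)

    def n_positions(self) -> int:
        return sum(len(v) for v in self._map.values())


def build_index(transcriptome: Iterable[Transcript], k: int = DEFAULT_MATCH_LENGTH) -> KmerIndex:
    index = KmerIndex(k)
    for t in transcriptome:
        index.add(t)
    return index


def _extend(query: str, target: str, qpos: int, tpos: int, k: int) -> tuple[int, int, int, int]:
    """Extend an exact k-mer seed to a maximal match; returns (qs, qe, ts, te)."""
    qs, ts = qpos, tpos
    while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1] != "N":
        qs -= 1
        ts -= 1
    qe, te = qpos + k, tpos + k
    nq, nt = len(query), len(target)
    while qe < nq and te < nt and query[qe] == target[te] != "N":
        qe += 1
        te += 1
    return qs, qe, ts, te


def scan_trigger(
    trigger: Transcript,
    index: KmerIndex,
    transcriptome: Iterable[Transcript] | Mapping[str, str],
    exclude_ids: frozenset[str] | set[str] = frozenset(),
    both_strands: bool = True,
) -> list[OffTargetHit]:
    """All maximal exact matches of length >= k between the trigger and the transcriptome.

    ``exclude_ids`` drops the intended targets (the S/T copies of the family)
    from the report.  Overlapping seeds belonging to the same maximal run are
    deduplicated, so each maximal match is reported exactly once.
    """
    k = index.k
    if trigger.length_nt < k:
        raise SequenceError(
            f"trigger {trigger.id!r} is shorter ({trigger.length_nt} nt) than k={k}"
        )
    if isinstance(transcriptome, Mapping):
        seqs = dict(transcriptome)
    else:
        seqs = {t.id: t.sequence for t in transcriptome}
    strands = [(Strand.SENSE, trigger.sequence)]
    if both_strands:
        strands.append((Strand.ANTISENSE, reverse_complement(trigger.sequence)))
    hits: list[OffTargetHit] = []
    seen: set[tuple[str, Strand, int, int]] = set()
    trig_len = trigger.length_nt
    for strand, query in strands:
        for qpos in range(len(query) - k + 1):
            kmer = query[qpos : qpos + k]
            if "N" in kmer:
                continue
            for tid, tpos in index.lookup(kmer):
                if tid in exclude_ids:
                    continue
                qs, qe, ts, te = _extend(query, seqs[tid], qpos, tpos, k)
                key = (tid, strand, ts, qs)
                if key in seen:
                    continue
                seen.add(key)
                if strand is Strand.SENSE:
                    trig_start, trig_end = qs, qe
                else:
                    trig_start, trig_end = trig_len - qe, trig_len - qs
                hits.append(
                    OffTargetHit(
                        trigger_id=trigger.id,
                        transcript_id=tid,
                        trigger_start=trig_start,
                        trigger_end=trig_end,
                        transcript_start=ts,
                        transcript_end=te,
                        strand=strand,
                        match_length_nt=qe - qs,
                    )
                )
    hits.sort(
        key=lambda h: (h.transcript_id, h.transcript_start, h.strand.value, h.trigger_start)
    )
    return hits


def classify_trigger(
    trigger: Transcript, hits: Sequence[OffTargetHit]
) -> tuple[Verdict, list[OffTargetHit]]:
    """``clean`` iff the scan produced no hits outside the excluded targets."""
    if not hits:
        return Verdict.CLEAN, []
    return Verdict.OFF_TARGET_RISK, list(hits)


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "trigger_id",
    "transcript_id",
    "trigger_start",
    "trigger_end",
    "transcript_start",
    "transcript_end",
    "strand",
    "match_length_nt",
]


def write_hits_tsv(hits: Iterable[OffTargetHit], path: str | Path) -> None:
    rows = [
        {
            "trigger_id": h.trigger_id,
            "transcript_id": h.transcript_id,
            "trigger_start": h.trigger_start,
            "trigger_end": h.trigger_end,
            "transcript_start": h.transcript_start,
            "transcript_end": h.transcript_end,
            "strand": h.strand.value,
            "match_length_nt": h.match_length_nt,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_verdicts_tsv(
    verdicts: Mapping[str, Verdict], n_hits: Mapping[str, int], path: str | Path
) -> None:
    rows = [
        {"trigger_id": tid, "verdict": v.value, "n_hits": n_hits.get(tid, 0)}
        for tid, v in verdicts.items()
    ]
    pd.DataFrame(rows, columns=["trigger_id", "verdict", "n_hits"]).to_csv(
        path, sep="\t", index=False
    )
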