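"""Candidate-gene selection from tissue expression tables.

The screen selects genes preferentially expressed in axillary-meristem zones
sampled at an early (EA) or very early (VE) developmental stage, relative to a
control zone.  A gene is a candidate iff

  (a) its RPKM in EA or VE is at least ``min_fold`` (default 10x) that of the
      control zone,
  (b) the assembled contig is longer than ``min_length_nt`` (default 200 bp,
      strict inequality), and
  (c) it is annotated as a transcription factor or unknown protein.

"Not detectable" (ND) is an explicit expression state, distinct from a
measured zero, and is represented by ``None``.  A tissue ND gives fold 0; a
control ND gives ``tissue / nd_epsilon`` with ``nd_epsilon`` defaulting to
0.1 RPKM (so any tissue RPKM >= 1 clears a 10x threshold against an
undetectable control).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .seqcore import AnnotationClass

__all__ = [
    "Tissue",
    "ExpressionRecord",
    "CandidateGene",
    "ScreenError",
    "compute_rpkm",
    "fold_enrichment",
    "assign_tissue",
    "select_candidates",
    "read_expression_tsv",
    "write_candidates_tsv",
    "DEFAULT_ND_EPSILON",
]

DEFAULT_ND_EPSILON = 0.1
ND_TOKEN = "ND"

#: RPKM value or None for "not detectable"
RpkmOrND = Optional[float]

DEFAULT_ALLOWED_CLASSES = frozenset(
    {AnnotationClass.TRANSCRIPTION_FACTOR, AnnotationClass.UNKNOWN}
)


class ScreenError(ValueError):
    """Raised on invalid screen inputs (duplicate ids, negative values, ...)."""


class Tissue(str, enum.Enum):
    EA = "EA"
    VE = "VE"


@dataclass
class ExpressionRecord:
    """Per-gene expression in EA, VE and control tissue (RPKM or ND).

    Raw per-tissue read counts and library sizes are optional; when present
    the RPKM values can be recomputed with :func:`compute_rpkm`.
    """

    gene_id: str
    length_nt: int
    ea: RpkmOrND
    ve: RpkmOrND
    control: RpkmOrND
    annotation_class: AnnotationClass = AnnotationClass.OTHER
    counts: Optional[dict[str, int]] = None
    total_mapped: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        for name, v in (("ea", self.ea), ("ve", self.ve), ("control", self.control)):
            if v is not None and v < 0:
                raise ScreenError(f"gene {self.gene_id!r}: negative {name} RPKM {v}")


@dataclass
class CandidateGene:
    gene_id: str
    assigned_tissue: Optional[Tissue]
    fold_vs_control: float  # may be math.inf
    passed_criteria: frozenset[str] = field(default_factory=frozenset)

    @property
    def selected(self) -> bool:
        return self.passed_criteria >= {"a", "b", "c"}


def compute_rpkm(read_count: int, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of exon per million mapped reads.

    ``read_count * 1e9 / (length_nt * total_mapped)``.
    """
    if length_nt <= 0:
        raise ScreenError("length_nt must be positive")
    if total_mapped <= 0:
        raise ScreenError("total_mapped must be positive")
    if read_count < 0:
        raise ScreenError("read_count must be non-negative")
    return read_count * 1e9 / (length_nt * total_mapped)


def fold_enrichment(
    tissue: RpkmOrND, control: RpkmOrND, nd_epsilon: float = DEFAULT_ND_EPSILON
) -> float:
    """Tissue-over-control RPKM ratio with the documented ND rule.

    Tissue ND -> 0.  Control ND -> ``tissue / nd_epsilon``.  A measured
    control of exactly 0 with positive tissue expression gives ``inf``.
    """
    if nd_epsilon <= 0:
        raise ScreenError("nd_epsilon must be positive")
    for name, v in (("tissue", tissue), ("control", control)):
        if v is not None and v < 0:
            raise ScreenError(f"negative {name} RPKM {v}")
    if tissue is None:
        return 0.0
    if control is None:
        return tissue / nd_epsilon
    if control == 0.0:
        return math.inf if tissue > 0 else 0.0
    return tissue / control


def assign_tissue(
    record: ExpressionRecord,
    folds: dict[Tissue, float],
    min_fold: float = 10.0,
) -> Tissue:
    """Tissue with the larger RPKM among tissues whose fold passes; ties go EA-first."""
    passing = [t for t in (Tissue.EA, Tissue.VE) if folds.get(t, 0.0) >= min_fold]
    if not passing:
        raise ScreenError(f"gene {record.gene_id!r}: no tissue passes fold {min_fold}")
    rpkm = {Tissue.EA: record.ea or 0.0, Tissue.VE: record.ve or 0.0}
    # max() keeps the first (EA) on exact ties because of iteration order
    return max(passing, key=lambda t: rpkm[t])


def select_candidates(
    records: Iterable[ExpressionRecord],
    min_fold: float = 10.0,
    min_length_nt: int = 200,
    allowed_classes: frozenset[AnnotationClass] = DEFAULT_ALLOWED_CLASSES,
    nd_epsilon: float = DEFAULT_ND_EPSILON,
) -> list[CandidateGene]:
    """Apply criteria (a)–(c) and assign a tissue to every selected gene.

    Returns one :class:`CandidateGene` per selected input gene, in input
    order.  ``assigned_tissue`` is the argmax-RPKM tissue among tissues whose
    fold passes.
    """
    out: list[CandidateGene] = []
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ScreenError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        folds = {
            Tissue.EA: fold_enrichment(rec.ea, rec.control, nd_epsilon),
            Tissue.VE: fold_enrichment(rec.ve, rec.control, nd_epsilon),
        }
        best_fold = max(folds.values())
        passed: set[str] = set()
        if best_fold >= min_fold:
            passed.add("a")
        if rec.length_nt > min_length_nt:
            passed.add("b")
        if rec.annotation_class in allowed_classes:
            passed.add("c")
        if passed >= {"a", "b", "c"}:
            out.append(
                CandidateGene(
                    gene_id=rec.gene_id,
                    assigned_tissue=assign_tissue(rec, folds, min_fold),
                    fold_vs_control=best_fold,
                    passed_criteria=frozenset(passed),
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def _parse_cell(v) -> RpkmOrND:
    if isinstance(v, str) and v.strip().upper() == ND_TOKEN:
        return None
    if pd.isna(v):
        return None
    return float(v)


def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """Read an expression table: gene_id, length_nt, ea, ve, control, class.

    ND is spelled ``ND``.  Optional count columns ``count_ea``, ``count_ve``,
    ``count_control`` and ``total_ea``/``total_ve``/``total_control`` are
    carried through when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    required = {"gene_id", "length_nt", "ea", "ve", "control", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ScreenError(f"expression table {path}: missing columns {sorted(missing)}")
    has_counts = {"count_ea", "count_ve", "count_control"} <= set(df.columns)
    has_totals = {"total_ea", "total_ve", "total_control"} <= set(df.columns)
    records = []
    for row in df.to_dict("records"):
        counts = (
            {k: int(row[f"count_{k}"]) for k in ("ea", "ve", "control")}
            if has_counts
            else None
        )
        totals = (
            {k: int(row[f"total_{k}"]) for k in ("ea", "ve", "control")}
            if has_totals
            else None
        )
        records.append(
            ExpressionRecord(
                gene_id=row["gene_id"],
                length_nt=int(row["length_nt"]),
                ea=_parse_cell(row["ea"]),
                ve=_parse_cell(row["ve"]),
                control=_parse_cell(row["control"]),
                annotation_class=AnnotationClass(row["class"]),
                counts=counts,
                total_mapped=totals,
            )
        )
    return records


def write_candidates_tsv(candidates: Iterable[CandidateGene], path: str | Path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "tissue": c.assigned_tissue.value if c.assigned_tissue else "",
            "fold": "inf" if math.isinf(c.fold_vs_control) else round(c.fold_vs_control, 4),
            "criteria_passed": "".join(sorted(c.passed_criteria)),
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=["gene_id", "tissue", "fold", "criteria_passed"]).to_csv(
        path, sep="\t", index=False
    )
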