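"""Loaders for the published reference measurements shipped with the package.

Two small tables from the tobacco axillary-meristem study are bundled as
package data and serve as fixed inputs:

* ``reference_expression.tsv`` — per-gene RPKM in the EA and VE axillary
  meristem zones and the control zone, for the 12 BLAST-identified homolog
  families and the 24 RNA-seq screen genes (EA1–EA11, VE1–VE13).  ``ND``
  marks expression below detection.
* ``reference_effects.tsv`` — construct-level RNAi effects relative to null
  segregants (mean ± SD over three single-locus transformant lines) for RNA
  expression and primary/secondary lateral-shoot number and weight, plus the
  published 1%-level significance marks (secondary-shoot columns only).

Contig lengths and annotation classes were not published alongside the RPKM
values; since every listed gene had, by construction, already passed the
length (>200 bp) and annotation (transcription factor / unknown) criteria,
the expression loader fills those fields with passing placeholder values
(length 1000 nt, class ``unknown`` for screen genes, ``transcription_factor``
for the named homolog families).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .enrichment_screen import ExpressionRecord, _parse_cell
from .seqcore import AnnotationClass

__all__ = [
    "load_reference_expression",
    "load_reference_effects",
    "EFFECTIVE_GENES",
]

#: the five constructs whose knock-down significantly suppressed secondary shoots
EFFECTIVE_GENES = frozenset({"NtLs", "NtBl1", "NtREV", "VE7", "VE12"})

_PLACEHOLDER_LENGTH_NT = 1000


def _data_path(name: str):
    return files("suckerscreen").joinpath("data", name)


def load_reference_expression(include_homologs: bool = False) -> list[ExpressionRecord]:
    """Expression records for the 24 screen genes (and optionally the 12 homologs)."""
    df = pd.read_csv(_data_path("reference_expression.tsv"), sep="\t", keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        if row["group"] == "homolog" and not include_homologs:
            continue
        cls = (
            AnnotationClass.TRANSCRIPTION_FACTOR
            if row["group"] == "homolog"
            else AnnotationClass.UNKNOWN
        )
        records.append(
            ExpressionRecord(
                gene_id=row["gene_id"],
                length_nt=_PLACEHOLDER_LENGTH_NT,
                ea=_parse_cell(row["ea"]),
                ve=_parse_cell(row["ve"]),
                control=_parse_cell(row["control"]),
                annotation_class=cls,
            )
        )
    return records


def load_reference_effects() -> pd.DataFrame:
    """Relative-effect summary rows: construct, trait, mean, sd, n (=3), marked."""
    df = pd.read_csv(_data_path("reference_effects.tsv"), sep="\t")
    df["n"] = 3  # three single-locus transformant lines per construct
    df["marked"] = df["marked"].astype(bool)
    return df
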