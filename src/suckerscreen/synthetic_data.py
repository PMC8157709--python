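"""Synthetic allotetraploid transcriptomes, expression tables and phenotype trials.

Every downstream stage of the pipeline is testable without external data
because this module generates inputs with known ground truth:

* **Transcriptomes** — for each target family an ancestral random sequence is
  mutated into an S copy and a T copy at a controlled nucleotide identity
  (default 95.4%, the homoeolog divergence scale of allotetraploid tobacco);
  same-family paralogs diverge further (default 50–65% identity, below the
  70% discrimination cap in places); unrelated background transcripts and
  optional short (< 200 nt) contaminant contigs complete the set.
* **Expression tables** — per-gene read counts and RPKM for the EA and VE
  axillary-meristem zones and a control zone, with a configurable fraction of
  genes enriched >= 10-fold in one zone, optional "not detectable" entries,
  and counts emitted so RPKM can be recomputed.
* **Phenotype trials** — per-plant lateral-shoot counts and weights for
  transgenic lines and their null segregants, with construct-specific
  multiplicative effects on secondary/tertiary shoots and none on primary
  shoots, mirroring a greenhouse design of three single-locus transformant
  lines per construct.

Divergence is substitution-only by default (``indel_rate = 0``), which keeps
recorded identities exact and alignments unambiguous.  Counts are drawn from
a negative-binomial with variance ``mu + (noise_cv * mu)^2`` (``noise_cv`` is
the extra-Poisson coefficient of variation; 0 gives Poisson), weights from a
log-normal with coefficient of variation ``noise_cv``.

Determinism: one master seed; each stage draws from its own documented
sub-stream (0 transcriptome, 1 expression, 2 phenotypes, 3 planting), so
identical configs give bit-identical outputs and stages are independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .enrichment_screen import ExpressionRecord, compute_rpkm
from .phenotype_stats import PHENOTYPE_COLUMNS, Genotype, Trait
from .seqcore import AnnotationClass, Subgenome, Transcript, reverse_complement

__all__ = [
    "SimConfig",
    "EffectMultipliers",
    "FoldDistribution",
    "BaselineMeans",
    "GroundTruth",
    "PlantedMatch",
    "SimConfigError",
    "default_effect_table",
    "simulate_transcriptome",
    "simulate_expression",
    "simulate_phenotypes",
    "plant_offtarget",
    "write_expression_tsv",
    "write_phenotype_tsv",
    "write_ground_truth_json",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# documented RNG sub-stream ids (master seed spawns one stream per stage)
_STREAM_TRANSCRIPTOME = 0
_STREAM_EXPRESSION = 1
_STREAM_PHENOTYPES = 2
_STREAM_PLANTING = 3


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class EffectMultipliers:
    """Multiplicative construct effects on shoot-order traits and expression.

    A multiplier scales both the count and the weight baseline of that shoot
    order.  Zero means complete suppression; negative values are rejected.
    """

    primary: float = 1.0
    secondary: float = 1.0
    tertiary: float = 1.0
    expression: float = 1.0

    def __post_init__(self) -> None:
        for name in ("primary", "secondary", "tertiary", "expression"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"multiplier {name} must be >= 0")


@dataclass(frozen=True)
class FoldDistribution:
    """Log-scale fold distribution for enriched genes (natural log)."""

    mean_log: float = 3.0  # e^3 ~ 20-fold
    sd_log: float = 0.3


@dataclass(frozen=True)
class BaselineMeans:
    """Wild-type trait scales: ~20 primary shoots, ~10 secondary, a few tertiary."""

    primary_n: float = 20.0
    primary_wt: float = 37.0
    secondary_n: float = 10.0
    secondary_wt: float = 20.0
    tertiary_n: float = 3.0
    tertiary_wt: float = 5.0
    expression: float = 1.0


def default_effect_table(
    n_constructs: int = 36,
    n_effective: int = 5,
    effective_mult: float = 0.1,
    knockdown_expression: float = 0.3,
) -> dict[str, EffectMultipliers]:
    """The study-shaped default: 36 knock-down constructs, 5 of which suppress
    secondary/tertiary shoots (the rest silence their target without a shoot
    phenotype)."""
    table: dict[str, EffectMultipliers] = {}
    for i in range(1, n_constructs + 1):
        name = f"construct{i:02d}"
        if i <= n_effective:
            table[name] = EffectMultipliers(
                secondary=effective_mult,
                tertiary=effective_mult,
                expression=knockdown_expression,
            )
        else:
            table[name] = EffectMultipliers(expression=knockdown_expression)
    return table


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # transcriptome
    n_target_pairs: int = 36
    n_paralog_families: int = 12
    n_paralogs_per_family: int = 2
    n_background: int = 300
    st_identity_target: float = 0.954
    paralog_identity_range: tuple[float, float] = (0.50, 0.65)
    transcript_length_range: tuple[int, int] = (800, 2000)
    short_contig_fraction: float = 0.05
    short_contig_length_range: tuple[int, int] = (80, 200)
    indel_rate: float = 0.0
    # expression
    enriched_fraction: float = 0.08
    fold_distribution: FoldDistribution = field(default_factory=FoldDistribution)
    nd_probability: Union[float, Mapping[str, float]] = 0.0
    total_mapped: int = 1_000_000
    control_mean_log: float = 3.0  # mean control count ~ e^3 ~ 20 reads
    control_sd_log: float = 1.0
    # phenotypes
    effect_table: Optional[dict[str, EffectMultipliers]] = None
    n_lines_per_construct: int = 3
    n_plants_per_line: int = 10
    noise_cv: float = 0.1
    baseline_means: BaselineMeans = field(default_factory=BaselineMeans)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.st_identity_target <= 1):
            raise SimConfigError("st_identity_target must be in (0, 1]")
        lo, hi = self.paralog_identity_range
        if lo > hi:
            raise SimConfigError("paralog_identity_range: min > max")
        if not (0 <= lo and hi <= 1):
            raise SimConfigError("paralog_identity_range must lie in [0, 1]")
        lo, hi = self.transcript_length_range
        if lo > hi:
            raise SimConfigError("transcript_length_range: min > max")
        if lo < 1:
            raise SimConfigError("transcript_length_range: min must be >= 1")
        for name in ("short_contig_fraction", "enriched_fraction", "indel_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimConfigError(f"{name} must be in [0, 1]")
        nd = self.nd_probability
        nd_values = nd.values() if isinstance(nd, Mapping) else [nd]
        if any(not (0 <= v <= 1) for v in nd_values):
            raise SimConfigError("nd_probability must be in [0, 1]")
        if self.n_paralog_families > self.n_target_pairs:
            raise SimConfigError("n_paralog_families cannot exceed n_target_pairs")
        if self.noise_cv < 0:
            raise SimConfigError("noise_cv must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def effects(self) -> dict[str, EffectMultipliers]:
        return self.effect_table if self.effect_table is not None else default_effect_table()


@dataclass(frozen=True)
class PlantedMatch:
    """A trigger substring copied into a background transcript."""

    transcript_id: str
    start: int
    end: int
    strand: str  # sense | antisense
    trigger_start: int
    trigger_end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """What the generator actually planted, for checking every pipeline stage."""

    enrichment: dict[str, Optional[str]] = field(default_factory=dict)  # gene -> EA/VE/None
    enriched_fold: dict[str, float] = field(default_factory=dict)
    st_identities: dict[str, float] = field(default_factory=dict)  # family -> pct
    paralog_identities: dict[str, float] = field(default_factory=dict)  # "target~paralog" -> pct
    planted_matches: list[PlantedMatch] = field(default_factory=list)
    effect_table: dict[str, EffectMultipliers] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate_exact(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each listed position with a uniformly chosen different base."""
    out = seq.copy()
    for pos in positions:
        current = out[pos]
        alternatives = _BASES[_BASES != current]
        out[pos] = rng.choice(alternatives)
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Optional single-base indels at the given per-site rate (off by default)."""
    if rate <= 0:
        return seq
    out: list[int] = []
    for base in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(int(base))
        if r >= rate / 2 and r < rate:
            out.append(int(rng.choice(_BASES)))  # insertion
    return np.asarray(out, dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_transcriptome(config: SimConfig) -> tuple[list[Transcript], GroundTruth]:
    """Generate S/T homoeolog pairs, paralog families, and background transcripts.

    Each family ``famNN`` contributes ``famNN_S`` and ``famNN_T`` derived from
    one ancestral sequence by splitting ``round((1 - identity) * L)``
    substitutions randomly between the two branches, so the realized pairwise
    identity is exact.  The first ``n_paralog_families`` families additionally
    carry paralogs ``famNN_paraM`` derived from the S copy at identities drawn
    uniformly from ``paralog_identity_range``.  Realized identities are
    recorded in the returned :class:`GroundTruth`.
    """
    config.validate()
    rng = config.rng(_STREAM_TRANSCRIPTOME)
    truth = GroundTruth(effect_table=config.effects())
    transcripts: list[Transcript] = []

    lo, hi = config.transcript_length_range
    for fam in range(1, config.n_target_pairs + 1):
        family_id = f"fam{fam:02d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_sequence(rng, length)
        n_diff = round((1.0 - config.st_identity_target) * length)
        diff_positions = rng.choice(length, size=n_diff, replace=False)
        to_s = rng.random(n_diff) < 0.5
        s_arr = _mutate_exact(ancestor, diff_positions[to_s], rng)
        t_arr = _mutate_exact(ancestor, diff_positions[~to_s], rng)
        s_arr = _apply_indels(s_arr, config.indel_rate, rng)
        t_arr = _apply_indels(t_arr, config.indel_rate, rng)
        if config.indel_rate == 0:
            st_identity = 100.0 * (1.0 - n_diff / length)
        else:  # realized identity must be measured once indels shift coordinates
            from .seqcore import global_align, percent_identity

            st_identity = percent_identity(global_align(_decode(s_arr), _decode(t_arr)))
        truth.st_identities[family_id] = st_identity
        transcripts.append(
            Transcript(
                f"{family_id}_S", _decode(s_arr), Subgenome.S, AnnotationClass.TRANSCRIPTION_FACTOR
            )
        )
        transcripts.append(
            Transcript(
                f"{family_id}_T", _decode(t_arr), Subgenome.T, AnnotationClass.TRANSCRIPTION_FACTOR
            )
        )
        if fam <= config.n_paralog_families:
            plo, phi = config.paralog_identity_range
            for j in range(1, config.n_paralogs_per_family + 1):
                ident = rng.uniform(plo, phi)
                n_p = round((1.0 - ident) * len(s_arr))
                pos = rng.choice(len(s_arr), size=n_p, replace=False)
                p_arr = _mutate_exact(s_arr, pos, rng)
                pid = f"{family_id}_para{j}"
                # at paralog-level divergence the optimal alignment may place a
                # few gaps that raise measured identity above the planted
                # substitution fraction, so record what an aligner measures
                from .seqcore import global_align, percent_identity

                truth.paralog_identities[f"{family_id}_S~{pid}"] = percent_identity(
                    global_align(_decode(s_arr), _decode(p_arr))
                )
                transcripts.append(
                    Transcript(pid, _decode(p_arr), Subgenome.NONE, AnnotationClass.OTHER)
                )

    n_short = round(config.short_contig_fraction * config.n_background)
    slo, shi = config.short_contig_length_range
    class_pool = [AnnotationClass.TRANSCRIPTION_FACTOR, AnnotationClass.UNKNOWN, AnnotationClass.OTHER]
    for i in range(1, config.n_background + 1):
        if i <= n_short:
            length = int(rng.integers(slo, shi + 1))
        else:
            length = int(rng.integers(lo, hi + 1))
        cls = class_pool[int(rng.integers(0, 3))]
        transcripts.append(
            Transcript(f"bg{i:04d}", _decode(_random_sequence(rng, length)), Subgenome.NONE, cls)
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_TISSUES = ("ea", "ve", "control")


def _nd_prob(config: SimConfig, tissue: str) -> float:
    nd = config.nd_probability
    if isinstance(nd, Mapping):
        return float(nd.get(tissue, 0.0))
    return float(nd)


def simulate_expression(
    transcriptome: Sequence[Transcript],
    config: SimConfig,
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[list[ExpressionRecord], GroundTruth]:
    """Expression tables with a known set of >= 10-fold tissue-enriched genes.

    Enriched genes are drawn (with probability ``enriched_fraction``) among
    genes that are screen-eligible by construction (length > 200 nt, class
    transcription factor or unknown), assigned EA or VE with equal
    probability, and given a tissue read count of ``ceil(control_count *
    fold)`` with ``fold = max(10, exp(N(mean_log, sd_log)))`` — so the
    recomputed RPKM ratio is >= 10 by construction.  Control counts are
    floored at one read (a detected gene has at least one read; a sampled
    zero would conflate "measured 0" with ND).  ND masking, when enabled,
    never hits the enriched tissue of an enriched gene.
    """
    if not transcriptome:
        raise SimConfigError("transcriptome is empty")
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    truth = ground_truth if ground_truth is not None else GroundTruth(effect_table=config.effects())
    records: list[ExpressionRecord] = []
    eligible_classes = {AnnotationClass.TRANSCRIPTION_FACTOR, AnnotationClass.UNKNOWN}
    for t in transcriptome:
        eligible = t.length_nt > 200 and t.annotation_class in eligible_classes
        enriched = eligible and (rng.random() < config.enriched_fraction)
        tissue = ("EA" if rng.random() < 0.5 else "VE") if enriched else None
        truth.enrichment[t.id] = tissue

        control_count = max(1, int(rng.poisson(math.exp(rng.normal(config.control_mean_log, config.control_sd_log)))))
        counts = {}
        for zone in ("ea", "ve"):
            base = rng.poisson(control_count * math.exp(rng.normal(0.0, 0.25)))
            counts[zone] = int(base)
        counts["control"] = control_count
        if enriched:
            fold = max(10.0, float(np.exp(rng.normal(config.fold_distribution.mean_log, config.fold_distribution.sd_log))))
            truth.enriched_fold[t.id] = fold
            zone = tissue.lower()
            counts[zone] = int(math.ceil(control_count * fold))

        rpkm: dict[str, Optional[float]] = {
            z: compute_rpkm(counts[z], t.length_nt, config.total_mapped) for z in _TISSUES
        }
        for z in _TISSUES:
            if enriched and tissue is not None and z == tissue.lower():
                continue  # planted enrichment is never masked
            if rng.random() < _nd_prob(config, z):
                rpkm[z] = None
                counts[z] = 0
        records.append(
            ExpressionRecord(
                gene_id=t.id,
                length_nt=t.length_nt,
                ea=rpkm["ea"],
                ve=rpkm["ve"],
                control=rpkm["control"],
                annotation_class=t.annotation_class,
                counts=dict(counts),
                total_mapped={z: config.total_mapped for z in _TISSUES},
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Overdispersed counts: NB with variance mu + (cv*mu)^2; Poisson when cv=0."""
    if mean == 0.0:
        return np.zeros(size, dtype=np.int64)
    if cv == 0.0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / (cv * cv)  # var = mu + mu^2/r
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _draw_weights(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal weights with arithmetic mean ``mean`` and coefficient of variation ``cv``."""
    if mean == 0.0:
        return np.zeros(size)
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


_TRAIT_KIND = {
    Trait.PRIMARY_N: ("primary", "count", "primary_n"),
    Trait.PRIMARY_WT: ("primary", "weight", "primary_wt"),
    Trait.SECONDARY_N: ("secondary", "count", "secondary_n"),
    Trait.SECONDARY_WT: ("secondary", "weight", "secondary_wt"),
    Trait.TERTIARY_N: ("tertiary", "count", "tertiary_n"),
    Trait.TERTIARY_WT: ("tertiary", "weight", "tertiary_wt"),
    Trait.EXPRESSION: ("expression", "weight", "expression"),
}


def simulate_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Per-plant phenotype records for every construct in the effect table.

    Null-segregant plants are drawn around the wild-type baselines; transgenic
    plants around baseline x construct multiplier.  Shoot counts and weights
    are drawn independently per trait (each trait then contributes an
    independent test to the effective-gene call).
    """
    config.validate()
    if config.n_lines_per_construct < 2:
        raise SimConfigError("n_lines_per_construct must be >= 2")
    if config.n_plants_per_line < 2:
        raise SimConfigError("n_plants_per_line must be >= 2")
    rng = config.rng(_STREAM_PHENOTYPES)
    effects = config.effects()
    base = config.baseline_means
    n = config.n_plants_per_line
    rows: dict[str, list] = {c: [] for c in PHENOTYPE_COLUMNS}

    def emit(construct: str, line: str, genotype: Genotype, trait: Trait, values: np.ndarray) -> None:
        for plant, v in enumerate(values, start=1):
            rows["construct_id"].append(construct)
            rows["line_id"].append(line)
            rows["genotype"].append(genotype.value)
            rows["plant_id"].append(f"{line}_{genotype.value}_{plant}")
            rows["trait"].append(trait.value)
            rows["value"].append(float(v))

    for construct, mult in effects.items():
        order_mult = {
            "primary": mult.primary,
            "secondary": mult.secondary,
            "tertiary": mult.tertiary,
            "expression": mult.expression,
        }
        for line_idx in range(1, config.n_lines_per_construct + 1):
            line = f"{construct}_L{line_idx}"
            for trait, (order, kind, attr) in _TRAIT_KIND.items():
                mean = getattr(base, attr)
                for genotype, m in (
                    (Genotype.NULL_SEGREGANT, 1.0),
                    (Genotype.TRANSGENIC, order_mult[order]),
                ):
                    if kind == "count":
                        values = _draw_counts(rng, mean * m, config.noise_cv, n)
                    else:
                        values = _draw_weights(rng, mean * m, config.noise_cv, n)
                    emit(construct, line, genotype, trait, values)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Off-target planting
# ---------------------------------------------------------------------------

def plant_offtarget(
    transcriptome: Sequence[Transcript],
    trigger_sequence: str,
    match_length: int,
    rng: np.random.Generator | int,
    eligible_ids: Optional[set[str]] = None,
) -> tuple[list[Transcript], PlantedMatch]:
    """Copy an exact trigger substring into a background transcript.

    A random trigger substring of exactly ``match_length`` nt (sense or
    antisense, recorded) replaces a same-length stretch of a randomly chosen
    transcript.  The flanking bases are forced to mismatch the trigger's
    neighbouring bases so the planted run is maximal at exactly
    ``match_length``.  Returns the modified transcriptome (new objects; input
    untouched) and the planting record.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng([rng, _STREAM_PLANTING])
    trigger_sequence = trigger_sequence.upper()
    if match_length > len(trigger_sequence):
        raise SimConfigError("match_length exceeds trigger length")
    if match_length < 1:
        raise SimConfigError("match_length must be >= 1")
    candidates = [
        (i, t)
        for i, t in enumerate(transcriptome)
        if (eligible_ids is None or t.id in eligible_ids)
        and t.length_nt >= match_length + 2
        and t.subgenome is Subgenome.NONE
    ]
    if not candidates:
        raise SimConfigError("no background transcript long enough to receive the planting")
    idx, host = candidates[int(rng.integers(0, len(candidates)))]
    trig_start = int(rng.integers(0, len(trigger_sequence) - match_length + 1))
    trig_end = trig_start + match_length
    segment = trigger_sequence[trig_start:trig_end]
    strand = "sense" if rng.random() < 0.5 else "antisense"
    insert = segment if strand == "sense" else reverse_complement(segment)
    pos = int(rng.integers(1, host.length_nt - match_length))  # leave both flanks
    seq = list(host.sequence)
    seq[pos : pos + match_length] = insert

    def _mismatch(forbidden: set[str]) -> str:
        pool = [b for b in "ACGT" if b not in forbidden]
        return pool[int(rng.integers(0, len(pool)))]

    # forbid the bases that would extend the planted run on either strand
    if strand == "sense":
        left_ext = trigger_sequence[trig_start - 1] if trig_start > 0 else None
        right_ext = trigger_sequence[trig_end] if trig_end < len(trigger_sequence) else None
    else:
        right_ext = (
            reverse_complement(trigger_sequence[trig_start - 1]) if trig_start > 0 else None
        )
        left_ext = (
            reverse_complement(trigger_sequence[trig_end]) if trig_end < len(trigger_sequence) else None
        )
    if left_ext is not None:
        seq[pos - 1] = _mismatch({left_ext})
    if right_ext is not None:
        seq[pos + match_length] = _mismatch({right_ext})

    new_host = Transcript(host.id, "".join(seq), host.subgenome, host.annotation_class)
    out = list(transcriptome)
    out[idx] = new_host
    record = PlantedMatch(
        transcript_id=host.id,
        start=pos,
        end=pos + match_length,
        strand=strand,
        trigger_start=trig_start,
        trigger_end=trig_end,
    )
    return out, record


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_expression_tsv(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "length_nt": r.length_nt,
            "ea": "ND" if r.ea is None else f"{r.ea:.4f}",
            "ve": "ND" if r.ve is None else f"{r.ve:.4f}",
            "control": "ND" if r.control is None else f"{r.control:.4f}",
            "class": r.annotation_class.value,
        }
        if r.counts:
            for z in _TISSUES:
                row[f"count_{z}"] = r.counts[z]
        if r.total_mapped:
            for z in _TISSUES:
                row[f"total_{z}"] = r.total_mapped[z]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "enrichment": truth.enrichment,
        "enriched_fold": truth.enriched_fold,
        "st_identities": truth.st_identities,
        "paralog_identities": truth.paralog_identities,
        "planted_matches": [
            {
                "transcript_id": p.transcript_id,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "trigger_start": p.trigger_start,
                "trigger_end": p.trigger_end,
            }
            for p in truth.planted_matches
        ],
        "effect_table": {
            name: {
                "primary_mult": m.primary,
                "secondary_mult": m.secondary,
                "tertiary_mult": m.tertiary,
                "expression_mult": m.expression,
            }
            for name, m in truth.effect_table.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
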