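"""Relative-effect phenotype statistics for knock-down and mutant lines.

Each RNAi construct is represented by several independent single-locus
transformant lines.  Within a line, transgenic plants are compared with their
null-segregant siblings: the *relative effect* for a trait is

    mean(transgenic values) / mean(null-segregant values)

computed per line.  The per-line relative values (typically three, one per
line) are then tested against 1.0 with a two-sided one-sample t-test; a
construct is called *effective* when, for secondary-shoot number and/or
weight, the test rejects at ``alpha`` (default 0.01) AND the mean relative
value is below 1 (a reduction, not an increase).

Degenerate-variance convention: when the per-line relative values have zero
standard deviation, the p-value is defined as 0 when the mean differs from
the null value and 1 when it equals it.  This is the limit of the standard
test as sd -> 0+ and is required to score all-zero suppression (e.g. a
construct whose transgenic plants produce no secondary shoots at all).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Genotype",
    "Trait",
    "TTestResult",
    "EffectSummary",
    "PhenotypeError",
    "relative_effect",
    "summarize_construct",
    "one_sample_ttest",
    "two_sample_ttest",
    "line_relative_effects",
    "effect_summaries",
    "summaries_from_stats",
    "call_effective_genes",
    "read_phenotype_tsv",
    "write_summary_tsv",
    "validate_phenotype_table",
    "PHENOTYPE_COLUMNS",
    "DEFAULT_CALL_TRAITS",
]

PHENOTYPE_COLUMNS = ["construct_id", "line_id", "genotype", "plant_id", "trait", "value"]


class PhenotypeError(ValueError):
    """Raised on malformed phenotype tables or invalid statistics inputs."""


class Genotype(str, enum.Enum):
    TRANSGENIC = "transgenic"
    NULL_SEGREGANT = "null_segregant"
    MUTANT = "mutant"
    WILD_TYPE = "wild_type"


class Trait(str, enum.Enum):
    EXPRESSION = "expression"
    PRIMARY_N = "primary_n"
    PRIMARY_WT = "primary_wt"
    SECONDARY_N = "secondary_n"
    SECONDARY_WT = "secondary_wt"
    TERTIARY_N = "tertiary_n"
    TERTIARY_WT = "tertiary_wt"


DEFAULT_CALL_TRAITS = (Trait.SECONDARY_N, Trait.SECONDARY_WT)

#: genotype pairs treated as (treated, control)
_CONTROL_OF = {
    Genotype.TRANSGENIC: Genotype.NULL_SEGREGANT,
    Genotype.MUTANT: Genotype.WILD_TYPE,
}


@dataclass
class TTestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    flavor: str  # one_sample | two_sample_pooled | two_sample_welch


@dataclass
class EffectSummary:
    """Construct-level relative effect for one trait (mean ± SD over lines)."""

    construct_id: str
    trait: Trait
    relative_mean: float  # NaN marks "not calculable" (control mean was 0)
    relative_sd: float
    n_lines: int
    p_value: Optional[float]
    significant_reduction: bool

    @property
    def calculable(self) -> bool:
        return not math.isnan(self.relative_mean)


def relative_effect(
    transgenic_values: Sequence[float], null_values: Sequence[float]
) -> float:
    """mean(treated) / mean(control); NaN ("not calculable") when control mean is 0."""
    t = np.asarray(transgenic_values, dtype=float)
    n = np.asarray(null_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise PhenotypeError("relative_effect needs non-empty groups")
    null_mean = n.mean()
    if null_mean == 0.0:
        return math.nan
    return float(t.mean() / null_mean)


def summarize_construct(per_line_ratios: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean and sample SD (n-1 denominator) of per-line relative values."""
    r = np.asarray(per_line_ratios, dtype=float)
    if r.size == 0:
        raise PhenotypeError("no per-line ratios to summarize")
    if r.size == 1:
        warnings.warn("single line: SD reported as 0", stacklevel=2)
        return float(r[0]), 0.0, 1
    return float(r.mean()), float(r.std(ddof=1)), int(r.size)


def one_sample_ttest(
    values: Optional[Sequence[float]] = None,
    mu: float = 1.0,
    *,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
    n: Optional[int] = None,
) -> TTestResult:
    """Two-sided one-sample t-test against ``mu``, from raw values or (mean, sd, n).

    The sd = 0 case follows the degenerate convention documented in the
    module docstring.
    """
    if values is not None:
        mean, sd, n = summarize_construct(values)
    if mean is None or sd is None or n is None:
        raise PhenotypeError("provide either raw values or mean, sd and n")
    if n < 2:
        raise PhenotypeError("one-sample t-test needs n >= 2")
    df = n - 1
    if sd == 0.0:
        if mean == mu:
            return TTestResult(0.0, df, 1.0, "one_sample")
        return TTestResult(math.copysign(math.inf, mean - mu), df, 0.0, "one_sample")
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), "one_sample")


def two_sample_ttest(
    group_a: Sequence[float], group_b: Sequence[float], flavor: str = "welch"
) -> TTestResult:
    """Two-sided two-sample t-test, Welch (default) or pooled-variance."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PhenotypeError("two-sample t-test needs n >= 2 per group")
    if flavor not in {"welch", "pooled"}:
        raise PhenotypeError(f"unknown t-test flavor {flavor!r}")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # both groups constant: equal means -> p = 1, else degenerate rejection
        if a.mean() == b.mean():
            return TTestResult(0.0, a.size + b.size - 2, 1.0, f"two_sample_{flavor}")
        return TTestResult(
            math.copysign(math.inf, a.mean() - b.mean()),
            a.size + b.size - 2,
            0.0,
            f"two_sample_{flavor}",
        )
    res = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
    df = res.df if hasattr(res, "df") else (a.size + b.size - 2)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), f"two_sample_{flavor}")


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise PhenotypeError(f"phenotype table missing columns {sorted(missing)}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise PhenotypeError("phenotype values must be finite")
    if (table["value"] < 0).any():
        raise PhenotypeError("phenotype values must be >= 0")
    # every (construct, line) must carry both genotype classes of a pair
    for (construct, line), grp in table.groupby(["construct_id", "line_id"]):
        genos = set(grp["genotype"])
        ok = any(
            treated.value in genos and control.value in genos
            for treated, control in _CONTROL_OF.items()
        )
        if not ok:
            raise PhenotypeError(
                f"construct {construct!r} line {line!r}: needs both genotype classes"
            )
    return table


def line_relative_effects(
    table: pd.DataFrame, construct_id: str, trait: Trait
) -> list[float]:
    """Per-line relative effects (treated over control) for one construct/trait."""
    sub = table[(table["construct_id"] == construct_id) & (table["trait"] == trait.value)]
    if sub.empty:
        raise PhenotypeError(f"construct {construct_id!r}: no rows for trait {trait.value}")
    ratios = []
    for line, grp in sub.groupby("line_id", sort=True):
        genos = set(grp["genotype"])
        for treated, control in _CONTROL_OF.items():
            if treated.value in genos and control.value in genos:
                ratios.append(
                    relative_effect(
                        grp.loc[grp["genotype"] == treated.value, "value"].to_numpy(),
                        grp.loc[grp["genotype"] == control.value, "value"].to_numpy(),
                    )
                )
                break
        else:
            raise PhenotypeError(
                f"construct {construct_id!r} line {line!r}: missing genotype pair"
            )
    return ratios


def _summary_frame(table: pd.DataFrame, mu: float, alpha: float) -> pd.DataFrame:
    """Vectorized per-(construct, trait) summaries of per-line relative effects."""
    geno_means = (
        table.groupby(["construct_id", "trait", "line_id", "genotype"], sort=True)["value"]
        .mean()
        .unstack("genotype")
    )
    treated = pd.Series(np.nan, index=geno_means.index)
    control = pd.Series(np.nan, index=geno_means.index)
    for tr, co in _CONTROL_OF.items():
        if tr.value in geno_means.columns and co.value in geno_means.columns:
            mask = geno_means[tr.value].notna() & geno_means[co.value].notna()
            treated[mask] = geno_means.loc[mask, tr.value]
            control[mask] = geno_means.loc[mask, co.value]
    ratio = treated / control.replace(0.0, np.nan)  # control mean 0 -> NC
    ratio[control == 0.0] = np.nan
    g = ratio.groupby(level=["construct_id", "trait"])
    out = pd.DataFrame(
        {
            "relative_mean": g.mean(),
            "relative_sd": g.std(ddof=1).fillna(0.0),
            "n_lines": g.count(),
            "nc": g.apply(lambda s: bool(s.isna().any())),
        }
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            out["relative_sd"] > 0,
            (out["relative_mean"] - mu) / (out["relative_sd"] / np.sqrt(out["n_lines"])),
            np.where(out["relative_mean"] == mu, 0.0, np.inf * np.sign(out["relative_mean"] - mu)),
        )
        p = 2.0 * stats.t.sf(np.abs(t), out["n_lines"] - 1)
    p = np.where(out["relative_sd"] > 0, p, np.where(out["relative_mean"] == mu, 1.0, 0.0))
    out["statistic"] = t
    out["p_value"] = p
    out["significant_reduction"] = (
        (out["p_value"] < alpha) & (out["relative_mean"] < mu) & ~out["nc"]
    )
    out.loc[out["nc"], ["relative_mean", "relative_sd"]] = np.nan
    out.loc[out["nc"], "p_value"] = np.nan
    return out


def effect_summaries(
    table: pd.DataFrame,
    traits: Optional[Sequence[Trait]] = None,
    mu: float = 1.0,
    alpha: float = 0.01,
) -> list[EffectSummary]:
    """Relative-effect summaries (mean ± SD over lines, t-test vs ``mu``) per construct/trait."""
    validate_phenotype_table(table)
    frame = _summary_frame(table, mu=mu, alpha=alpha)
    if traits is not None:
        keep = {t.value for t in traits}
        frame = frame[frame["trait"].isin(keep)]
    return [
        EffectSummary(
            construct_id=row.construct_id,
            trait=Trait(row.trait),
            relative_mean=row.relative_mean,
            relative_sd=row.relative_sd,
            n_lines=int(row.n_lines),
            p_value=None if np.isnan(row.p_value) else float(row.p_value),
            significant_reduction=bool(row.significant_reduction),
        )
        for row in frame.itertuples(index=False)
    ]


def summaries_from_stats(
    stats_table: pd.DataFrame, mu: float = 1.0, alpha: float = 0.01
) -> list[EffectSummary]:
    """Build summaries from already-summarized (construct, trait, mean, sd, n) rows.

    This is the entry point for reproducing printed tables, where only the
    construct-level mean ± SD over lines is available.
    """
    required = {"construct", "trait", "mean", "sd", "n"}
    missing = required - set(stats_table.columns)
    if missing:
        raise PhenotypeError(f"summary table missing columns {sorted(missing)}")
    out = []
    for row in stats_table.to_dict("records"):
        res = one_sample_ttest(mean=float(row["mean"]), sd=float(row["sd"]), n=int(row["n"]), mu=mu)
        out.append(
            EffectSummary(
                construct_id=str(row["construct"]),
                trait=Trait(row["trait"]),
                relative_mean=float(row["mean"]),
                relative_sd=float(row["sd"]),
                n_lines=int(row["n"]),
                p_value=res.p_value,
                significant_reduction=bool(res.p_value < alpha and row["mean"] < mu),
            )
        )
    return out


def call_effective_genes(
    summaries: Iterable[EffectSummary],
    traits: Sequence[Trait] = DEFAULT_CALL_TRAITS,
    alpha: float = 0.01,
) -> set[str]:
    """Constructs with a significant reduction (p < alpha, mean < 1) in any listed trait.

    Raises when a construct lacks a row for one of the requested traits.
    """
    traits = tuple(traits)
    by_construct: dict[str, dict[Trait, EffectSummary]] = {}
    for s in summaries:
        by_construct.setdefault(s.construct_id, {})[s.trait] = s
    effective: set[str] = set()
    for construct, rows in by_construct.items():
        for trait in traits:
            if trait not in rows:
                raise PhenotypeError(
                    f"construct {construct!r}: missing summary for trait {trait.value}"
                )
            s = rows[trait]
            if (
                s.calculable
                and s.p_value is not None
                and s.p_value < alpha
                and s.relative_mean < 1.0
            ):
                effective.add(construct)
                break
    return effective


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_phenotype_table(df)


def write_summary_tsv(summaries: Iterable[EffectSummary], path: str | Path) -> None:
    rows = [
        {
            "construct": s.construct_id,
            "trait": s.trait.value,
            "relative_mean": "NC" if not s.calculable else round(s.relative_mean, 4),
            "relative_sd": "NC" if not s.calculable else round(s.relative_sd, 4),
            "n_lines": s.n_lines,
            "p_value": "" if s.p_value is None else f"{s.p_value:.6g}",
            "significant_reduction": s.significant_reduction,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
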