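"""Pipeline orchestration: simulate -> screen -> design -> offtarget -> phenostats.

A run is driven by a :class:`RunConfig` (optionally parsed from a flat
``key = value`` text file), writes every stage artifact under one output
directory, and produces a :class:`RunReport` whose manifest maps each output
file to its SHA-256 digest — so a rerun with the same config can be checked
for bit-identical outputs.  Report numbers are recomputed from the artifacts
on disk, never cached, so the report and the files cannot disagree.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
import pandas as pd

from . import enrichment_screen as screen
from . import offtarget_scan as offtarget
from . import phenotype_stats as pheno
from . import synthetic_data as synth
from . import trigger_design as design
from .seqcore import Transcript, read_fasta, write_fasta

__all__ = [
    "RunConfig",
    "RunReport",
    "ConfigError",
    "StageError",
    "parse_config_file",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger("suckerscreen")

ALL_STAGES = ("simulate", "screen", "design", "offtarget", "phenostats")


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value, missing path)."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    outdir: Path = Path("suckerscreen_run")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation scale
    n_target_pairs: int = 36
    n_paralog_families: int = 12
    n_background: int = 300
    st_identity_target: float = 0.954
    enriched_fraction: float = 0.08
    # screen
    min_fold: float = 10.0
    min_length_nt: int = 200
    # design
    trigger_length_nt: int = 430
    min_st_identity_pct: float = 90.0
    max_paralog_identity_pct: float = 70.0
    # offtarget
    k: int = 22
    # phenostats
    alpha: float = 0.01
    log_level: str = "INFO"

    def sim_config(self) -> synth.SimConfig:
        return synth.SimConfig(
            seed=self.seed,
            n_target_pairs=self.n_target_pairs,
            n_paralog_families=self.n_paralog_families,
            n_background=self.n_background,
            st_identity_target=self.st_identity_target,
            enriched_fraction=self.enriched_fraction,
            effect_table=synth.default_effect_table(n_constructs=self.n_target_pairs),
        )

    def design_config(self) -> design.DesignConfig:
        return design.DesignConfig(
            trigger_length_nt=self.trigger_length_nt,
            min_st_identity_pct=self.min_st_identity_pct,
            max_paralog_identity_pct=self.max_paralog_identity_pct,
        )

    def as_flat_dict(self) -> dict[str, str]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "stages":
                v = ",".join(v)
            out[f.name] = str(v)
        return out


_BOOL = {"true": True, "false": False}


def parse_config_file(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    values: dict[str, object] = {}
    known = {f.name: f for f in fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict[str, object] = {}
    for key, val in values.items():
        f = known[key]
        try:
            if key == "stages":
                if isinstance(val, str):
                    val = tuple(s.strip() for s in val.split(",") if s.strip())
                bad = set(val) - set(ALL_STAGES)
                if bad:
                    raise ValueError(f"unknown stages {sorted(bad)}")
                kwargs[key] = tuple(val)
            elif key == "outdir":
                kwargs[key] = Path(val)
            elif f.type in ("int", int):
                kwargs[key] = int(val)
            elif f.type in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: {exc}") from exc
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunReport:
    config: dict[str, str]
    stages_run: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    summary: dict[str, object] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(report: RunReport, outdir: Path, *paths: Path) -> None:
    for p in paths:
        report.manifest[str(p.relative_to(outdir))] = _sha256(p)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order; abort on the first failure."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.as_flat_dict())

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, outdir, report)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        report.stages_run.append(stage)
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    return report


def _stage_simulate(config: RunConfig, outdir: Path, report: RunReport) -> None:
    sim = config.sim_config()
    transcripts, truth = synth.simulate_transcriptome(sim)
    records, truth = synth.simulate_expression(transcripts, sim, truth)
    phenotypes = synth.simulate_phenotypes(sim)

    fasta = outdir / "transcriptome.fasta"
    write_fasta(transcripts, fasta)
    pairs = outdir / "pairs.tsv"
    rows = []
    for fam in range(1, sim.n_target_pairs + 1):
        fid = f"fam{fam:02d}"
        paralogs = [
            f"{fid}_para{j}" for j in range(1, sim.n_paralogs_per_family + 1)
        ] if fam <= sim.n_paralog_families else []
        rows.append(
            {"family_id": fid, "s_id": f"{fid}_S", "t_id": f"{fid}_T", "paralog_ids": ",".join(paralogs)}
        )
    pd.DataFrame(rows).to_csv(pairs, sep="\t", index=False)
    expr = outdir / "expression.tsv"
    synth.write_expression_tsv(records, expr)
    phen = outdir / "phenotypes.tsv"
    synth.write_phenotype_tsv(phenotypes, phen)
    gt = outdir / "ground_truth.json"
    synth.write_ground_truth_json(truth, gt)
    _register(report, outdir, fasta, pairs, expr, phen, gt)
    report.summary["n_transcripts"] = len(transcripts)
    report.summary["n_expression_records"] = len(records)


def _stage_screen(config: RunConfig, outdir: Path, report: RunReport) -> None:
    records = screen.read_expression_tsv(outdir / "expression.tsv")
    candidates = screen.select_candidates(
        records, min_fold=config.min_fold, min_length_nt=config.min_length_nt
    )
    out = outdir / "candidates.tsv"
    screen.write_candidates_tsv(candidates, out)
    _register(report, outdir, out)
    report.summary["n_candidates"] = len(candidates)
    report.summary["n_candidates_ea"] = sum(
        1 for c in candidates if c.assigned_tissue is screen.Tissue.EA
    )
    report.summary["n_candidates_ve"] = sum(
        1 for c in candidates if c.assigned_tissue is screen.Tissue.VE
    )


def _stage_design(config: RunConfig, outdir: Path, report: RunReport) -> None:
    transcripts = {t.id: t for t in read_fasta(outdir / "transcriptome.fasta")}
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t", keep_default_na=False)
    dconf = config.design_config()
    triggers: list[Transcript] = []
    rows = []
    for row in pairs.to_dict("records"):
        pair = design.HomoeologPair(
            transcripts[row["s_id"]], transcripts[row["t_id"]], row["family_id"]
        )
        paralogs = [transcripts[p] for p in str(row["paralog_ids"]).split(",") if p]
        cand = design.design_trigger(pair, paralogs, dconf)
        triggers.append(Transcript(f"trigger_{cand.family_id}", cand.sequence))
        rows.append(
            {
                "family_id": cand.family_id,
                "source_gene_id": cand.source_gene_id,
                "start": cand.start,
                "end": cand.end,
                "st_identity_pct": round(cand.st_identity_pct, 3),
                "max_paralog_identity_pct": round(cand.max_paralog_identity_pct, 3),
                "paralog_breakdown": ";".join(
                    f"{k}={v:.2f}" for k, v in sorted(cand.paralog_identities.items())
                ),
            }
        )
    fa = outdir / "triggers.fasta"
    write_fasta(triggers, fa)
    rep = outdir / "trigger_report.tsv"
    pd.DataFrame(rows).to_csv(rep, sep="\t", index=False)
    _register(report, outdir, fa, rep)
    stats = design.summarize_triggers(
        [
            design.TriggerCandidate(
                r["family_id"], r["source_gene_id"], r["start"], r["end"],
                transcripts[r["source_gene_id"]].sequence[r["start"]:r["end"]],
                r["st_identity_pct"], r["max_paralog_identity_pct"],
            )
            for r in rows
        ]
    )
    report.summary["n_triggers"] = stats["n"]
    report.summary["mean_trigger_length_nt"] = stats["mean_length_nt"]
    report.summary["mean_trigger_st_identity_pct"] = stats["mean_st_identity_pct"]


def _stage_offtarget(config: RunConfig, outdir: Path, report: RunReport) -> None:
    transcripts = read_fasta(outdir / "transcriptome.fasta")
    triggers = read_fasta(outdir / "triggers.fasta")
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t", keep_default_na=False)
    exclude_by_family = {
        row["family_id"]: {row["s_id"], row["t_id"]} for row in pairs.to_dict("records")
    }
    index = offtarget.build_index(transcripts, k=config.k)
    all_hits: list[offtarget.OffTargetHit] = []
    verdicts: dict[str, offtarget.Verdict] = {}
    n_hits: dict[str, int] = {}
    for trig in triggers:
        family = trig.id.removeprefix("trigger_")
        hits = offtarget.scan_trigger(
            trig, index, transcripts, exclude_ids=exclude_by_family.get(family, set())
        )
        verdict, hits = offtarget.classify_trigger(trig, hits)
        verdicts[trig.id] = verdict
        n_hits[trig.id] = len(hits)
        all_hits.extend(hits)
    hits_path = outdir / "offtarget_hits.tsv"
    offtarget.write_hits_tsv(all_hits, hits_path)
    verd_path = outdir / "offtarget_verdicts.tsv"
    offtarget.write_verdicts_tsv(verdicts, n_hits, verd_path)
    _register(report, outdir, hits_path, verd_path)
    report.summary["n_offtarget_hits"] = len(all_hits)
    report.summary["n_clean_triggers"] = sum(
        1 for v in verdicts.values() if v is offtarget.Verdict.CLEAN
    )


def _stage_phenostats(config: RunConfig, outdir: Path, report: RunReport) -> None:
    table = pheno.read_phenotype_tsv(outdir / "phenotypes.tsv")
    summaries = pheno.effect_summaries(table, alpha=config.alpha)
    out = outdir / "effect_summaries.tsv"
    pheno.write_summary_tsv(summaries, out)
    effective = pheno.call_effective_genes(summaries, alpha=config.alpha)
    calls = outdir / "effective_genes.tsv"
    pd.DataFrame({"construct": sorted(effective)}).to_csv(calls, sep="\t", index=False)
    _register(report, outdir, out, calls)
    report.summary["n_effective_genes"] = len(effective)
    report.summary["effective_genes"] = sorted(effective)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "design": _stage_design,
    "offtarget": _stage_offtarget,
    "phenostats": _stage_phenostats,
}


def write_report(report: RunReport, path: str | Path) -> str:
    """Human-readable run summary; also returned as a string."""
    lines = ["# suckerscreen run report", "", "## configuration"]
    lines += [f"{k} = {v}" for k, v in report.config.items()]
    lines += ["", "## stages run", ", ".join(report.stages_run) or "(none)"]
    lines += ["", "## summary"]
    lines += [f"{k}: {v}" for k, v in report.summary.items()] or ["(empty)"]
    lines += ["", "## manifest (sha256)"]
    lines += [f"{digest}  {name}" for name, digest in sorted(report.manifest.items())]
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
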