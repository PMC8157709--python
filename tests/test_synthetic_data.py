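import math

import numpy as np
import pytest

from suckerscreen.enrichment_screen import select_candidates
from suckerscreen.phenotype_stats import Trait, call_effective_genes, effect_summaries
from suckerscreen.seqcore import global_align, percent_identity, write_fasta
from suckerscreen.synthetic_data import (
    EffectMultipliers,
    SimConfig,
    SimConfigError,
    simulate_expression,
    simulate_phenotypes,
    simulate_transcriptome,
)

CALL_TRAITS = [Trait.SECONDARY_N, Trait.SECONDARY_WT]


def small_config(**kw):
    defaults = dict(
        seed=11,
        n_target_pairs=6,
        n_paralog_families=2,
        n_background=30,
        transcript_length_range=(600, 900),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_degenerate_length_range_rejected(self):
        with pytest.raises(SimConfigError, match="min > max"):
            SimConfig(transcript_length_range=(500, 400))

    def test_degenerate_paralog_range_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(paralog_identity_range=(0.8, 0.5))

    def test_fractions_bounded(self):
        with pytest.raises(SimConfigError):
            SimConfig(enriched_fraction=1.5)

    def test_negative_multiplier_rejected_zero_allowed(self):
        with pytest.raises(SimConfigError):
            EffectMultipliers(secondary=-0.1)
        assert EffectMultipliers(secondary=0.0).secondary == 0.0


class TestSimulateTranscriptome:
    def test_full_identity_target_gives_identical_homoeologs(self):
        transcripts, truth = simulate_transcriptome(small_config(st_identity_target=1.0))
        byid = {t.id: t for t in transcripts}
        for fam, ident in truth.st_identities.items():
            assert ident == 100.0
            assert byid[f"{fam}_S"].sequence == byid[f"{fam}_T"].sequence

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        paths = []
        for i in (1, 2):
            transcripts, _ = simulate_transcriptome(small_config())
            p = tmp_path / f"run{i}.fasta"
            write_fasta(transcripts, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_realized_st_identity_matches_alignment_oracle(self):
        """50 pairs at 95.4% / 1500 nt: mean realized identity inside [93.4, 97.4],
        each pair verified against the full alignment."""
        config = SimConfig(
            seed=5,
            n_target_pairs=50,
            n_paralog_families=0,
            n_background=0,
            transcript_length_range=(1500, 1500),
        )
        transcripts, truth = simulate_transcriptome(config)
        byid = {t.id: t for t in transcripts}
        realized = []
        for fam, recorded in truth.st_identities.items():
            aligned = percent_identity(
                global_align(byid[f"{fam}_S"].sequence, byid[f"{fam}_T"].sequence)
            )
            assert aligned == pytest.approx(recorded, abs=0.5)
            realized.append(aligned)
        assert 93.4 <= np.mean(realized) <= 97.4

    def test_recorded_paralog_identities_agree_with_alignment(self):
        transcripts, truth = simulate_transcriptome(small_config())
        byid = {t.id: t for t in transcripts}
        assert truth.paralog_identities
        for key, recorded in truth.paralog_identities.items():
            target, paralog = key.split("~")
            aligned = percent_identity(
                global_align(byid[target].sequence, byid[paralog].sequence)
            )
            assert aligned == pytest.approx(recorded, abs=0.5)

    def test_short_contigs_present_at_configured_fraction(self):
        transcripts, _ = simulate_transcriptome(
            small_config(n_background=100, short_contig_fraction=0.10)
        )
        short = [t for t in transcripts if t.id.startswith("bg") and t.length_nt <= 200]
        assert len(short) == 10


class TestSimulateExpression:
    def test_zero_enriched_fraction_nothing_passes_screen(self):
        config = small_config(enriched_fraction=0.0, nd_probability=0.0)
        transcripts, truth = simulate_transcriptome(config)
        records, truth = simulate_expression(transcripts, config, truth)
        assert select_candidates(records) == []
        assert all(t is None for t in truth.enrichment.values())

    def test_enriched_gene_rpkm_ratio_recomputed_from_counts_is_at_least_10(self):
        from suckerscreen.enrichment_screen import compute_rpkm

        config = small_config(enriched_fraction=0.5)
        transcripts, truth = simulate_transcriptome(config)
        records, truth = simulate_expression(transcripts, config, truth)
        enriched = {g: t for g, t in truth.enrichment.items() if t}
        assert enriched
        for r in records:
            if r.gene_id not in enriched:
                continue
            zone = enriched[r.gene_id].lower()
            ratio = compute_rpkm(
                r.counts[zone], r.length_nt, r.total_mapped[zone]
            ) / compute_rpkm(r.counts["control"], r.length_nt, r.total_mapped["control"])
            assert ratio >= 10.0

    def test_nd_probability_one_for_control_blanks_every_control(self):
        config = small_config(nd_probability={"control": 1.0})
        transcripts, truth = simulate_transcriptome(config)
        records, _ = simulate_expression(transcripts, config, truth)
        assert all(r.control is None for r in records)

    def test_screen_recall_100pct_and_low_false_positive_rate(self):
        """With ND off, every planted enrichment survives the screen with the right
        tissue; background genes pass at < 1%."""
        config = SimConfig(
            seed=23, n_target_pairs=20, n_paralog_families=0, n_background=500,
            enriched_fraction=0.1, nd_probability=0.0,
        )
        transcripts, truth = simulate_transcriptome(config)
        records, truth = simulate_expression(transcripts, config, truth)
        selected = {c.gene_id: c.assigned_tissue.value for c in select_candidates(records)}
        planted = {g: t for g, t in truth.enrichment.items() if t}
        for gene, tissue in planted.items():
            assert selected.get(gene) == tissue
        false_pos = set(selected) - set(planted)
        eligible = len(records)
        assert len(false_pos) / eligible < 0.01

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_expression([], small_config())


class TestSimulatePhenotypes:
    def test_zero_multiplier_and_zero_noise_give_exactly_zero_counts(self):
        table = {"c1": EffectMultipliers(secondary=0.0)}
        config = small_config(effect_table=table, noise_cv=0.0)
        df = simulate_phenotypes(config)
        sub = df[(df["trait"] == "secondary_n") & (df["genotype"] == "transgenic")]
        assert (sub["value"] == 0.0).all()
        nulls = df[(df["trait"] == "secondary_n") & (df["genotype"] == "null_segregant")]
        assert (nulls["value"] > 0).any()

    def test_determinism(self):
        a = simulate_phenotypes(small_config())
        b = simulate_phenotypes(small_config())
        assert a.equals(b)

    def test_null_effective_call_rate_is_nominal(self):
        """All multipliers 1.0: the alpha=0.01 effective call fires at ~1%
        (1,000 null constructs, 99% binomial band)."""
        null_table = {f"c{i:03d}": EffectMultipliers() for i in range(100)}
        called = 0
        for seed in range(10):
            config = SimConfig(seed=seed, effect_table=null_table)
            summaries = effect_summaries(simulate_phenotypes(config), traits=CALL_TRAITS)
            called += len(call_effective_genes(summaries))
        rate = called / 1000
        half = 2.576 * math.sqrt(0.01 * 0.99 / 1000)
        assert 0.01 - half <= rate <= 0.01 + half

    def test_recall_of_strong_suppression_is_high(self):
        """secondary multiplier 0.13 at noise_cv 0.1 and 3 lines: recall >= 0.95
        over 200 simulated constructs."""
        table = {f"c{i:03d}": EffectMultipliers(secondary=0.13) for i in range(100)}
        recalled = 0
        for seed in range(2):
            config = SimConfig(seed=100 + seed, effect_table=table)
            summaries = effect_summaries(simulate_phenotypes(config), traits=CALL_TRAITS)
            recalled += len(call_effective_genes(summaries))
        assert recalled / 200 >= 0.95

    def test_too_few_lines_or_plants_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_phenotypes(small_config(n_lines_per_construct=1))
        with pytest.raises(SimConfigError):
            simulate_phenotypes(small_config(n_plants_per_line=1))
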