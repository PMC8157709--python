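import numpy as np
import pytest

from suckerscreen.seqcore import SequenceError, Subgenome, Transcript
from suckerscreen.trigger_design import (
    DesignConfig,
    HomoeologPair,
    NoValidTriggerError,
    design_trigger,
    homoeolog_window_scan,
    paralog_discrimination_scan,
    summarize_triggers,
)
from tests.conftest import make_pair
from tests.oracles import exhaustive_design, mutate, naive_slide_max_identity, random_dna

SMALL = DesignConfig(trigger_length_nt=60, min_st_identity_pct=85.0, max_paralog_identity_pct=70.0)


def identical_pair(rng, length=300, family="famI"):
    seq = random_dna(rng, length)
    return HomoeologPair(
        Transcript(f"{family}_S", seq, Subgenome.S),
        Transcript(f"{family}_T", seq, Subgenome.T),
        family,
    )


class TestHomoeologWindowScan:
    def test_identical_homoeologs_all_windows_100(self, rng):
        profile = homoeolog_window_scan(identical_pair(rng), SMALL)
        assert all(v == 100.0 for v in profile.identities)

    def test_profile_dips_exactly_over_a_diverged_block(self, rng):
        s = random_dna(rng, 400)
        block = (200, 250)
        t = s[: block[0]] + mutate(s[block[0] : block[1]], 30, rng) + s[block[1] :]
        pair = HomoeologPair(
            Transcript("f_S", s, Subgenome.S), Transcript("f_T", t, Subgenome.T), "f"
        )
        profile = homoeolog_window_scan(pair, SMALL)
        for start, v in profile.entries:
            overlaps = start < block[1] and start + SMALL.trigger_length_nt > block[0]
            assert (v < 100.0) == overlaps

    def test_gene_shorter_than_trigger_rejected_with_advice(self, rng):
        with pytest.raises(SequenceError, match="shorter trigger"):
            homoeolog_window_scan(identical_pair(rng, length=50), SMALL)

    def test_subgenome_tags_validated(self, rng):
        seq = random_dna(rng, 100)
        with pytest.raises(SequenceError, match="subgenome"):
            HomoeologPair(Transcript("a", seq), Transcript("b", seq, Subgenome.T), "f")


class TestParalogDiscriminationScan:
    def test_paralog_identical_to_window_source_scores_100(self, rng):
        window = random_dna(rng, 60)
        host = random_dna(rng, 100) + window + random_dna(rng, 100)
        assert paralog_discrimination_scan(window, [Transcript("p", host)]) == {"p": 100.0}

    def test_empty_paralog_set_gives_empty_map(self):
        assert paralog_discrimination_scan("ACGT" * 20, []) == {}

    def test_antisense_copy_detected_when_both_strands_scanned(self, rng):
        from suckerscreen.seqcore import reverse_complement

        window = random_dna(rng, 50)
        host = random_dna(rng, 60) + reverse_complement(window) + random_dna(rng, 60)
        both = paralog_discrimination_scan(window, [Transcript("p", host)])
        sense_only = paralog_discrimination_scan(
            window, [Transcript("p", host)], scan_both_strands=False
        )
        assert both["p"] == 100.0
        assert sense_only["p"] < 100.0

    def test_matches_naive_exhaustive_slide_oracle(self, rng):
        window = random_dna(rng, 40)
        for _ in range(3):
            paralogs = [
                Transcript(f"p{i}", mutate(random_dna(rng, 30) + window + random_dna(rng, 50), int(rng.integers(5, 20)), rng))
                for i in range(3)
            ]
            got = paralog_discrimination_scan(window, paralogs)
            for p in paralogs:
                assert got[p.id] == pytest.approx(
                    naive_slide_max_identity(window, p.sequence), abs=0.5
                )

    def test_paralog_shorter_than_window_cannot_reach_100(self, rng):
        window = random_dna(rng, 50)
        short = Transcript("p", window[10:30])  # perfect 20-nt submatch
        got = paralog_discrimination_scan(window, [short])
        assert got["p"] == pytest.approx(100.0 * 20 / 50)


class TestDesignTrigger:
    def test_identical_homoeologs_no_paralogs_leftmost_window(self, rng):
        pair = identical_pair(rng)
        cand = design_trigger(pair, (), SMALL)
        assert (cand.start, cand.end) == (0, 60)
        assert cand.st_identity_pct == 100.0
        assert cand.sequence == pair.s_gene.sequence[:60]

    def test_paralog_cap_forces_the_second_best_window(self, rng):
        """A perfectly conserved region that the paralog shares must be rejected in
        favour of a slightly diverged region the paralog does not share."""
        shared = random_dna(rng, 80)  # S/T-identical AND present in the paralog
        private = random_dna(rng, 80)  # S/T-nearly-identical, absent from the paralog
        spacer = random_dna(rng, 30)
        s = shared + spacer + private
        t = shared + spacer + mutate(private, 4, rng)
        pair = HomoeologPair(
            Transcript("f_S", s, Subgenome.S), Transcript("f_T", t, Subgenome.T), "f"
        )
        paralog = Transcript("f_para1", random_dna(rng, 40) + shared + random_dna(rng, 40))
        config = DesignConfig(
            trigger_length_nt=60, min_st_identity_pct=85.0, max_paralog_identity_pct=70.0
        )
        cand = design_trigger(pair, [paralog], config)
        # every window fully inside the shared block (start <= 20) scores 100%
        # against the paralog and must be rejected despite perfect S/T identity
        assert cand.start > 20
        assert cand.max_paralog_identity_pct < 70.0
        start, st, pmax = exhaustive_design(pair, [paralog], config)
        assert (cand.start, cand.st_identity_pct, cand.max_paralog_identity_pct) == (
            start,
            pytest.approx(st),
            pytest.approx(pmax),
        )

    def test_equals_exhaustive_window_search(self, rng):
        config = DesignConfig(
            trigger_length_nt=50, min_st_identity_pct=80.0, max_paralog_identity_pct=70.0
        )
        for trial in range(4):
            pair = make_pair(rng, length=250, n_subs=20, family_id=f"f{trial}")
            paralogs = [
                Transcript(f"f{trial}_p{i}", mutate(pair.s_gene.sequence, 90, rng))
                for i in range(2)
            ]
            cand = design_trigger(pair, paralogs, config)
            start, st, pmax = exhaustive_design(pair, paralogs, config)
            assert cand.start == start
            assert cand.st_identity_pct == pytest.approx(st)
            assert cand.max_paralog_identity_pct == pytest.approx(pmax)

    def test_relaxing_paralog_cap_never_lowers_achieved_st_identity(self, rng):
        pair = make_pair(rng, length=300, n_subs=25)
        paralogs = [Transcript("p1", mutate(pair.s_gene.sequence, 100, rng))]
        achieved = []
        for cap in (68.0, 75.0, 82.0):
            config = DesignConfig(
                trigger_length_nt=60, min_st_identity_pct=85.0, max_paralog_identity_pct=cap
            )
            try:
                achieved.append(design_trigger(pair, paralogs, config).st_identity_pct)
            except NoValidTriggerError:
                achieved.append(float("-inf"))
        assert achieved == sorted(achieved)

    def test_no_valid_trigger_reports_binding_constraints(self, rng):
        seq = random_dna(rng, 120)
        pair = HomoeologPair(
            Transcript("f_S", seq, Subgenome.S), Transcript("f_T", seq, Subgenome.T), "f"
        )
        paralog = Transcript("p", seq)  # shares everything: every window hits the cap
        with pytest.raises(NoValidTriggerError) as err:
            design_trigger(pair, [paralog], SMALL)
        assert err.value.family_id == "f"
        assert all(why == "paralog" for _, why in err.value.diagnostics)

    def test_chosen_window_constraints_hold_when_rechecked_independently(self, rng):
        from suckerscreen.seqcore import global_align, windowed_identity

        pair = make_pair(rng, length=400, n_subs=20)
        paralogs = [Transcript("p1", mutate(pair.s_gene.sequence, 150, rng))]
        cand = design_trigger(pair, paralogs, SMALL)
        aln = global_align(pair.s_gene.sequence, pair.t_gene.sequence)
        profile = dict(windowed_identity(aln, SMALL.trigger_length_nt).entries)
        assert profile[cand.start] == pytest.approx(cand.st_identity_pct)
        assert cand.st_identity_pct >= SMALL.min_st_identity_pct
        assert naive_slide_max_identity(cand.sequence, paralogs[0].sequence) < 70.0


class TestSummarizeTriggers:
    def test_means(self, rng):
        pair = identical_pair(rng, length=600)
        c1 = design_trigger(pair, (), DesignConfig(trigger_length_nt=400, min_st_identity_pct=90))
        c2 = design_trigger(pair, (), DesignConfig(trigger_length_nt=460, min_st_identity_pct=90))
        stats = summarize_triggers([c1, c2])
        assert stats == {"n": 2, "mean_length_nt": 430.0, "mean_st_identity_pct": 100.0}

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            summarize_triggers([])


class TestDesignConfigValidation:
    def test_cap_must_be_below_floor(self):
        with pytest.raises(ValueError):
            DesignConfig(min_st_identity_pct=60.0, max_paralog_identity_pct=70.0)
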