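# Methods

This note documents the models, conventions and design choices behind each
module, what the synthetic-data generator does and does not emulate, and the
package's known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Sequence core

**Alphabet and coordinates.** DNA over {A, C, G, T, N}; `N` never counts as a
match, not even against another `N` (it is an assembly ambiguity code, not a
wildcard). All coordinates are 0-based, half-open. FASTA headers follow
`id|subgenome|class` with `S`/`T`/`none` subgenome tags for the two
progenitor genomes of allotetraploid tobacco (*N. sylvestris*,
*N. tomentosiformis*).

**Alignment.** Global pairwise alignment with affine gaps via
`Bio.Align.PairwiseAligner`, default scoring match +2, mismatch −3, gap open
−5, gap extend −2 (megablast-style weights, appropriate for the highly
similar homoeolog pairs this package aligns; no scheme is canonical for the
problem, so the scoring is a `Scoring` parameter everywhere). A gap of length
L costs `open + L·extend`. The first alignment in the aligner's deterministic
traceback order is used, so outputs are reproducible; the test suite checks
optimal *scores* against a brute-force DP that enumerates every gap length
explicitly, plus exhaustive enumeration of short two-letter pairs, so
tie-breaking never affects correctness claims.

**Percent identity.** Identity depends on the denominator, and no single
convention is standard, so the choice is an explicit `IdentityMode`: all
alignment columns; columns excluding terminal gap runs (default — terminal
gaps reflect length differences, not divergence); or the shorter ungapped
sequence. Windowed identity profiles place windows on the ungapped target
sequence and divide matches by the alignment columns the window spans, so a
gap inside a window depresses its identity.

## Enrichment screen

The screen operates on RPKM (reads per kilobase of exon per million mapped
reads, `count × 10⁹ / (length × total)`): the available published evidence
for the 10-fold criterion is an RPKM table, and scale factors cancel in the
ratio, so count-level and RPKM-level screening agree whenever library sizes
are fixed per tissue (the scale-invariance test checks this).

"Not detectable" (ND) is a distinct state, never conflated with a measured
zero. Fold rules: tissue ND ⇒ fold 0; control ND ⇒ `tissue / nd_epsilon`
with `nd_epsilon = 0.1` RPKM, so any tissue RPKM ≥ 1 clears the 10× bar
against an undetectable control. This floor is what reproduces the reference
selections whose control column is ND; it is exposed as a parameter because
the numeric meaning of ND below detection is not knowable from the data. A
measured control of exactly 0 with positive tissue signal yields an infinite
fold — kept distinct from the ND path.

The length criterion is strict (`> 200 bp`). Tissue assignment is the argmax
of RPKM among tissues whose fold passes, ties EA-first; this reproduces
reference genes that pass in both tissues but are named for the stronger one.

## Trigger design

Objective: **maximize S/T window identity subject to a hard paralog cap**
(< 70% by default), ties to the leftmost window. The two stated goals —
cover both homoeologs, discriminate against paralogs — are combined this way
because the cap is a stated cut-off while homoeolog coverage is a graded
preference. The designer enumerates every window (step 1 by default), so the
optimum is exact; an acceptance test checks equality with an independent
exhaustive search.

The trigger is cut from the S copy by default (`source_subgenome` is
configurable; which copy was cloned is arbitrary at ~95% identity). Default
length is 430 nt.

Paralog identity is a **gapless sliding comparison**: the window is slid over
the paralog at every offset on both strands (hairpin RNAi is
strand-symmetric) and identity is matches / window length, maximized over
offsets. Gapless is the honest measure under the package's
substitution-dominated divergence model and is also what the small-RNA
mechanism sees (contiguous base-pairing); it is computed exactly with a
per-diagonal cumulative-sum decomposition, O((n+m)·n) per paralog. A paralog
shorter than the window keeps the window-length denominator and therefore
cannot reach 100%.

The per-paralog cap is applied to the **maximum** over paralogs and strands —
the stricter reading of per-family discrimination.

Reported trigger S/T identity is the windowed identity in the default mode.
Note that a designer that picks the *most conserved* window reports a mean
trigger identity above the genome-wide S/T mean — on synthetic data at 95.4%
pairwise identity the chosen windows average ≈ 97% (computed by
`scripts/acceptance.py`).

## Off-target scan

The 22-nt risk rule is literal sequence identity, so the scan implements the
rule itself: an exact k-mer index (k = 22 default, k ≥ 8 enforced) over the
transcriptome, seeds looked up from the trigger and its reverse complement,
each seed extended to a maximal run, duplicates from overlapping seeds
collapsed by their extended endpoints. Every shared substring of length ≥ k
is covered by exactly one reported maximal hit (checked against a quadratic
all-substrings oracle), reported substrings re-verify character-by-character,
and scanning the reverse-complemented trigger yields the strand-flipped hit
multiset. Both strands are scanned by default (`both_strands=False` gives a
sense-only scan). Intended targets (the family's S and T copies) are passed
as an exclusion set; sibling paralogs are *not* excluded — a ≥ 22-nt paralog
match is precisely the risk the designer is meant to avoid. A trigger is
`clean` iff the scan returns no hits.

## Phenotype statistics

The relative effect of a construct on a trait is computed per line:
`mean(transgenic) / mean(null segregants)`, then summarized over lines as
mean ± sample SD (n − 1). Each line's null segregants are the matched
control because they share the transformation event's genetic background
minus the transgene. A zero control mean makes the ratio "not calculable"
(NaN, propagated, never significant).

Significance is a **one-sample, two-sided t-test of the per-line relative
values against 1.0** (df = n − 1 = 2 for three lines). This choice — rather
than a two-sample test on raw plants — reproduces the reference table's
marks exactly, including rejecting a 0.57 ± 0.10 cell (p ≈ 0.018 > 0.01).
Effectiveness additionally requires the mean relative value to be below 1
(reduction-only): a significant *increase* (1.08 ± 0.01) must not be called
suppression. The sd = 0 convention (p = 0 if mean ≠ 1, else 1) is the
sd → 0⁺ limit of the standard test and is required by all-zero suppression
rows; it is a documented convention, not silent behavior.

Two-sample tests (for mutant-vs-wild-type comparisons) default to Welch;
pooled variance is available since the original flavor is unstated. The
effective-gene call uses α = 0.01 on secondary-shoot number and weight; no
multiple-testing correction is applied, matching the screening practice the
package models.

## Synthetic data generator

The generator's defaults encode the study design: 36 target families (12
carrying paralogs, 24 without), S/T identity 95.4%, paralogs at 50–65%
identity, 300 background transcripts of 0.8–2 kb, 5% short (< 200 nt)
contaminant contigs, 36 RNAi constructs with three transformant lines each
and 10 plants per genotype class per line (T1 family sizes are not published;
10 per class is a realistic greenhouse family), five constructs with a 0.1
multiplier on secondary/tertiary shoots and the rest phenotype-neutral, all
constructs knocked down to 0.3 relative expression.

**Divergence model.** Per-site substitutions, uniform over the three
alternative bases, no indels by default (`indel_rate` exists but defaults to
0): identities stay interpretable and alignments unambiguous. S and T derive
from one ancestral sequence by splitting exactly
`round((1 − identity) · L)` substitutions randomly between the branches, so
realized S/T identity is exact. Paralogs derive from the S copy at a
uniform-drawn identity; their *recorded* ground-truth identity is measured on
the optimal global alignment, because at 50–65% identity the aligner
legitimately places a few gaps that raise measured identity 1–4 points above
the substitution fraction — the recorded value is defined as "what the
aligner measures on the emitted sequences".

**Expression model.** Control counts are log-normal-Poisson
(`exp(N(3, 1))` mean reads, floored at one read — a detected gene has at
least one read, and a sampled zero would conflate measured 0 with ND);
non-enriched tissue counts vary around control by a log-normal factor
(σ = 0.25), giving a background fold distribution centred at 1 whose 10×
tail is negligible. Enriched genes (fraction `enriched_fraction`, drawn only
among screen-eligible genes so planted truth survives criteria b and c) get
`ceil(control_count × fold)` reads in their tissue with
`fold = max(10, exp(N(3.0, 0.3)))` — the recomputed RPKM ratio is ≥ 10 by
construction. One expression column per tissue (no replicates), matching a
single laser-microdissection pool per zone. ND masking is per-cell with
probability `nd_probability` (scalar or per-tissue), never applied to the
enriched tissue of an enriched gene.

**Phenotype model.** Counts are negative-binomial with variance
`μ + (cv·μ)²` (`noise_cv` is the extra-Poisson CV; 0 gives Poisson), weights
log-normal with CV `noise_cv`; baselines follow wild-type field magnitudes
(≈ 20 primary shoots, ≈ 10 secondary, ≈ 3 tertiary; weights 37/20/5 g).
Number and weight are drawn independently per trait: real shoot weights
correlate with counts, but independent traits make number and weight two
independent tests, which is what the nominal false-call rate of the
"number and/or weight" rule presumes (two one-sided 0.005 events ≈ 0.01).
This is the main idealization of the phenotype model.

**Determinism.** One master seed; stages draw from documented sub-streams
(0 transcriptome, 1 expression, 2 phenotypes, 3 planting) via
`default_rng([seed, stream])`, so identical configs give bit-identical
outputs and stages are independently reproducible.

**Off-target planting** copies a trigger substring of exactly the requested
length (sense or antisense, recorded) into a background transcript,
replacing in place, and forces both flanking bases to mismatch the trigger's
neighbouring bases so the planted run is maximal at exactly the requested
length — this is what makes 21-nt boundary negatives exact.

**What passing tests do and do not show.** The generator has no 454
sequencing error model, no read-level simulation, no assembly artifacts
beyond short contigs, no correlated traits, no line-to-line effect
heterogeneity, and substitution-only divergence. Tests passing on this model
validate the *algorithms* (screen logic, window optimization, exact
matching, test statistics and their calibration) — not robustness to indels,
misassembly or trait correlation in real tobacco data.

## Numerical and scale choices

* Window identities and paralog identities are ratios of integer match
  counts, so designer-vs-oracle comparisons are exact float equalities.
* The null-calibration acceptance test uses 10,000 simulated null constructs
  (100 studies × 100 constructs) against the 99% binomial band around 0.01;
  the module-level test uses 1,000. The acceptance *script* uses 2,000 nulls
  and 20 recovery seeds to stay fast while quoting its `n` alongside each
  value.
* Designer–oracle equivalence runs on 400–600-nt genes with 100-nt triggers;
  aligner–oracle equivalence on all two-letter pairs of lengths ≤ 4 plus 200
  sampled pairs of lengths 5–12 (the brute-force oracle is cubic, so sizes
  are chosen for exactness per instance, with breadth from sampling).

## Known limitations

* The paralog scan is gapless by design; a paralog whose similarity to the
  trigger window is mediated by an indel-rich alignment could score lower
  than a gapped aligner would report.
* The one-sample t on three per-line ratios assumes the relative values are
  approximately normal; with count-valued traits the per-line ratio is a
  ratio of means of 10 plants, which is close to normal but slightly
  right-skewed — the measured null call rate (reported by the acceptance
  script) sits near, not exactly at, the nominal level.
* The effective-gene call applies no multiple-testing correction across 36
  constructs (by design, matching the modeled practice): over many
  constructs, a calibrated 1% test necessarily produces occasional false
  calls, so perfect precision across thousands of null construct-tests is
  not a property this procedure can have.
* `classify_trigger` is binary (clean / off-target risk); it does not rank
  risks by match length or target expression.
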