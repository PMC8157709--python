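# suckerscreen

Tools for finding and validating lateral-shoot (sucker) suppression genes in
allotetraploid tobacco (*Nicotiana tabacum*).

After a tobacco plant is topped, axillary buds grow out as primary, then
secondary and tertiary lateral shoots ("suckers") that must be removed by
hand or with chemicals. A computational route to sucker-suppression varieties
has four stages, and this package implements all of them as a tested library
with a thin command-line interface:

1. **Enrichment screen** (`suckerscreen.enrichment_screen`) — select genes
   preferentially expressed in the early (EA) or very early (VE) axillary
   meristem zone. A gene is a candidate iff (a) its RPKM in EA or VE is
   ≥ 10× the control zone, (b) the assembled contig is > 200 bp, and
   (c) it is annotated as a transcription factor or unknown protein.
   RPKM = count × 10⁹ / (length × library size); "not detectable" (ND) is an
   explicit state (an ND control is floored at 0.1 RPKM, an ND tissue gives
   fold 0).
2. **Trigger design** (`suckerscreen.trigger_design`) — tobacco inherited an
   S and a T subgenome, so every target has two homoeologous copies at
   roughly 95% identity. The designer slides a fixed-length window (default
   430 nt) along the S/T global alignment and returns the most conserved
   window — so one hairpin silences both copies — subject to a hard paralog
   cap: the window's best gapless match against any same-family paralog, on
   either strand, must stay below 70% identity, so siblings such as the
   three *NtBl* or four *NtCUC* genes are not co-silenced.
3. **Off-target scan** (`suckerscreen.offtarget_scan`) — a shared run of
   ≥ 22 consecutive identical nucleotides between a trigger and any
   non-target transcript is an off-target risk. The scan is exact k-mer
   seeding plus maximal extension on both strands (the criterion is literal
   identity, so no heuristic aligner is involved); each maximal run is
   reported once with exact coordinates.
4. **Phenotype statistics** (`suckerscreen.phenotype_stats`) — per
   transformant line, trait means of transgenic plants are divided by the
   null-segregant means; the per-line relative values *r₁…rₙ* (n = 3 lines)
   are tested against 1 with a two-sided one-sample t-test,
   t = (r̄ − 1)/(s/√n), df = n − 1. A construct is *effective* when
   secondary-shoot number and/or weight shows p < 0.01 **and** r̄ < 1
   (reduction only). When s = 0 the p-value is taken as the sd → 0⁺ limit
   (0 if r̄ ≠ 1, else 1), which is what scores an all-zero suppression row.

A fifth module, `suckerscreen.synthetic_data`, generates transcriptomes,
expression tables and phenotype trials with known ground truth (controlled
S/T identity, planted enrichment, planted ≥ 22-nt off-target matches, known
effect multipliers), so every stage is testable without external data.
`suckerscreen.pipeline` chains the stages deterministically under one master
seed and writes a manifest of SHA-256 digests.

Two small published measurement tables (per-gene RPKM for 36 genes; relative
RNAi effects, mean ± SD over three lines, for 36 constructs) ship as package
data and are loaded by `suckerscreen.reference_tables`.

## Worked example

```bash
python examples/01_enrichment_screen.py
```

```
screened 24 genes -> 24 candidates (11 EA-assigned, 13 VE-assigned)
  EA1    tissue=EA fold=329.3
  EA2    tissue=EA fold=13.6
  ...
```

All 24 reference genes pass the screen; 11 are assigned to EA and 13 to VE
(the tissue with the larger RPKM among those passing 10×). `EA2`'s fold is
20.13/1.48 = 13.6; `EA1`'s control is ND, so its fold uses the 0.1-RPKM
floor.

```bash
python examples/04_effective_genes.py
```

```
construct  trait         mean±SD        p        significant
NtLs       secondary_n   0.13±0.09   0.0035   yes
NtLs       secondary_wt  0.10±0.06   0.0015   yes
NtBl1      secondary_n   0.00±0.00   0.0000   yes
NtBl1      secondary_wt  0.00±0.00   0.0000   yes
NtREV      secondary_n   0.06±0.10   0.0038   yes
NtREV      secondary_wt  0.03±0.04   0.0006   yes
VE7        secondary_n   0.33±0.09   0.0060   yes
VE7        secondary_wt  0.26±0.11   0.0073   yes
VE12       secondary_wt  0.05±0.08   0.0024   yes

effective genes (5): NtBl1, NtLs, NtREV, VE12, VE7
```

Exactly nine secondary-shoot cells reject at the 1% level under the
reduction-only rule, yielding five effective constructs. Near-misses (e.g.
0.57 ± 0.10, p ≈ 0.018; 0.28 ± 0.30, p ≈ 0.053) stay unflagged, as does a
tight *increase* (1.08 ± 0.01).

The other examples design a trigger on a synthetic homoeolog pair
(`02_trigger_design.py`), recover a planted 26-nt off-target match with exact
coordinates (`03_offtarget_scan.py`), and run the full pipeline
(`05_full_pipeline.py`).

### Command line

```bash
suckerscreen run --outdir out --seed 7                 # full synthetic run
suckerscreen screen --expression expr.tsv --out cands.tsv
suckerscreen design --targets t.fa --pairs pairs.tsv --paralogs p.fa \
    --length 430 --max-paralog-identity 70 --out-triggers trig.fa --out-report rep.tsv
suckerscreen offtarget --triggers trig.fa --transcriptome tx.fa --k 22 \
    --out-hits hits.tsv --out-verdicts verdicts.tsv
suckerscreen phenostats --phenotypes pheno.tsv --alpha 0.01 --out summary.tsv
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

## Layout

```
src/suckerscreen/     library (seqcore, enrichment_screen, trigger_design,
                      offtarget_scan, phenotype_stats, synthetic_data,
                      pipeline, cli, reference_tables, data/)
tests/                pytest suite with independent oracles
examples/             one narrative script per capability
docs/methods.md       models, assumptions, parameter choices, limitations
scripts/acceptance.py headline-quantity reproduction
```
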