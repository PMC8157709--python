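"""Call effective suppression genes from the bundled relative-effect table.

Each construct has three transformant lines; per line the trait mean of
transgenic plants is divided by the null-segregant mean.  A one-sample t-test
of the three relative values against 1.0 (two-sided, alpha = 0.01, reductions
only) marks significant suppression of secondary lateral shoots.
"""

from suckerscreen.phenotype_stats import call_effective_genes, summaries_from_stats
from suckerscreen.reference_tables import load_reference_effects

df = load_reference_effects()
secondary = df[df["trait"].isin(["secondary_n", "secondary_wt"])]
summaries = summaries_from_stats(secondary)

print("construct  trait         mean±SD        p        significant")
for s in summaries:
    if s.significant_reduction:
        print(f"{s.construct_id:10s} {s.trait.value:13s} "
              f"{s.relative_mean:.2f}±{s.relative_sd:.2f}   {s.p_value:.4f}   yes")

effective = call_effective_genes(summaries)
print(f"\neffective genes ({len(effective)}): {', '.join(sorted(effective))}")
print("A construct is effective when secondary-shoot number and/or weight is "
      "significantly reduced relative to null segregants.")
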