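"""End-to-end synthetic cohort: simulate, validate, compare tube conditions.

Simulates the 4-condition x 3-donor PRM cohort (all 57 scheduled precursors
of the packaged roster plus shuffled decoys), runs the XIC filter cascade
with cohort-level acceptance, and prints the per-sample validated counts,
the ANOVA/Tukey comparison across conditions, and the head of the
row-scaled heatmap matrix.
"""

from xlinkprm import SimulationConfig, anova_table, run_cohort_analysis

analysis = run_cohort_analysis(SimulationConfig(seed=1))

print("Validated crosslinked precursor ions per sample")
print("  (Streck/formaldehyde should sit near the 57 scheduled targets;")
print("   EDTA/allantoin near zero, since their signal is ~5% of S/F):")
for sid, n in analysis.counts_per_sample.items():
    print(f"  {sid}: {n}")

truth = analysis.simulation.truth_frame()
decoys = truth[truth.is_decoy]
print(f"\nDecoy targets monitored: {decoys.entry_label.nunique()}; "
      f"decoys validated anywhere: {int(decoys.detectable.sum())} (expected 0)")

print("\nOne-way ANOVA across conditions: "
      f"F = {analysis.anova.f_statistic:.1f}, p = {analysis.anova.p_value:.2e}")
print(anova_table(analysis.anova).to_string(index=False))
print("  'ns' for S vs F and significant S/F vs E/A is the expected pattern.")

print("\nRow-scaled mean-area heatmap matrix (first 5 pairs):")
print(analysis.heatmap.head(5).round(3).to_string())
print("  Each row is scaled to its maximum; values near 1 in F/S and near 0")
print("  in E/A reproduce the condition contrast of the injected crosslinks.")
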