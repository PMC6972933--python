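"""Hemispheric laterality of the bundle across simulated subjects.

Runs the full pipeline on phantom subjects whose right hemisphere carries
30% more VOF streamlines than the left, then summarizes the laterality
index LI = (L - R)/(L + R) for the tract count, tract volume and mean FA
across subjects with a paired t-test.
"""

from vofdissect import PhantomConfig, PipelineConfig, SubjectSpec, run_pipeline

config = PipelineConfig(
    subjects=[SubjectSpec(f"subject{i:02d}", seed=i) for i in range(1, 7)],
    phantom=PhantomConfig(
        n_vof=300, n_ilf=60, n_af=60, n_clutter=30,
        # identical endpoint statistics on both sides; only the count differs
        endpoint_props_dorsal={"V3CD": 0.35, "V3A": 0.25},
        endpoint_props_ventral={"V4": 0.6},
        endpoint_props_lateral={"LO1": 0.4},
    ),
    right_count_factor=1.3,
    write_outputs=False,
)
results = run_pipeline(config)

print(results["laterality"].query("quantity == 'n_tracts'").round(3).to_string(index=False))
print()
for quantity, s in results["summaries"].items():
    flag = "  [degenerate: zero-variance differences]" if s.degenerate else ""
    print(f"{quantity:10s} LI = {s.mean_li:+.3f} +/- {s.sem_li:.3f} "
          f"(paired t = {s.t_statistic:.2f}, p = {s.p_value:.4f}){flag}")
print("\nNegative LI means rightward lateralization: the configured 30% "
      "right-count surplus is recovered as LI ~ -0.13 for the tract count "
      "and a smaller volume asymmetry; mean FA stays symmetric.  The count "
      "contrast is deterministic here (every subject 300 vs 390 tracts), so "
      "its paired t-test is flagged degenerate rather than silently infinite.")
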