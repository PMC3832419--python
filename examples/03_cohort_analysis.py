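"""Full cohort analysis on a synthetic study.

Generates a 12-subject cohort with the default planted intentional-learning
effect, runs the complete pipeline in memory and prints the statistics a
study report would quote: per-task deviations from baseline, the
repeated-measures ANOVA over tasks, and the deviation-vs-recall correlations.
"""

import netlearn as nl

spec = nl.CohortSpec(n_subjects=12, fs=127.155, duration_B=81.0,
                     duration_L1=49.0, duration_L2=49.0, seed=8)
result = nl.analyze_bundles(nl.generate_cohort(spec), nl.PipelineConfig())

print(f"{result.n_subjects} subjects analyzed\n")
print("task  mean C (sd)        mean L (sd)")
for task, s in result.task_summary.items():
    print(f" {task:3s}  {s['C']['mean']:.3f} ({s['C']['sd']:.3f})    "
          f"{s['L']['mean']:.3f} ({s['L']['sd']:.3f})")

print("\nbaseline-relative deviations:")
for task, s in result.deviation_summary.items():
    print(f" {task}: dC% = {s['dC_pct']['mean']:+6.2f} ({s['dC_pct']['sd']:.2f})   "
          f"dL% = {s['dL_pct']['mean']:+6.2f} ({s['dL_pct']['sd']:.2f})")

a = result.anova_C
print(f"\nrm-ANOVA on C: F({a.df_num:.0f},{a.df_den:.0f}) = {a.F:.2f}, "
      f"p = {a.p_uncorrected:.4f} (GG: {a.p_gg:.4f}, HF: {a.p_hf:.4f}; "
      f"eps_GG = {a.epsilon_gg:.2f})")
print(f"rm-ANOVA on L: F = {result.anova_L.F:.2f}, "
      f"p = {result.anova_L.p_primary:.4f}")
if result.pairwise_C:
    for pair, v in result.pairwise_C.items():
        print(f"  paired t {pair}: t = {v['t']:+.2f}, p = {v['p']:.4f}")

print("\ncorrelations with recall:")
for pair, v in result.correlations.items():
    print(f"  {pair}: r = {v['r']:+.2f} (p = {v['p']:.3f})")

print("\nThe clustering coefficient rises during intentional learning (L2) "
      "and the\nrise correlates with intentional recall; the path length and "
      "the incidental\ntask show no systematic change.")
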