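# netlearn

Functional brain networks from EEG phase synchronization during verbal
learning, with cohort-level statistics relating network changes to memory
performance.

## The scientific problem

When people memorize verbal material, distributed brain regions transiently
coordinate. One way to quantify this from scalp EEG is to treat electrodes as
nodes of a graph, connect the most phase-synchronized pairs, and track global
graph statistics over a cognitive test schedule: a resting baseline (B), an
*incidental* learning task (L1: listening to 15 nouns without instruction to
memorize) and an *intentional* learning task (L2: explicit instruction to
memorize 15 different nouns), each followed later by free recall.

`netlearn` implements this chain end to end:

1. **Phase synchronization.** Each channel's instantaneous phase φ(t) is the
   argument of its analytic signal (Hilbert transform, after mean removal).
   For every consecutive 16.1-s window, each channel pair (j,k) gets the
   *mean phase coherence*

   R_jk = | (1/T) Σ_t exp(i [φ_j(t) − φ_k(t)]) |  ∈ [0, 1],

   with R = 1 for perfect phase locking and a Rayleigh noise floor
   √(π/4T) for independent phases.

2. **Network construction.** Per window, the E = round(kN/2) strongest pairs
   become edges of a binary graph (N = 29 scalp channels, target mean degree
   k = ⌈2 ln N⌉ = 7, satisfying the random-graph connectedness bound
   k > 2 ln N while keeping the network sparse). If the graph still
   disintegrates, the strongest remaining entries that bridge components are
   added (flagged and logged).

3. **Graph statistics.** Clustering coefficient C (mean over nodes of the
   triangle fraction among connected triples) and average shortest path
   length L (mean hop count over all node pairs).

4. **Cohort analysis.** Window metrics are averaged per task; learning tasks
   are expressed as percent deviations from the same subject's baseline
   (ΔC%, ΔL%); tasks are compared with a repeated-measures ANOVA
   (Greenhouse–Geisser / Huynh–Feldt sphericity corrections) and paired
   t-tests; deviations are correlated (Pearson) with the number of recalled
   words.

5. **Synthetic cohorts.** Because no EEG of this design is publicly
   available, the package ships a generator that plants the effect of
   interest in phase space: oscillator channels in frequency communities
   with sub-cluster structure, an intentional-learning coupling boost scaled
   by a latent per-subject ability, and recall scores driven by the same
   ability. Every downstream claim is testable against this ground truth.

## Worked example

```python
import netlearn as nl

# a small synthetic study: 6 subjects, shortened tasks
spec = nl.CohortSpec(n_subjects=6, fs=127.155, duration_B=81.0,
                     duration_L1=49.0, duration_L2=49.0, seed=1)
bundles = nl.generate_cohort(spec)
result = nl.analyze_bundles(bundles, nl.PipelineConfig())

d = result.deviation_summary
print(f"dC% L1 = {d['L1']['dC_pct']['mean']:+.2f}  "
      f"dC% L2 = {d['L2']['dC_pct']['mean']:+.2f}")
print(f"ANOVA on C: F = {result.anova_C.F:.2f}, p = {result.anova_C.p_primary:.4f}")
r = result.correlations["dC_L2~recall_intentional"]
print(f"r(dC_L2, intentional recall) = {r['r']:+.2f} (p = {r['p']:.3f})")
```

prints (seed 1):

```
dC% L1 = +3.35  dC% L2 = +12.24
ANOVA on C: F = 3.21, p = 0.1272
r(dC_L2, intentional recall) = +0.85 (p = 0.032)
```

The clustering coefficient rises during intentional learning (here strongly,
as this tiny demo cohort happens to contain two high-ability subjects) while
the incidental task moves it much less, and the size of the rise tracks how
many words a subject later recalls; six subjects are too few for the omnibus
ANOVA to reach significance. At the study's full scale (33 subjects) the
mean ΔC% during intentional learning is a few percent and the task effect on
C is clearly significant while L stays flat.

The `examples/` directory walks through each stage separately; the
command-line interface mirrors the library
(`netlearn simulate | run | metrics | make-fixtures`).

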