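# Methods

This note records the model, the defaults and the design decisions behind
`netlearn`, in the spirit of a model-description chapter: what is computed,
under which assumptions, and what the synthetic validation does and does not
demonstrate.

## Analysis chain

### Instantaneous phase and mean phase coherence

Phases come from the analytic-signal approach: each channel is
mean-subtracted (a DC offset corrupts the analytic phase everywhere) and
Hilbert-transformed; the phase is the complex argument. No band-pass
filtering is applied beyond the recorded 0–50 Hz bandwidth: the analytic
phase adaptively follows the channel's *predominant* rhythm, which is
preferable to imposing fixed frequency bands that may hold no power. When
several rhythms superimpose, the instantaneous frequency fluctuates around
the predominant one; the temporal average in the coherence estimator damps
the resulting phase jitter.

The interdependence measure between channels j and k over a window of T
samples is the mean phase coherence
R_jk = |T⁻¹ Σ_t exp(i[φ_j(t) − φ_k(t)])| ∈ [0, 1]. For independent phases
E[R] ≈ √(π/4T) (Rayleigh resultant), which is the estimator's noise floor —
about 0.014 at T = 4094.

**Phase is extracted once per task segment, then windowed.** The alternative
(per-window Hilbert transforms) would put edge artifacts at every window
join; computing over the whole segment confines them to the two segment
ends. Windows are consecutive, non-overlapping, ⌊16.1 s · fs⌋ samples each
(4094 at 254.31 Hz), the trailing remainder discarded: a 3-minute task yields
11 windows, a 5-minute baseline 18. Window onset→sample mapping uses
0-based, half-open ranges; task onsets map by round-half-even.

### Network construction

Each window's R matrix is thresholded by *rank*, not by a fixed numeric
cutoff: the E = round(kN/2) largest off-diagonal entries become edges. Node
count and link density both bias C and L, so holding both fixed across
windows, tasks and subjects is what makes the comparisons meaningful. The
default target mean degree is k = ⌈2 ln N⌉ (7 for N = 29, giving E = 102 and
link density 0.25): the smallest integer satisfying the random-graph
connectedness bound k > 2 ln N while keeping the graph sparse. Values at or
below the bound are allowed but logged as a warning. Ties at the cutoff are
broken by ascending channel-index pair — deterministic and seed-free.

A thresholded graph can still be disconnected (L would be infinite). Rather
than discarding such windows — which would break the fixed per-task window
counts — construction adds the strongest remaining entries *that bridge
distinct components*, in rank order, until one component remains. Repairs
are flagged on the network and logged, because they raise the edge count
above E.

### Graph statistics

Per node, C_i = 2·(triangles through i)/(k_i(k_i−1)) for degree k_i ≥ 2 and
C_i = 0 otherwise (the convention that makes the global mean over *all*
nodes well defined); global C is the mean over nodes. L is the mean
unweighted shortest-path length (breadth-first search on unit weights) over
all unordered pairs; disconnected input raises an error rather than
returning infinity. Triangle counting is done with dense matrix algebra and
shortest paths with `scipy.sparse.csgraph`; the test suite checks both
against exhaustive brute-force enumeration (all 996 connected graphs on ≤ 7
nodes, plus random graphs at the study size) and against networkx.

### Cohort statistics

Window metrics are averaged arithmetically per task (C_T, L_T). Because raw
network characteristics vary strongly between individuals, learning tasks
are normalized per subject as percent deviations from baseline,
ΔC% = 100·(C_task − C_B)/C_B and analogously ΔL%.

The omnibus task comparison is a one-way repeated-measures ANOVA over
(B, L1, L2), computed from the classical sums-of-squares decomposition with
the subject-by-condition interaction as error term. Sphericity is never
assumed: the Greenhouse–Geisser epsilon is estimated from the covariance of
the conditions (clamped to [1/(m−1), 1]) and the Huynh–Feldt correction is
derived from it (clamped above at 1); corrected p-values scale both degrees
of freedom by epsilon. The GG-corrected p is treated as primary when
ε_GG < 0.75 (the usual convention), the uncorrected p otherwise. With two
conditions the ANOVA reduces exactly to the paired t-test (F = t²), which
the tests verify, and the implementation is cross-checked against pingouin.

Pairwise paired t-tests run only after a significant omnibus test, without
further multiplicity correction; all tests are two-sided. Pearson
correlations (two-sided p via the t transform) are reported for
(ΔC%_L1, incidental recall), (ΔC%_L2, intentional recall), the two ΔL%
analogues, and the cross pair (ΔC%_L2, incidental recall). Headline
statistics merge the control and patient groups; a group-stratified summary
is kept as a secondary table. Subjects missing any task or the behavior row
are excluded with a logged warning.

## Synthetic cohorts

The generator's purpose is a cohort whose *ground truth* encodes the effect
the pipeline is meant to detect, so that recovery can be scored.

**Oscillators and coupling.** Each channel is
x(t) = a·cos(2π f_c t + ϕ(t)) + noise, with amplitude a ~ U(0.7, 1.3),
channel-independent white measurement noise (relative amplitude 0.4), and a
phase-wander process ϕ(t) that is a weighted sum of three unit-variance
Ornstein–Uhlenbeck processes (correlation time 0.35 s, total sd 1.5 rad):
one shared by the channel's frequency community, one shared by its
sub-cluster, one private. The squared weights sum to one, so the *fraction*
of shared wander variance is the coupling strength, and the mean phase
coherence of a pair increases monotonically with it (verified by
Monte-Carlo over a coupling grid). Coupling lives in phase space because
the analysis chain measures phase synchronization — amplitude mixing would
exercise the wrong mechanism.

**Structure.** Channels are partitioned into 2 frequency communities (rhythm
drawn per community from 4–20 Hz, ≥ 2 Hz apart, so cross-community pairs
decohere through frequency drift), each split into two sub-clusters. The
within-community shared fraction is `base_coupling` = 0.30 in every task.

**The planted effect.** During intentional learning (L2) the sub-cluster
processes gain weight `effect_delta · max(0, 1 + z)` for a subject with
latent ability z; incidental learning applies no modulation by default. The
hierarchical (sub-cluster) form is deliberate: under fixed-edge-count
thresholding, a *uniform* within-community coupling increase either leaves
the edge set unchanged or trades cross-community bridges for within-community
edges — the first produces no clustering effect, the second drags the
average shortest path length along with it. Strengthening sub-clusters
instead reallocates edges *within* communities toward triangle-rich
sub-cliques while inter-community bridge counts stay essentially constant:
C rises with ability, L stays flat, which is exactly the dissociation the
pipeline is supposed to resolve.

**Ability and recall.** Latent ability is z = group offset + 0.8·N(0,1),
with offsets +0.6 (controls) and −0.9 (patients). Recall scores are
intentional = clamp(round(10.0 + 2.5 z + ε), 0, 15) and
incidental = clamp(round(7.7 + 2.33 z + ε'), 0, 15) with ε ~ N(0, 1.8²)
in words. These coefficients put the four group means near 11.5/9.1
(controls) and 7.7/5.6 (patients) with within-group sds near 2.8 — the
scale reported for this kind of cohort — and make the two recall scores
positively correlated through the shared ability.

**Calibration.** `effect_delta` defaults to 0.10, fixed once by simulation
so that the ground-truth correlation between ability and ΔC%_L2 is ≈ 0.6
under the validation conditions (33 subjects, 16.1-s windows, 5 baseline and
3 learning windows per subject at half the study sampling rate). Larger
values push the correlation toward 0.75+ but begin to induce a systematic
path-length effect, which the planted model is supposed to exclude.

**Determinism.** Every subject's randomness derives from
(master seed, subject index) via `numpy` seed sequences, so a subject's data
are independent of cohort size bookkeeping order, and identical seeds give
bit-identical cohorts.

**What the generator does not emulate.** Volume conduction and a common
reference (which inflate zero-lag coherence between neighboring
electrodes), 1/f broadband background, artifacts (ocular, muscular,
amplifier), non-stationary rhythm switching, and any spatial electrode
geometry. Passing the validation therefore shows that the *chain of
estimators and statistics* recovers a phase-space effect of plausible size
at study-realistic dimensions — not that real EEG of this design would show
the effect, nor that artifacts could not mimic it.

## Problem sizes used in validation

Full study scale (29 channels, 254.31 Hz, 300/180/180-s tasks, 33 subjects)
is used in the acceptance script, where one cohort is analyzed end to end.
The replicate-heavy checks scale down to stay desk-sized: effect-recovery
runs 100 cohorts of 33 subjects at 127.155 Hz with 81/49/49-s tasks (5/3/3
windows); the type-I-error check runs 500 null cohorts of 8 subjects, 12
channels at 63.578 Hz with 35-s tasks (2 windows each). Under the null the
task labels are exchangeable by construction, so the rejection rate is
insensitive to this down-scaling; for effect recovery the shortened tasks
make per-task means noisier, which the calibration above already reflects.

## Known limitations

* EDF support covers the common 16-bit variant with a fixed physical range
  per file; EDF+ annotations are ignored.
* Connectedness repair changes the effective edge count for the affected
  windows (logged); metrics from repaired windows are not excluded.
* The rm-ANOVA handles one within factor with complete cases only; subjects
  with missing cells are dropped, not imputed.
* With very small windows (T ≲ 100) the mean-phase-coherence noise floor is
  large and rank thresholding approaches random edge selection; window
  length below ~5 s is not recommended at typical EEG rates.
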