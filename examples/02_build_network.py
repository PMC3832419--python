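"""From one EEG segment to functional networks and their statistics.

Takes one synthetic subject, extracts the baseline and intentional-learning
segments, computes per-window synchronization matrices, thresholds them into
fixed-degree binary networks and prints clustering coefficient C and average
shortest path length L per window.
"""

import numpy as np

import netlearn as nl

spec = nl.CohortSpec(n_subjects=2, n_channels=16, fs=127.155,
                     duration_B=49.0, duration_L1=33.0, duration_L2=49.0,
                     gap_s=2.0, effect_delta=0.4, seed=5)
bundle = nl.generate_subject(spec, 0)
print(f"subject {bundle.behavior.subject_id} ({bundle.behavior.group}), "
      f"latent ability z = {bundle.truth.ability_z:+.2f}")

for task in ("B", "L2"):
    segment = nl.extract_segment(bundle.recording, bundle.schedule, task)
    mats = nl.sync_matrices(segment)                 # 16.1-s windows
    nets = [nl.threshold_network(m) for m in mats]   # mean degree ceil(2 ln N)
    rows = nl.window_metrics(nets)
    print(f"\ntask {task}: {len(rows)} windows, "
          f"{nets[0].n_edges} edges each (repaired: "
          f"{sum(n.repaired for n in nets)}/{len(nets)})")
    for r in rows:
        print(f"  window {r.window_index}:  C = {r.clustering:.3f}  "
              f"L = {r.path_length:.3f}")
    print(f"  task mean: C = {np.mean([r.clustering for r in rows]):.3f}  "
          f"L = {np.mean([r.path_length for r in rows]):.3f}")

print("\nWith a strong planted effect, C is higher during intentional "
      "learning (L2)\nthan at baseline while L changes little: edges "
      "concentrate into triangle-rich\nsub-clusters without losing the "
      "between-community bridges.")
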