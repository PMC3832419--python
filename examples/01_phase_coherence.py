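"""Mean phase coherence of two coupled oscillators.

Generates pairs of noisy 10-Hz oscillator channels that share an increasing
fraction of their phase wander, and prints the mean phase coherence (MPC) of
each pair next to the estimator's noise floor.
"""

import numpy as np

import netlearn as nl

FS = 127.155
T_WINDOW = int(np.floor(16.1 * FS))

print(f"window: 16.1 s = {T_WINDOW} samples; "
      f"Rayleigh noise floor sqrt(pi/4T) = {nl.rayleigh_level(T_WINDOW):.4f}\n")
print("coupling   mean MPC")
for coupling in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
    values = []
    for seed in range(5):
        rec = nl.coupled_pair(coupling, duration_s=33.0, fs=FS, seed=seed)
        values += [m.values[0, 1] for m in nl.sync_matrices(rec)]
    print(f"  {coupling:.1f}      {np.mean(values):.3f}")

print("\nMPC rises monotonically with the shared-wander fraction: 0 coupling"
      "\nsits near the noise floor, full coupling approaches perfect locking"
      "\n(capped below 1 by measurement noise).")
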