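"""Simulate a benchmark VAR network and read off its true information measures.

The seven-node preset mimics the topology of a brain-cardiovascular-
respiratory network: bidirectional coupling between cardiac period (RR)
and respiration (RESP), cardiac and respiratory drive of the pulse
arrival time (PAT), and two weak brain-to-peripheral links.
"""

import numpy as np

from netinfodyn import benchmark_preset, model_implied_measures, simulate_var

spec = benchmark_preset("paperlike7")
print("nodes:", spec.labels)
print("true directed links (source -> target):")
adj = spec.truth_adjacency
for i in range(spec.M):
    for j in range(spec.M):
        if i != j and adj[i, j]:
            print(f"  {spec.labels[i]} -> {spec.labels[j]}")

# exact measures implied by the model (no estimation involved)
truth = model_implied_measures(spec.to_model(), labels=spec.labels)
print("\nmodel-implied measures (nats):")
print(f"{'node':6s} {'H':>7s} {'S':>7s} {'T':>7s} {'N':>7s}")
for j, lab in enumerate(truth.labels):
    print(f"{lab:6s} {truth.H[j]:7.3f} {truth.S[j]:7.3f} "
          f"{truth.T[j]:7.3f} {truth.N[j]:7.3f}")

# one finite realization; identical seed gives an identical series
X = simulate_var(spec, n_samples=300, seed=1)
print(f"\nsimulated series: {X.shape[0]} x {X.shape[1]}, "
      f"sample sd per node: {np.round(X.std(axis=1), 2)}")
print("Storage S is predictability from a node's own past; transfer T is "
      "what the rest of the network adds; N is the unpredictable rest. "
      "Peripheral nodes store more, brain-band nodes generate more new "
      "information - by construction of the preset.")
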