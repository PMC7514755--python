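"""Decompose a network series into storage, transfer and new information.

Every node's entropy splits exactly as H = S + T + N: what its own past
explains (S), what the other nodes' pasts add (T), and what remains
unpredictable (N).  Conditional transfer entropies T_{i->j|k} quantify
each directed pair link beyond all other nodes.
"""

import numpy as np

from netinfodyn import decompose_network, preprocess_recording, synth_recording

rec = synth_recording(duration=490.0, state="REST", seed=21)
net = preprocess_recording(rec)

meas = decompose_network(net.X, labels=net.labels)  # order chosen by AIC
print(f"VAR order (AIC): {meas.m}, backend: {meas.backend}\n")
print(meas.to_frame(subject="demo", state="REST").round(3).to_string(index=False))

resid = np.max(np.abs(meas.H - (meas.S + meas.T + meas.N)))
print(f"\ndecomposition identity residual: {resid:.2e} (exact by construction)")

print("\nconditional transfer matrix (rows = sources, cols = targets, nats):")
print(meas.tcond_frame().round(3).to_string())
print("\nLarge entries mark strong directed influences; RESP -> RR is the "
      "respiratory sinus arrhythmia the generator builds in.")
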