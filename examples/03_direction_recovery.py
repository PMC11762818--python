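"""Recover the direction of a known coupling from PCMI asymmetry.

Simulates a 4-channel recording with a single unidirectional Alpha2 edge
(channel 0 -> 1, 10 ms conduction lag, strength 0.6) and shows that the
segment-averaged PCMI is larger in the true direction.
"""

import numpy as np

from mssecnn import CouplingEdge, SimConfig, ordinalize, pcmi_directed, \
    preprocess_recording, simulate_recording

cfg = SimConfig(
    n_channels=4, duration=120.0,
    coupling_edges=[CouplingEdge(src=0, dst=1, band="Alpha2", lag=10, strength=0.6)],
    class_effect=0.0,
)
rec = simulate_recording(cfg, label="pre", seed=0)
segments = preprocess_recording(rec)

fwd, rev = [], []
for seg in segments:
    s0 = ordinalize(seg.data["Alpha2"][0])
    s1 = ordinalize(seg.data["Alpha2"][1])
    fwd.append(pcmi_directed(s0, s1))
    rev.append(pcmi_directed(s1, s0))

print(f"segments: {len(segments)}")
print(f"PCMI(0 -> 1): {np.mean(fwd):.4f} bits  (true coupling direction)")
print(f"PCMI(1 -> 0): {np.mean(rev):.4f} bits")
print(f"directionality index: "
      f"{(np.mean(fwd) - np.mean(rev)) / (np.mean(fwd) + np.mean(rev)):+.3f}")
# A positive index recovers the injected 0 -> 1 direction; the magnitude is
# small because both channels share strong instantaneous band correlation.
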