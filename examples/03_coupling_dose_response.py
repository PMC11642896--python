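"""Dose-response of causal features to the planted coupling strength.

Generates a few recordings per coupling level and shows that linear
Granger causality and transfer entropy in the respiration->RR direction
rise monotonically with the fraction of RR variance driven by breathing.
"""

import numpy as np

from cardioresp import HEALTHY, generate_recording
from cardioresp.coupling import directional_coupling_features
from cardioresp.features import paired_signals_25hz
from cardioresp.synthetic import calibrate_preset

levels = (0.0, 0.2, 0.5, 0.8)
print(f"{'coupling':>8} {'GC':>8} {'TE bits':>8} {'lsNGC F':>8}")
for c in levels:
    preset = HEALTHY.with_(coupling_strength=c)
    cal = calibrate_preset(preset, seed=12345)
    gc, te, f = [], [], []
    for i in range(5):
        rec = generate_recording(preset, seed=100 + i,
                                 scales=(cal.a, cal.g), between_subject=False)
        resp25, rr25 = paired_signals_25hz(rec)
        feats = directional_coupling_features(resp25, rr25, "Resp->RR", seed=i)
        gc.append(feats["GC_RespToRR"])
        te.append(feats["TE_RespToRR"])
        f.append(feats["lsNGC_F_RespToRR"])
    print(f"{c:8.1f} {np.mean(gc):8.3f} {np.mean(te):8.4f} {np.mean(f):8.1f}")

print("\nAll three causal measures increase with the planted coupling:")
print("at 0 the RR series is independent of respiration and the values")
print("sit at their estimation-noise floor.")
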