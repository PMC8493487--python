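"""Why a Stokes-only polarimeter misreads fiber orientation.

A sample whose circular retardance is ignored by the naive
pure-linear-retarder analysis shows an optic-axis deviation of exactly
half the circular retardance, with opposite sign.  The sweep below
regresses the deviation against circular retardance.
"""

import numpy as np

import mmpol as mp

M, truth = mp.deviation_sweep(np.linspace(-1.0, -0.05, 12), deltaL=1.5, theta=0.3, block_px=4)
est = mp.analyze_stack(mp.simulate_stack(M))
table, r = mp.axis_deviation_analysis(
    est.thetaFA_S, truth["thetaFA"], truth["deltaC"], block_px=4
)
good = table.dropna(subset=["deviation_rad"])
print(good[["col", "deltaC_rad", "deviation_rad"]].to_string(index=False))

slope = np.polyfit(good.deltaC_rad, good.deviation_rad, 1)[0]
print(f"\nregression slope: {slope:.6f} (deviation = -deltaC/2)")
print(f"Pearson r: {r:.6f}")
print("a circular retardance of -0.8 rad therefore fakes a +0.4 rad axis rotation")
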