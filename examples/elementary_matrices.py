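"""Elementary Mueller matrices: retarder, polarizer, circular retarder.

Builds the ideal quarter waveplate at 30 deg and the horizontal
polarizer, and shows how a circular retarder rotates a linear state on
the Poincare sphere.
"""

import numpy as np

import mmpol as mp

qwp = mp.mueller_linear_retarder(np.pi / 2, np.deg2rad(30))
print("Quarter waveplate, fast axis 30 deg:")
print(np.round(qwp, 3))
# m24 = -0.866 fixes the handedness convention used throughout the package

pol = mp.mueller_linear_polarizer(0.0)
print("\nHorizontal linear polarizer (m11-normalized):")
print(np.round(pol, 3))

# a circular retarder of +0.6 rad carries horizontal light to azimuth
# -0.6 rad in the S1-S2 plane (clockwise rotation about S3)
s_out = mp.apply_mueller(mp.mueller_circular_retarder(0.6), mp.unit_stokes("H"))
azimuth = np.arctan2(s_out[2], s_out[1])
print(f"\nCircular retarder 0.6 rad on H light -> S1-S2 azimuth {azimuth:+.3f} rad")
print("(equals -0.6: positive circular retardance rotates clockwise)")
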