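"""Gate collective variables and microstate maps.

Measures the two intracellular-gate distances (R5-D369 salt bridge,
Y268-Q361 hydrogen bond) and the Y268 chi1 rotamer on synthetic frames,
then projects a fluctuating gate onto the 2D distance plane and locates
the populated microstates.
"""

import numpy as np

from leutkit.mdgeom import (GateTimeSeries, chi1, classify_chi1, cv_density,
                            gate_distances)
from frame_helpers import make_gate_frame

frame = make_gate_frame()
d_salt, d_hbond = gate_distances(frame)
angle = chi1(frame, 268)
print(f"R5-D369 = {d_salt:.2f} A   Y268-Q361 = {d_hbond:.2f} A   "
      f"chi1(Y268) = {angle:.0f} deg ({classify_chi1(angle)})")

# a fluctuating gate: closed (4 A, 3 A), salt-bridge-open (9 A, 3 A) and
# doubly open (8 A, 7.5 A) populations
rng = np.random.default_rng(0)
populations = [(4.0, 3.0, 2000), (9.0, 3.0, 1200), (8.0, 7.5, 600)]
d1 = np.concatenate([rng.normal(a, 0.15, n) for a, _, n in populations])
d2 = np.concatenate([rng.normal(b, 0.15, n) for _, b, n in populations])
series = GateTimeSeries(salt_bridge=d1, hbond=d2,
                        chi1_deg=np.full(d1.size, np.nan),
                        frame_indices=np.arange(d1.size))

cvmap = cv_density(series, bin_width=0.25, n_peaks=3)
for m in cvmap.microstates:
    print(f"microstate '{m.label}': center = ({m.center[0]:.2f}, "
          f"{m.center[1]:.2f}) A, {m.count} frames in peak bin")
# Microstates are ranked local maxima of the 2D histogram: 'a' is the
# most populated (closed) gate configuration, 'b' and 'c' the partially
# opened ones.
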