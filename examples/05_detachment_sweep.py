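"""Sweep the detachment coefficient and watch transport switch on.

The unbinding rate scales as 1/Ad, so small Ad means near-instant unbinding
and large Ad long processive runs.  The mean zero-load run length is
(P_f/P_det) x 8 nm = Ad x 8 nm: transport requires runs longer than the
110 nm spring dead zone, i.e. Ad well above ~14, which this mini sweep makes
visible in the steady-state velocity.
"""

import numpy as np

from kinnet import SimulationParams, run_ensemble
from kinnet.engine import with_ad
from kinnet.observables import cargo_velocity

base = SimulationParams(structure="NRS", n_mts=80, duration=10.0, n_replicates=20)

print(f"{'Ad':>8} {'run length (nm)':>16} {'vc 5-10 s (nm/s)':>18}")
for ad in (0.2, 1.0, 5.0, 20.0, 100.0):
    records = run_ensemble(with_ad(base, ad), master_seed=3)
    times, vc = cargo_velocity(records, window=0.1)
    sel = times >= 5.0
    print(f"{ad:8.1f} {ad * 8:16.1f} {np.nanmean(vc[sel]):18.1f}")
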