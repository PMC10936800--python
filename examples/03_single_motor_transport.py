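"""Single-motor transport oracle: velocity = step size x stepping rate.

One kinesin on a single straight microtubule, detachment disabled and
thermal noise off.  After the dead-zone spring engages (the motor must lead
the cargo by r0 = 110 nm before any force is transmitted), the cargo is
dragged at the unloaded stepping speed: the tiny drag force
gamma * v ~ 0.13 pN barely loads the motor.
"""

import numpy as np

from kinnet import CargoParams, MotorParams, SimulationParams, run_simulation
from kinnet.network import Microtubule, Network, compute_crossings, RegionGeometry

mt = Microtubule(id=0, minus_end=np.array([50.0, 3500.0]),
                 unit_vector=np.array([1.0, 0.0]))
net = Network([mt], compute_crossings([mt]), "NRS", RegionGeometry(), seed=0)

params = SimulationParams(
    n_motors=1,
    duration=25.0,
    n_replicates=1,
    motor=MotorParams(Ad=float("inf")),  # detachment off
    cargo=CargoParams(kBT=0.0),  # noise off
    fpt_target=0.0,
)
tr = run_simulation(params, network=net, seed=3)
sel = tr.times >= 2.0
v = (tr.cargo[-1, 0] - tr.cargo[sel][0, 0]) / (tr.times[-1] - tr.times[sel][0])
print(f"measured cargo velocity: {v:.1f} nm/s")
print("expected: 8 nm x (R/(1+R))/tau_D(0) = 143.7 nm/s at zero load")
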