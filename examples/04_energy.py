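"""ATP accounting: from synaptic current to pump cost.

A rectangular 100 pA EPSC lasting 10 ms moves 1 pC of charge; at 3 Na+ per
ATP that is ~2.08 million ATP molecules.  The same conversion applied to a
simulated synaptic event gives the metabolic price of one EPSP.
"""

import numpy as np

from stellate import charge_to_atp, generate_morphology, simulate
from stellate.biophysics import CLS_INDEX
from stellate.energetics import charge_pC_to_atp

dt = 0.01
trace = np.full(int(10 / dt) + 1, -0.1)  # 100 pA inward, 10 ms
print(f"rectangular 1 pC EPSC -> {charge_to_atp(trace, dt):.4g} ATP")

morph = generate_morphology(seed=1)
comp = int(np.argmin(np.abs(morph.path_distance - 80.0)))
ev = (np.array([0.005]), np.array([comp]), np.array([CLS_INDEX["tc"]]), np.array([0.001]))
sim = simulate(morph, events=ev, duration_s=0.06, dt_ms=0.025)
atp = charge_pC_to_atp(sim.charge_pC["tc"])
print(f"one 1 nS tc event moves {sim.charge_pC['tc']:.3f} pC -> {atp:.3g} ATP")

# Roughly: 1 nS x 70 mV x ~2.5 ms of effective kernel ~ 0.17 pC, i.e. a few
# hundred thousand ATP per quantum -- the currency the efficiency analysis is
# denominated in.
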