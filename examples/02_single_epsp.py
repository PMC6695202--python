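"""Somatic EPSP and IPSP of single synaptic events at their default sizes.

Activates one thalamocortical synapse (1 nS peak, tau 0.3/1.7 ms, E = 0 mV)
and one inhibitory synapse (0.5 nS, tau 1/10 ms, E = -75 mV) on a dendritic
compartment ~80 um from the soma and reports the somatic peak responses.
"""

import numpy as np

from stellate import generate_morphology, simulate
from stellate.biophysics import CLS_INDEX

morph = generate_morphology(seed=1)
comp = int(np.argmin(np.abs(morph.path_distance - 80.0)))
print(f"synapse on compartment {comp} at {morph.path_distance[comp]:.1f} um")

ev = (np.array([0.005]), np.array([comp]), np.array([CLS_INDEX["tc"]]), np.array([0.001]))
sim = simulate(morph, events=ev, duration_s=0.06, dt_ms=0.025, record_dt_ms=0.025)
print(f"tc EPSP peak:  {sim.vm_soma.max() + 70:.3f} mV  (target ~0.6-0.8 mV)")

ev = (np.array([0.005]), np.array([comp]), np.array([CLS_INDEX["inh"]]), np.array([0.0005]))
sim = simulate(morph, events=ev, duration_s=0.12, dt_ms=0.025, record_dt_ms=0.025)
print(f"inh IPSP peak: {-(sim.vm_soma.min() + 70) * 1e3:.1f} uV  (population mean ~93 uV)")

# The EPSP is sub-millivolt: a single thalamocortical contact barely moves the
# soma, which is what makes this synapse 'weak' and the information question
# interesting.
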