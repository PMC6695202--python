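"""Voltage-gated channel kinetics and their tabulated form.

The membrane carries four active conductances:

* fast Na (gates m^3 h), Traub-type rate functions with a threshold-shift
  parameter ``v_t`` that places spike threshold near -50 mV;
* delayed-rectifier K (n^4), same family;
* slow non-inactivating K (p), a high-threshold conductance with a sigmoid
  steady state and a slow, voltage-independent time constant -- this is the
  adaptation current that keeps the bombarded cell at a low firing rate;
* L-type Ca (q^2) with a fixed reversal potential; its current is tiny and is
  tracked mainly for the calcium bookkeeping.

The rate constants are frozen here; they are this package's parameterisation
of a standard cortical Hodgkin-Huxley scheme.  The integrator never evaluates
these functions directly: ``build_gate_tables`` pre-tabulates, for a given time
step, the steady state and the Rush-Larsen decay factor exp(-dt/tau) of every
gate on a fine voltage grid.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GATES", "gate_steady_tau", "build_gate_tables", "VGRID_MIN", "VGRID_MAX", "VGRID_DV"]

V_T = -55.0  # mV, threshold shift of the Na/Kdr rate functions
KS_VHALF = -25.0  # mV, slow-K activation midpoint
KS_SLOPE = 5.0  # mV
KS_TAU = 600.0  # ms, voltage-independent (slow spike-frequency adaptation)
CA_VHALF = -20.0  # mV, L-type activation midpoint
CA_SLOPE = 6.0  # mV
CA_TAU = 2.0  # ms

GATES = ("m", "h", "n", "p", "q")

VGRID_MIN = -120.0
VGRID_MAX = 70.0
VGRID_DV = 0.05


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity patched."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 + x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs / y))
    return out


def gate_steady_tau(gate: str, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state value and time constant (ms) of one gate at voltage v (mV)."""
    v = np.asarray(v, dtype=float)
    if gate == "m":
        a = 0.32 * _vtrap(v - V_T - 13.0, 4.0)
        b = 0.28 * _vtrap(-(v - V_T - 40.0), 5.0)
    elif gate == "h":
        a = 0.128 * np.exp(-(v - V_T - 17.0) / 18.0)
        b = 4.0 / (1.0 + np.exp(-(v - V_T - 40.0) / 5.0))
    elif gate == "n":
        a = 0.032 * _vtrap(v - V_T - 15.0, 5.0)
        b = 0.5 * np.exp(-(v - V_T - 10.0) / 40.0)
    elif gate == "p":
        # high-threshold, very slow activation: with the large somatic density
        # this acts as cumulative spike-frequency adaptation while staying
        # nearly silent at sub-threshold voltages
        inf = 1.0 / (1.0 + np.exp(-(v - KS_VHALF) / KS_SLOPE))
        tau = np.full_like(v, KS_TAU)
        return inf, tau
    elif gate == "q":
        inf = 1.0 / (1.0 + np.exp(-(v - CA_VHALF) / CA_SLOPE))
        tau = np.full_like(v, CA_TAU)
        return inf, tau
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"unknown gate {gate!r}")
    tau = 1.0 / (a + b)
    return a * tau, np.maximum(tau, 0.01)


def build_gate_tables(dt_ms: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Tabulate (inf, exp(-dt/tau)) for all gates on the voltage grid.

    Returns ``(inf_table, decay_table, vmin, inv_dv)`` where the tables have
    shape (n_gates, n_voltages) and are meant for linear interpolation.
    """
    v = np.arange(VGRID_MIN, VGRID_MAX + VGRID_DV, VGRID_DV)
    inf = np.empty((len(GATES), v.size))
    dec = np.empty((len(GATES), v.size))
    for g, name in enumerate(GATES):
        gi, gt = gate_steady_tau(name, v)
        inf[g] = gi
        dec[g] = np.exp(-dt_ms / gt)
    return inf, dec, VGRID_MIN, 1.0 / VGRID_DV
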