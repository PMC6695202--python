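"""ATP accounting of postsynaptic ion flux.

Every inward charge at excitatory synapses and through Na channels is treated
as Na+ that the Na,K-ATPase must extrude at a stoichiometry of 3 Na+ per ATP,
so ATP = Q / (3 e).  Inhibitory (Cl-) flux carries no ATP cost in the
signalling budget, and the calcium pump's ATP is excluded by default; both are
deliberate accounting choices, not measurements.

Sign convention: membrane currents are negative inward.  Trace integration
uses the trapezoidal rule on the negative (inward) part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophysics import SimulationResult

__all__ = [
    "ELEMENTARY_CHARGE",
    "ATP_PER_CHARGE",
    "EnergyReport",
    "charge_to_atp",
    "charge_pC_to_atp",
    "synaptic_energy",
    "ap_energy",
    "efficiency",
    "energy_report",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
NA_PER_ATP = 3.0
ATP_PER_CHARGE = 1.0 / (NA_PER_ATP * ELEMENTARY_CHARGE)  # ATP per coulomb


def charge_to_atp(current_nA: np.ndarray, dt_ms: float) -> float:
    """ATP count for the inward charge carried by a current trace.

    Integrates the inward (negative) part of the trace with the trapezoidal
    rule; Q in pC converts to ATP via Q / (3 e).
    """
    i = np.asarray(current_nA, dtype=float)
    if not np.all(np.isfinite(i)):
        raise ValueError("current trace contains non-finite samples")
    inward = np.clip(-i, 0.0, None)  # nA, now positive
    q_pC = float(np.trapezoid(inward, dx=dt_ms))  # nA * ms = pC
    return q_pC * 1e-12 * ATP_PER_CHARGE


def charge_pC_to_atp(q_pC: float) -> float:
    """ATP count for an already-integrated inward charge (pC)."""
    return q_pC * 1e-12 * ATP_PER_CHARGE


def synaptic_energy(sim: SimulationResult, cls: str) -> float:
    """ATP/s spent reversing the inward synaptic flux of one class.

    Uses the full-resolution charge accumulated during the run (the recorded
    current traces are subsampled and would under-resolve fast EPSCs).
    """
    if cls not in sim.charge_pC:
        raise KeyError(f"simulation carries no current for class {cls!r}")
    return charge_pC_to_atp(sim.charge_pC[cls]) / sim.duration_s


def ap_energy(sim: SimulationResult, window_ms: float | None = None) -> float:
    """ATP/s for the Na-channel current.

    By default the whole-trace integral is used: it is parameter-free and, at
    rest, the Na window current is negligible.  With ``window_ms`` the
    integral is restricted to +-window_ms around each detected spike (a
    sensitivity-analysis variant; requires recorded traces).
    """
    if window_ms is None:
        return charge_pC_to_atp(sim.charge_na_pC) / sim.duration_s
    if sim.i_na.size == 0:
        raise ValueError("windowed AP energy needs recorded traces")
    dt = sim.record_dt_ms
    mask = np.zeros(sim.i_na.size, dtype=bool)
    half = int(round(window_ms / dt))
    for t in sim.spike_times_s:
        c = int(round(t * 1000.0 / dt))
        mask[max(c - half, 0) : c + half + 1] = True
    return charge_to_atp(np.where(mask, sim.i_na, 0.0), dt) / sim.duration_s


def efficiency(te_bits_per_s: float, atp_per_s: float) -> float:
    """Bits transmitted per ATP molecule consumed."""
    if atp_per_s <= 0:
        raise ZeroDivisionError(
            "ATP rate is zero (gain 0?) - efficiency undefined"
        )
    return te_bits_per_s / atp_per_s


@dataclass
class EnergyReport:
    """Signalling ATP budget of one run (ATP/s)."""

    atp_syn: float  # axon of interest, summed over its three contacts
    atp_tc: float
    atp_cc: float
    atp_ap: float  # Na-channel (action potential) load
    mode: str = "model-currents"

    @property
    def atp_total_signalling(self) -> float:
        return self.atp_syn + self.atp_tc + self.atp_cc + self.atp_ap


def energy_report(sim: SimulationResult, mode: str = "model-currents") -> EnergyReport:
    return EnergyReport(
        atp_syn=synaptic_energy(sim, "syn"),
        atp_tc=synaptic_energy(sim, "tc"),
        atp_cc=synaptic_energy(sim, "cc"),
        atp_ap=ap_energy(sim),
        mode=mode,
    )
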