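"""Membrane model assembly and simulation driver.

The model is a branched-cable Hodgkin-Huxley neuron: passive leak everywhere,
fast Na / delayed-rectifier K / slow K concentrated at the soma with much lower
dendritic densities, a tiny uniformly distributed L-type Ca conductance, and a
calcium pool per compartment (buffer, membrane pump, longitudinal diffusion).

The resting potential is made an exact equilibrium by solving the per-compartment
leak reversal so that the net membrane current vanishes at V_rest with every
gate at its steady state -- the conventional way of initialising a cell that
carries standing sub-threshold conductances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import channels
from .engine import run_model
from .morphology import Morphology

__all__ = [
    "MembraneParams",
    "CalciumParams",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "detect_spikes",
]

SYN_CLASSES = ("tc", "cc", "inh", "syn")
CLS_INDEX = {name: i for i, name in enumerate(SYN_CLASSES)}


class SimulationError(RuntimeError):
    pass


@dataclass
class MembraneParams:
    """Passive and active membrane parameters.

    ``cm`` is 1.5 uF/cm^2: the standard 1 uF/cm^2 raised by 50% to absorb the
    membrane added by spines, which are not modelled explicitly.  Conductance
    densities are in mS/cm^2 except ``g_ca_density`` which is in pS/um^2
    (equivalent to 1e-4 mS/cm^2 per unit).
    """

    cm: float = 1.5  # uF/cm^2
    rm: float = 16_000.0  # Ohm cm^2
    ra: float = 100.0  # Ohm cm
    v_rest: float = -70.0  # mV
    e_na: float = 70.0  # mV
    e_k: float = -77.0  # mV
    e_ca: float = 120.0  # mV (fixed Ca reversal)
    g_na_soma: float = 300.0
    g_kdr_soma: float = 30.0
    g_ks_soma: float = 100.0
    g_na_dend: float = 3.0
    g_kdr_dend: float = 1.0
    g_ks_dend: float = 1.0
    g_ca_density: float = 0.03  # pS/um^2, uniform

    def densities(self, region: np.ndarray) -> dict[str, np.ndarray]:
        soma = region == 0
        g_na = np.where(soma, self.g_na_soma, self.g_na_dend).astype(float)
        g_kdr = np.where(soma, self.g_kdr_soma, self.g_kdr_dend).astype(float)
        g_ks = np.where(soma, self.g_ks_soma, self.g_ks_dend).astype(float)
        return {"na": g_na, "kdr": g_kdr, "ks": g_ks}


@dataclass
class CalciumParams:
    """Calcium pool parameters (Carnevale-Hines style buffer and pump)."""

    enabled: bool = True
    d_ca: float = 0.6  # um^2/ms, longitudinal diffusion
    buffer_total: float = 3e-3  # mM (3 uM)
    k_d: float = 1e-3  # mM (1 uM)
    buffer_kon: float = 1.0  # mM^-1 ms^-1
    pump_density: float = 1e-13  # mol/cm^2
    k1: float = 1.0  # mM^-1 ms^-1
    k2: float = 0.005  # ms^-1
    k3: float = 1.0  # ms^-1
    k4: float = 0.005  # mM^-1 ms^-1

    @property
    def pump_kd_binding(self) -> float:
        """Apparent dissociation constant of the binding step (mM)."""
        return self.k2 / self.k1

    @property
    def pump_kd_release(self) -> float:
        """Apparent dissociation constant of the release step (mM)."""
        return self.k3 / self.k4


# Double-exponential kernel constants per class: (tau_rise, tau_fall, E_rev,
# g_peak).  Kernels are peak-normalised: the stated conductance is the peak
# reached after one event (pass ``peak_normalized=False`` to ``simulate`` for
# raw amplitude semantics).
DEFAULT_KERNELS = {
    "tc": (0.3, 1.7, 0.0, 0.001),
    "cc": (0.3, 1.7, 0.0, 0.0008),
    "inh": (1.0, 10.0, -75.0, 0.0005),
    "syn": (0.3, 1.7, 0.0, 0.001),
}


def kernel_norm(tau_rise: float, tau_fall: float) -> float:
    """Peak value of exp(-t/tau_fall) - exp(-t/tau_rise) (at its analytic
    maximum); dividing by it converts amplitude to peak-conductance semantics."""
    if not tau_fall > tau_rise > 0:
        raise ValueError("require tau_fall > tau_rise > 0")
    tp = (tau_rise * tau_fall) / (tau_fall - tau_rise) * np.log(tau_fall / tau_rise)
    return float(np.exp(-tp / tau_fall) - np.exp(-tp / tau_rise))


@dataclass
class SimulationResult:
    """Output of one seeded run."""

    duration_s: float
    dt_ms: float
    record_dt_ms: float
    t_rec_ms: np.ndarray  # recording grid
    vm_soma: np.ndarray  # mV on the recording grid
    spike_times_s: np.ndarray
    syn_current: dict[str, np.ndarray]  # nA, summed over compartments, per class
    i_na: np.ndarray  # nA, total Na-channel current
    inj_current: dict[str, np.ndarray]  # nA per injected-conductance channel
    charge_pC: dict[str, float]  # inward synaptic charge per class (full-dt)
    charge_na_pC: float
    charge_inj_pC: dict[str, float]
    seed: int | None
    config_fingerprint: str

    @property
    def firing_rate_hz(self) -> float:
        return float(len(self.spike_times_s) / self.duration_s)

    def save_spikes_csv(self, path: str) -> None:
        np.savetxt(path, self.spike_times_s, fmt="%.6f")

    def save_traces_h5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["record_dt_ms"] = self.record_dt_ms
            f.attrs["duration_s"] = self.duration_s
            f.attrs["config_fingerprint"] = self.config_fingerprint
            f.create_dataset("t_ms", data=self.t_rec_ms)
            f.create_dataset("vm_soma", data=self.vm_soma)
            f.create_dataset("i_na", data=self.i_na)
            f.create_dataset("spike_times_s", data=self.spike_times_s)
            for k, tr in self.syn_current.items():
                f.create_dataset(f"i_syn/{k}", data=tr)


def _fingerprint(*parts) -> str:
    js = json.dumps([str(p) for p in parts], sort_keys=True)
    return hashlib.sha256(js.encode()).hexdigest()[:16]


def _equilibrium_leak(morph: Morphology, mp: MembraneParams,
                      g_leak: np.ndarray, g_arrays: dict[str, np.ndarray],
                      g_ca: np.ndarray) -> np.ndarray:
    v0 = mp.v_rest
    gates = {g: channels.gate_steady_tau(g, np.array([v0]))[0][0] for g in channels.GATES}
    i_active = (
        g_arrays["na"] * gates["m"] ** 3 * gates["h"] * (v0 - mp.e_na)
        + (g_arrays["kdr"] * gates["n"] ** 4 + g_arrays["ks"] * gates["p"]) * (v0 - mp.e_k)
        + g_ca * gates["q"] ** 2 * (v0 - mp.e_ca)
    )
    return v0 + i_active / g_leak


def build_arrays(morph: Morphology, mp: MembraneParams):
    """Per-compartment capacitance (nF), leak (uS), channel conductances (uS)
    and axial coupling to the parent (uS)."""
    area = morph.area  # um^2
    cap = mp.cm * area * 1e-5  # nF
    g_leak = (1.0 / mp.rm) * 1e3 * area * 1e-5  # uS
    dens = mp.densities(morph.region)
    g = {k: v * area * 1e-5 for k, v in dens.items()}  # mS/cm^2 -> uS
    g_ca = mp.g_ca_density * 1e-4 * area * 1e-5  # pS/um^2 -> mS/cm^2 -> uS

    n = morph.n_compartments
    g_ax = np.zeros(n)
    half_r = mp.ra * (2.0 * morph.length / (np.pi * morph.diameter**2)) * 1e4  # Ohm
    # the soma is treated as a point: only the child's half-resistance counts
    for i in range(1, n):
        pa = int(morph.parent[i])
        r = half_r[i] + (0.0 if morph.region[pa] == 0 else half_r[pa])
        g_ax[i] = 1e6 / r  # uS
    return cap, g_leak, g, g_ca, g_ax


def simulate(
    morph: Morphology,
    membrane: MembraneParams | None = None,
    calcium: CalciumParams | None = None,
    events: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    duration_s: float = 1.0,
    dt_ms: float = 0.025,
    seed: int | None = None,
    kernels: dict[str, tuple[float, float, float, float]] | None = None,
    inj_conductance: dict[str, tuple[np.ndarray, float]] | None = None,
    i_const_nA: np.ndarray | None = None,
    record_dt_ms: float = 0.1,
    record_traces: bool = True,
    spike_threshold_mV: float = 0.0,
    spike_lockout_ms: float = 3.0,
    passive: bool = False,
    peak_normalized: bool = True,
) -> SimulationResult:
    """Integrate the model under a synaptic event train.

    ``events`` is ``(times_s, comp_ids, class_idx, weights_uS)`` with class
    indices following :data:`SYN_CLASSES`; weights are peak conductances.
    ``inj_conductance`` maps a label to ``(g_trace_uS_on_dt_grid, e_rev_mV)``
    injected at the soma with the instantaneous-voltage current law.
    """
    if duration_s <= 0 or dt_ms <= 0:
        raise ValueError("duration and dt must be positive")
    mp = membrane or MembraneParams()
    cp = calcium or CalciumParams()
    kern = dict(DEFAULT_KERNELS)
    if kernels:
        kern.update(kernels)

    n = morph.n_compartments
    cap, g_leak, g, g_ca_arr, g_ax = build_arrays(morph, mp)
    if passive:
        z = np.zeros(n)
        g = {"na": z, "kdr": z.copy(), "ks": z.copy()}
        g_ca_arr = np.zeros(n)
    e_leak = _equilibrium_leak(morph, mp, g_leak, g, g_ca_arr)

    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    tab_inf, tab_dec, vmin, inv_dv = channels.build_gate_tables(dt_ms)

    # synapse class constants
    n_cls = len(SYN_CLASSES)
    syn_dec_r = np.empty(n_cls)
    syn_dec_f = np.empty(n_cls)
    syn_e = np.empty(n_cls)
    syn_norm = np.empty(n_cls)
    for c, name in enumerate(SYN_CLASSES):
        tr, tf, e, _g = kern[name]
        syn_dec_r[c] = np.exp(-dt_ms / tr)
        syn_dec_f[c] = np.exp(-dt_ms / tf)
        syn_e[c] = e
        syn_norm[c] = kernel_norm(tr, tf) if peak_normalized else 1.0

    if events is None:
        ev_t = np.empty(0)
        ev_comp = np.empty(0, dtype=np.int64)
        ev_cls = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0)
    else:
        ev_t, ev_comp, ev_cls, ev_w = events
        ev_t = np.asarray(ev_t, dtype=float)
        ev_comp = np.asarray(ev_comp, dtype=np.int64)
        ev_cls = np.asarray(ev_cls, dtype=np.int64)
        ev_w = np.asarray(ev_w, dtype=float)
        if ev_comp.size and (ev_comp.min() < 0 or ev_comp.max() >= n):
            raise ValueError("event refers to unknown compartment id")
        keep = ev_t < duration_s
        ev_t, ev_comp, ev_cls, ev_w = ev_t[keep], ev_comp[keep], ev_cls[keep], ev_w[keep]
        order = np.argsort(ev_t, kind="stable")
        ev_t, ev_comp, ev_cls, ev_w = ev_t[order], ev_comp[order], ev_cls[order], ev_w[order]
    ev_step = np.minimum((ev_t * 1000.0 / dt_ms).astype(np.int64), max(n_steps - 1, 0))

    inj_labels: list[str] = []
    if inj_conductance:
        inj_labels = list(inj_conductance)
        inj_g = np.zeros((len(inj_labels), n_steps))
        inj_e = np.zeros(len(inj_labels))
        for j, lab in enumerate(inj_labels):
            tr, e = inj_conductance[lab]
            tr = np.asarray(tr, dtype=float)
            if tr.size != n_steps:
                raise ValueError(
                    f"injected conductance {lab!r} has {tr.size} samples, expected {n_steps}"
                )
            inj_g[j] = tr
            inj_e[j] = e
    else:
        inj_g = np.zeros((0, n_steps))
        inj_e = np.zeros(0)

    i_const = np.zeros(n) if i_const_nA is None else np.asarray(i_const_nA, dtype=float)

    rec_every = max(1, int(round(record_dt_ms / dt_ms)))
    lockout_steps = max(1, int(round(spike_lockout_ms / dt_ms)))

    (v_final, spikes_ms, q_cls, q_na, q_inj, vm_rec, i_cls_rec, i_na_rec,
     i_inj_rec, status, t_fail) = run_model(
        morph.parent, cap, g_leak, e_leak, g_ax,
        g["na"], g["kdr"], g["ks"], g_ca_arr, mp.e_na, mp.e_k, mp.e_ca,
        tab_inf, tab_dec, vmin, inv_dv,
        syn_dec_r, syn_dec_f, syn_e, syn_norm,
        ev_step, ev_comp, ev_cls, ev_w,
        inj_g, inj_e, i_const,
        cp.enabled and not passive, cp.d_ca, cp.buffer_total, cp.buffer_kon,
        cp.k_d * cp.buffer_kon, cp.pump_density, cp.k1, cp.k2, cp.k3, cp.k4,
        dt_ms, n_steps, rec_every, record_traces,
        spike_threshold_mV, lockout_steps,
        morph.length, morph.area,
    )
    if status != 0:
        raise SimulationError(f"numerical divergence at t = {t_fail:.3f} ms")

    n_rec = vm_rec.size if record_traces else 0
    t_rec = np.arange(n_rec) * rec_every * dt_ms
    fp = _fingerprint(asdict(mp), asdict(cp), kern, duration_s, dt_ms, seed, n,
                      peak_normalized)
    return SimulationResult(
        duration_s=duration_s,
        dt_ms=dt_ms,
        record_dt_ms=rec_every * dt_ms,
        t_rec_ms=t_rec,
        vm_soma=vm_rec if record_traces else np.empty(0),
        spike_times_s=spikes_ms / 1000.0,
        syn_current={name: i_cls_rec[c] if record_traces else np.empty(0)
                     for c, name in enumerate(SYN_CLASSES)},
        i_na=i_na_rec if record_traces else np.empty(0),
        inj_current={lab: i_inj_rec[j] if record_traces else np.empty(0)
                     for j, lab in enumerate(inj_labels)},
        charge_pC={name: float(q_cls[c]) for c, name in enumerate(SYN_CLASSES)},
        charge_na_pC=float(q_na),
        charge_inj_pC={lab: float(q_inj[j]) for j, lab in enumerate(inj_labels)},
        seed=seed,
        config_fingerprint=fp,
    )


def detect_spikes(
    vm: np.ndarray,
    threshold_mV: float = 0.0,
    dt_ms: float = 0.1,
    lockout_ms: float = 3.0,
) -> np.ndarray:
    """Spike times (s) from a uniformly sampled voltage trace.

    One spike per upward threshold crossing, with a refractory lockout so a
    single action potential is never counted twice.
    """
    vm = np.asarray(vm, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise ValueError("voltage trace contains non-finite samples")
    above = vm >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    lockout = lockout_ms / dt_ms
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= lockout:
            kept.append(c)
    idx = np.asarray(kept)
    frac = (threshold_mV - vm[idx - 1]) / (vm[idx] - vm[idx - 1])
    return (idx - 1 + frac) * dt_ms / 1000.0
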