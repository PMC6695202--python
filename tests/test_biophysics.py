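"""Cable integrator: resting equilibrium, passive closed forms, EPSPs, spikes."""

from __future__ import annotations

import numpy as np
import pytest

from stellate import CalciumParams, MembraneParams, detect_spikes, simulate
from stellate.biophysics import CLS_INDEX, SimulationError, build_arrays


def single_event(comp, cls, g=0.001, t=0.005):
    return (np.array([t]), np.array([comp]), np.array([CLS_INDEX[cls]]), np.array([g]))


def test_passive_rest_is_flat(default_morph):
    sim = simulate(default_morph, events=None, duration_s=0.2, dt_ms=0.025, passive=True)
    assert np.allclose(sim.vm_soma, -70.0, atol=1e-9)


def test_active_rest_is_equilibrated(default_morph):
    sim = simulate(default_morph, events=None, duration_s=1.0, dt_ms=0.025)
    assert np.abs(sim.vm_soma + 70.0).max() < 0.5
    assert len(sim.spike_times_s) == 0


def test_passive_steady_state_matches_input_resistance(soma_only):
    # isopotential passive soma: dV = I * Rm / A
    i_inj = 0.02  # nA
    ic = np.array([i_inj])
    sim = simulate(soma_only, events=None, duration_s=0.5, dt_ms=0.025,
                   i_const_nA=ic, passive=True)
    rm, area = 16_000.0, 757.0
    dv_expect = i_inj * 1e-9 * rm / (area * 1e-8) * 1e3  # mV
    dv_got = sim.vm_soma[-1] + 70.0
    assert dv_got == pytest.approx(dv_expect, rel=1e-3)


def test_charge_conservation_passive_step(soma_only):
    # injected charge = capacitive + leak charge in the RC limit
    i_inj = 0.05
    dur = 0.3
    sim = simulate(soma_only, events=None, duration_s=dur, dt_ms=0.01,
                   i_const_nA=np.array([i_inj]), passive=True,
                   record_dt_ms=0.01)
    dv = sim.vm_soma + 70.0
    cap = 1.5 * 757.0 * 1e-5  # nF
    g_leak = 757.0 * 1e-5 * 1e3 / 16_000.0  # uS
    q_inj = i_inj * sim.t_rec_ms[-1]  # pC over the recorded window
    q_cap = cap * dv[-1]
    q_leak = g_leak * np.trapezoid(dv, dx=sim.record_dt_ms)
    assert q_cap + q_leak == pytest.approx(q_inj, rel=1e-3)


def test_epsp_dt_convergence(default_morph):
    comp = int(np.argmin(np.abs(default_morph.path_distance - 80)))
    peaks = []
    for dt in (0.025, 0.0125):
        sim = simulate(default_morph, events=single_event(comp, "tc"),
                       duration_s=0.06, dt_ms=dt, record_dt_ms=0.025)
        peaks.append(sim.vm_soma.max() + 70.0)
    assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.01


def test_single_tc_epsp_amplitude(default_morph):
    comp = int(np.argmin(np.abs(default_morph.path_distance - 80)))
    sim = simulate(default_morph, events=single_event(comp, "tc"),
                   duration_s=0.06, dt_ms=0.025)
    peak = sim.vm_soma.max() + 70.0
    assert 0.4 < peak < 1.2  # ~0.6-0.8 mV depending on location


def test_instantiated_conductances_scale_with_area(default_morph):
    cap, g_leak, g, g_ca, g_ax = build_arrays(default_morph, MembraneParams())
    area = default_morph.area
    soma = default_morph.region == 0
    assert np.allclose(g["na"][soma], 300.0 * area[soma] * 1e-5)
    assert np.allclose(g["na"][~soma], 3.0 * area[~soma] * 1e-5)
    assert np.allclose(g_ca, 0.03 * 1e-4 * area * 1e-5)
    assert np.allclose(cap, 1.5 * area * 1e-5)


def test_calcium_system_is_a_small_perturbation(default_morph):
    comp = int(np.argmin(np.abs(default_morph.path_distance - 80)))
    ev = single_event(comp, "tc")
    with_ca = simulate(default_morph, events=ev, duration_s=0.06, dt_ms=0.025)
    no_ca = simulate(default_morph, events=ev, duration_s=0.06, dt_ms=0.025,
                     calcium=CalciumParams(enabled=False))
    p1 = with_ca.vm_soma.max() + 70
    p2 = no_ca.vm_soma.max() + 70
    assert abs(p1 - p2) / p2 < 0.05


def test_event_on_unknown_compartment_rejected(soma_only):
    with pytest.raises(ValueError):
        simulate(soma_only, events=single_event(5, "tc"), duration_s=0.05)


def test_determinism_bit_identical(default_morph):
    ev = single_event(10, "tc")
    a = simulate(default_morph, events=ev, duration_s=0.1, dt_ms=0.05)
    b = simulate(default_morph, events=ev, duration_s=0.1, dt_ms=0.05)
    assert np.array_equal(a.vm_soma, b.vm_soma)
    assert np.array_equal(a.spike_times_s, b.spike_times_s)
    assert a.charge_pC == b.charge_pC


def test_current_step_fires_repetitively(default_morph):
    ic = np.zeros(default_morph.n_compartments)
    ic[0] = 0.5
    sim = simulate(default_morph, events=None, duration_s=1.0, dt_ms=0.025,
                   i_const_nA=ic)
    assert len(sim.spike_times_s) >= 5
    assert np.all(np.diff(sim.spike_times_s) > 0)
    assert sim.vm_soma.max() > 0  # overshooting action potentials


def test_detect_spikes_threshold_and_lockout():
    dt = 0.1
    vm = np.full(3000, -70.0)
    for c in (500, 1500, 2500):  # three separated transients
        vm[c : c + 20] = 10.0
    times = detect_spikes(vm, threshold_mV=-20.0, dt_ms=dt)
    assert len(times) == 3
    assert np.allclose(times, np.array([500, 1500, 2500]) * dt / 1000, atol=1e-3)

    assert detect_spikes(np.full(100, -70.0), 0.0, dt).size == 0
    with pytest.raises(ValueError):
        detect_spikes(np.array([0.0, np.nan]), 0.0, dt)


def test_lockout_suppresses_double_counting():
    dt = 0.1
    vm = np.full(200, -70.0)
    vm[50:52] = 10.0
    vm[55:57] = 10.0  # second crossing 0.5 ms later: within lockout
    vm[150:152] = 10.0
    assert detect_spikes(vm, -20.0, dt, lockout_ms=3.0).size == 2


def test_result_serialisation_round_trip(tmp_path, default_morph):
    sim = simulate(default_morph, events=single_event(10, "tc"),
                   duration_s=0.05, dt_ms=0.05)
    csv = tmp_path / "spikes.csv"
    sim.save_spikes_csv(str(csv))
    assert csv.exists()
    h5 = tmp_path / "traces.h5"
    sim.save_traces_h5(str(h5))
    import h5py

    with h5py.File(h5) as f:
        assert f["vm_soma"].shape == sim.vm_soma.shape
        assert f.attrs["dt_ms"] == 0.05
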