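"""Synapse populations, event sampling, input train, gain, somatic lumping."""

from __future__ import annotations

import numpy as np
import pytest

from stellate import (
    BackgroundConfig,
    InputTrain,
    SynKernel,
    apply_gain,
    build_background,
    lump_to_soma,
    make_input_train,
    place_axon_of_interest,
    sample_events,
)
from stellate.synapses import axon_events, default_kernel, event_weights, merge_event_trains


def test_kernel_shape_and_peak():
    k = SynKernel(0.3, 1.7, 0.0, 0.001)
    t = np.linspace(0, 20, 20001)
    g = k.evaluate(t)
    # peak-normalised: the maximum equals the stated peak conductance
    assert g.max() == pytest.approx(k.g_peak, rel=1e-6)
    assert t[np.argmax(g)] == pytest.approx(k.t_peak, abs=1e-3)
    assert np.trapezoid(g, t) == pytest.approx(k.time_integral_ms, rel=1e-4)
    with pytest.raises(ValueError):
        SynKernel(2.0, 1.0, 0.0, 0.001)


def test_background_rates_follow_spine_counts(default_morph):
    cc = build_background(default_morph, "cc")
    assert cc.total_rate_hz == pytest.approx(1870 * 0.45, rel=1e-9)
    inh = build_background(default_morph, "inh")
    assert inh.total_rate_hz == pytest.approx(460 * 0.09, rel=1e-9)
    tc = build_background(default_morph, "tc")
    assert tc.total_rate_hz == pytest.approx(470 * 4.0, rel=1e-9)
    # tc weights form a probability distribution over dendritic compartments
    w = tc.rates_hz / tc.total_rate_hz
    assert w.min() >= 0 and w.sum() == pytest.approx(1.0)
    # placement mass concentrates around the Gaussian mean (83.6 um)
    d = default_morph.path_distance[tc.comp_ids]
    mean_d = float((w * d).sum())
    assert 60 < mean_d < 110


def test_background_requires_dendrites(soma_only):
    with pytest.raises(ValueError):
        build_background(soma_only, "cc")


def test_single_dendrite_chain_takes_all_tc_rate(chain10):
    tc = build_background(chain10, "tc")
    assert tc.rates_hz.sum() == pytest.approx(1880.0)


def test_poisson_sampling_statistics_and_determinism(default_morph):
    tc = build_background(default_morph, "tc")
    a = sample_events(tc, 10.0, seed=5)
    b = sample_events(tc, 10.0, seed=5)
    assert np.array_equal(a.times_s, b.times_s)
    assert np.array_equal(a.comp_ids, b.comp_ids)
    # expected count 18,800; Poisson sd ~ 137
    assert abs(a.n_events - 18_800) < 5 * np.sqrt(18_800)
    # zero rate -> empty train
    from dataclasses import replace

    empty = sample_events(replace(tc, rates_hz=tc.rates_hz * 0.0), 5.0, seed=1)
    assert empty.n_events == 0


def test_axon_placement_on_one_lineage(default_morph):
    ids = place_axon_of_interest(default_morph, seed=0)
    assert len(ids) == 3 and len(set(ids)) == 3
    d = default_morph.path_distance[ids]
    assert np.all(d >= 53) and np.all(d <= 107)
    # all three on one root-to-tip lineage
    path = set(default_morph.root_to_tip_path(max(ids, key=lambda i: default_morph.path_distance[i])))
    assert set(ids) <= path


def test_axon_placement_exact_chain():
    from tests.conftest import chain_morphology

    m = chain_morphology(n_links=12, link_um=12.0)
    # midpoints at 6, 18, 30, ..., compartments exist near 60/78/96
    ids = place_axon_of_interest(m, seed=3)
    d = sorted(m.path_distance[ids])
    assert d[1] == pytest.approx(78.0, abs=6.1)


def test_axon_placement_error_on_shallow_tree(chain10):
    from tests.conftest import chain_morphology

    shallow = chain_morphology(n_links=2, link_um=10.0)
    with pytest.raises(ValueError):
        place_axon_of_interest(shallow)


def test_input_train_block_structure_and_rate():
    tr = make_input_train("synthetic", seed=11)
    assert tr.duration_s == 125.0
    times = tr.times_s
    assert times.size == 5 * tr.block_times_s.size
    # exact block repetition
    assert np.allclose(times[: tr.block_times_s.size], tr.block_times_s)
    assert abs(tr.mean_rate_hz - 4.3) < 0.6
    # refractoriness >= 3 ms within the block
    assert np.diff(tr.block_times_s).min() >= 0.003


def test_input_train_from_file(tmp_path):
    f = tmp_path / "spikes.txt"
    f.write_text("1.0\n")
    tr = make_input_train("file", path=str(f))
    assert np.allclose(tr.times_s, [1, 26, 51, 76, 101])
    f.write_text("0.5\n0.1\n")
    with pytest.raises(ValueError):
        make_input_train("file", path=str(f))


def test_gain_scales_tc_and_syn_only(default_morph):
    pops = [build_background(default_morph, c) for c in ("tc", "cc", "inh")]
    scaled = apply_gain(pops, 1.2)
    by = {p.cls: p for p in scaled}
    assert by["tc"].effective_g_peak == pytest.approx(0.0012)
    assert by["cc"].effective_g_peak == pytest.approx(0.0008)
    assert by["inh"].effective_g_peak == pytest.approx(0.0005)
    # rates (event trains) untouched
    assert np.array_equal(by["tc"].rates_hz, pops[0].rates_hz)
    with pytest.raises(ValueError):
        apply_gain(pops, -0.1)
    # gain 0 silences the scaled classes
    assert apply_gain(pops, 0.0)[0].effective_g_peak == 0.0


def test_gain_commutes_with_sampling(default_morph):
    pops = [build_background(default_morph, "tc")]
    ev1 = sample_events(apply_gain(pops, 2.4)[0], 3.0, seed=9)
    ev2 = sample_events(pops[0], 3.0, seed=9)
    assert np.array_equal(ev1.times_s, ev2.times_s)
    assert np.array_equal(ev1.comp_ids, ev2.comp_ids)


def test_lump_to_soma_single_event_matches_kernel(default_morph):
    from stellate.synapses import EventTrain
    from stellate.biophysics import CLS_INDEX

    pops = [build_background(default_morph, "tc")]
    dt = 0.05
    ev = EventTrain(np.array([0.0]), np.array([1]), np.array([CLS_INDEX["tc"]]), 0.2)
    g = lump_to_soma(pops, ev, 0.2, dt)["tc"]
    t = np.arange(g.size) * dt
    want = pops[0].kernel.evaluate(t)
    assert np.allclose(g, want, atol=1e-9)

    # two simultaneous events superpose linearly
    ev2 = EventTrain(np.array([0.0, 0.0]), np.array([1, 2]),
                     np.full(2, CLS_INDEX["tc"]), 0.2)
    g2 = lump_to_soma(pops, ev2, 0.2, dt)["tc"]
    assert np.allclose(g2, 2 * want, atol=1e-9)


def test_lump_to_soma_mean_matches_campbell(default_morph):
    # time-average of Poisson shot noise = rate x kernel integral
    pops = [build_background(default_morph, "tc")]
    ev = sample_events(pops[0], 60.0, seed=2)
    g = lump_to_soma(pops, ev, 60.0, 0.1)["tc"]
    kern = pops[0].kernel
    want = pops[0].total_rate_hz * kern.time_integral_ms * 1e-3  # uS
    assert g.mean() == pytest.approx(want, rel=0.05)


def test_merged_events_keep_order_and_weights(default_morph):
    pops = [build_background(default_morph, c) for c in ("tc", "cc")]
    trains = [sample_events(p, 2.0, seed=i) for i, p in enumerate(pops)]
    merged = merge_event_trains(trains, 2.0)
    assert np.all(np.diff(merged.times_s) >= 0)
    w = event_weights(pops, merged)
    assert set(np.round(np.unique(w), 6)) == {0.0008, 0.001}
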