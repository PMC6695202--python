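"""Morphology generator: summary statistics, invariants, SWC round trip."""

from __future__ import annotations

import numpy as np
import pytest

from stellate import MorphologyConfig, generate_morphology, path_distance_profile
from stellate.morphology import MorphologyError, read_swc, write_swc


def test_default_morphology_matches_target_statistics(default_morph):
    m = default_morph
    assert m.soma_area == pytest.approx(757.0)
    assert m.dendritic_area == pytest.approx(11_885.0, rel=1e-9)
    assert abs(m.n_compartments - 360) <= 20
    assert m.length.max() <= 21.0 + 1e-9
    mean_len = m.length[m.dendrite_ids].mean()
    assert abs(mean_len - 14.6) / 14.6 <= 0.20
    # placement depth: the tc Gaussian and the axon of interest must fit
    assert m.path_distance.max() >= 150.0
    assert np.any((m.path_distance >= 70) & (m.path_distance <= 90))


def test_area_conservation_and_tree_structure(default_morph):
    m = default_morph
    assert m.total_area == pytest.approx(m.soma_area + m.dendritic_area)
    # connected, acyclic, single root: every compartment reaches the root
    for tip in (1, m.n_compartments - 1):
        path = m.root_to_tip_path(tip)
        assert path[0] == 0


def test_same_seed_bit_identical_different_seed_differs():
    a = generate_morphology(seed=3)
    b = generate_morphology(seed=3)
    c = generate_morphology(seed=4)
    assert np.array_equal(a.length, b.length)
    assert np.array_equal(a.diameter, b.diameter)
    assert not np.array_equal(a.length, c.length)
    # aggregates agree across seeds within invariant tolerances
    assert c.dendritic_area == pytest.approx(a.dendritic_area)
    assert abs(c.n_compartments - a.n_compartments) <= 20


def test_unbranched_cylinder_splits_by_ceiling_division():
    cfg = MorphologyConfig(
        n_primary=1,
        level_lengths=(100.0,),
        length_jitter=0.0,
        dendritic_area=float(np.pi * 1.0 * 100.0),
        target_n_compartments=0,
    )
    m = generate_morphology(cfg, seed=0)
    dend = m.dendrite_ids
    assert dend.size == 5
    assert np.allclose(m.length[dend], 20.0)


def test_path_distance_midpoint_convention():
    cfg = MorphologyConfig(
        n_primary=1, level_lengths=(40.0,), length_jitter=0.0,
        dendritic_area=float(np.pi * 40.0), target_n_compartments=0,
    )
    m = generate_morphology(cfg, seed=0)
    prof = path_distance_profile(m)
    assert prof[0] == 0.0
    dend = m.dendrite_ids
    assert [round(prof[i], 6) for i in dend] == [10.0, 30.0]
    # midpoint consistency on the chain
    d0, d1 = dend
    assert abs(prof[d1] - prof[d0]) == pytest.approx(
        (m.length[d0] + m.length[d1]) / 2
    )


def test_unsatisfiable_config_raises():
    with pytest.raises(MorphologyError):
        generate_morphology(MorphologyConfig(n_primary=0), seed=0)
    with pytest.raises(MorphologyError):
        generate_morphology(MorphologyConfig(dendritic_area=-1.0), seed=0)
    with pytest.raises(MorphologyError):
        # deep design but max length violation impossible: lengths must be cut
        generate_morphology(MorphologyConfig(max_comp_length=0.0), seed=0)


def test_swc_round_trip(tmp_path, default_morph):
    path = str(tmp_path / "cell.swc")
    write_swc(default_morph, path)
    back = read_swc(path)
    assert back.n_compartments == default_morph.n_compartments
    assert np.allclose(back.length, default_morph.length, rtol=1e-5)
    assert np.allclose(back.diameter, default_morph.diameter, rtol=1e-5)
    assert np.allclose(back.area, default_morph.area, rtol=1e-4)
    assert np.allclose(back.path_distance, default_morph.path_distance, rtol=1e-5)
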