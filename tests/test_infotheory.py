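"""Transfer entropy, entropy rate and transmission classification."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from stellate import (
    BinarySequence,
    TEConfig,
    binarize,
    classify_transmission,
    entropy_rate,
    estimate_te,
    scan_frame_shift,
    te_noise,
    transfer_entropy,
)
from stellate.infotheory import _word_codes


# ---------------------------------------------------------------------------
# independent oracle: enumerate every joint outcome explicitly
# ---------------------------------------------------------------------------

def brute_force_te(x: np.ndarray, y: np.ndarray, k: int, l: int, u: int) -> float:
    """Plug-in TE by explicit enumeration over all word combinations."""
    n = len(x)
    start = max(k - 1, l - 1 + u)
    samples = []
    for t in range(start, n - 1):
        yw = tuple(y[t - k + 1 : t + 1])
        xw = tuple(x[t + 1 - u - l + 1 : t + 1 - u + 1])
        samples.append((y[t + 1], yw, xw))
    n_s = len(samples)
    te = 0.0
    for ynext, yw, xw in set(samples):
        c_joint = sum(1 for s in samples if s == (ynext, yw, xw))
        c_yw_xw = sum(1 for s in samples if (s[1], s[2]) == (yw, xw))
        c_yw = sum(1 for s in samples if s[1] == yw)
        c_next_yw = sum(1 for s in samples if (s[0], s[1]) == (ynext, yw))
        p = c_joint / n_s
        te += p * np.log2((c_joint / c_yw_xw) / (c_next_yw / c_yw))
    return te


@pytest.mark.parametrize("k,l,u", [(1, 1, 0), (1, 1, 2), (2, 2, 0), (3, 2, 1)])
def test_te_matches_brute_force_enumeration(k, l, u):
    rng = np.random.default_rng(7)
    for trial in range(8):
        n = rng.integers(12, 21)
        x = rng.integers(0, 2, n).astype(np.uint8)
        y = rng.integers(0, 2, n).astype(np.uint8)
        got = transfer_entropy(x, y, k=k, l=l, u=u)
        want = brute_force_te(x, y, k, l, u)
        assert got == pytest.approx(want, abs=1e-12)


def test_te_perfect_echo_is_one_bit():
    # output = input delayed by u bins; H(input) = 1 bit/bin
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 20_000).astype(np.uint8)
    u = 3
    y = np.roll(x, u)
    te = transfer_entropy(x, y, k=1, u=u)
    assert te == pytest.approx(1.0, abs=0.01)


def test_te_independent_sequences_near_zero():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 100_000).astype(np.uint8)
    y = rng.integers(0, 2, 100_000).astype(np.uint8)
    assert transfer_entropy(x, y, k=1) < 1e-3


def test_te_directionality_on_noisy_echo():
    rng = np.random.default_rng(2)
    x = (rng.random(50_000) < 0.2).astype(np.uint8)
    noise = (rng.random(50_000) < 0.05).astype(np.uint8)
    y = np.roll(x, 1) | noise
    fwd = transfer_entropy(x, y, k=1, u=1)
    # reverse direction measured at the same lag convention
    bwd = transfer_entropy(y, x, k=1, u=1)
    assert fwd > bwd


def test_te_bias_grows_with_k_but_corrected_te_stays_near_zero():
    rng = np.random.default_rng(3)
    x = (rng.random(41_666) < 0.013).astype(np.uint8)
    y = (rng.random(41_666) < 0.012).astype(np.uint8)
    raws = [transfer_entropy(x, y, k=k) for k in (1, 4, 7, 10)]
    assert raws == sorted(raws)  # documented upward bias with k
    cfg = TEConfig(k=10, n_scrambles=10, seed=0)
    noise_mean, noise_sd = te_noise(x, y, cfg)
    corrected = raws[-1] - noise_mean
    assert abs(corrected) < 2 * max(noise_sd, 1e-6)


def test_te_bounded_by_input_entropy_rate():
    rng = np.random.default_rng(4)
    x = (rng.random(41_666) < 0.013).astype(np.uint8)
    y = np.roll(x, 1)
    seq = BinarySequence(x, 3.0)
    h_in = entropy_rate(seq, word_length=8)
    te = transfer_entropy(x, y, k=8, u=1) * 1000.0 / 3.0
    assert te <= h_in + 1e-6


def test_scramble_preserves_counts_and_marginals():
    rng = np.random.default_rng(5)
    x = (rng.random(5000) < 0.1).astype(np.uint8)
    y = (rng.random(5000) < 0.1).astype(np.uint8)
    for mode in ("bins", "words"):
        cfg = TEConfig(k=5, n_scrambles=3, scramble_mode=mode, seed=9)
        from stellate.infotheory import _scrambled

        xs = _scrambled(x, mode, cfg.k, np.random.default_rng(0))
        assert xs.sum() == x.sum()
        assert xs.size == x.size


def test_te_noise_zero_for_all_zero_input():
    x = np.zeros(2000, dtype=np.uint8)
    y = (np.random.default_rng(0).random(2000) < 0.2).astype(np.uint8)
    cfg = TEConfig(k=2, n_scrambles=5, seed=1)
    mean, _sd = te_noise(x, y, cfg)
    assert mean == 0.0


def test_frame_shift_scan_recovers_delay():
    rng = np.random.default_rng(6)
    x = (rng.random(30_000) < 0.15).astype(np.uint8)
    y = np.roll(x, 2)
    cfg = TEConfig(k=1, u_max=6, n_scrambles=2, seed=0)
    profile, u_star = scan_frame_shift(x, y, cfg)
    assert u_star == 2
    assert profile[2] == max(profile)


def test_estimate_te_reports_consistent_fields():
    rng = np.random.default_rng(8)
    x = (rng.random(20_000) < 0.05).astype(np.uint8)
    y = np.roll(x, 1) | (rng.random(20_000) < 0.02).astype(np.uint8)
    res = estimate_te(BinarySequence(x, 3.0), BinarySequence(y, 3.0),
                      TEConfig(k=4, u_max=4, n_scrambles=5, seed=2))
    assert res.te == pytest.approx(res.te_raw - res.te_noise, abs=1e-12)
    assert res.te_raw >= 0
    assert 0 <= res.u_star <= 4
    assert res.profile_raw.size == 5


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def test_binarize_counts_and_same_bin_collapse():
    seq = binarize(np.array([0.0010, 0.0029]), duration_s=0.03, bin_width_ms=3.0)
    assert len(seq) == 10
    assert seq.bits.sum() == 1 and seq.bits[0] == 1

    assert len(binarize(np.array([]), 125.0, 3.0)) == 41_666

    with pytest.raises(ValueError):
        binarize(np.array([0.5, 0.1]), 1.0, 3.0)


def test_word_codes_enumeration():
    bits = np.array([1, 0, 1, 1], dtype=np.uint8)
    codes = _word_codes(bits, 2)
    # windows (1,0), (0,1), (1,1) with the most recent bin in the low bit
    assert codes.tolist() == [0b10, 0b01, 0b11]


# ---------------------------------------------------------------------------
# entropy rate
# ---------------------------------------------------------------------------

def test_entropy_rate_zero_and_iid_limits():
    zero = BinarySequence(np.zeros(50_000, dtype=np.uint8), 3.0)
    assert entropy_rate(zero, word_length=3) == 0.0

    rng = np.random.default_rng(10)
    p = 0.2
    iid = BinarySequence((rng.random(400_000) < p).astype(np.uint8), 3.0)
    h_bin = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    got = entropy_rate(iid, word_length=6)
    assert got == pytest.approx(h_bin * 1000 / 3.0, rel=0.02)


def test_entropy_rate_guard_on_short_sequences():
    short = BinarySequence(np.zeros(100, dtype=np.uint8), 3.0)
    with pytest.raises(ValueError):
        entropy_rate(short, word_length=10)


# ---------------------------------------------------------------------------
# transmission classification
# ---------------------------------------------------------------------------

def test_classification_identical_and_disjoint_trains():
    t = np.array([0.1, 0.5, 1.0])
    same = classify_transmission(t, t)
    assert same["input_to_output"] == 1.0
    assert same["output_without_input"] == 0.0

    far = classify_transmission(t, t + 10.0)
    assert far["input_to_output"] == 0.0
    assert far["output_without_input"] == 1.0


def test_classification_window_edges():
    res = classify_transmission(np.array([1.0]), np.array([1.017]), window_s=0.018)
    assert res["input_to_output"] == 1.0
    res = classify_transmission(np.array([1.0]), np.array([1.020]), window_s=0.018)
    assert res["input_to_output"] == 0.0
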