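"""Transfer entropy and related estimators on binarised spike trains.

The estimator is the plug-in (histogram) transfer entropy on binary sequences:

    TE(J -> I) = sum p(i_{n+1}, i_n^{(k)}, j_{n+1-u}^{(l)})
                 log2 [ p(i_{n+1} | i_n^{(k)}, j_{n+1-u}^{(l)})
                        / p(i_{n+1} | i_n^{(k)}) ]

with words of k (target) and l (source) contiguous past bins and an optional
frame shift u that lags the source relative to the predicted bin.  Finite data
make the raw estimate biased upward, so an estimated noise floor -- the same
quantity computed against permuted sources, averaged over many permutations --
is subtracted:  TE = TE_raw - TE_noise.  Negative corrected values are
reported as-is (clipping would bias averages across seeds).

Rates are per bin; divide by the bin width (3 ms by default) for bits/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinarySequence",
    "TEConfig",
    "TEResult",
    "binarize",
    "transfer_entropy",
    "te_noise",
    "scan_frame_shift",
    "estimate_te",
    "entropy_rate",
    "classify_transmission",
]

MAX_WORD_LENGTH = 16  # guard against bias explosion of the plug-in estimator


@dataclass
class BinarySequence:
    bits: np.ndarray  # uint8 {0,1}
    bin_width_ms: float = 3.0
    origin_s: float = 0.0

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if self.bits.size and self.bits.max() > 1:
            raise ValueError("bits must be 0/1")

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def rate_hz(self) -> float:
        return float(self.bits.sum() / (self.bits.size * self.bin_width_ms * 1e-3))


def binarize(spike_times_s: np.ndarray, duration_s: float, bin_width_ms: float = 3.0) -> BinarySequence:
    """1 iff at least one spike falls in the half-open bin [t, t + bin)."""
    t = np.asarray(spike_times_s, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if t.size and (t.min() < 0 or t.max() > duration_s):
        raise ValueError("spike times outside [0, duration]")
    n = int(np.floor(duration_s * 1000.0 / bin_width_ms))
    bits = np.zeros(n, dtype=np.uint8)
    idx = np.floor(t * 1000.0 / bin_width_ms).astype(np.int64)
    idx = idx[idx < n]
    bits[idx] = 1
    return BinarySequence(bits, bin_width_ms)


@dataclass
class TEConfig:
    k: int = 10  # word length, shared between source and target (l = k)
    u_max: int = 10  # maximum frame shift, in bins
    n_scrambles: int = 30
    scramble_mode: str = "bins"  # "bins" or "words"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.k > MAX_WORD_LENGTH:
            raise ValueError(f"k must be in [1, {MAX_WORD_LENGTH}]")
        if self.u_max < 0:
            raise ValueError("u_max must be >= 0")
        if self.n_scrambles < 1:
            raise ValueError("n_scrambles must be >= 1")
        if self.scramble_mode not in ("bins", "words"):
            raise ValueError("scramble_mode must be 'bins' or 'words'")


@dataclass
class TEResult:
    te_raw: float  # bits/s
    te_noise: float  # bits/s, mean over scrambles
    te_noise_sd: float  # bits/s, spread over scrambles
    te: float  # bits/s, te_raw - te_noise (may be negative)
    u_star: int  # frame shift maximising te_raw
    profile_raw: np.ndarray  # te_raw (bits/s) for u = 0..u_max
    bin_width_ms: float
    config: TEConfig


def _word_codes(bits: np.ndarray, k: int) -> np.ndarray:
    """Integer code of the k-bin word ending at index j + k - 1, for every j."""
    from numpy.lib.stride_tricks import sliding_window_view

    powers = (1 << np.arange(k - 1, -1, -1)).astype(np.int64)
    win = sliding_window_view(bits.astype(np.int64), k)
    return win @ powers


def transfer_entropy(
    source: BinarySequence | np.ndarray,
    target: BinarySequence | np.ndarray,
    k: int = 10,
    l: int | None = None,
    u: int = 0,
) -> float:
    """Plug-in transfer entropy source -> target, in bits per bin.

    The source word ends at bin n + 1 - u, i.e. u lags the source relative to
    the predicted target bin (u = 0 means the source word includes the bin
    simultaneous with the prediction).
    """
    x = source.bits if isinstance(source, BinarySequence) else np.asarray(source, dtype=np.uint8)
    y = target.bits if isinstance(target, BinarySequence) else np.asarray(target, dtype=np.uint8)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    l = k if l is None else l
    if k > MAX_WORD_LENGTH or l > MAX_WORD_LENGTH:
        raise ValueError(f"word length above the configured maximum {MAX_WORD_LENGTH}")
    n = x.size
    # predicted bin index n+1 ranges over [start+1, n-1]
    start = max(k - 1, l - 1 + u)  # smallest n with all words in range
    if n - 1 - start < 1:
        raise ValueError("sequences too short for the requested k, l, u")

    yw = _word_codes(y, k)  # index j holds word ending at bin j+k-1
    xw = _word_codes(x, l)
    ns = np.arange(start, n - 1)
    y_next = y[ns + 1].astype(np.int64)
    y_word = yw[ns - (k - 1)]
    x_word = xw[(ns + 1 - u) - (l - 1)]

    code = y_next + (y_word << 1) + (x_word << (k + 1))
    joint, cnt = np.unique(code, return_counts=True)
    n_samp = ns.size

    j_next = joint & 1
    j_yw = (joint >> 1) & ((1 << k) - 1)
    j_xw = joint >> (k + 1)

    def marginal(codes: np.ndarray) -> np.ndarray:
        u_c, inv = np.unique(codes, return_inverse=True)
        sums = np.bincount(inv, weights=cnt)
        return sums[inv]

    c_yw_xw = marginal(j_yw + (j_xw << k))
    c_yw = marginal(j_yw)
    c_next_yw = marginal(j_next + (j_yw << 1))

    te = np.sum(cnt * (np.log2(cnt * c_yw) - np.log2(c_yw_xw * c_next_yw))) / n_samp
    return float(max(te, 0.0))


def _scrambled(x: np.ndarray, mode: str, k: int, rng: np.random.Generator) -> np.ndarray:
    if mode == "bins":
        return rng.permutation(x)
    # "words": permute non-overlapping k-bin blocks, tail left in place
    n_blocks = x.size // k
    out = x.copy()
    blocks = out[: n_blocks * k].reshape(n_blocks, k)
    out[: n_blocks * k] = blocks[rng.permutation(n_blocks)].reshape(-1)
    return out


def te_noise(
    source: BinarySequence | np.ndarray,
    target: BinarySequence | np.ndarray,
    config: TEConfig,
    u: int = 0,
) -> tuple[float, float]:
    """Mean and s.d. (bits/bin) of TE between permuted source and true target."""
    x = source.bits if isinstance(source, BinarySequence) else np.asarray(source, dtype=np.uint8)
    rng = np.random.default_rng(config.seed)
    vals = np.empty(config.n_scrambles)
    for s in range(config.n_scrambles):
        xs = _scrambled(x, config.scramble_mode, config.k, rng)
        vals[s] = transfer_entropy(xs, target, k=config.k, u=u)
    return float(vals.mean()), float(vals.std(ddof=1)) if config.n_scrambles > 1 else 0.0


def scan_frame_shift(
    source: BinarySequence | np.ndarray,
    target: BinarySequence | np.ndarray,
    config: TEConfig,
) -> tuple[np.ndarray, int]:
    """TE_raw (bits/bin) at u = 0..u_max and the argmax (ties -> smaller u)."""
    profile = np.array(
        [transfer_entropy(source, target, k=config.k, u=u) for u in range(config.u_max + 1)]
    )
    u_star = int(np.argmax(profile))  # np.argmax returns the first maximum
    return profile, u_star


def estimate_te(
    source: BinarySequence,
    target: BinarySequence,
    config: TEConfig | None = None,
) -> TEResult:
    """Full estimate: frame-shift scan, noise floor at the best shift, TE."""
    cfg = config or TEConfig()
    if source.bin_width_ms != target.bin_width_ms:
        raise ValueError("sequences binned at different widths")
    per_s = 1000.0 / source.bin_width_ms
    profile, u_star = scan_frame_shift(source, target, cfg)
    noise_mean, noise_sd = te_noise(source, target, cfg, u=u_star)
    raw = profile[u_star]
    return TEResult(
        te_raw=float(raw * per_s),
        te_noise=noise_mean * per_s,
        te_noise_sd=noise_sd * per_s,
        te=float((raw - noise_mean) * per_s),
        u_star=u_star,
        profile_raw=profile * per_s,
        bin_width_ms=source.bin_width_ms,
        config=cfg,
    )


def entropy_rate(seq: BinarySequence, word_length: int = 10) -> float:
    """Conditional block-entropy rate H(n) - H(n-1), in bits/s.

    Requires the sequence to be much longer than 2^word_length to keep the
    plug-in block entropies from collapsing.
    """
    bits = seq.bits
    if word_length < 1 or word_length > MAX_WORD_LENGTH:
        raise ValueError("word length out of range")
    if bits.size < 4 * (1 << word_length):
        raise ValueError(
            "sequence too short for this word length (plug-in bias guard)"
        )

    def block_entropy(m: int) -> float:
        if m == 0:
            return 0.0
        codes = _word_codes(bits, m)
        _, cnt = np.unique(codes, return_counts=True)
        p = cnt / cnt.sum()
        return float(-(p * np.log2(p)).sum())

    h = block_entropy(word_length) - block_entropy(word_length - 1)
    return h * 1000.0 / seq.bin_width_ms


def classify_transmission(
    input_spikes_s: np.ndarray,
    output_spikes_s: np.ndarray,
    window_s: float = 0.018,
) -> dict[str, float]:
    """Simple input/output transmission bookkeeping.

    Each input spike is 'transmitted' if an output spike follows within
    (t, t + window]; each output spike is 'spontaneous' if no input precedes
    it within [t - window, t).  Returns the fractions.
    """
    tin = np.asarray(input_spikes_s, dtype=float)
    tout = np.asarray(output_spikes_s, dtype=float)
    if np.any(np.diff(tin) < 0) or np.any(np.diff(tout) < 0):
        raise ValueError("spike times must be sorted")
    res = {
        "input_to_output": np.nan,
        "input_no_output": np.nan,
        "output_without_input": np.nan,
    }
    if tin.size:
        nxt = np.searchsorted(tout, tin, side="left")
        has_out = (nxt < tout.size) & (tout[np.minimum(nxt, tout.size - 1)] <= tin + window_s)
        res["input_to_output"] = float(has_out.mean())
        res["input_no_output"] = float(1.0 - has_out.mean())
    if tout.size:
        prv = np.searchsorted(tin, tout, side="right") - 1
        has_in = (prv >= 0) & (tin[np.maximum(prv, 0)] >= tout - window_s)
        res["output_without_input"] = float(1.0 - has_in.mean())
    return res
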