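"""Synapse populations and input signals.

Three background populations bombard the cell: thalamocortical (tc) relay
input, excitatory corticocortical (cc) input and inhibitory (inh) input.  Each
is realised as one lumped synapse per dendritic compartment whose event rate is
set so that the compartment stands in for its share of the underlying spine
population (1870 cc / 460 inh / 470 tc spines at 0.45 / 0.09 / 4 Hz per spine).
cc and inh spines are spread uniformly per unit membrane area; tc spines follow
a Gaussian in path distance from the soma (mean 83.6 um, s.d. 28.3 um,
truncated at zero), weighted by compartment area.

On top of the background, a single "axon of interest" contacts the tree at
three clustered sites (~78 um from the soma, spaced by ~18 um) that fire
synchronously following a fixed input spike train: a 25 s segment at ~4.3 Hz
played five times (125 s).  A dimensionless gain rescales the peak conductance
of the tc class and the axon of interest together, leaving cc and inh fixed --
gain 1 is the physiological conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .biophysics import CLS_INDEX, DEFAULT_KERNELS, kernel_norm
from .morphology import Morphology

__all__ = [
    "SynKernel",
    "SynapsePopulation",
    "EventTrain",
    "InputTrain",
    "BackgroundConfig",
    "build_background",
    "sample_events",
    "place_axon_of_interest",
    "make_input_train",
    "apply_gain",
    "lump_to_soma",
    "merge_event_trains",
]


@dataclass(frozen=True)
class SynKernel:
    """Peak-normalised double-exponential conductance kernel.

    The conductance after one event is ``g_peak * (exp(-t/tau_fall) -
    exp(-t/tau_rise)) / norm`` where ``norm`` is the analytic maximum of the
    difference of exponentials, so ``g_peak`` is the peak conductance actually
    reached (~0.57 is the un-normalised peak for the 0.3/1.7 ms kernel).
    """

    tau_rise: float  # ms
    tau_fall: float  # ms
    e_rev: float  # mV
    g_peak: float  # uS, peak conductance of one event

    def __post_init__(self):
        if not self.tau_fall > self.tau_rise > 0:
            raise ValueError("require tau_fall > tau_rise > 0")

    @property
    def norm(self) -> float:
        """Peak of the unit-amplitude difference of exponentials."""
        return kernel_norm(self.tau_rise, self.tau_fall)

    @property
    def t_peak(self) -> float:
        tr, tf = self.tau_rise, self.tau_fall
        return tr * tf / (tf - tr) * float(np.log(tf / tr))

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Conductance (uS) at times t_ms after one event."""
        t = np.asarray(t_ms, dtype=float)
        out = np.exp(-t / self.tau_fall) - np.exp(-t / self.tau_rise)
        out[t < 0] = 0.0
        return self.g_peak * out / self.norm

    @property
    def time_integral_ms(self) -> float:
        """Time integral of the kernel (uS ms)."""
        return self.g_peak * (self.tau_fall - self.tau_rise) / self.norm


def default_kernel(cls: str) -> SynKernel:
    tr, tf, e, g = DEFAULT_KERNELS[cls]
    return SynKernel(tr, tf, e, g)


@dataclass
class BackgroundConfig:
    n_spines: dict | None = None  # per class
    per_spine_rate_hz: dict | None = None
    tc_gauss_mean_um: float = 83.6
    tc_gauss_sd_um: float = 28.3

    def __post_init__(self):
        if self.n_spines is None:
            self.n_spines = {"tc": 470, "cc": 1870, "inh": 460}
        if self.per_spine_rate_hz is None:
            self.per_spine_rate_hz = {"tc": 4.0, "cc": 0.45, "inh": 0.09}


@dataclass
class SynapsePopulation:
    cls: str  # tc / cc / inh / syn
    kernel: SynKernel
    comp_ids: np.ndarray  # compartments carrying a lumped synapse
    rates_hz: np.ndarray  # per-compartment event rate
    gain: float = 1.0

    @property
    def total_rate_hz(self) -> float:
        return float(self.rates_hz.sum())

    @property
    def effective_g_peak(self) -> float:
        """Peak conductance after gain scaling (gain acts on tc/syn only)."""
        g = self.kernel.g_peak
        return g * self.gain if self.cls in ("tc", "syn") else g


@dataclass
class EventTrain:
    times_s: np.ndarray
    comp_ids: np.ndarray
    cls: np.ndarray  # class index into biophysics.SYN_CLASSES
    duration_s: float

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.comp_ids = np.asarray(self.comp_ids, dtype=np.int64)
        self.cls = np.asarray(self.cls, dtype=np.int64)
        if self.times_s.size and (
            self.times_s.min() < 0 or self.times_s.max() >= self.duration_s
        ):
            raise ValueError("event times must lie in [0, duration)")
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return int(self.times_s.size)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.times_s, "compartment": self.comp_ids, "class": self.cls}
        ).to_csv(path, index=False)


def build_background(
    morph: Morphology, cls: str, config: BackgroundConfig | None = None
) -> SynapsePopulation:
    """Lumped background synapses of one class, one per dendritic compartment."""
    if cls not in ("tc", "cc", "inh"):
        raise ValueError(f"not a background class: {cls!r}")
    cfg = config or BackgroundConfig()
    dend = morph.dendrite_ids
    if dend.size == 0 or morph.area[dend].sum() <= 0:
        raise ValueError("morphology has no dendritic area to place synapses on")
    area = morph.area[dend]
    total = cfg.n_spines[cls] * cfg.per_spine_rate_hz[cls]
    if cls == "tc":
        d = morph.path_distance[dend]
        w = area * np.exp(-0.5 * ((d - cfg.tc_gauss_mean_um) / cfg.tc_gauss_sd_um) ** 2)
    else:
        w = area.copy()
    w = w / w.sum()
    return SynapsePopulation(
        cls=cls, kernel=default_kernel(cls), comp_ids=dend, rates_hz=total * w
    )


def sample_events(pop: SynapsePopulation, duration_s: float, seed: int) -> EventTrain:
    """Homogeneous Poisson events, independent per compartment."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    total = pop.total_rate_hz
    n = rng.poisson(total * duration_s) if total > 0 else 0
    if n == 0:
        empty = np.empty(0)
        return EventTrain(empty, np.empty(0, dtype=np.int64),
                          np.empty(0, dtype=np.int64), duration_s)
    comps = rng.choice(pop.comp_ids, size=n, p=pop.rates_hz / total)
    times = rng.uniform(0.0, duration_s, size=n)
    order = np.argsort(times, kind="stable")
    cls_idx = np.full(n, CLS_INDEX[pop.cls], dtype=np.int64)
    return EventTrain(times[order], comps[order], cls_idx, duration_s)


def place_axon_of_interest(
    morph: Morphology,
    target_distance_um: float = 78.0,
    spacing_um: float = 18.0,
    seed: int = 0,
) -> list[int]:
    """Pick three clustered contacts on one dendritic lineage.

    The three sites sit as close as achievable to target - spacing, target and
    target + spacing along a single root-to-tip path; the qualifying path is
    chosen at random (seeded) among tips deep enough to cover the span.
    """
    lo = target_distance_um - spacing_um
    hi = target_distance_um + spacing_um
    children = morph.children()
    tips = [i for i in range(morph.n_compartments) if not children[i] and morph.region[i] != 0]
    candidates = []
    for tip in tips:
        path = [i for i in morph.root_to_tip_path(tip) if morph.region[i] != 0]
        d = morph.path_distance[path]
        if d.min() <= lo and d.max() >= hi and len(path) >= 3:
            candidates.append((tip, path, d))
    if not candidates:
        raise ValueError(
            "no root-to-tip path spans the required distance range; "
            "regenerate the morphology with longer dendrites"
        )
    rng = np.random.default_rng(seed)
    tip, path, d = candidates[rng.integers(len(candidates))]
    chosen: list[int] = []
    for target in (lo, target_distance_um, hi):
        order = np.argsort(np.abs(d - target))
        for j in order:
            if path[j] not in chosen:
                chosen.append(path[j])
                break
    return sorted(chosen, key=lambda i: morph.path_distance[i])


@dataclass
class InputTrain:
    """The axon-of-interest spike train: one block repeated n_repeats times."""

    block_times_s: np.ndarray  # within [0, block_s)
    block_s: float = 25.0
    n_repeats: int = 5

    def __post_init__(self):
        self.block_times_s = np.asarray(self.block_times_s, dtype=float)
        if np.any(np.diff(self.block_times_s) < 0):
            raise ValueError("spike times must be sorted")
        if self.block_times_s.size and (
            self.block_times_s.min() < 0 or self.block_times_s.max() >= self.block_s
        ):
            raise ValueError("block spike times must lie in [0, block_s)")

    @property
    def duration_s(self) -> float:
        return self.block_s * self.n_repeats

    @property
    def times_s(self) -> np.ndarray:
        return np.concatenate(
            [self.block_times_s + k * self.block_s for k in range(self.n_repeats)]
        )

    @property
    def mean_rate_hz(self) -> float:
        return float(self.times_s.size / self.duration_s)


def make_input_train(
    mode: str = "synthetic",
    seed: int | None = None,
    path: str | None = None,
    rate_hz: float = 4.3,
    refractory_s: float = 0.003,
    block_s: float = 25.0,
    n_repeats: int = 5,
) -> InputTrain:
    """Build the 125 s input train (a 25 s block played five times).

    Synthetic mode draws a renewal process with an absolute refractory period
    (dead time + exponential), standing in for a relay-cell response train at
    ~4.3 Hz.  File mode reads one spike time (seconds) per line for the block.
    """
    if mode == "synthetic":
        if seed is None:
            raise ValueError("synthetic mode needs a seed")
        rng = np.random.default_rng(seed)
        mean_isi = 1.0 / rate_hz
        if mean_isi <= refractory_s:
            raise ValueError("rate incompatible with refractory period")
        times = []
        t = rng.exponential(mean_isi - refractory_s)
        while t < block_s:
            times.append(t)
            t += refractory_s + rng.exponential(mean_isi - refractory_s)
        block = np.asarray(times)
    elif mode == "file":
        if path is None:
            raise ValueError("file mode needs a path")
        block = np.loadtxt(path, ndmin=1, dtype=float)
        if np.any(block < 0):
            raise ValueError("negative spike times in file")
        if np.any(np.diff(block) < 0):
            raise ValueError("unsorted spike times in file")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return InputTrain(block_times_s=block, block_s=block_s, n_repeats=n_repeats)


def apply_gain(populations: list[SynapsePopulation], gain: float) -> list[SynapsePopulation]:
    """Scale the peak conductance of the tc and syn classes; cc/inh untouched."""
    if gain < 0:
        raise ValueError("gain must be non-negative")
    out = []
    for pop in populations:
        if pop.cls in ("tc", "syn"):
            out.append(replace(pop, gain=gain))
        else:
            out.append(replace(pop))
    return out


def axon_events(train: InputTrain, contact_ids: list[int]) -> EventTrain:
    """Synchronous events of the axon of interest at its three contacts."""
    t = train.times_s
    times = np.repeat(t, len(contact_ids))
    comps = np.tile(np.asarray(contact_ids, dtype=np.int64), t.size)
    cls = np.full(times.size, CLS_INDEX["syn"], dtype=np.int64)
    return EventTrain(times, comps, cls, train.duration_s)


def merge_event_trains(trains: list[EventTrain], duration_s: float) -> EventTrain:
    times = np.concatenate([tr.times_s for tr in trains]) if trains else np.empty(0)
    comps = (
        np.concatenate([tr.comp_ids for tr in trains])
        if trains
        else np.empty(0, dtype=np.int64)
    )
    cls = (
        np.concatenate([tr.cls for tr in trains]) if trains else np.empty(0, dtype=np.int64)
    )
    order = np.argsort(times, kind="stable")
    return EventTrain(times[order], comps[order], cls[order], duration_s)


def event_weights(populations: list[SynapsePopulation], train: EventTrain) -> np.ndarray:
    """Peak-conductance weight (uS) for every event, after gain scaling."""
    g_by_cls = {}
    for pop in populations:
        g_by_cls[CLS_INDEX[pop.cls]] = pop.effective_g_peak
    return np.asarray([g_by_cls[int(c)] for c in train.cls])


def lump_to_soma(
    populations: list[SynapsePopulation],
    events: EventTrain,
    duration_s: float,
    dt_ms: float,
) -> dict[str, np.ndarray]:
    """Summed somatic conductance traces for the excitatory background classes.

    All synapses of a class are relocated to the soma and their kernels
    superposed on the simulation grid (inhibition is deliberately absent: the
    lumped noise trains are excitatory only).  Returns ``{"tc": g, "cc": g}``
    in uS.
    """
    from scipy.signal import lfilter

    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    out: dict[str, np.ndarray] = {}
    for pop in populations:
        if pop.cls not in ("tc", "cc"):
            continue
        sel = events.cls == CLS_INDEX[pop.cls]
        idx = np.minimum(
            (events.times_s[sel] * 1000.0 / dt_ms).astype(np.int64), n_steps - 1
        )
        imp = np.bincount(idx, minlength=n_steps).astype(float)
        w = pop.effective_g_peak / pop.kernel.norm
        df = np.exp(-dt_ms / pop.kernel.tau_fall)
        dr = np.exp(-dt_ms / pop.kernel.tau_rise)
        fall = lfilter([1.0], [1.0, -df], imp)
        rise = lfilter([1.0], [1.0, -dr], imp)
        out[pop.cls] = w * (fall - rise)
    return out
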