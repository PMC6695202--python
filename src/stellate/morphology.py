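"""Stylised layer-4 spiny stellate morphologies.

A real reconstruction is replaced by a reproducible generator that matches the
summary statistics of the modelled cell: a single isopotential soma of 757 um^2,
a dendritic arbor of 11,885 um^2 split into ~360 compartments of at most 21 um
(14.6 um on average), with path distances spanning well past 150 um so that
distance-dependent synapse placement rules are realisable.

Path distances use the midpoint convention: the distance of a compartment is
measured from the soma centre to the compartment's midpoint along the tree, and
the soma itself contributes no path length (it is the tree's origin point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Compartment",
    "Morphology",
    "MorphologyConfig",
    "MorphologyError",
    "generate_morphology",
    "path_distance_profile",
    "write_swc",
    "read_swc",
]

SOMA = 0
DENDRITE = 1


class MorphologyError(ValueError):
    """A structural or constraint violation in a morphology."""


@dataclass(frozen=True)
class Compartment:
    """One cylindrical (or, for the soma, spherical-equivalent) compartment."""

    id: int
    parent_id: int | None
    length: float  # um
    diameter: float  # um
    area: float  # um^2
    path_distance: float  # um, midpoint along the tree to the soma centre
    region: int  # SOMA or DENDRITE


@dataclass
class Morphology:
    """Branched compartment tree stored as flat arrays (root first).

    ``parent[i] == -1`` marks the root (soma).  Compartments are ordered so a
    parent always precedes its children, which is the ordering the cable solver
    relies on.
    """

    parent: np.ndarray  # int64, -1 for the root
    length: np.ndarray  # um
    diameter: np.ndarray  # um
    area: np.ndarray  # um^2
    path_distance: np.ndarray  # um
    region: np.ndarray  # int8

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.path_distance = np.asarray(self.path_distance, dtype=float)
        self.region = np.asarray(self.region, dtype=np.int8)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return int(self.parent.size)

    @property
    def soma_area(self) -> float:
        return float(self.area[self.region == SOMA].sum())

    @property
    def dendritic_area(self) -> float:
        return float(self.area[self.region == DENDRITE].sum())

    @property
    def total_area(self) -> float:
        return float(self.area.sum())

    @property
    def dendrite_ids(self) -> np.ndarray:
        return np.flatnonzero(self.region == DENDRITE)

    def compartments(self) -> list[Compartment]:
        return [
            Compartment(
                id=i,
                parent_id=None if self.parent[i] < 0 else int(self.parent[i]),
                length=float(self.length[i]),
                diameter=float(self.diameter[i]),
                area=float(self.area[i]),
                path_distance=float(self.path_distance[i]),
                region=int(self.region[i]),
            )
            for i in range(self.n_compartments)
        ]

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_compartments)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[int(p)].append(i)
        return out

    def root_to_tip_path(self, tip: int) -> list[int]:
        """Compartment ids from the root down to ``tip`` (inclusive)."""
        path = [int(tip)]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path[::-1]

    def validate(self) -> None:
        n = self.n_compartments
        if n == 0:
            raise MorphologyError("empty morphology")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != 0:
            raise MorphologyError("morphology must have exactly one root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise MorphologyError("parents must precede children (topological order)")
        if np.any(self.length <= 0) or np.any(self.diameter <= 0):
            raise MorphologyError("non-positive compartment length or diameter")
        if np.any(self.path_distance < 0):
            raise MorphologyError("negative path distance")
        if self.path_distance[0] != 0.0:
            raise MorphologyError("root path distance must be zero")
        p = self.parent[1:]
        if np.any(self.path_distance[1:] < self.path_distance[p] - 1e-9):
            raise MorphologyError("path_distance decreases from parent to child")


@dataclass
class MorphologyConfig:
    """Settings for the stylised stellate generator.

    The defaults were tuned once so that the generated arbor reproduces the
    target soma/dendrite areas, the ~360-compartment discretisation and somatic
    EPSP amplitudes in the few-tenths-of-a-millivolt range for a 1 nS contact,
    and are then frozen.
    """

    n_primary: int = 6  # primary dendrites leaving the soma
    level_lengths: tuple[float, ...] = (33.0, 47.0, 58.0, 66.0)  # um per branch order
    trunk_diameter: float = 1.5  # um, before global area rescaling
    taper: float = 0.7  # child/parent diameter ratio at branch points
    # optional explicit diameter per branch order (before rescaling); overrides
    # the geometric taper when given
    level_diameters: tuple[float, ...] | None = None
    length_jitter: float = 0.12  # lognormal sigma on branch lengths
    soma_area: float = 757.0  # um^2
    dendritic_area: float = 11_885.0  # um^2
    max_comp_length: float = 21.0  # um
    target_n_compartments: int = 360  # soma included


def _soma_geometry(area: float) -> tuple[float, float]:
    # Sphere-equivalent cylinder with L = diam, the usual single-point soma.
    d = float(np.sqrt(area / np.pi))
    return d, d


def generate_morphology(config: MorphologyConfig | None = None, seed: int = 0) -> Morphology:
    """Generate a reproducible stylised stellate morphology.

    Branch lengths get a seeded lognormal jitter, diameters taper by a fixed
    ratio at every branch point, and the whole dendritic surface is rescaled so
    that the summed dendritic area matches ``config.dendritic_area`` exactly.
    Segments are then cut into compartments no longer than
    ``config.max_comp_length``; extra cuts are added greedily (longest current
    compartment first) until the requested compartment count is reached.
    """
    cfg = config or MorphologyConfig()
    if cfg.n_primary < 1:
        raise MorphologyError("n_primary must be >= 1")
    if cfg.dendritic_area <= 0 or cfg.soma_area <= 0:
        raise MorphologyError("areas must be positive")
    if cfg.max_comp_length <= 0:
        raise MorphologyError("max_comp_length must be positive")
    if not cfg.level_lengths:
        raise MorphologyError("level_lengths must be non-empty")

    rng = np.random.default_rng(seed)

    # Build branch segments: (parent_segment, length, diameter).
    seg_parent: list[int] = []
    seg_len: list[float] = []
    seg_diam: list[float] = []

    if cfg.level_diameters is not None and len(cfg.level_diameters) != len(cfg.level_lengths):
        raise MorphologyError("level_diameters must match level_lengths")

    def grow(parent_seg: int, level: int, diam: float) -> None:
        if level >= len(cfg.level_lengths):
            return
        base = cfg.level_lengths[level]
        d = diam if cfg.level_diameters is None else cfg.level_diameters[level]
        n_branches = 1 if level == 0 else 2
        for _ in range(n_branches):
            length = base * float(np.exp(rng.normal(0.0, cfg.length_jitter)))
            seg_parent.append(parent_seg)
            seg_len.append(length)
            seg_diam.append(d)
            grow(len(seg_parent) - 1, level + 1, d * cfg.taper)

    for _ in range(cfg.n_primary):
        grow(-1, 0, cfg.trunk_diameter)

    seg_len_arr = np.asarray(seg_len)
    seg_diam_arr = np.asarray(seg_diam)

    # Rescale diameters so the dendritic membrane area is met exactly.
    raw_area = float(np.sum(np.pi * seg_diam_arr * seg_len_arr))
    seg_diam_arr = seg_diam_arr * (cfg.dendritic_area / raw_area)

    # Cut segments into compartments <= max length; greedily refine to the
    # requested count (mean length then lands near total_length / (n - 1)).
    n_cuts = np.maximum(1, np.ceil(seg_len_arr / cfg.max_comp_length).astype(int))
    target_dend = max(cfg.target_n_compartments - 1, len(seg_len))
    while int(n_cuts.sum()) < target_dend:
        i = int(np.argmax(seg_len_arr / n_cuts))
        n_cuts[i] += 1

    parent: list[int] = [-1]
    length: list[float] = [_soma_geometry(cfg.soma_area)[1]]
    diameter: list[float] = [_soma_geometry(cfg.soma_area)[0]]
    area: list[float] = [cfg.soma_area]
    region: list[int] = [SOMA]

    seg_tip: dict[int, int] = {}  # segment index -> id of its distal compartment
    for s in range(len(seg_len)):
        attach = 0 if seg_parent[s] < 0 else seg_tip[seg_parent[s]]
        piece = seg_len_arr[s] / n_cuts[s]
        for _ in range(n_cuts[s]):
            parent.append(attach)
            length.append(float(piece))
            diameter.append(float(seg_diam_arr[s]))
            area.append(float(np.pi * seg_diam_arr[s] * piece))
            region.append(DENDRITE)
            attach = len(parent) - 1
        seg_tip[s] = attach

    parent_arr = np.asarray(parent, dtype=np.int64)
    length_arr = np.asarray(length)
    pd = _path_distances(parent_arr, length_arr, np.asarray(region, dtype=np.int8))

    morph = Morphology(
        parent=parent_arr,
        length=length_arr,
        diameter=np.asarray(diameter),
        area=np.asarray(area),
        path_distance=pd,
        region=np.asarray(region, dtype=np.int8),
    )
    _check_generated(morph, cfg)
    return morph


def _path_distances(parent: np.ndarray, length: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Midpoint path distances; the soma counts as a point at the origin."""
    n = parent.size
    pd = np.zeros(n)
    # distance of a compartment's proximal end from the soma centre
    proximal = np.zeros(n)
    for i in range(1, n):
        p = parent[i]
        if region[p] == SOMA:
            proximal[i] = 0.0
        else:
            proximal[i] = proximal[p] + length[p]
        pd[i] = proximal[i] + 0.5 * length[i]
    return pd


def _check_generated(morph: Morphology, cfg: MorphologyConfig) -> None:
    if np.any(morph.length > cfg.max_comp_length + 1e-9):
        raise MorphologyError(
            f"compartment longer than the {cfg.max_comp_length} um maximum"
        )
    if abs(morph.dendritic_area - cfg.dendritic_area) > 1e-6 * cfg.dendritic_area:
        raise MorphologyError("dendritic area constraint not met after rescaling")
    # Distance-dependent synapse placement needs depth; only enforced when the
    # configured design depth allows it (tiny test morphologies are exempt).
    if sum(cfg.level_lengths) >= 150.0 and morph.path_distance.max() < 150.0:
        raise MorphologyError(
            "path distances do not span 150 um; increase level_lengths"
        )


def path_distance_profile(morph: Morphology) -> dict[int, float]:
    """Per-compartment path distance (um along the tree, midpoint convention)."""
    morph.validate()
    return {i: float(morph.path_distance[i]) for i in range(morph.n_compartments)}


# ---------------------------------------------------------------------------
# SWC serialisation.  Synthetic 3-D coordinates are laid out deterministically
# (each primary dendrite in its own direction) purely so that lengths and radii
# round-trip; they carry no biological meaning.
# ---------------------------------------------------------------------------

def write_swc(morph: Morphology, path: str) -> None:
    children = morph.children()
    pos = np.zeros((morph.n_compartments, 3))
    # direction per compartment: inherit from parent, fan out at branch points
    dirs = np.zeros((morph.n_compartments, 3))
    primaries = children[0]
    for j, c in enumerate(primaries):
        theta = 2.0 * np.pi * j / max(len(primaries), 1)
        dirs[c] = (np.cos(theta), np.sin(theta), 0.0)
    order = list(range(1, morph.n_compartments))
    for i in order:
        p = int(morph.parent[i])
        if p != 0:
            sibs = children[p]
            if len(sibs) > 1:
                k = sibs.index(i)
                ang = (k - (len(sibs) - 1) / 2.0) * 0.5
                c, s = np.cos(ang), np.sin(ang)
                dx, dy, dz = dirs[p]
                dirs[i] = (c * dx - s * dy, s * dx + c * dy, dz)
            else:
                dirs[i] = dirs[p]
            base = pos[p]
        else:
            base = pos[0]
        pos[i] = base + dirs[i] * morph.length[i]

    with open(path, "w") as fh:
        fh.write("# synthetic stylised stellate morphology (SWC)\n")
        for i in range(morph.n_compartments):
            t = 1 if morph.region[i] == SOMA else 3
            r = morph.diameter[i] / 2.0
            p = int(morph.parent[i]) + 1 if morph.parent[i] >= 0 else -1
            x, y, z = pos[i]
            fh.write(f"{i + 1} {t} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {p}\n")


def read_swc(path: str) -> Morphology:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            rows.append(
                (int(f[0]), int(f[1]), float(f[2]), float(f[3]), float(f[4]), float(f[5]), int(f[6]))
            )
    if not rows:
        raise MorphologyError("empty SWC file")
    ids = {r[0]: k for k, r in enumerate(rows)}
    n = len(rows)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n)
    diameter = np.zeros(n)
    area = np.zeros(n)
    region = np.zeros(n, dtype=np.int8)
    pos = np.array([[r[2], r[3], r[4]] for r in rows])
    for k, r in enumerate(rows):
        diameter[k] = 2.0 * r[5]
        region[k] = SOMA if r[1] == 1 else DENDRITE
        if r[6] == -1:
            # sphere-equivalent soma point
            length[k] = diameter[k]
            area[k] = np.pi * diameter[k] ** 2
        else:
            parent[k] = ids[r[6]]
            length[k] = float(np.linalg.norm(pos[k] - pos[parent[k]]))
            area[k] = np.pi * diameter[k] * length[k]
    pd = _path_distances(parent, length, region)
    return Morphology(parent=parent, length=length, diameter=diameter, area=area,
                      path_distance=pd, region=region)
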