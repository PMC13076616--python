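"""Surrogate dendritic morphologies and SWC serialization.

The published reconstructions used for the retinal and cortical
detectors are not redistributed; instead this module grows surrogate
arbors with matching segment counts and spatial scale: a planar,
radially branching arbor for the direction-selective ganglion cell
(DSGC, 352 segments spanning ~300 µm) and an apical/basal arbor for a
layer 2/3 pyramidal cell (69 segments).

A morphology is a rooted tree of cylindrical segments; the root is the
(spherical) soma.  Node ``i``'s parent always has a smaller index, so
array order is a valid elimination order for the cable solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Morphology",
    "generate_dsgc_morphology",
    "generate_pyramidal_morphology",
    "read_swc",
    "write_swc",
]


@dataclass
class Morphology:
    """Compartmental tree: positions (µm), diameters (µm), parent links."""

    xyz: np.ndarray        # (n, 3) node positions, µm
    diameter: np.ndarray   # (n,) segment diameter, µm
    parent: np.ndarray     # (n,) parent index, -1 for the root
    ntype: np.ndarray      # (n,) SWC type code (1 soma, 3 dendrite, 4 apical)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.ntype = np.asarray(self.ntype, dtype=int)
        n = self.xyz.shape[0]
        if not (self.diameter.shape == (n,) and self.parent.shape == (n,)):
            raise ValueError("inconsistent morphology arrays")
        roots = np.nonzero(self.parent < 0)[0]
        if roots.size != 1 or roots[0] != 0:
            raise ValueError("morphology must have exactly one root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children")
        if np.any(self.diameter <= 0):
            raise ValueError("diameters must be positive")

    @property
    def n_segments(self) -> int:
        return self.xyz.shape[0]

    def lengths(self) -> np.ndarray:
        """Segment lengths (µm); the soma gets its own diameter."""
        L = np.empty(self.n_segments)
        L[0] = self.diameter[0]
        L[1:] = np.linalg.norm(self.xyz[1:] - self.xyz[self.parent[1:]], axis=1)
        return L

    def areas(self) -> np.ndarray:
        """Membrane areas (µm²): sphere for the soma, open cylinders else."""
        L = self.lengths()
        a = np.pi * self.diameter * L
        a[0] = np.pi * self.diameter[0] ** 2
        return a

    def path_to_root(self, i: int) -> list[int]:
        path = [i]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_segments)]
        for i in range(1, self.n_segments):
            ch[self.parent[i]].append(i)
        return ch


def _grow_tree(
    rng: np.random.Generator,
    n_segments: int,
    radius: float,
    planar: bool,
    n_primary: int,
    seg_len: float,
    branch_prob: float,
    soma_diam: float,
    start_diam: float,
    tip_diam: float,
    ntype_code: int = 3,
    origin: np.ndarray | None = None,
    cone_axis: np.ndarray | None = None,
    cone_half_angle: float = np.pi,
) -> tuple[list, list, list, list]:
    """Stochastic outward growth from the soma until n_segments nodes exist."""
    xyz = [np.zeros(3) if origin is None else np.asarray(origin, dtype=float)]
    diam = [soma_diam]
    parent = [-1]
    ntype = [1]

    def _unit(theta):
        return np.array([np.cos(theta), np.sin(theta), 0.0])

    tips: list[tuple[int, np.ndarray]] = []
    for k in range(n_primary):
        if cone_axis is None:
            theta = 2.0 * np.pi * k / n_primary + rng.normal(0.0, 0.15)
            d = _unit(theta)
        else:
            d = np.asarray(cone_axis, dtype=float)
            ang = rng.uniform(-cone_half_angle, cone_half_angle)
            c, s = np.cos(ang), np.sin(ang)
            d = np.array([d[0] * c - d[1] * s, d[0] * s + d[1] * c, 0.0])
        tips.append((0, d))

    while len(xyz) < n_segments:
        if not tips:  # revive growth from a random non-soma node
            j = int(rng.integers(1, len(xyz)))
            v = xyz[j] - xyz[parent[j]] if parent[j] >= 0 else _unit(rng.uniform(0, 2 * np.pi))
            nv = np.linalg.norm(v)
            v = v / nv if nv > 0 else _unit(rng.uniform(0, 2 * np.pi))
            tips.append((j, v))
        idx = int(rng.integers(len(tips)))
        node, direction = tips.pop(idx)
        ang = rng.normal(0.0, 0.25)
        c, s = np.cos(ang), np.sin(ang)
        d = np.array([direction[0] * c - direction[1] * s,
                      direction[0] * s + direction[1] * c,
                      0.0 if planar else direction[2]])
        d /= np.linalg.norm(d)
        pos = xyz[node] + d * seg_len
        r = np.linalg.norm(pos - xyz[0])
        frac = min(r / radius, 1.0)
        xyz.append(pos)
        diam.append(start_diam + (tip_diam - start_diam) * frac)
        parent.append(node)
        ntype.append(ntype_code)
        new = len(xyz) - 1
        if r < radius:
            tips.append((new, d))
            if rng.uniform() < branch_prob:
                ang2 = rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9)
                c2, s2 = np.cos(ang2), np.sin(ang2)
                d2 = np.array([d[0] * c2 - d[1] * s2, d[0] * s2 + d[1] * c2, 0.0])
                tips.append((new, d2))
    return xyz, diam, parent, ntype


def generate_dsgc_morphology(n_segments: int = 352, radius: float = 150.0,
                             seed: int = 0) -> Morphology:
    """Planar, radially branching DSGC-like arbor.

    ``n_segments`` counts all compartments including the soma (the
    published reconstruction this surrogate stands in for has 352).
    ``radius`` (µm) is the dendritic reach from the soma, matching the
    300 µm receptive-field coverage.
    """
    if n_segments < 10:
        raise ValueError("n_segments must be at least 10")
    rng = np.random.default_rng(seed)
    xyz, diam, parent, ntype = _grow_tree(
        rng, n_segments, radius, planar=True, n_primary=5, seg_len=radius / 11.0,
        branch_prob=0.35, soma_diam=15.0, start_diam=2.0, tip_diam=0.5)
    return Morphology(np.array(xyz), np.array(diam), np.array(parent), np.array(ntype))


def generate_pyramidal_morphology(n_segments: int = 69, seed: int = 0,
                                  apical_extent: float = 250.0,
                                  basal_extent: float = 120.0) -> Morphology:
    """Pyramidal-like arbor: apical trunk and tuft plus basal dendrites."""
    if n_segments < 12:
        raise ValueError("n_segments must be at least 12")
    rng = np.random.default_rng(seed)
    n_apical = int(round(n_segments * 0.55))
    up = np.array([0.0, 1.0, 0.0])
    down = np.array([0.0, -1.0, 0.0])
    xyz, diam, parent, ntype = _grow_tree(
        rng, n_apical, apical_extent, planar=True, n_primary=1,
        seg_len=apical_extent / 10.0, branch_prob=0.30, soma_diam=18.0,
        start_diam=3.0, tip_diam=0.6, ntype_code=4, cone_axis=up,
        cone_half_angle=0.2)
    n0 = len(xyz)
    # basal skirt grown below the soma, re-rooted onto node 0
    bxyz, bdiam, bparent, _ = _grow_tree(
        rng, n_segments - n0 + 1, basal_extent, planar=True, n_primary=3,
        seg_len=basal_extent / 6.0, branch_prob=0.3, soma_diam=18.0,
        start_diam=1.5, tip_diam=0.5, cone_axis=down, cone_half_angle=1.0)
    for i in range(1, len(bxyz)):
        xyz.append(bxyz[i])
        diam.append(bdiam[i])
        parent.append(0 if bparent[i] == 0 else bparent[i] + n0 - 1)
        ntype.append(3)
    return Morphology(np.array(xyz), np.array(diam), np.array(parent), np.array(ntype))


# ---------------------------------------------------------------------------
# SWC (standard 7-column dialect, µm)


def write_swc(morph: Morphology, path) -> None:
    with open(path, "w") as f:
        f.write("# index type x y z radius parent (µm)\n")
        for i in range(morph.n_segments):
            x, y, z = morph.xyz[i]
            f.write(f"{i + 1} {morph.ntype[i]} {x:.6g} {y:.6g} {z:.6g} "
                    f"{morph.diameter[i] / 2.0:.6g} "
                    f"{morph.parent[i] + 1 if morph.parent[i] >= 0 else -1}\n")


def read_swc(path) -> Morphology:
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC row: {line!r}")
            rows.append(parts)
    ids = np.array([int(r[0]) for r in rows])
    order = np.argsort(ids)
    remap = {int(rows[j][0]): rank for rank, j in enumerate(order)}
    n = len(rows)
    xyz = np.empty((n, 3))
    diam = np.empty(n)
    parent = np.empty(n, dtype=int)
    ntype = np.empty(n, dtype=int)
    for rank, j in enumerate(order):
        r = rows[j]
        ntype[rank] = int(r[1])
        xyz[rank] = [float(r[2]), float(r[3]), float(r[4])]
        diam[rank] = 2.0 * float(r[5])
        p = int(r[6])
        parent[rank] = -1 if p < 0 else remap[p]
    return Morphology(xyz, diam, parent, ntype)
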