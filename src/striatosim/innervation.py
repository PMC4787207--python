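"""Spatial maps of dopamine terminals and their progressive loss.

Two idealizations of denervation:

* microscale / coherent — terminals are uniform points; partial denervation
  removes each terminal independently, so the surviving innervation stays
  spatially uniform and every location remains within reach of release sites.
* mesoscale — terminals belong to spherical axonal arbors; denervation
  removes whole arbors, and once enough arbors are gone, connected regions
  with no terminals at all (voids) appear.

Positions are in µm; voxel indexing is 0-based with positions binned to the
lattice of the owning :class:`~striatosim.config.Lattice`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .config import ConfigError, Lattice

__all__ = [
    "TerminalMap",
    "ArborSet",
    "DenervationSpec",
    "Void",
    "build_microscale",
    "build_mesoscale",
    "denervate_uniform",
    "denervate_arbors",
    "find_voids",
]


@dataclass(frozen=True)
class DenervationSpec:
    mode: str  # "uniform_random" | "arbor_loss"
    fraction: float
    seed: int

    def __post_init__(self):
        if self.mode not in ("uniform_random", "arbor_loss"):
            raise ConfigError(f"unknown denervation mode {self.mode!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("denervation fraction must be in [0, 1]")


@dataclass
class ArborSet:
    """Spherical axonal arbors: centers, common radius, coverage bookkeeping."""

    centers: np.ndarray  # (n, 3) µm
    radius: float  # µm
    coverage_fraction: float
    reference_volume: float  # µm³ (volume in which coverage_fraction is defined)

    @property
    def n_arbors(self) -> int:
        return len(self.centers)


@dataclass
class TerminalMap:
    """Point set of dopamine release/uptake sites on a lattice."""

    lattice: Lattice
    positions: np.ndarray  # (n, 3) µm
    arbor_id: Optional[np.ndarray] = None  # (n,) int parent arbor, mesoscale only
    intact_density: float = 0.0  # reference density (1/µm³) before any denervation
    denervation_history: List[DenervationSpec] = field(default_factory=list)

    @property
    def n_terminals(self) -> int:
        return len(self.positions)

    @property
    def density(self) -> float:
        return self.n_terminals / self.lattice.volume

    def voxel_indices(self) -> np.ndarray:
        """Per-terminal (ix, iy, iz) voxel indices."""
        shape = np.asarray(self.lattice.shape)
        idx = np.floor(self.positions / self.lattice.voxel_size).astype(np.int64)
        return np.clip(idx, 0, shape - 1)

    def counts(self) -> np.ndarray:
        """Per-voxel terminal counts, shape = lattice.shape."""
        shape = self.lattice.shape
        if self.n_terminals == 0:
            return np.zeros(shape, dtype=np.int64)
        idx = self.voxel_indices()
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        c = np.bincount(flat, minlength=int(np.prod(shape)))
        return c.reshape(shape)


def build_microscale(lattice: Lattice, terminal_density: float, seed: int) -> TerminalMap:
    """Uniform random (Poisson) terminal placement at ``terminal_density``."""
    if terminal_density < 0:
        raise ConfigError("terminal_density must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    n = rng.poisson(terminal_density * lattice.volume)
    pos = rng.random((n, 3)) * np.asarray(lattice.extent)
    return TerminalMap(lattice=lattice, positions=pos, intact_density=terminal_density)


def build_mesoscale(
    lattice: Lattice,
    n_arbors: int,
    coverage_fraction: float,
    terminal_density: float,
    seed: int,
    reference_volume: Optional[float] = None,
) -> tuple[ArborSet, TerminalMap]:
    """Arbors as uniform-center spheres, terminals Poisson-placed inside each.

    Each arbor covers ``coverage_fraction`` of ``reference_volume`` (the
    lattice volume by default, playing the role of a desk-scale striatal
    reference).  Per-arbor terminal intensity is chosen so the intact
    composite density equals ``terminal_density`` in expectation: each arbor
    receives Poisson(terminal_density × V_lattice / n_arbors) terminals.
    """
    if n_arbors < 0:
        raise ConfigError("n_arbors must be non-negative")
    if not 0.0 < coverage_fraction < 1.0:
        raise ConfigError("coverage_fraction must be in (0, 1)")
    if terminal_density < 0:
        raise ConfigError("terminal_density must be non-negative")
    v_ref = lattice.volume if reference_volume is None else reference_volume
    radius = (3.0 * coverage_fraction * v_ref / (4.0 * np.pi)) ** (1.0 / 3.0)
    if 2 * radius > min(lattice.extent):
        raise ConfigError(
            f"arbor diameter {2 * radius:.1f} µm exceeds lattice extent "
            f"{min(lattice.extent):.1f} µm; reduce coverage or reference volume"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    extent = np.asarray(lattice.extent)
    centers = rng.random((n_arbors, 3)) * extent

    positions: List[np.ndarray] = []
    arbor_ids: List[np.ndarray] = []
    mean_per_arbor = terminal_density * lattice.volume / max(n_arbors, 1)
    for i in range(n_arbors):
        k = rng.poisson(mean_per_arbor)
        if k == 0:
            continue
        # uniform in sphere via normalized Gaussian directions
        d = rng.normal(size=(k, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = radius * rng.random(k) ** (1.0 / 3.0)
        p = centers[i] + d * r[:, None]
        positions.append(np.mod(p, extent))  # periodic wrap
        arbor_ids.append(np.full(k, i, dtype=np.int64))

    if positions:
        pos = np.concatenate(positions)
        ids = np.concatenate(arbor_ids)
    else:
        pos = np.empty((0, 3))
        ids = np.empty(0, dtype=np.int64)
    arbors = ArborSet(
        centers=centers,
        radius=radius,
        coverage_fraction=coverage_fraction,
        reference_volume=v_ref,
    )
    tmap = TerminalMap(
        lattice=lattice, positions=pos, arbor_id=ids, intact_density=terminal_density
    )
    return arbors, tmap


def coverage_counts(
    arbors: ArborSet, lattice: Lattice, points: np.ndarray
) -> np.ndarray:
    """Number of arbors whose sphere contains each query point (periodic)."""
    from scipy.spatial import cKDTree

    extent = np.asarray(lattice.extent)
    tree = cKDTree(np.mod(arbors.centers, extent), boxsize=extent)
    return np.asarray(
        [len(tree.query_ball_point(p, arbors.radius)) for p in np.atleast_2d(points)]
    )


def denervate_uniform(tmap: TerminalMap, fraction: float, seed: int) -> TerminalMap:
    """Remove each terminal independently with probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    spec = DenervationSpec("uniform_random", fraction, seed)
    if tmap.n_terminals == 0 or fraction == 0.0:
        keep = np.ones(tmap.n_terminals, dtype=bool)
    elif fraction == 1.0:
        keep = np.zeros(tmap.n_terminals, dtype=bool)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(12,)))
        keep = rng.random(tmap.n_terminals) >= fraction
    return TerminalMap(
        lattice=tmap.lattice,
        positions=tmap.positions[keep],
        arbor_id=None if tmap.arbor_id is None else tmap.arbor_id[keep],
        intact_density=tmap.intact_density,
        denervation_history=tmap.denervation_history + [spec],
    )


def denervate_arbors(
    arbors: ArborSet, tmap: TerminalMap, fraction: float, seed: int
) -> TerminalMap:
    """Remove ⌊fraction × n_arbors⌉ whole arbors chosen uniformly."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    if tmap.arbor_id is None:
        raise ConfigError("terminal map lacks arbor ancestry; build with build_mesoscale")
    spec = DenervationSpec("arbor_loss", fraction, seed)
    n_remove = int(round(fraction * arbors.n_arbors))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    removed = rng.choice(arbors.n_arbors, size=n_remove, replace=False) if n_remove else np.empty(0, dtype=int)
    keep = ~np.isin(tmap.arbor_id, removed)
    return TerminalMap(
        lattice=tmap.lattice,
        positions=tmap.positions[keep],
        arbor_id=tmap.arbor_id[keep],
        intact_density=tmap.intact_density,
        denervation_history=tmap.denervation_history + [spec],
    )


@dataclass(frozen=True)
class Void:
    """A connected region of terminal-free voxels."""

    component_id: int
    voxel_indices: np.ndarray  # (k, 3) int
    n_voxels: int
    equivalent_diameter: float  # µm, diameter of the equal-volume sphere


def find_voids(
    tmap: TerminalMap, min_equiv_diameter: float = 0.0, reach: float = 4.0
) -> List[Void]:
    """Connected regions with no terminal within ``reach`` µm.

    At the default terminal density (~0.8 per voxel) almost half of all
    voxels are empty by Poisson chance and, being above the site-percolation
    threshold, they form a lattice-spanning connected cluster — so "empty
    voxel" cannot define a void.  A void is instead seeded by voxels farther
    than ``reach`` (comparable to the nearest-terminal spacing plus the
    intact uptake screening length) from every terminal, then grown back by
    the same radius so its extent matches the truly denervated region.
    Components are 6-connected and returned largest first; the equivalent
    diameter of a component of volume V is (6V/π)^(1/3).
    """
    counts = tmap.counts()
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    if tmap.n_terminals == 0:
        empty = np.ones(counts.shape, dtype=bool)
    else:
        dist = ndimage.distance_transform_edt(
            counts == 0, sampling=tmap.lattice.voxel_size
        )
        core = dist > reach
        if reach > 0 and core.any():
            r = int(np.ceil(reach / tmap.lattice.voxel_size))
            off = np.arange(-r, r + 1)
            oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
            ball = (oz ** 2 + oy ** 2 + ox ** 2) * tmap.lattice.voxel_size ** 2 <= reach ** 2
            empty = ndimage.binary_dilation(core, structure=ball)
        else:
            empty = core
    labels, n = ndimage.label(empty, structure=structure)
    voids: List[Void] = []
    if n == 0:
        return voids
    sizes = ndimage.sum_labels(empty, labels, index=np.arange(1, n + 1))
    voxvol = tmap.lattice.voxel_volume
    for cid, size in enumerate(sizes, start=1):
        vol = float(size) * voxvol
        d_eq = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        if d_eq >= min_equiv_diameter:
            idx = np.argwhere(labels == cid)
            voids.append(Void(cid, idx, int(size), d_eq))
    voids.sort(key=lambda v: -v.n_voxels)
    return voids
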