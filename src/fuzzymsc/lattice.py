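"""3D on-lattice culture domain with single-occupancy patches.

The simulation world is a regular grid of ``nx x ny x nz`` patches (eight
z-layers by default, reflecting that osteoblastic MSC cultures build more
than four cell layers). Each patch holds at most one cell. Neighbourhoods
are 3D Moore (26-connected) by default, truncated at the solid domain
walls; von Neumann (6-connected) is available as an alternative.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

__all__ = ["LatticeWorld", "MOORE_OFFSETS", "VON_NEUMANN_OFFSETS"]

MOORE_OFFSETS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)
VON_NEUMANN_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))

EMPTY = -1


class LatticeWorld:
    """Single-occupancy lattice with Moore or von Neumann neighbourhoods.

    Parameters
    ----------
    nx, ny, nz
        Grid dimensions in patches; ``nz`` defaults to 8 layers with z=0
        the culture surface.
    patch_size_um
        Patch edge length in micrometres (one cell diameter).
    neighborhood
        ``"moore"`` (default) or ``"von_neumann"``.
    """

    def __init__(self, nx: int, ny: int, nz: int = 8, patch_size_um: float = 15.0,
                 neighborhood: str = "moore") -> None:
        if min(nx, ny, nz) < 1:
            raise ValueError("dimensions must be positive")
        self.shape = (nx, ny, nz)
        self.patch_size_um = float(patch_size_um)
        if neighborhood not in ("moore", "von_neumann"):
            raise ValueError(f"unknown neighborhood {neighborhood!r}")
        self.neighborhood = neighborhood
        self.offsets = MOORE_OFFSETS if neighborhood == "moore" else VON_NEUMANN_OFFSETS
        #: cell id per patch, EMPTY (-1) where vacant
        self.occupancy = np.full(self.shape, EMPTY, dtype=np.int64)
        self._kernel = self._make_kernel()
        self._neighbor_counts = convolve(
            np.ones(self.shape), self._kernel, mode="constant", cval=0.0
        ).round().astype(np.int64)
        self._build_neighbor_table()

    def _build_neighbor_table(self) -> None:
        """Flat neighbour lookup (n_patches, n_offsets), -1 padded."""
        nx, ny, nz = self.shape
        xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        coords = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
        table = np.full((coords.shape[0], len(self.offsets)), -1, dtype=np.int64)
        for k, off in enumerate(self.offsets):
            q = coords + np.asarray(off)
            ok = ((q >= 0) & (q < np.asarray(self.shape))).all(axis=1)
            table[ok, k] = np.ravel_multi_index(tuple(q[ok].T), self.shape)
        self._flat_neighbors = table
        self._occ_flat = self.occupancy.reshape(-1)  # shared memory view

    def _make_kernel(self) -> np.ndarray:
        k = np.zeros((3, 3, 3))
        for dx, dy, dz in self.offsets:
            k[dx + 1, dy + 1, dz + 1] = 1.0
        return k

    # -- geometry ----------------------------------------------------------

    def in_domain(self, patch) -> bool:
        x, y, z = patch
        nx, ny, nz = self.shape
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz

    def _require(self, patch) -> None:
        if not self.in_domain(patch):
            raise ValueError(f"patch {patch} outside the domain {self.shape}")

    def neighbors(self, patch) -> list[tuple[int, int, int]]:
        """Neighbouring patches, truncated at the walls (no wrap)."""
        self._require(patch)
        x, y, z = patch
        out = []
        for dx, dy, dz in self.offsets:
            q = (x + dx, y + dy, z + dz)
            if self.in_domain(q):
                out.append(q)
        return out

    def neighbor_count(self, patch) -> int:
        self._require(patch)
        return int(self._neighbor_counts[patch])

    # -- occupancy ---------------------------------------------------------

    def is_vacant(self, patch) -> bool:
        self._require(patch)
        return self.occupancy[tuple(patch)] == EMPTY

    def place(self, cell_id: int, patch) -> None:
        self._require(patch)
        if self.occupancy[tuple(patch)] != EMPTY:
            raise RuntimeError(f"occupancy conflict at {patch}")
        self.occupancy[tuple(patch)] = cell_id

    def remove(self, patch) -> None:
        self._require(patch)
        self.occupancy[tuple(patch)] = EMPTY

    def move(self, src, dst) -> None:
        cell_id = self.occupancy[tuple(src)]
        if cell_id == EMPTY:
            raise RuntimeError(f"no cell at {src}")
        self.place(int(cell_id), dst)
        self.occupancy[tuple(src)] = EMPTY

    def vacant_neighbors(self, patch) -> list[tuple[int, int, int]]:
        """Adjacent vacant patches (empty when fully surrounded)."""
        flat = self.vacant_neighbors_flat(int(np.ravel_multi_index(tuple(patch), self.shape)))
        return [tuple(int(v) for v in q) for q in zip(*np.unravel_index(flat, self.shape))]

    def vacant_neighbors_flat(self, flat_patch: int) -> np.ndarray:
        """Flat indices of vacant neighbours; the engine's fast path."""
        if not 0 <= flat_patch < self._flat_neighbors.shape[0]:
            raise ValueError(f"flat patch {flat_patch} outside the domain")
        nbrs = self._flat_neighbors[flat_patch]
        return nbrs[(nbrs >= 0) & (self._occ_flat[nbrs] == EMPTY)]

    # -- density -----------------------------------------------------------

    def cell_density(self, patch) -> float:
        """Occupied fraction of the patch neighbourhood, in [0, 1]."""
        self._require(patch)
        occupied = sum(self.occupancy[q] != EMPTY for q in self.neighbors(patch))
        return occupied / self.neighbor_count(patch)

    def density_field(self) -> np.ndarray:
        """Vectorised cell density for every patch at once."""
        occ = (self.occupancy != EMPTY).astype(float)
        counts = convolve(occ, self._kernel, mode="constant", cval=0.0)
        return counts.round() / self._neighbor_counts

    def occupied_patches(self) -> np.ndarray:
        return np.argwhere(self.occupancy != EMPTY)

    @property
    def n_occupied(self) -> int:
        return int((self.occupancy != EMPTY).sum())

    def check_consistency(self, positions: np.ndarray, alive: np.ndarray) -> None:
        """Assert occupancy map and cell registry agree (debug invariant)."""
        live = np.flatnonzero(alive)
        if live.size != self.n_occupied:
            raise RuntimeError("occupancy count disagrees with live-cell registry")
        for i in live:
            patch = tuple(positions[i])
            if self.occupancy[patch] != i:
                raise RuntimeError(f"cell {i} not registered at its patch {patch}")
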