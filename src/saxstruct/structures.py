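"""Structural containers: atomic models, dummy-atom bead models, density grids.

Atomic models hold full or C-alpha-level coordinates in Angstrom; bead models
are the uniform-sphere dummy-atom representation produced by ab initio shape
reconstruction. Both can be superposed and both scatter via the Debye sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import MEAN_RESIDUE_ELECTRONS, RESIDUE_ELECTRONS


@dataclass
class AtomicModel:
    """Atomic coordinates with per-atom metadata.

    All coordinate arrays are (n, 3) in Angstrom. ``hetero`` flags HETATM
    sites (metal ions such as Zn); protein atoms are non-hetero.
    """

    coords: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    chain: np.ndarray
    element: np.ndarray
    hetero: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n == 0:
            raise ValueError("empty model")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.chain = np.asarray(self.chain, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        for arr in (self.residue_index, self.residue_name, self.atom_name,
                    self.chain, self.element, self.hetero):
            if arr.shape[0] != n:
                raise ValueError("per-atom arrays must match coords length")

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    @classmethod
    def from_ca(
        cls,
        coords: np.ndarray,
        residue_index: np.ndarray | None = None,
        residue_name: str | np.ndarray = "ALA",
        chain: str = "A",
        label: str = "",
    ) -> "AtomicModel":
        """Build a C-alpha-only model from bare coordinates."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = coords.shape[0]
        if residue_index is None:
            residue_index = np.arange(1, n + 1)
        if isinstance(residue_name, str):
            residue_name = np.full(n, residue_name, dtype=object)
        return cls(
            coords=coords,
            residue_index=np.asarray(residue_index),
            residue_name=np.asarray(residue_name, dtype=object),
            atom_name=np.full(n, "CA", dtype=object),
            chain=np.full(n, chain, dtype=object),
            element=np.full(n, "C", dtype=object),
            hetero=np.zeros(n, dtype=bool),
            label=label,
        )

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.hetero

    def ca_mask(self) -> np.ndarray:
        names = np.array([str(a).strip() for a in self.atom_name])
        return (names == "CA") & self.protein_mask

    def ca_coords(self) -> np.ndarray:
        mask = self.ca_mask()
        if not np.any(mask):
            raise ValueError("model has no CA atoms")
        return self.coords[mask]

    def ca_residue_index(self) -> np.ndarray:
        return self.residue_index[self.ca_mask()]

    def select_residues(self, first: int, last: int) -> "AtomicModel":
        """Sub-model with residue_index in [first, last] (protein atoms)."""
        mask = (self.residue_index >= first) & (self.residue_index <= last) & self.protein_mask
        if not np.any(mask):
            raise ValueError(f"no atoms in residue range {first}-{last}")
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            coords=self.coords[mask],
            residue_index=self.residue_index[mask],
            residue_name=self.residue_name[mask],
            atom_name=self.atom_name[mask],
            chain=self.chain[mask],
            element=self.element[mask],
            hetero=self.hetero[mask],
            label=self.label,
        )

    def residue_electrons(self) -> np.ndarray:
        """Electron count per CA site (coarse residue form factors)."""
        mask = self.ca_mask()
        out = np.empty(int(mask.sum()))
        for i, rn in enumerate(self.residue_name[mask]):
            out[i] = RESIDUE_ELECTRONS.get(str(rn).strip().upper(), MEAN_RESIDUE_ELECTRONS)
        return out

    def hetero_sites(self) -> list[tuple[str, np.ndarray]]:
        """(element, position) for each HETATM site."""
        idx = np.nonzero(self.hetero)[0]
        return [(str(self.element[i]).strip().upper(), self.coords[i]) for i in idx]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        new = replace(self)
        new.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass
class BeadModel:
    """Dummy-atom shape model: equal spheres with per-bead occupancy weight."""

    centers: np.ndarray
    bead_radius: float
    occupancy: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.centers.shape[0] == 0:
            raise ValueError("empty bead model")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        if self.occupancy is None:
            self.occupancy = np.ones(self.centers.shape[0])
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape[0] != self.centers.shape[0]:
            raise ValueError("occupancy length mismatch")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1 + 1e-9):
            raise ValueError("occupancy must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.centers.shape[0])

    @property
    def volume(self) -> float:
        """Total excluded volume: n_beads x single-bead volume (A^3)."""
        return float(len(self)) * (4.0 / 3.0) * np.pi * self.bead_radius**3

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadModel":
        new = replace(self)
        new.centers = self.centers @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass
class DensityGrid:
    """Regular 3-D density map: ``values[i, j, k]`` at origin + voxel*(i,j,k)."""

    origin: np.ndarray
    voxel: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("density values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.voxel * np.arange(self.values.shape[d])
            for d in range(3)
        )  # type: ignore[return-value]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; zero outside the grid."""
        rho, _ = self.interpolate_with_gradient(points)
        return rho

    def interpolate_with_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear density and its analytic spatial gradient at ``points``.

        Outside the grid both are zero (the map exerts no force there).
        """
        pts = (np.asarray(points, dtype=float).reshape(-1, 3) - self.origin) / self.voxel
        nx, ny, nz = self.values.shape
        rho = np.zeros(pts.shape[0])
        grad = np.zeros_like(pts)
        inside = np.all((pts >= 0) & (pts <= np.array([nx, ny, nz]) - 1), axis=1)
        if not np.any(inside):
            return rho, grad
        p = pts[inside]
        i0 = np.minimum(p.astype(int), np.array([nx, ny, nz]) - 2)
        f = p - i0
        v = self.values
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        c000 = v[ix, iy, iz]
        c100 = v[ix + 1, iy, iz]
        c010 = v[ix, iy + 1, iz]
        c110 = v[ix + 1, iy + 1, iz]
        c001 = v[ix, iy, iz + 1]
        c101 = v[ix + 1, iy, iz + 1]
        c011 = v[ix, iy + 1, iz + 1]
        c111 = v[ix + 1, iy + 1, iz + 1]
        # interpolate along x, then y, then z
        c00 = c000 + fx * (c100 - c000)
        c10 = c010 + fx * (c110 - c010)
        c01 = c001 + fx * (c101 - c001)
        c11 = c011 + fx * (c111 - c011)
        c0 = c00 + fy * (c10 - c00)
        c1 = c01 + fy * (c11 - c01)
        rho[inside] = c0 + fz * (c1 - c0)
        # analytic derivatives of the trilinear form
        dx00 = c100 - c000
        dx10 = c110 - c010
        dx01 = c101 - c001
        dx11 = c111 - c011
        dx0 = dx00 + fy * (dx10 - dx00)
        dx1 = dx01 + fy * (dx11 - dx01)
        gx = (dx0 + fz * (dx1 - dx0)) / self.voxel
        gy = ((c10 - c00) + fz * ((c11 - c01) - (c10 - c00))) / self.voxel
        gz = (c1 - c0) / self.voxel
        grad[inside] = np.column_stack([gx, gy, gz])
        return rho, grad

    def integral(self) -> float:
        return float(self.values.sum() * self.voxel**3)
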