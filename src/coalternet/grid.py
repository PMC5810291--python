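"""Voxel-grid geometry shared by all stages.

Every volumetric object in the pipeline (modeled-alteration maps, ALE maps,
atlas volumes, brain masks) lives on a :class:`VolumeGrid`: an axis-aligned,
isotropic lattice of voxel centers in stereotaxic (Talairach) millimetre
space.  World coordinates map to voxel indices by snapping to the nearest
voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Default bounding box covering the Talairach atlas extent (mm).
DEFAULT_BOUNDS = ((-70.0, 70.0), (-104.0, 68.0), (-60.0, 78.0))
DEFAULT_VOXEL_SIZE = 2.0


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic, axis-aligned voxel lattice.

    Parameters
    ----------
    origin : tuple of float
        Millimetre coordinate of the center of voxel (0, 0, 0).
    voxel_size : float
        Isotropic voxel edge length in mm.
    dims : tuple of int
        Number of voxels along x, y, z.
    """

    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(int(d) <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @classmethod
    def talairach(cls, voxel_size: float = DEFAULT_VOXEL_SIZE,
                  bounds=DEFAULT_BOUNDS) -> "VolumeGrid":
        """Grid covering the default Talairach bounding box."""
        origin = tuple(lo for lo, _ in bounds)
        dims = tuple(int(np.floor((hi - lo) / voxel_size)) + 1
                     for lo, hi in bounds)
        return cls(origin=origin, voxel_size=voxel_size, dims=dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size ** 3)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (axis-aligned RAS+)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Snap world mm coordinates to nearest voxel indices.

        Accepts a single (3,) coordinate or an (n, 3) array; returns int
        indices of the same leading shape.  Indices may fall outside the
        grid; use :meth:`contains_voxel` / :meth:`contains_world` to check.
        """
        xyz = np.asarray(xyz, dtype=float)
        idx = np.rint((xyz - np.asarray(self.origin)) / self.voxel_size)
        return idx.astype(int)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """World mm coordinates of voxel centers."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + ijk * self.voxel_size

    def contains_voxel(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=int)
        dims = np.asarray(self.dims)
        return np.all((ijk >= 0) & (ijk < dims), axis=-1)

    def contains_world(self, xyz) -> np.ndarray:
        """True where a world coordinate snaps to an in-grid voxel."""
        return self.contains_voxel(self.world_to_voxel(xyz))

    def all_voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center world coordinates (C order)."""
        ii, jj, kk = np.indices(self.dims)
        ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.voxel_to_world(ijk)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (self.dims == other.dims
                and abs(self.voxel_size - other.voxel_size) <= tol
                and all(abs(a - b) <= tol
                        for a, b in zip(self.origin, other.origin)))
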