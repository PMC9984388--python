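"""Voxelized reciprocal-space maps on subdivided Miller-index grids.

A :class:`VoxelMap` samples intensity on a 3D grid of fractional Miller
indices. Each axis runs from ``-hmax`` to ``+hmax`` in steps of
``1/subdivision`` with an odd subdivision, so that voxel centers coincide
with integer Miller indices (reciprocal-lattice points) and every voxel
belongs to the Brillouin zone of exactly one RLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelMap"]


@dataclass
class VoxelMap:
    """Reciprocal-space intensity map with uncertainties and mask.

    Attributes
    ----------
    geometry : UnitCellGeometry
    hmax : tuple of int
        Maximum integer Miller index along each axis.
    subdivision : tuple of int
        Odd number of voxels per reciprocal-lattice spacing along each axis.
    data, sigma : ndarray
        Intensity (electron units per cell) and uncertainty, shape
        ``(2*hmax*s + 1, ...)`` per axis.
    measured : ndarray of bool
        False marks missing voxels (e.g. Bragg-excluded).
    """

    geometry: object
    hmax: tuple
    subdivision: tuple
    data: np.ndarray = None
    sigma: np.ndarray = None
    measured: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.hmax = tuple(int(h) for h in self.hmax)
        self.subdivision = tuple(int(s) for s in self.subdivision)
        if any(s % 2 == 0 or s < 1 for s in self.subdivision):
            raise ValueError("subdivisions must be odd positive integers")
        if self.data is None:
            self.data = np.zeros(self.shape)
        if self.sigma is None:
            self.sigma = np.zeros(self.shape)
        if self.measured is None:
            self.measured = np.ones(self.shape, dtype=bool)
        for arr_name in ("data", "sigma", "measured"):
            arr = getattr(self, arr_name)
            if arr.shape != self.shape:
                raise ValueError(f"{arr_name} has shape {arr.shape}, "
                                 f"expected {self.shape}")

    # -- grid geometry ---------------------------------------------------
    @property
    def shape(self):
        return tuple(2 * h * s + 1 for h, s in zip(self.hmax, self.subdivision))

    def axis(self, i):
        """Fractional Miller indices along axis i."""
        h, s = self.hmax[i], self.subdivision[i]
        return np.arange(-h * s, h * s + 1) / s

    def h_grid(self):
        """Fractional Miller index of every voxel, shape (*shape, 3)."""
        ax = [self.axis(i) for i in range(3)]
        H = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        return H

    def q_grid(self):
        """Cartesian scattering vectors (2*pi convention), shape (*shape, 3)."""
        return self.h_grid() @ self.geometry.recip.T

    def s_magnitude(self):
        """|q| / 2 pi = 1/d for every voxel."""
        return np.linalg.norm(self.q_grid(), axis=-1) / (2 * np.pi)

    def rlp_index(self):
        """Integer Miller index of the RLP owning each voxel."""
        return np.round(self.h_grid()).astype(int)

    def index_of(self, h_frac):
        """Array index of the voxel at fractional Miller index ``h_frac``."""
        idx = []
        for i in range(3):
            s, hm = self.subdivision[i], self.hmax[i]
            j = int(round(h_frac[i] * s)) + hm * s
            if not 0 <= j < self.shape[i]:
                raise IndexError(f"h={h_frac} outside map")
            idx.append(j)
        return tuple(idx)

    def copy(self, data=None, sigma=None, measured=None):
        return VoxelMap(
            geometry=self.geometry, hmax=self.hmax, subdivision=self.subdivision,
            data=np.array(self.data if data is None else data),
            sigma=np.array(self.sigma if sigma is None else sigma),
            measured=np.array(self.measured if measured is None else measured),
        )

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Write the map (grid metadata, data, sigma, mask) to HDF5."""
        import h5py
        g = self.geometry
        with h5py.File(path, "w") as fh:
            fh.attrs["cell"] = [g.a, g.b, g.c, g.alpha, g.beta, g.gamma]
            fh.attrs["hmax"] = self.hmax
            fh.attrs["subdivision"] = self.subdivision
            from .crystal_model import symop_to_string
            fh.attrs["operators"] = [symop_to_string(R, t) for R, t in g.operators]
            fh.create_dataset("data", data=self.data, compression="gzip")
            fh.create_dataset("sigma", data=self.sigma, compression="gzip")
            fh.create_dataset("measured", data=self.measured, compression="gzip")

    @classmethod
    def load(cls, path):
        import h5py
        from .crystal_model import UnitCellGeometry
        with h5py.File(path, "r") as fh:
            cell = fh.attrs["cell"]
            ops = list(fh.attrs["operators"])
            geom = UnitCellGeometry(*cell, operators=ops)
            return cls(
                geometry=geom,
                hmax=tuple(int(x) for x in fh.attrs["hmax"]),
                subdivision=tuple(int(x) for x in fh.attrs["subdivision"]),
                data=fh["data"][()],
                sigma=fh["sigma"][()],
                measured=fh["measured"][()].astype(bool),
            )

    def export_mrc(self, path):
        """Export intensities as a minimal CCP4/MRC volume (mode 2 float32).

        Intended for visualization only; axis order is (h, k, l) fastest to
        slowest mapped to columns/rows/sections.
        """
        data = np.ascontiguousarray(self.data, dtype=np.float32)
        nz, ny, nx = data.shape
        header = np.zeros(256, dtype=np.int32)
        fheader = header.view(np.float32)
        header[0:3] = [nx, ny, nz]
        header[3] = 2  # mode 2: float32
        header[7:10] = [nx, ny, nz]
        g = self.geometry
        fheader[10:16] = [g.a, g.b, g.c, g.alpha, g.beta, g.gamma]
        header[16:19] = [1, 2, 3]
        fheader[19] = float(data.min())
        fheader[20] = float(data.max())
        fheader[21] = float(data.mean())
        header[52] = int.from_bytes(b"MAP ", "little")
        header[53] = 0x00004144  # little-endian machine stamp
        with open(path, "wb") as fh:
            fh.write(header.tobytes())
            fh.write(data.transpose(2, 1, 0).tobytes())
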