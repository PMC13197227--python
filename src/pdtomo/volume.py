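"""3D density volumes with physical voxel size, backed by MRC2014 files.

Conventions: right-handed coordinates in nanometres; ``data[ix, iy, iz]``
with 0-based indexing; the centre of voxel (0, 0, 0) sits at ``origin_nm``.
The default voxel size, 0.76 nm, matches 4x-binned tomograms recorded at
1.9 Å pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["Volume", "read_mrc", "write_mrc"]

DEFAULT_VOXEL_NM = 0.76


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    data : ndarray
        3D array indexed ``[ix, iy, iz]``.
    voxel_size_nm : float
        Edge length of one cubic voxel, nm.
    origin_nm : ndarray
        Position of the centre of voxel (0, 0, 0), nm.
    """

    data: np.ndarray
    voxel_size_nm: float = DEFAULT_VOXEL_NM
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume.data must be 3D")
        if any(s < 16 for s in self.data.shape):
            raise ValueError("grid dimensions must be >= 16 per axis")
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def nm_to_voxel(self, pos_nm: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a physical position (may be off-grid)."""
        return (np.asarray(pos_nm, dtype=float) - self.origin_nm) / self.voxel_size_nm

    def voxel_to_nm(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.voxel_size_nm + self.origin_nm

    def centre_nm(self) -> np.ndarray:
        """Physical position of the grid centre (voxel (n-1)/2)."""
        return self.voxel_to_nm((np.array(self.shape) - 1) / 2.0)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size_nm, self.origin_nm.copy())

    def normalized(self) -> "Volume":
        """Zero-mean, unit-variance copy (variance guarded)."""
        d = self.data.astype(np.float64)
        sd = d.std()
        if sd == 0:
            return Volume(np.zeros_like(self.data), self.voxel_size_nm, self.origin_nm.copy())
        return Volume(((d - d.mean()) / sd).astype(np.float32), self.voxel_size_nm, self.origin_nm.copy())


def write_mrc(vol: Volume, path: str) -> None:
    """Write as MRC2014 mode 2 (float32); voxel size stored in Å in the header."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    a = 10.0 * vol.voxel_size_nm  # nm -> Å
    nx, ny, nz = vol.data.shape
    grid.set_unit_cell(gemmi.UnitCell(nx * a, ny * a, nz * a, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    # origin (Å) in words 50-52 of the MRC2014 header
    for i, o in enumerate(vol.origin_nm):
        m.set_header_float(50 + i, float(o) * 10.0)
    m.write_ccp4_map(str(path))


def read_mrc(path: str) -> Volume:
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    voxel_a = m.grid.unit_cell.a / m.grid.nu
    origin = np.array([m.header_float(50 + i) for i in range(3)]) / 10.0
    return Volume(data, voxel_size_nm=voxel_a / 10.0, origin_nm=origin)
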