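"""Reading and writing MRC/CCP4 2014 volumes.

The package works on a single in-memory container, :class:`VolumeGrid`,
which stores the density as a 3D float array in a fixed internal axis
convention (slowest to fastest: Z, Y, X), the isotropic voxel size in
Angstrom, and the physical origin. Files whose header declares a
different axis order (``mapc``/``mapr``/``maps``) are permuted on read so
that all downstream spatial filters see a consistent orientation.

Only the plain MRC2014 subset needed for single-particle reconstructions
is supported: modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16),
no extended header interpretation beyond skipping it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid", "read_volume", "write_volume"]

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


@dataclass
class VolumeGrid:
    """A 3D scalar field with physical sampling metadata.

    Parameters
    ----------
    data : ndarray
        Density values, axis order (Z, Y, X).
    voxel_size : float
        Edge length of a voxel in Angstrom (isotropic).
    origin : tuple of float
        Physical offset of the first voxel in Angstrom, (x, y, z).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D, got {self.data.ndim} dimensions"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this grid's sampling metadata."""
        return VolumeGrid(data, voxel_size=self.voxel_size, origin=self.origin)

    def validate_as_mask(self) -> None:
        """Check that values lie in [0, 1] (soft masks / definitions)."""
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(
                f"mask values must lie in [0, 1], observed range [{lo:g}, {hi:g}]"
            )


def _parse_header(buf: bytes) -> dict:
    words_i = np.frombuffer(buf, dtype="<i4", count=56)
    words_f = np.frombuffer(buf, dtype="<f4", count=56)
    hdr = {
        "n_cols": int(words_i[0]),
        "n_rows": int(words_i[1]),
        "n_secs": int(words_i[2]),
        "mode": int(words_i[3]),
        "m_grid": words_i[7:10].astype(int),  # mx, my, mz
        "cella": words_f[10:13].astype(float),
        "mapcrs": words_i[16:19].astype(int),  # mapc, mapr, maps
        "nsymbt": int(words_i[23]),
        "origin": tuple(float(v) for v in words_f[49:52]),
    }
    return hdr


def read_volume(path) -> VolumeGrid:
    """Read an MRC2014 volume into the internal (Z, Y, X) convention.

    The voxel size is taken from the cell dimensions divided by the grid
    sampling. Anisotropy beyond 1% triggers a warning and the mean of
    the three axis spacings is used.
    """
    with open(path, "rb") as fh:
        buf = fh.read(_HEADER_BYTES)
        if len(buf) < _HEADER_BYTES:
            raise OSError(f"{path}: truncated MRC header ({len(buf)} bytes)")
        hdr = _parse_header(buf)
        if buf[208:212] not in (b"MAP ", b"MAP\x00"):
            raise OSError(f"{path}: not an MRC2014 file (missing MAP stamp)")
        if hdr["mode"] not in _MODE_DTYPES:
            raise OSError(f"{path}: unsupported MRC mode {hdr['mode']}")
        n_cols, n_rows, n_secs = hdr["n_cols"], hdr["n_rows"], hdr["n_secs"]
        if min(n_cols, n_rows, n_secs) < 1:
            raise OSError(
                f"{path}: volume is not 3D (dims {n_cols}x{n_rows}x{n_secs})"
            )
        fh.seek(_HEADER_BYTES + hdr["nsymbt"])
        dtype = _MODE_DTYPES[hdr["mode"]]
        count = n_cols * n_rows * n_secs
        raw = np.fromfile(fh, dtype=np.dtype(dtype).newbyteorder("<"), count=count)
    if raw.size != count:
        raise OSError(f"{path}: truncated data section ({raw.size}/{count} voxels)")

    data = raw.reshape(n_secs, n_rows, n_cols).astype(np.float32)
    # File axes slow->fast carry crystallographic meanings (maps, mapr, mapc),
    # each in {1:X, 2:Y, 3:Z}; permute to internal (Z, Y, X).
    mapc, mapr, maps = hdr["mapcrs"]
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise OSError(f"{path}: invalid axis mapping {(mapc, mapr, maps)}")
    meanings = [maps, mapr, mapc]
    perm = [meanings.index(3), meanings.index(2), meanings.index(1)]
    data = np.ascontiguousarray(data.transpose(perm))

    m_grid = hdr["m_grid"]
    cella = hdr["cella"]
    with np.errstate(invalid="ignore"):
        spacing = np.where(m_grid > 0, cella / np.maximum(m_grid, 1), 0.0)
    spacing = spacing[spacing > 0]
    if spacing.size == 0:
        voxel_size = 1.0
    else:
        voxel_size = float(spacing.mean())
        if spacing.size == 3 and (spacing.max() - spacing.min()) > 0.01 * voxel_size:
            warnings.warn(
                f"anisotropic voxel size {tuple(np.round(spacing, 4))}; "
                f"using mean {voxel_size:.4f} A",
                stacklevel=2,
            )
    return VolumeGrid(data, voxel_size=voxel_size, origin=hdr["origin"])


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as a float32 MRC2014 file.

    Refuses non-finite data: NaN/Inf voxels would silently corrupt any
    downstream consumer of the map.
    """
    data = np.asarray(grid.data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("can only write 3D volumes")
    if not np.isfinite(data).all():
        raise ValueError("volume contains non-finite values; refusing to write")

    nz, ny, nx = data.shape
    header_i = np.zeros(256, dtype="<i4")
    header_f = header_i.view("<f4")
    header_i[0:3] = (nx, ny, nz)
    header_i[3] = 2  # mode: float32
    header_i[7:10] = (nx, ny, nz)
    header_f[10:13] = np.array([nx, ny, nz], dtype=np.float64) * grid.voxel_size
    header_f[13:16] = 90.0
    header_i[16:19] = (1, 2, 3)
    header_f[19] = float(data.min())
    header_f[20] = float(data.max())
    header_f[21] = float(data.mean())
    header_i[22] = 1  # ispg: volume
    header_f[49:52] = grid.origin
    header_i[52] = int.from_bytes(b"MAP ", "little")
    header_i[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")
    header_f[54] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(header_i.tobytes())
        data.tofile(fh)
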