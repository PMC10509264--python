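"""Local-filter kernels, normalization tiling, and the automatic percentile.

The local-scale estimator measures contrast with a windowed max-value
filter over a spherical neighborhood ``V`` of each voxel, and normalizes
it by a tau-percentile taken over a sparse set of cubic tiles ``W_j``.
The percentile is chosen automatically so that the probability of
under-estimating the maximum from ``n_V`` samples equals the worst-case
over-estimation ``1 - tau``: tau_n is the unique positive root of

    x**n + x - 1 = 0

which is distribution-free as long as the samples are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleKernel",
    "TilingScheme",
    "solve_tau",
    "kernel_size_from_resolution",
    "build_spherical_kernel",
    "place_tiles",
    "DEFAULT_TILE_EDGE",
    "DEFAULT_GRID_COUNT",
]

#: Default normalization-region edge (voxels) and per-dimension tile count.
DEFAULT_TILE_EDGE = 12
DEFAULT_GRID_COUNT = 20


def solve_tau(n: int, tol: float = 1e-9) -> float:
    """Automatic percentile tau_n for a kernel sampling ``n`` voxels.

    Solves ``x**n + x - 1 = 0`` on (0, 1) by bisection; the polynomial is
    strictly increasing there with G(0) = -1 and G(1) = 1, so the root is
    unique and bisection cannot fail.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    if n == 1:
        return 0.5
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid**n + mid - 1.0 < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def kernel_size_from_resolution(r: float, d: float) -> int:
    """Kernel edge in voxels for a map at resolution/low-pass ``r`` (A).

    The smallest odd integer strictly greater than ``2 r / d`` where ``d``
    is the voxel size, clamped below at 3 (a 1-voxel kernel would make
    the max filter the identity).
    """
    if not (r > 0 and d > 0):
        raise ValueError(f"resolution and voxel size must be positive, got r={r}, d={d}")
    q = 2.0 * r / d
    k = int(np.floor(q)) + 1
    if k % 2 == 0:
        k += 1
    return max(k, 3)


@dataclass(frozen=True)
class ScaleKernel:
    """Spherical voxel neighborhood for the max-value filter.

    ``offsets`` are the integer displacements with Euclidean norm at most
    ``radius`` inside the k-cube; ``tau`` defaults to the automatic
    percentile for ``n_V`` independent samples.
    """

    size: int
    radius: float
    offsets: np.ndarray = field(repr=False)
    tau: float

    @property
    def n_v(self) -> int:
        return len(self.offsets)

    @property
    def footprint(self) -> np.ndarray:
        """Boolean k^3 mask usable as an ndimage footprint."""
        h = self.size // 2
        fp = np.zeros((self.size,) * 3, dtype=bool)
        idx = self.offsets + h
        fp[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return fp


def build_spherical_kernel(
    k: int, radius: float | None = None, tau: float | None = None
) -> ScaleKernel:
    """Build the radial cartesian kernel of edge ``k`` and given radius.

    ``radius`` defaults to ``k / 2`` (the inscribed sphere). ``tau``
    overrides the automatic percentile when given.
    """
    k = int(k)
    if k < 3 or k % 2 == 0:
        raise ValueError(f"kernel size must be an odd integer >= 3, got {k}")
    if radius is None:
        radius = k / 2.0
    if not 0 < radius <= k * np.sqrt(3) / 2:
        raise ValueError(f"radius {radius} outside (0, k*sqrt(3)/2]")
    h = k // 2
    ax = np.arange(-h, h + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = zz**2 + yy**2 + xx**2 <= radius**2 + 1e-12
    offsets = np.stack([zz[keep], yy[keep], xx[keep]], axis=1)
    if len(offsets) == 0:
        raise ValueError("radius excludes even the center voxel")
    if tau is None:
        tau = solve_tau(len(offsets))
    elif not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    return ScaleKernel(size=k, radius=float(radius), offsets=offsets, tau=float(tau))


@dataclass(frozen=True)
class TilingScheme:
    """Sparse placement of cubic normalization regions ``W_j``."""

    tile_edge: int
    grid_count: int
    tile_origins: np.ndarray = field(repr=False)

    @property
    def n_tiles(self) -> int:
        return len(self.tile_origins)

    @property
    def tile_voxels(self) -> int:
        return self.tile_edge**3

    def tile_centers(self) -> np.ndarray:
        return self.tile_origins + self.tile_edge // 2


def place_tiles(
    shape: tuple[int, int, int],
    tile_edge: int = DEFAULT_TILE_EDGE,
    grid_count: int = DEFAULT_GRID_COUNT,
) -> TilingScheme:
    """Evenly distribute ``grid_count**3`` tiles across the volume.

    Tile origins are spaced linearly from 0 to ``dim - tile_edge`` per
    dimension (rounded to voxels), so every tile lies fully inside the
    volume; tiles may overlap or leave gaps — the normalizer is a global
    maximum over tiles, so exhaustive coverage is not required.
    """
    shape = tuple(int(s) for s in shape)
    tile_edge = int(tile_edge)
    grid_count = int(grid_count)
    if grid_count < 1:
        raise ValueError(f"grid_count must be >= 1, got {grid_count}")
    if tile_edge < 1 or tile_edge > min(shape):
        raise ValueError(
            f"tile edge {tile_edge} does not fit inside volume of shape {shape}"
        )
    per_dim = [
        np.round(np.linspace(0, dim - tile_edge, grid_count)).astype(int)
        for dim in shape
    ]
    zz, yy, xx = np.meshgrid(*per_dim, indexing="ij")
    origins = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    return TilingScheme(tile_edge=tile_edge, grid_count=grid_count, tile_origins=origins)
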