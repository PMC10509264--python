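"""Synthetic density phantoms with known ground-truth local scale.

Phantoms are built from soft-sphere blobs (cosine-tapered edges) placed
in an empty box: each blob carries an amplitude, a true scale (the
occupancy the forward model applies), and an optional Gaussian blur
standing in for B-factor resolution loss. The noise-free ideal map is
degraded per the forward model ``F = F_ideal * S`` and zero-mean
Gaussian solvent noise is added, giving every estimator and modifier a
volume whose correct answer is known exactly.

Blobs deliberately replace atomic-model densities: they preserve the
piecewise-scale structure the estimator assumes while removing any
dependence on structure files. A region that should respond to blur
like atomic detail is modelled as a cluster of small blobs rather than
one large plateau (blur cannot lower the interior of a large constant
sphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kernels import ScaleKernel, TilingScheme
from .scale import estimate_local_scale
from .volume_io import VolumeGrid

__all__ = ["Blob", "PhantomSpec", "make_phantom", "apply_forward_model", "occupancy_sweep"]


@dataclass(frozen=True)
class Blob:
    """One soft-sphere component of a phantom.

    center : voxel coordinates (z, y, x)
    radius : Angstrom
    amplitude : gray-scale peak value
    true_scale : occupancy in [0, 1] the forward model applies
    blur_sigma : Gaussian blur in Angstrom applied to this blob's
        ideal density (resolution-loss proxy); 0 disables it
    """

    center: tuple[float, float, float]
    radius: float
    amplitude: float = 1.0
    true_scale: float = 1.0
    blur_sigma: float = 0.0

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"blob radius must be positive, got {self.radius}")
        if not 0.0 <= self.true_scale <= 1.0:
            raise ValueError(f"true scale must lie in [0, 1], got {self.true_scale}")
        if self.blur_sigma < 0:
            raise ValueError("blur sigma must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; deterministic given seed."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    blobs: tuple[Blob, ...] = field(default_factory=tuple)
    noise_sd: float = 0.0
    edge_width: float = 2.0  # cosine taper width, voxels
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "blobs", tuple(self.blobs))
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _soft_sphere(spec: PhantomSpec, blob: Blob) -> np.ndarray:
    """Unit-amplitude soft sphere: 1 inside, cosine taper over the edge."""
    r_vox = blob.radius / spec.voxel_size
    w = spec.edge_width
    grids = np.ogrid[tuple(slice(0, n) for n in spec.shape)]
    dist = np.sqrt(
        sum((g - c) ** 2 for g, c in zip(grids, blob.center))
    )
    inner = max(r_vox - w, 0.0)
    profile = np.zeros(spec.shape, dtype=np.float64)
    profile[dist <= inner] = 1.0
    taper = (dist > inner) & (dist < r_vox)
    if w > 0:
        profile[taper] = 0.5 * (1.0 + np.cos(np.pi * (dist[taper] - inner) / (r_vox - inner)))
    return profile


def make_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, np.ndarray, VolumeGrid]:
    """Build (observed F, true scale field, noise-free ideal map).

    ``F_ideal`` is the sum of the (optionally blurred) blob densities at
    full occupancy; the true scale field holds each blob's occupancy on
    its support and 0 in solvent; ``F`` multiplies the two voxelwise and
    adds N(0, noise_sd**2) solvent noise. Blur is applied to the ideal
    density before the scale multiplies it: occupancy degrades contrast,
    not resolution. Blobs whose supports overlap must agree on the true
    scale, otherwise the ground truth would be ambiguous.
    """
    for blob in spec.blobs:
        r_vox = blob.radius / spec.voxel_size
        for c, n in zip(blob.center, spec.shape):
            if c - r_vox < -0.5 or c + r_vox > n - 0.5:
                raise ValueError(f"blob at {blob.center} does not fit in {spec.shape}")

    ideal = np.zeros(spec.shape, dtype=np.float64)
    scaled = np.zeros(spec.shape, dtype=np.float64)
    true_scale = np.zeros(spec.shape, dtype=np.float64)
    claimed = np.zeros(spec.shape, dtype=bool)
    for blob in spec.blobs:
        density = blob.amplitude * _soft_sphere(spec, blob)
        if blob.blur_sigma > 0:
            density = ndimage.gaussian_filter(
                density, sigma=blob.blur_sigma / spec.voxel_size
            )
        support = density > 1e-6 * abs(blob.amplitude)
        conflict = claimed & support & (np.abs(true_scale - blob.true_scale) > 1e-9)
        if conflict.any():
            raise ValueError(
                "overlapping blobs disagree on true scale; ground truth ambiguous"
            )
        true_scale[support] = blob.true_scale
        claimed |= support
        ideal += density
        scaled += density * blob.true_scale

    rng = np.random.default_rng(spec.seed)
    observed = scaled
    if spec.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    f = VolumeGrid(observed.astype(np.float32), voxel_size=spec.voxel_size)
    f_ideal = VolumeGrid(ideal.astype(np.float32), voxel_size=spec.voxel_size)
    return f, true_scale, f_ideal


def apply_forward_model(f_ideal: VolumeGrid, s: np.ndarray) -> VolumeGrid:
    """Degrade an ideal map by a scale field: voxelwise ``F = F_ideal * S``."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape != f_ideal.shape:
        raise ValueError(f"scale shape {s.shape} != map shape {f_ideal.shape}")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scale values must lie in [0, 1]")
    return f_ideal.with_data(
        (np.asarray(f_ideal.data, dtype=np.float64) * s).astype(np.float32)
    )


def interior_mask(spec: PhantomSpec, blob: Blob, margin: float = 3.0) -> np.ndarray:
    """Boolean mask of voxels well inside a blob (margin in voxels)."""
    grids = np.ogrid[tuple(slice(0, n) for n in spec.shape)]
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, blob.center)))
    return dist <= blob.radius / spec.voxel_size - spec.edge_width - margin


def occupancy_sweep(
    base_spec: PhantomSpec,
    scales,
    kernel: ScaleKernel,
    tiling: TilingScheme | None = None,
    scaled_blob: int = 1,
    estimator=estimate_local_scale,
) -> list[dict]:
    """Estimate recovery across a sweep of true occupancies.

    For each value in ``scales`` the blob at index ``scaled_blob`` of
    ``base_spec`` is regenerated at that true scale (all other blobs
    unchanged) and the local scale estimated; the mean and sd of the
    estimate over the blob's interior voxels are recorded. Returns one
    dict per sweep point with keys ``true_scale``, ``mean_estimate``,
    ``sd_estimate``.
    """
    scales = list(scales)
    if any(not 0.0 <= s <= 1.0 for s in scales):
        raise ValueError("swept scales must lie in [0, 1]")
    rows = []
    for s_true in scales:
        blobs = list(base_spec.blobs)
        blobs[scaled_blob] = Blob(
            center=blobs[scaled_blob].center,
            radius=blobs[scaled_blob].radius,
            amplitude=blobs[scaled_blob].amplitude,
            true_scale=float(s_true),
            blur_sigma=blobs[scaled_blob].blur_sigma,
        )
        spec = PhantomSpec(
            shape=base_spec.shape,
            voxel_size=base_spec.voxel_size,
            blobs=tuple(blobs),
            noise_sd=base_spec.noise_sd,
            edge_width=base_spec.edge_width,
            seed=base_spec.seed,
        )
        f, _, _ = make_phantom(spec)
        est = estimator(f, kernel, tiling)
        region = interior_mask(spec, blobs[scaled_blob])
        vals = est.values[region]
        rows.append(
            {
                "true_scale": float(s_true),
                "mean_estimate": float(vals.mean()),
                "sd_estimate": float(vals.std()),
            }
        )
    return rows
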