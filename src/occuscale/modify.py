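"""Map modification by estimated local scale.

With the forward model ``F = F_ideal * S``, dividing by a power of the
estimated scale emulates a reconstruction from more homogeneous data:

* amplify:   ``F * S**(1/gamma - 1)``  (gamma -> inf recovers F_ideal)
* attenuate: ``F * S**(gamma - 1)``    (more heterogeneity than observed)
* sigmoid:   attenuates below a pivot scale mu and amplifies above it.

Amplification is inverse filtering and hence noise-sensitive, so
modified maps are multiplied by the solvent confidence (suppression) and
the original solvent background is added back (retention); attenuated
solvent-adjacent noise can additionally be compensated with synthetic
noise matching the input solvent's distribution and spectrum. The
scale ratio ``M = S_target / S`` is an optimal soft mask for particle
signal-subtraction workflows.
"""

from __future__ import annotations

import numpy as np

from .scale import ScaleMap, clamp
from .solvent import ConfidenceMap
from .volume_io import VolumeGrid

__all__ = [
    "amplify",
    "attenuate",
    "sigmoid_scale",
    "sigmoid_modify",
    "suppress_solvent",
    "retain_solvent",
    "solvent_power_spectrum",
    "synthesize_matched_noise",
    "compensate_attenuation_noise",
    "subtraction_mask",
    "EPS_SCALE",
]

#: Floor for S wherever it appears with a negative power; estimation noise
#: at near-zero scale is handled by confidence suppression, the floor only
#: guards the arithmetic.
EPS_SCALE = 1e-3


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if gamma < 1.0:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    return gamma


def _scale_values(s: ScaleMap | np.ndarray, shape=None) -> np.ndarray:
    values = s.values if isinstance(s, ScaleMap) else np.asarray(s)
    if shape is not None and values.shape != shape:
        raise ValueError(f"scale shape {values.shape} != map shape {shape}")
    return np.asarray(values, dtype=np.float64)


def amplify(grid: VolumeGrid, scale: ScaleMap, gamma: float) -> VolumeGrid:
    """Amplify partial occupancy: ``F * S**(1/gamma - 1)`` (gamma >= 1)."""
    gamma = _check_gamma(gamma)
    if gamma == 1.0:
        return grid.with_data(np.array(grid.data, copy=True))
    s = np.maximum(_scale_values(scale, grid.shape), EPS_SCALE)
    out = np.asarray(grid.data, dtype=np.float64) * s ** (1.0 / gamma - 1.0)
    return grid.with_data(out.astype(np.float32))


def attenuate(grid: VolumeGrid, scale: ScaleMap, gamma: float) -> VolumeGrid:
    """Attenuate partial occupancy: ``F * S**(gamma - 1)`` (gamma >= 1)."""
    gamma = _check_gamma(gamma)
    if gamma == 1.0:
        return grid.with_data(np.array(grid.data, copy=True))
    s = _scale_values(scale, grid.shape)
    out = np.asarray(grid.data, dtype=np.float64) * s ** (gamma - 1.0)
    return grid.with_data(out.astype(np.float32))


def sigmoid_scale(s, gamma: float, mu: float):
    """Logistic remapping of scale about the pivot ``mu``.

    The pivot is first shifted to ``mu_s = ((1-mu)/mu)**(1 - 1/gamma) + 1)**-1``
    so that 0, ``mu`` and 1 are exact fixed points for every ``gamma``;
    ``gamma = 1`` gives ``mu_s = 0.5`` and the identity map. Output lies
    in [0, 1] and is monotone non-decreasing in the input.
    """
    gamma = _check_gamma(gamma)
    if not 0.0 < mu < 1.0:
        raise ValueError(f"pivot mu must lie in (0, 1), got {mu}")
    s_arr = np.asarray(s, dtype=np.float64)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError("scale values must lie in [0, 1]")
    mu_s = 1.0 / (((1.0 - mu) / mu) ** (1.0 - 1.0 / gamma) + 1.0)
    num = s_arr * (1.0 - mu_s)
    den = mu_s * (1.0 - s_arr)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        odds = np.where(den > 0, num / den, np.inf)
        out = np.where(
            s_arr >= 1.0,
            1.0,
            np.where(odds > 0, 1.0 / (1.0 + odds ** -gamma), 0.0),
        )
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out)
    return out


def sigmoid_modify(
    grid: VolumeGrid, scale: ScaleMap, gamma: float, mu: float
) -> VolumeGrid:
    """Sigmoid modification ``F * S_{gamma,mu} / S``.

    Regions below the pivot scale are attenuated and regions above it
    amplified; at ``S = mu`` the map is unchanged.
    """
    gamma = _check_gamma(gamma)
    if gamma == 1.0:
        return grid.with_data(np.array(grid.data, copy=True))
    s = _scale_values(scale, grid.shape)
    s_mod = sigmoid_scale(np.clip(s, 0.0, 1.0), gamma, mu)
    out = (
        np.asarray(grid.data, dtype=np.float64)
        * s_mod
        / np.maximum(s, EPS_SCALE)
    )
    return grid.with_data(out.astype(np.float32))


def _check_conf(grid: VolumeGrid, conf: ConfidenceMap) -> np.ndarray:
    c = np.asarray(conf.values, dtype=np.float64)
    if c.shape != grid.shape:
        raise ValueError(f"confidence shape {c.shape} != map shape {grid.shape}")
    return c


def suppress_solvent(modified: VolumeGrid, conf: ConfidenceMap) -> VolumeGrid:
    """Soft-mask a modified map by the confidence: ``Q = F_mod * C``."""
    c = _check_conf(modified, conf)
    return modified.with_data(
        (np.asarray(modified.data, dtype=np.float64) * c).astype(np.float32)
    )


def retain_solvent(
    suppressed: VolumeGrid, original: VolumeGrid, conf: ConfidenceMap
) -> VolumeGrid:
    """Add back the original solvent background: ``R = Q + F * (1 - C)``."""
    if suppressed.shape != original.shape:
        raise ValueError("map shapes differ")
    c = _check_conf(original, conf)
    out = np.asarray(suppressed.data, dtype=np.float64) + np.asarray(
        original.data, dtype=np.float64
    ) * (1.0 - c)
    return original.with_data(out.astype(np.float32))


def _radial_power_spectrum(data: np.ndarray) -> np.ndarray:
    """Mean squared Fourier amplitude per integer-frequency shell."""
    ft = np.fft.fftn(data)
    power = np.abs(ft) ** 2 / data.size
    freqs = [np.fft.fftfreq(n) * n for n in data.shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    shell = np.rint(np.sqrt(fz**2 + fy**2 + fx**2)).astype(int)
    n_shells = shell.max() + 1
    sums = np.bincount(shell.ravel(), weights=power.ravel(), minlength=n_shells)
    counts = np.bincount(shell.ravel(), minlength=n_shells)
    return sums / np.maximum(counts, 1)


def solvent_power_spectrum(
    grid: VolumeGrid, conf: ConfidenceMap, threshold: float = 0.5
) -> tuple[np.ndarray, float, float]:
    """Radial power spectrum and moments of the solvent region.

    The map is centered on the solvent mean and masked to low-confidence
    voxels; the masked power is divided by the solvent volume fraction
    to correct for the missing support.
    """
    c = _check_conf(grid, conf)
    mask = c < threshold
    n_solvent = int(mask.sum())
    if n_solvent < 1000:
        raise ValueError(
            f"too few solvent voxels ({n_solvent}) to estimate a noise spectrum"
        )
    data = np.asarray(grid.data, dtype=np.float64)
    mean = float(data[mask].mean())
    sd = float(data[mask].std())
    fraction = n_solvent / data.size
    masked = np.where(mask, data - mean, 0.0)
    spectrum = _radial_power_spectrum(masked) / fraction
    return spectrum, mean, sd


def synthesize_matched_noise(
    grid: VolumeGrid, conf: ConfidenceMap, seed: int
) -> VolumeGrid:
    """Random field matching the input solvent's spectrum and moments.

    Random Fourier phases are drawn deterministically from ``seed`` and
    the per-shell amplitudes are set to the measured solvent amplitudes,
    so the radially averaged power spectrum matches by construction; the
    DC term restores the solvent mean.
    """
    spectrum, mean, sd = solvent_power_spectrum(grid, conf)
    shape = grid.shape
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    ft = np.fft.fftn(white)
    freqs = [np.fft.fftfreq(n) * n for n in shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    shell = np.rint(np.sqrt(fz**2 + fy**2 + fx**2)).astype(int)
    amplitude = np.sqrt(np.maximum(spectrum[shell] * white.size, 0.0))
    mags = np.abs(ft)
    phases = np.where(mags > 0, ft / np.maximum(mags, 1e-300), 1.0)
    colored = phases * amplitude
    colored[(0,) * len(shape)] = mean * white.size
    noise = np.fft.ifftn(colored).real
    return grid.with_data(noise.astype(np.float32))


def compensate_attenuation_noise(
    retained: VolumeGrid,
    noise: VolumeGrid,
    scale: ScaleMap,
    gamma: float,
    conf: ConfidenceMap,
) -> VolumeGrid:
    """Refill noise removed by attenuation: ``T = R + N * (S - S**gamma) * C``.

    ``S - S**gamma`` is exactly the amplitude the attenuation removed
    from unit-scale noise, so fully occupied regions (S = 1) and solvent
    (C ~ 0) receive nothing.
    """
    gamma = _check_gamma(gamma)
    if retained.shape != noise.shape:
        raise ValueError("map shapes differ")
    s = _scale_values(scale, retained.shape)
    c = _check_conf(retained, conf)
    out = np.asarray(retained.data, dtype=np.float64) + np.asarray(
        noise.data, dtype=np.float64
    ) * (s - s**gamma) * c
    return retained.with_data(out.astype(np.float32))


def subtraction_mask(
    scale: ScaleMap,
    target,
    tol: float = 1e-6,
    like: VolumeGrid | None = None,
) -> VolumeGrid:
    """Optimal particle signal-subtraction mask ``M = S_target / S``.

    ``target`` may be a ScaleMap, an array, or a scalar; it must not
    exceed the estimated scale anywhere (beyond ``tol``), since the mask
    can only attenuate. The result is clamped to [0, 1]. ``like``
    supplies voxel-size/origin metadata for the output grid.
    """
    s = _scale_values(scale)
    if np.isscalar(target):
        t = np.full_like(s, float(target))
    else:
        t = _scale_values(target, s.shape)
    excess = t - s
    meaningful = s > EPS_SCALE
    if np.any(excess[meaningful] > tol):
        raise ValueError(
            "target scale exceeds estimated scale; a subtraction mask "
            "can only attenuate (target <= S everywhere)"
        )
    m = clamp(t / np.maximum(s, EPS_SCALE), 0.0, 1.0).astype(np.float32)
    if like is not None:
        return like.with_data(m)
    return VolumeGrid(m)
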