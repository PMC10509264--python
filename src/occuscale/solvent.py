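"""Solvent noise model and per-voxel confidence.

Cryo-EM maps are mostly solvent, whose values form a dominant,
approximately Gaussian peak in the gray-value histogram. A Gaussian is
fitted to that peak (optionally excluding voxels covered by a
"solvent definition" mask over the non-solvent regions) and each voxel
is assigned a confidence in [0, 1]: the relative probability that its
value was drawn from map content rather than from the solvent model.
The confidence map is a soft solvent mask used to keep inverse-filter
amplification from blowing up noise; it never hard-segments the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .scale import ScaleMap
from .volume_io import VolumeGrid

__all__ = [
    "Histogram",
    "SolventModel",
    "ConfidenceMap",
    "build_histogram",
    "fit_solvent_model",
    "confidence_map",
    "primary_confidence_limit",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class Histogram:
    """Equal-width gray-value histogram of a reconstruction."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def delta(self) -> float:
        """Bin width in map gray-scale units."""
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SolventModel:
    """Gaussian fit to the dominant (solvent) histogram peak."""

    mean: float
    sd: float
    amplitude: float  # peak height in counts
    delta: float  # histogram bin width the fit was made at

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"solvent sd must be positive, got {self.sd}")
        if not self.delta > 0:
            raise ValueError(f"bin width must be positive, got {self.delta}")

    def pdf(self, x):
        return np.exp(-0.5 * ((np.asarray(x) - self.mean) / self.sd) ** 2) / (
            self.sd * np.sqrt(2.0 * np.pi)
        )


@dataclass
class ConfidenceMap:
    """Per-voxel probability-like confidence that a voxel is content."""

    values: np.ndarray
    model: SolventModel
    solvent_def_used: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("confidence map must be 3D")

    @property
    def shape(self):
        return self.values.shape


def build_histogram(grid: VolumeGrid, n_bins: int = DEFAULT_N_BINS) -> Histogram:
    """Histogram of all voxel values with equal-width bins over [min, max]."""
    if n_bins < 32:
        raise ValueError(f"n_bins must be >= 32, got {n_bins}")
    data = np.asarray(grid.data)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("constant volume has no histogram structure")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    return Histogram(edges=edges, counts=counts)


def _gauss(x, amp, mean, sd):
    return amp * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_solvent_model(
    grid: VolumeGrid,
    solvent_def: VolumeGrid | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[SolventModel, Histogram]:
    """Fit the Gaussian solvent model to the main histogram peak.

    The peak is located as the argmax of 3-bin-smoothed counts and the
    fit window extends outward to half-maximum on each side. When a
    solvent definition is supplied (a [0, 1] mask covering NON-solvent
    regions), voxels under it are excluded from the fitted counts — but
    the bin grid is still that of the full map, so the model's ``delta``
    matches the full-map histogram used for confidence.

    Returns the model together with the full-map histogram.
    """
    hist = build_histogram(grid, n_bins=n_bins)
    if solvent_def is not None:
        if solvent_def.shape != grid.shape:
            raise ValueError("solvent definition shape does not match map")
        solvent_def.validate_as_mask()
        keep = np.asarray(solvent_def.data) < 0.5
        if not keep.any():
            raise ValueError("solvent definition covers the entire map")
        fit_counts, _ = np.histogram(
            np.asarray(grid.data)[keep], bins=hist.edges
        )
    else:
        fit_counts = hist.counts

    smoothed = np.convolve(fit_counts, np.ones(3) / 3.0, mode="same")
    peak = int(np.argmax(smoothed))
    half = smoothed[peak] / 2.0
    lo = peak
    while lo > 0 and smoothed[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < len(smoothed) - 1 and smoothed[hi + 1] >= half:
        hi += 1
    lo, hi = max(lo - 1, 0), min(hi + 1, len(smoothed) - 1)
    x = hist.centers[lo : hi + 1]
    y = fit_counts[lo : hi + 1].astype(float)
    fwhm = max(hist.centers[hi] - hist.centers[lo], hist.delta)
    p0 = (float(fit_counts[peak]), float(hist.centers[peak]), fwhm / 2.355)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=p0, maxfev=10000,
            bounds=([0, -np.inf, hist.delta / 10.0], [np.inf, np.inf, np.inf]),
        )
        amp, mean, sd = (float(v) for v in popt)
    except (RuntimeError, ValueError) as exc:
        if hi - lo <= 4:
            # quasi-delta peak (e.g. noise-free synthetic solvent): the
            # least-squares problem is degenerate, fall back to moments
            w = y / max(y.sum(), 1.0)
            mean = float((w * x).sum())
            sd = float(np.sqrt(max((w * (x - mean) ** 2).sum(), 0.0)))
            sd = max(sd, hist.delta / 2.0)
            amp = float(fit_counts[peak])
        else:
            raise RuntimeError(
                "solvent model fit failed; consider supplying a solvent "
                "definition mask covering the non-solvent regions"
            ) from exc
    return SolventModel(mean=mean, sd=sd, amplitude=amp, delta=hist.delta), hist


def confidence_map(
    grid: VolumeGrid,
    model: SolventModel,
    hist: Histogram,
    solvent_def_used: bool = False,
) -> ConfidenceMap:
    """Per-voxel confidence from the content/solvent probability ratio.

    For each histogram bin the ratio of the empirical probability of the
    bin (from the full map) to the solvent-model probability of the same
    bin is computed; the ratio is mapped into [0, 1] via
    ``clamp((ratio - 1) / ratio, 0, 1)`` — a value explained by the
    solvent model (ratio <= 1) gets confidence 0, a value the model
    cannot explain (ratio >> 1) gets confidence -> 1. Above the solvent
    mean the per-bin confidence is made monotone non-decreasing by a
    running maximum, so sparsely populated high-value bins cannot dip.
    """
    if abs(hist.delta - model.delta) > 1e-6 * max(model.delta, 1e-30):
        raise ValueError("histogram bin width does not match the fitted model")
    p_emp = hist.counts / max(hist.n_total, 1)
    p_model = model.pdf(hist.centers) * hist.delta
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_model > 0, p_emp / np.maximum(p_model, 1e-300), np.inf)
        ratio = np.where(p_emp == 0, 0.0, ratio)
        conf_bin = np.where(np.isfinite(ratio), (ratio - 1.0) / np.maximum(ratio, 1e-30), 1.0)
    conf_bin = np.clip(conf_bin, 0.0, 1.0)
    above = hist.centers > model.mean
    conf_bin[above] = np.maximum.accumulate(conf_bin[above])

    data = np.asarray(grid.data)
    idx = np.clip(
        np.digitize(data, hist.edges) - 1, 0, len(hist.counts) - 1
    )
    return ConfidenceMap(
        values=conf_bin[idx].astype(np.float32),
        model=model,
        solvent_def_used=solvent_def_used,
    )


def primary_confidence_limit(
    scale: ScaleMap,
    conf: ConfidenceMap,
    bin_width: float = 0.02,
    min_voxels: int = 10,
) -> float:
    """Scale value below which voxels are no more credible than noise.

    Voxels are binned by their estimated scale and scanned in ascending
    order; S_p is the center of the last low-confidence bin (median
    confidence < 0.5) before the first confident bin — the scale at
    which confidence crosses 0.5. The scan stops at the crossing because
    the max filter dilates the scale field beyond the content it
    measured, leaving a halo of high-scale solvent voxels that would
    otherwise dominate the high-scale bins. Returns 0 when even the
    lowest-scale voxels are confident, and the highest populated bin
    when no bin is (an all-noise map). Bins with fewer than
    ``min_voxels`` voxels are skipped with a warning.
    """
    if scale.shape != conf.shape:
        raise ValueError("scale and confidence shapes differ")
    s = np.asarray(scale.values).ravel()
    c = np.asarray(conf.values).ravel()
    n_bins = max(int(round(1.0 / bin_width)), 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    s_p = 0.0
    skipped = 0
    order = np.argsort(idx, kind="stable")
    bounds = np.searchsorted(idx[order], np.arange(n_bins + 1))
    for b in range(n_bins):
        sel = order[bounds[b] : bounds[b + 1]]
        if len(sel) == 0:
            continue
        if len(sel) < min_voxels:
            skipped += 1
            continue
        if float(np.median(c[sel])) < 0.5:
            s_p = 0.5 * (edges[b] + edges[b + 1])
        else:
            break
    if skipped:
        warnings.warn(
            f"{skipped} sparsely populated scale bins skipped when "
            "determining the primary confidence limit",
            stacklevel=2,
        )
    return float(s_p)
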