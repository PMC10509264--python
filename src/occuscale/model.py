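"""Model/Results interface over the local-scale pipeline.

:class:`LocalScaleModel` is constructed from a reconstruction plus the
estimation parameters (kernel, tiling, percentile, low-pass cutoff);
``fit()`` runs scale estimation, solvent-model fitting, confidence
computation and (optionally) noise-level recalibration, returning a
:class:`LocalScaleResults` that carries the estimates and diagnostics
and exposes the modification operators.

    >>> model = LocalScaleModel(volume, mode="occupancy")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> amplified = res.amplify(gamma=4)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import modify as _modify
from .kernels import (
    DEFAULT_GRID_COUNT,
    DEFAULT_TILE_EDGE,
    ScaleKernel,
    TilingScheme,
    build_spherical_kernel,
    kernel_size_from_resolution,
    place_tiles,
)
from .scale import (
    DEFAULT_LOWPASS_A,
    ScaleMap,
    estimate_local_scale,
    lowpass,
    recalibrate_zero_point,
    targeted_scale_estimate,
)
from .solvent import (
    ConfidenceMap,
    Histogram,
    SolventModel,
    confidence_map,
    fit_solvent_model,
    primary_confidence_limit,
)
from .volume_io import VolumeGrid, read_volume

__all__ = ["LocalScaleModel", "LocalScaleResults"]


class LocalScaleModel:
    """Local-scale estimation model for a cryo-EM reconstruction.

    Parameters
    ----------
    volume : VolumeGrid
        Input reconstruction.
    mode : {"occupancy", "plain"}
        Occupancy mode estimates from a low-pass-filtered copy so that
        the remaining contrast attenuation reflects composition; plain
        mode estimates directly and also responds to resolution
        differences.
    lowpass_cutoff : float, optional
        Occupancy-mode cutoff in Angstrom (default 6 A when the map
        resolution is unknown).
    kernel_size, kernel_radius, tau : optional
        Max-filter kernel overrides; by default the kernel size is
        matched to the low-pass cutoff (occupancy mode) or set to 5
        voxels, with the inscribed-sphere radius and the automatic
        percentile for its sample count.
    tile_edge, grid_count : int
        Normalization tiling (defaults 12 and 20).
    solvent_def : VolumeGrid, optional
        Mask covering NON-solvent regions, excluded from the solvent
        fit only.
    target_mask : VolumeGrid, optional
        Restrict the full-scale normalizer to tiles centered in this
        mask (dedicated-tau targeted estimate).
    recalibrate : bool
        Shift the scale zero-point to the primary confidence limit.
    """

    def __init__(
        self,
        volume: VolumeGrid,
        mode: str = "occupancy",
        lowpass_cutoff: float | None = None,
        kernel_size: int | None = None,
        kernel_radius: float | None = None,
        tau: float | None = None,
        tile_edge: int = DEFAULT_TILE_EDGE,
        grid_count: int = DEFAULT_GRID_COUNT,
        solvent_def: VolumeGrid | None = None,
        target_mask: VolumeGrid | None = None,
        recalibrate: bool = False,
    ) -> None:
        if mode not in ("occupancy", "plain"):
            raise ValueError(f"mode must be 'occupancy' or 'plain', got {mode!r}")
        self.volume = volume
        self.mode = mode
        self.lowpass_cutoff = (
            float(lowpass_cutoff)
            if lowpass_cutoff is not None
            else (DEFAULT_LOWPASS_A if mode == "occupancy" else None)
        )
        if kernel_size is None:
            if self.lowpass_cutoff is not None:
                kernel_size = kernel_size_from_resolution(
                    self.lowpass_cutoff, volume.voxel_size
                )
            else:
                kernel_size = 5
        self.kernel: ScaleKernel = build_spherical_kernel(
            kernel_size, radius=kernel_radius, tau=tau
        )
        self.tiling: TilingScheme = place_tiles(
            volume.shape, tile_edge=tile_edge, grid_count=grid_count
        )
        self.solvent_def = solvent_def
        self.target_mask = target_mask
        self.recalibrate = recalibrate

    @classmethod
    def from_file(cls, path, **kwargs) -> "LocalScaleModel":
        """Construct from an MRC/CCP4 map on disk."""
        return cls(read_volume(path), **kwargs)

    def fit(self) -> "LocalScaleResults":
        """Run the estimation pipeline and return the results object."""
        volume = self.volume
        estimation_input = volume
        if self.mode == "occupancy":
            estimation_input = lowpass(volume, self.lowpass_cutoff)
        if self.target_mask is not None:
            scale = targeted_scale_estimate(
                estimation_input, self.target_mask, self.kernel, self.tiling
            )
        else:
            scale = estimate_local_scale(
                estimation_input, self.kernel, self.tiling
            )
        scale.mode = self.mode
        scale.lowpass_cutoff = self.lowpass_cutoff

        solvent_model, hist = fit_solvent_model(volume, self.solvent_def)
        conf = confidence_map(
            volume, solvent_model, hist,
            solvent_def_used=self.solvent_def is not None,
        )
        s_p = primary_confidence_limit(scale, conf)
        if self.recalibrate:
            scale = recalibrate_zero_point(scale, s_p)
        return LocalScaleResults(
            model=self,
            scale=scale,
            solvent=solvent_model,
            histogram=hist,
            confidence=conf,
            s_p=s_p,
        )


@dataclass
class LocalScaleResults:
    """Fitted local-scale estimate, solvent model and diagnostics."""

    model: LocalScaleModel
    scale: ScaleMap
    solvent: SolventModel
    histogram: Histogram
    confidence: ConfidenceMap
    s_p: float
    _extras: dict[str, Any] = field(default_factory=dict, repr=False)

    # -- diagnostics -------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        m = self.model
        s = self.scale
        vals = s.values
        lines = [
            "Local scale estimation results",
            "==============================",
            f"map shape:            {m.volume.shape}",
            f"voxel size:           {m.volume.voxel_size:.4g} A",
            f"mode:                 {s.mode}",
            f"low-pass cutoff:      "
            + (f"{s.lowpass_cutoff:.4g} A" if s.lowpass_cutoff else "none"),
            f"kernel size / radius: {m.kernel.size} / {m.kernel.radius:.3g} voxels",
            f"kernel samples n_V:   {m.kernel.n_v}",
            f"percentile tau:       {s.tau_used:.6f}",
            f"normalizer:           {s.normalizer:.6g}",
            f"tiles:                {m.tiling.n_tiles} of {m.tiling.tile_edge}^3 voxels",
            f"scale range:          [{vals.min():.3f}, {vals.max():.3f}]",
            f"solvent model:        mean {self.solvent.mean:.4g}, "
            f"sd {self.solvent.sd:.4g} (bin width {self.solvent.delta:.4g})",
            f"confidence limit S_p: {self.s_p:.3f}"
            + ("  (recalibrated)" if s.recalibrated else ""),
        ]
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serializable run report."""
        m = self.model
        return {
            "mode": self.scale.mode,
            "kernel": {
                "size": m.kernel.size,
                "radius": m.kernel.radius,
                "n_v": m.kernel.n_v,
            },
            "tau": self.scale.tau_used,
            "tiling": {
                "tile_edge": m.tiling.tile_edge,
                "grid_count": m.tiling.grid_count,
                "n_tiles": m.tiling.n_tiles,
            },
            "lowpass_cutoff": self.scale.lowpass_cutoff,
            "normalizer": self.scale.normalizer,
            "solvent": {
                "mean": self.solvent.mean,
                "sd": self.solvent.sd,
                "amplitude": self.solvent.amplitude,
                "delta": self.solvent.delta,
            },
            "s_p": self.s_p,
            "recalibrated": self.scale.recalibrated,
            "voxel_size": m.volume.voxel_size,
            "shape": list(m.volume.shape),
        }

    # -- modification ------------------------------------------------

    def _finish(
        self, modified: VolumeGrid, suppress: bool, retain: bool
    ) -> VolumeGrid:
        if suppress:
            modified = _modify.suppress_solvent(modified, self.confidence)
            if retain:
                modified = _modify.retain_solvent(
                    modified, self.model.volume, self.confidence
                )
        return modified

    def amplify(
        self, gamma: float, suppress_solvent: bool = True, retain_solvent: bool = True
    ) -> VolumeGrid:
        """Amplified map; solvent is suppressed and retained by default
        so that noise is never amplified."""
        out = _modify.amplify(self.model.volume, self.scale, gamma)
        return self._finish(out, suppress_solvent, retain_solvent)

    def attenuate(
        self,
        gamma: float,
        suppress_solvent: bool = True,
        retain_solvent: bool = True,
        compensate_noise: bool = False,
        seed: int = 0,
    ) -> VolumeGrid:
        """Attenuated map; optionally refills the noise the attenuation
        removed with synthetic solvent-matched noise."""
        out = _modify.attenuate(self.model.volume, self.scale, gamma)
        out = self._finish(out, suppress_solvent, retain_solvent)
        if compensate_noise and gamma > 1.0:
            noise = _modify.synthesize_matched_noise(
                self.model.volume, self.confidence, seed
            )
            out = _modify.compensate_attenuation_noise(
                out, noise, self.scale, gamma, self.confidence
            )
        return out

    def sigmoid(
        self,
        gamma: float,
        mu: float,
        suppress_solvent: bool = True,
        retain_solvent: bool = True,
    ) -> VolumeGrid:
        """Sigmoid-modified map about pivot scale ``mu``."""
        out = _modify.sigmoid_modify(self.model.volume, self.scale, gamma, mu)
        return self._finish(out, suppress_solvent, retain_solvent)

    def subtraction_mask(self, target) -> VolumeGrid:
        """Signal-subtraction mask toward a target scale (scalar, array,
        or ScaleMap); sigmoid-derived targets are first capped at the
        estimated scale so values above the pivot remain unmodified."""
        t = target.values if isinstance(target, ScaleMap) else np.asarray(target)
        t = np.minimum(t, self.scale.values)
        return _modify.subtraction_mask(self.scale, t, like=self.model.volume)
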