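# Methods

## Model

A single-particle cryo-EM reconstruction `F` is treated as an ideal,
compositionally homogeneous map `F_ideal` degraded voxelwise by a
multiplicative local scale:

    F = F_ideal · S,    S_i ∈ [0, 1]

`S` absorbs every source of local contrast loss — partial occupancy,
flexibility, misalignment. The estimator makes no assumption about the
intensity distribution of the map; it assumes only that

1. **some region of the map is at full scale** — a normalization tile
   exists whose intensity distribution represents homogeneous signal;
2. **the solvent background is zero-mean** — images were conventionally
   background-normalized, so zero density defines zero scale;
3. for the occupancy interpretation, **resolution is locally
   homogeneous** (or has been equalized, see occupancy mode).

### The estimator

    Ŝ_i = clamp( max_{V_i}(F) / max_j per_τ(F | W_j), 0, 1 )

* The numerator is a windowed max-value filter over a spherical voxel
  neighborhood `V_i`. The maximum measures the upper edge of the local
  intensity distribution, which scales with signal strength; it is
  cheap, robust to solvent inclusion, and preserves sharp boundaries
  (it is a grayscale dilation).
* The denominator is the full-scale reference: over a sparse set of
  cubic tiles `W_j`, the largest τ-percentile of the voxel values in a
  tile. A percentile rather than a maximum makes the reference robust
  to single high-mass atoms; the max over tiles makes it global, so the
  tiles need not cover the volume.
* Clamping is required because the max over `V_i` can exceed the τ-th
  percentile of the strongest tile.

### The automatic percentile τ_n

With `n = n_V` samples in the kernel, the estimate over-shoots by at
most `1 − τ` (the percentile's headroom), and under-shoots when the
kernel is unlikely to have sampled up to the τ-quantile. Setting the
percentile where the CDF of the n-sample maximum equals the survival
function of one sample, `G(x)^n = 1 − G(x)`, balances the two. The
quantile level is therefore the unique positive root of

    x^n + x − 1 = 0

independent of the distribution of the map values (distribution enters
only through the empirical quantile). The root is found by bisection on
(0, 1) — the polynomial is strictly increasing there with a guaranteed
sign change — to 1e-9. τ₁ = 0.5 exactly, τ₁₉ ≈ 0.8902, and τ_n ≥ 0.9
from n = 27 on. The derivation assumes voxels in the kernel are
independent; low-pass filtering correlates them, which lowers the
effective sample count and argues for a smaller τ.
`calibrate_tau_effective` measures that correction empirically on
phantoms with known ground truth by a grid search over τ ∈ (0.5, τ_n]
at true scale 0.5; ties resolve to the largest τ (least correction), so
uncorrelated input returns τ_n.

### Occupancy mode

Contrast loss from resolution variation (B-factor blur) and from
occupancy are indistinguishable in a single voxel. Occupancy mode
low-pass filters the map (raised-cosine edge, default cutoff 6 Å) and
estimates `S` from the filtered copy: the filter attenuates
resolution-dependent contrast by the same factor everywhere — including
in the normalization tiles — so the surviving differences reflect
composition. The cost is delocalization: filtering spreads density
outside the kernel window, which biases the estimate slightly downward
on sharp input. Occupancy mode therefore trades a small systematic
under-estimate for insensitivity to blur; on phantoms with equal
occupancy and blur sigmas of 0 vs 2 voxels, the between-region
difference shrinks more than threefold.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| kernel size `k` | smallest odd > 2r/d (5 if no cutoff) | voxels | max-filter window edge; clamped at ≥ 3 |
| kernel radius | k/2 | voxels | spherical neighborhood radius (inscribed sphere) |
| τ | root of x^n+x−1 | — | normalizer percentile; override to trade over/under-estimation |
| tile edge | 12 | voxels | granularity of the full-scale reference: smaller lets local mass define full scale, larger averages it away |
| tile grid | 20 per dim | — | 8000 tiles; sparse, coverage not required |
| low-pass cutoff | 6 | Å | occupancy-mode equalizer; larger cutoff = stronger filtering |
| γ | ≥ 1 | — | modification power; 1 = identity, ∞ → full homogenization |
| μ | (0, 1) | scale | sigmoid pivot; scale value left unmodified |
| n_bins | 256 | — | solvent histogram resolution (δ small vs solvent sd) |

The (5, 2.5) kernel default reflects the common case of maps sampled
near their resolution limit; a (3, 1.6) kernel (n_V = 19) trades
granularity for noise sensitivity and must be requested explicitly.

## Solvent model and confidence

The map histogram (256 equal-width bins over [min, max]) is dominated
by the solvent peak in realistic maps. A Gaussian is least-squares
fitted to the peak, located as the argmax of 3-bin-smoothed counts and
windowed to half-maximum on each side. When the fit window is
quasi-degenerate (a near-delta peak, as in noise-free synthetic maps)
the fit falls back to moment estimates with the sd floored at half a
bin. If signal occupies a large fraction of the box the solvent sd is
over-estimated; a *solvent definition* — a [0, 1] mask covering
non-solvent regions — excludes those voxels from the fitted counts
only. It never clips the confidence map or the outputs.

Confidence per histogram bin is the ratio of the empirical bin
probability to the solvent-model bin probability, mapped to [0, 1] as
`clamp((ratio − 1)/ratio, 0, 1)`: ratio ≤ 1 (fully explained by
solvent) gives 0, ratio ≫ 1 gives → 1. The mapping is a declared
convention — the ratio itself is unbounded and no canonical
normalization exists. Above the solvent mean the per-bin confidence is
made monotone by a running maximum so sparsely populated bins cannot
dip.

The **primary confidence limit** S_p is the scale at which confidence
crosses 0.5: voxels are binned by estimated scale (bin width 0.02,
bins under 10 voxels skipped with a warning) and scanned in ascending
order; S_p is the last bin with median confidence below 0.5 before the
first confident bin. The scan stops at the crossing deliberately: the
max filter dilates the scale field ~one kernel radius beyond the
content that produced it, leaving a halo of high-scale voxels whose
*values* are solvent; a global "largest unconfident bin" rule would be
dominated by that halo. Noise-level recalibration
`S′ = (S − S_p)/(1 − S_p)` (clamped after shifting) is **off by
default**: at low SNR it risks under-estimating occupancy, and the
zero-mean background assumption already anchors the zero point.

## Modification

With `S` estimated, `F̂_ideal = F/S` (inverse filtering). Amplification
`F·S^(1/γ−1)` and attenuation `F·S^(γ−1)` interpolate between the map
and its homogenized/suppressed versions; γ = 1 is the exact identity on
every path. The sigmoid modification remaps the scale through a
logistic curve whose shifted pivot `μ_s = (((1−μ)/μ)^(1−1/γ) + 1)^{-1}`
makes {0, μ, 1} exact fixed points, then applies `F·S_{γ,μ}/S`.

Inverse filtering is noise-sensitive, so modified maps are multiplied
by the confidence (`Q = F_mod·C`) and the original solvent is added
back (`R = Q + F·(1−C)`) by default; the scale is floored at 1e-3
wherever it appears with a negative power — the floor guards the
arithmetic, the confidence does the actual suppression. Attenuation
removes noise along with signal in partially occupied regions;
`T = R + N·(S − S^γ)·C` refills exactly the removed amplitude with
synthetic noise `N` whose radial power spectrum per shell is set to the
measured solvent spectrum (random phases from the seed, per-shell
amplitudes deterministic, DC restoring the solvent mean; masked-power
estimates are corrected by the solvent volume fraction). Noise
compensation is defined for attenuation only and is off by default for
sigmoid outputs.

A subtraction mask `M = S_target/S` (clamped to [0, 1]) converts any
strictly attenuating target — a constant, `S^γ`, or a sigmoid-remapped
scale capped at `S` so values above the pivot stay unmodified — into a
soft mask for particle signal-subtraction pipelines. Targets exceeding
the estimated scale are rejected: a mask cannot amplify.

## Synthetic phantoms

`make_phantom` builds volumes from soft-sphere blobs (cosine-tapered
edges, default 2-voxel taper) with per-blob amplitude, occupancy
(`true_scale`), and Gaussian blur standing in for B-factor resolution
loss. Blur is applied to the ideal density *before* the occupancy
multiplies it — occupancy reduces contrast, not resolution. Solvent
noise is zero-mean Gaussian, generated from the spec's seed. The
generator emulates: piecewise-constant occupancy, resolution loss, and
additive background noise.

It does **not** emulate atomic scattering structure, CTF effects,
Fourier-space correlations of real reconstruction noise, masking
artifacts from upstream classification, or gray-value distributions of
heavy atoms. A green recovery test therefore establishes that the
estimator is correct under the forward model it assumes — not that
every real map satisfies those assumptions (maps with strong
flexibility, detergent micelles, or heavy-atom clusters are exactly the
documented hard cases).

Regions that should respond to blur like atomic detail are modelled as
a plateau body carrying small-radius bumps: blurring a large constant
sphere leaves its interior untouched, so an isolated-sphere phantom
cannot express B-factor contrast loss at all.

## Numerical choices

* Percentiles: linear interpolation between order statistics
  (`numpy.percentile` default), pinned so sort-based oracles agree
  exactly.
* Max-filter boundaries: edge replication, so border voxels are not
  deflated by out-of-volume zeros.
* Low-pass filter: sharp cutoff with a raised-cosine roll-off of 2
  Fourier voxels; a hard edge would ring and the max filter would pick
  the ringing up. The cutoff is in Å: *larger cutoffs filter more*.
  Mean (DC) is preserved; cutoffs below Nyquist (2·voxel) are errors.
* Recalibration clamps after shifting (the raw formula maps S < S_p
  negative).
* Tiling anchors tiles at evenly spaced, clamped origins so every tile
  is fully interior; tiles may overlap or leave gaps — only the max
  over tiles matters.
* MRC I/O normalizes the header axis order (mapc/mapr/maps) to a fixed
  internal Z, Y, X convention on read; anisotropic voxel sizes beyond
  1% are averaged with a warning. Data is written as float32, mode 2.
* Degenerate inputs: constant volumes are rejected by the histogram
  (no structure to fit); all-negative maps are rejected by the
  normalizer ("no full-scale region"); NaN/Inf voxels are refused at
  write time.

## Known limitations

* Flexibility and misalignment reduce local scale; occupancy mode only
  partially neutralizes them, and amplification of such regions
  exaggerates mass. The estimate is a measure of contrast, and only of
  occupancy when its assumptions hold.
* The max-value filter rides the upper noise envelope: noise biases the
  estimate upward, by roughly the expected maximum of n_V noise samples
  over the normalizer — compact kernels are markedly less sensitive.
* Full scale is relative: a region dominated by heavy atoms, or a
  normalization tile too small to average over local mass, shifts the
  reference. The tile size is the instrument for controlling this.
* S_p and the confidence map inherit the scale field's dilation halo;
  recalibration should be combined with a solvent definition in
  high-noise settings.
* Only isotropic voxels and single-volume inputs are supported; no
  half-map merging, no particle-image operations.
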