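# Methods

## The measurement model

A confocal AO-SLO mosaic image of the parafoveal retina is modeled as

    I(x) = B + Σ_k A_k · exp(−|x − c_k|² / 2σ_k²) + ε,

a constant background B plus one isotropic Gaussian bright spot per cone
(center c_k, profile width σ_k, peak amplitude A_k) and additive Gaussian
read noise ε. The quantity of interest is the per-spot physical diameter

    d_k = 2√2 · σ_k · p   [μm],

where p is the pixel scale in μm/px. 2√2·σ is the full width of a Gaussian
at 1/e of its peak, so d is a well-defined optical size readout (the
reflectance profile of the cone outer segment), not an anatomical inner
segment diameter. A spot with d ≥ 6.0 μm is classed as *enlarged*; the
comparison is closed (≥). At the default pixel scale of 0.85 μm/px the
threshold corresponds to σ = 6.0/(2√2·0.85) ≈ 2.496 px.

## Scale selection

σ_k is estimated by automatic scale selection. The scale-normalized
Laplacian of Gaussian

    R(x, σ) = −σ² ∇²(G_σ * I)(x)

(γ = 1 normalization, sign chosen so bright blobs give positive peaks) has,
for a Gaussian spot of width σ₀ and amplitude A, the closed-form center
response

    R(σ) = 2A σ² σ₀² / (σ₀² + σ²)²,

which is maximized exactly at σ = σ₀ with value A/2. This closed form is
the oracle for the sizing tests: recovered σ_max is within 1.5% of truth
and the extremal response within 0.1% of A/2 across σ₀ ∈ [1, 4] px on
noise-free blobs.

Implementation choices:

- **Scale grid**: geometric, 0.8–6.0 px in 25 levels. At 0.85 μm/px this
  spans diameters 1.9–14.4 μm, bracketing both the healthy band and the
  enlarged class with margin. The geometric spacing makes the grid uniform
  in log σ, so a parabolic fit through the extremal level and its two
  neighbors (in log σ) removes the ~8.8% grid quantization; residual scale
  error is well under the 5% tolerance the tests assert.
- **Spatial tolerance**: the response at each scale is read as the maximum
  within a 1 px Chebyshev window around the labeled cone, absorbing
  sub-pixel labeling offsets.
- **Degenerate profiles** return flags, not fabricated values: `grid_edge`
  when the argmax sits on the first/last level (spot smaller/larger than
  the grid), `no_extremum` when the profile is monotone. Flagged
  measurements are retained but excluded from downstream statistics.
- **Multiple interior extrema**: the largest response wins; exact ties go
  to the smaller σ (the conservative size claim, and deterministic).
- **Border margin**: ceil(3·σ_grid_max) = 18 px, full kernel support at the
  largest scale; cones inside the margin are flagged `border`.
- The image mean is subtracted before filtering. The Laplacian annihilates
  constants analytically; demeaning also suppresses the small DC artifact
  of the truncated discrete kernel.

### Resolving limit at dense packing

The LoG response at one cone includes the (negative) side lobes of its
neighbors. Quantitatively, a hexagonal ring of normal spots at
center-to-center distance 8 px deflates the measured σ of a σ = 2.9 px
(8.2 px wide) spot by ~35%, pushing enlarged spots below the 6 μm
threshold; at 12 px the deflation is ~9% and the two size classes separate
cleanly. This is a property of the estimator itself at that packing
density, not of the implementation — the enlarged class is simply below
the method's resolving limit when spot diameter ≈ spacing.

## Cone labeling

Detection mirrors the classic low-pass + local-maximum recipe for AO-SLO
mosaics: a frequency-domain Gaussian low-pass with half-power at
1/cutoff_period (smooth, ringing-free, mean-preserving), followed by local
maxima accepted greedily in descending filtered intensity under a minimum
separation, with 3×3 quadratic sub-pixel refinement. The cutoff period is
tied to the expected cone spacing at the imaged eccentricity
(period = spacing/2: passes the mosaic's fundamental spatial frequency,
suppresses super-Nyquist noise). Spacing comes from a small monotone
lookup (3.0 μm at the fovea to 11.0 μm at 3 mm; 7.0 μm at the 1.0 mm
study eccentricity), linearly interpolated and clamped with a warning
outside the table — the lookup is configurable because published spacing
values vary by study and subject. The peak threshold is relative to the
robust (1st–99th percentile) intensity range, default 0.1. All acceptance
decisions are made on the refined coordinates, so the pairwise
min-distance invariant holds exactly on every output; exact intensity
ties break by scan order for determinism. Manual edits apply removals
first (nearest match within 2 px), then additions, which must respect the
min-distance against surviving points.

## Frame processing

Registration is translation-only phase correlation (cross-power-spectrum
peak), integer precision by default with optional ×4 Fourier-upsampled
refinement. Translation dominates inter-frame motion at this field size
(340 μm); non-rigid strip distortion is out of scope. Confidence is the
ratio of the correlation peak to the largest secondary peak outside an
11×11 exclusion window; a ratio below 3 flags low confidence (warn and
proceed; the flag propagates into measurement QC). Averaging compensates
each frame by its estimated shift and averages over the common overlap,
cropping rather than padding so border pixels are true means. The mean is
computed as `base + mean(frame_i − base)`, which is exact for identical
frames and avoids accumulation error. Whether real acquisitions should be
registered before averaging is exposed as a flag (`--no-register`), since
acquisition software may already have done so.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes; it
defines the conditions under which the pipeline is validated.

- **Geometry**: jittered hexagonal lattice (row pitch s·√3/2, alternate
  rows offset s/2), positional jitter sd 0.4 px, 3% random site dropout.
  Default spacing 12 px (10.2 μm). No published spacing accompanies the
  study conditions; the default is chosen so that both size classes lie
  within the scale-selection method's resolving limit (see above) while
  remaining plausible for a parafoveal mosaic with reduced density.
- **Size classes**: normal σ ~ N(1.75, 0.12) px truncated at 3 sd —
  >99% of true diameters in the 3.5–5.0 μm band at 0.85 μm/px — and an
  enlarged class σ ~ N(2.9, 0.25) px. The control profile draws 0.5% of
  sites from the enlarged class, the RP profile 5%. The truth `enlarged`
  flag is recomputed from σ and pixel scale, never stored as class
  membership: ~5% of enlarged-class draws fall below the 6.0 μm threshold,
  so the truth share is slightly below the mixture fraction.
- **Rendering**: spots are evaluated analytically on ±4σ windows, giving
  exact sub-pixel placement with no supersampling. Amplitudes are
  N(100, 15), background 10, per-frame iid Gaussian noise sd 5 (5% of
  amplitude), clipped at zero.
- **Acquisition**: 32 frames per region; global rigid translations
  N(0, 1.5 px) quantized to 0.25 px (frame 0 is the unshifted reference,
  and truth coordinates are frame-0 coordinates). `generate_mosaic`
  shortcuts the stack by rendering the expectation image with residual
  noise sd noise_sd/√n_frames.
- **Reproducibility**: one seed fans out to five independent substreams
  (lattice, size classes, amplitudes, shifts, noise), so each stochastic
  component is reproducible on its own and `generate_region` is
  bit-reproducible.
- **Storage**: frames are written as 16-bit TIFF/PNG after min-max scaling
  with the affine recorded in the JSON sidecar, so float intensities
  round-trip to within one quantization step.

What the generator does **not** emulate: optical residuals of the AO loop
(speckle, anisoplanatism), rod intrusion, torsional eye motion, non-rigid
intra-frame distortion, reflectance flicker between frames, or spatial
correlation between enlargement and dropout. Tests passing on synthetic
mosaics therefore validate the measurement chain under the stated model,
not the full physics of patient imaging.

## Cohort statistics

Diameters of QC-passing spots are pooled per eye across the four imaged
regions; a pooled count below 500 raises a QC warning. Size histograms use
0.5 μm bins over 2.0–9.0 μm (resolving the 3.5–5.0 band and placing the
6.0 threshold on a bin edge), with out-of-range values counted in the end
bins so percentages always sum to 100. Group comparison of per-eye
enlarged percentages uses Welch's t by default (Student as an option) —
with unequal group sizes and no variance-homogeneity guarantee, Welch is
the safer default. χ² on 2×2 frequency tables is Pearson without
continuity correction by default (Yates behind a flag). Multi-group
comparisons use one-way ANOVA followed by Tukey–Kramer: the studentized
range statistic q = |Δmean| / √(MSE/2·(1/nᵢ+1/nⱼ)) referred to the
studentized-range distribution with N−k df, which reduces to Tukey's HSD
for equal group sizes (verified against statsmodels to 1e-10) and matches
scipy's unequal-n implementation. Summary sds use the sample (n−1)
convention. Stored values are never rounded; one-decimal rounding happens
only in report rendering.

The bundled ten-case reference cohort ships as a plain CSV
(`data/rp_cohort.csv`) with per-case metadata (age, sex, inheritance mode,
axial length, visual acuity, perimetry indices, ellipsoid-zone status) and
the per-case enlarged-spot percentage; it drives the worked examples and
the exact-value tests (mean 5.26 → 5.3 at one decimal, minimum 0.5,
maximum 5.7 among intact-EZ cases).

### Validation oracles and problem sizes

- The t-test implementations are checked against an independent
  permutation oracle. For tiny samples the oracle enumerates all label
  assignments exactly; agreement between Welch p and permutation p is
  asserted only on well-behaved data (normal, n = 30 per group, 4000
  draws), because the two do not agree beyond Monte-Carlo resolution for
  pathological small samples — a frozen enumeration of one such outlier
  dataset documents the divergence.
- Power/type-I calibration at the study design size (7 vs 10 eyes,
  600 spots each, 0.5% vs 5% true enlarged fractions) runs at the
  diameter level — eyes are drawn from the class mixture without image
  rendering — with 100 replicates for power and 1000 for the null
  rejection rate. Sizing error (~0.1–0.2 μm per spot) is omitted at this
  level; its effect on a binary ≥6 μm classification at these effect
  sizes is negligible relative to binomial sampling noise, and the fully
  imaged study in the acceptance script covers the complete chain once.
- Tukey–Kramer family-wise error under the null (3 groups, n = 6,
  10,000 simulations) is computed with a vectorized q statistic against
  the 0.05 critical value; the decision rule is cross-checked against the
  package's own p-values on a subsample.

## Known limitations

- Sizing assumes isotropic Gaussian spots; elliptical or ring-shaped
  reflectance profiles will be summarized by a single scale.
- The enlarged class becomes unmeasurable when spot diameter approaches
  the lattice spacing (neighbor deflation, above); the pipeline does not
  attempt to correct for packing density.
- Registration is global and rigid; saccadic or torsional frames are only
  flagged via the confidence ratio, not rejected or warped.
- The eccentricity→spacing lookup is a coarse default; studies with their
  own density data should supply their table.
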