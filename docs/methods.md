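# Methods

This note documents the models, numerical choices and known limitations
of the actinflow pipeline. Nothing here states an empirical result that
the test suite does not itself compute.

## Coordinate and unit conventions

`x` is the column index, `y` the row index; the origin is the center of
the top-left pixel and `y` increases downward; indexing is 0-based.
All velocities are computed in px/frame and converted to µm/min only at
reporting time (`value × pixel_size_um × 60 / frame_interval_s`).
Defaults: 0.10625 µm/px (a 16-px interrogation window spanning 1.7 µm)
and 30 s between frames, matching spinning-disk acquisitions of
Lifeact-labelled actin at half-minute intervals.

## Synthetic speckle-flow generator

The generator exists to provide ground truth: a latent texture is
rendered once, then advected, bleached, masked and observed with noise.

**Texture.** Point speckles at uniform random positions (default 400
per 100×100 px ≈ 0.04/px, chosen by the standard PIV seeding guideline
of roughly 10 particles per final 16×16 interrogation window) with
amplitudes uniform in [0.5, 1.5]× a base amplitude, blurred by a
Gaussian PSF (σ = 1 px); optional filamentous cables are long blurred
line segments emulating actin bundles. Rendering uses wrap boundary so
the texture is statistically seamless under advection.

**Flow kinds.** `uniform` (dx, dy); `rotation` (rigid,
(u, v) = ω(−(y−c_y), x−c_x)); `zero`; weighted `composite`; and
`radial_inward` with speed profile

    s(r) = peak_speed · (r/L) · e^(1 − r/L)

directed toward the sink. The profile is a design choice (only a peak
speed and decay length are externally meaningful): it is smooth, exactly
zero at the sink, attains exactly `peak_speed` at r = L, and decays
exponentially — qualitatively matching flow that is generated at the
cell periphery and disassembled at the nucleus.

**Advection.** Backward warping: frame_{t+1}(x) = frame_t(x − u(x)),
evaluated with bicubic interpolation (`map_coordinates`, order 3, wrap
boundary). Forward splatting was rejected for hole artifacts. A warp by
an identically zero field is short-circuited to the identity so
noise-free zero-flow sequences are bit-identical across frames. Under
uniform flow and wrap boundary the warp conserves total intensity to
interpolation tolerance (tested < 1 % per frame at 3 px/frame).

**Noise and bleaching.** Photon-like noise is Gaussian with variance
`photon_noise_scale × intensity` (a Gaussian approximation to Poisson
shot noise, accurate at the tens-of-counts level the defaults produce),
plus additive Gaussian read noise; bleaching is a per-frame
multiplicative decay e^(−bleach_rate) applied to the latent signal.
All randomness flows from one `numpy` Generator seeded by the
`FlowSpec` seed: identical specs give bit-identical stacks.

**Aliasing guard.** If the peak in-mask displacement exceeds half the
final interrogation window the generator logs and raises a `UserWarning`
(circular correlation cannot resolve such shifts).

**What the generator does not emulate.** Actin network remodeling
(polymerization/depolymerization), 3-D motion and z-projection effects
(analyzed movies may have been projections of 7–10 z-planes; the
generator is strictly 2-D and this is a stated limitation, not a guess),
spatially varying background, and camera fixed-pattern noise. A green
recovery test therefore establishes correctness of the measurement
chain, not robustness to every property of real data.

## PIV engine

**Correlation.** Windows are mean-subtracted before correlation. The
first pass uses zero-padded linear FFT correlation (no wraparound bias
at large displacements); subsequent passes use circular FFT correlation,
valid because residuals after deformation are ≪ window size. The
integer peak is searched over lags |d| ≤ window/2 and equals the
brute-force all-lags argmax (tested exhaustively). Zero-variance
windows return a flagged invalid result rather than raising.

**Subpixel.** 3-point Gaussian interpolation per axis,
δ = (ln c₋₁ − ln c₊₁)/(2 ln c₋₁ − 4 ln c₀ + 2 ln c₊₁), with a parabolic
fallback whenever any of the three correlation values is non-positive
(log undefined). Peak quality is the primary/secondary peak ratio after
blanking a 3×3 region around the primary.

**Multi-pass deformation.** Default schedule 64 → 32 → 16 px with 50 %
overlap (the final window and overlap are the published analysis
settings; the coarse-to-fine schedule is the conventional default of
deformation PIV). Each pass warps frame A by −½ and frame B by +½ of
the bilinearly interpolated predictor field (central-difference image
deformation, bicubic warp, second-order accurate); measured residuals
are added to the predictor interpolated at the new nodes. Node grids
start at the image edge with spacing window × (1 − overlap); node
coordinates are true pixel-block centers (origin + (window−1)/2).

**Masking.** Windows with in-mask coverage < 0.5 are dropped; kept
windows have out-of-mask pixels replaced by the window's in-mask mean,
which contributes zero signal to the mean-subtracted correlation. The
mechanism of the original analysis is not published; this is the
package's explicit, configurable choice.

**Validation.** Normalized median test on the 8-neighborhood with
stabilization ε₀ = 0.1 px and threshold 2.0 (the PIVlab convention;
configurable). Flagged vectors are replaced by the valid-neighbor
median and marked `interpolated`; replaced vectors are excluded from
statistical pooling by default. A frame pair with > 50 % flagged
vectors is marked unreliable in the provenance record. On very coarse
grids (e.g. the 3×3 first pass) over strongly non-uniform flow the
test's local-homogeneity assumption fails and it over-flags; this only
smooths the predictor, and the finer passes re-measure the residual, so
accuracy is unaffected (covered by the rotation-recovery test).

**Accuracy.** On default synthetic texture, uniform flows ≤ 4 px/frame
are recovered with mean absolute error < 0.2 px/frame; error grows with
photon noise and sparser seeding (the benchmark suite tabulates this).

## Decomposition and pooling

The signed radial component at node p with nuclear center c is
v⃗ · (c − p)/|c − p|: **positive = inward**. Around-nucleus samples come
from the configured box (default side 48 px in the bundled configs;
when only a nuclear width is known, a box of 3× that width is the
recommended default); inward and outward sets store magnitudes so both
are gamma-fittable on x ≥ 0, and the signed values are retained in the
long sample table. Exactly tangential vectors (component exactly 0,
measure-zero under noise) and nodes coinciding with the center are
excluded with logged counts. Whole-cell pooling uses Euclidean speeds —
no center is referenced for the whole-cell distribution.

## Gamma statistics

The density is evaluated in log space (`gammaln`). The MLE solves
log k − ψ(k) = log(sample mean) − mean(log samples) by Brent's method
bracketed around Minka's closed-form starter, then θ = mean/k; the
method-of-moments alternative uses k = m²/v, θ = v/m (ddof = 1). Both
methods therefore satisfy kθ = sample mean to machine precision, which
is asserted as an invariant. Exact zeros are dropped with a logged
count before fitting (they arise only from noise-free synthetic input;
the density is degenerate at 0 for k < 1). Fits refuse fewer than 50
positive samples or zero-spread samples. Goodness of fit is the KS
statistic against the fitted CDF, reported as a diagnostic only.

Group comparison is the two-sided equal-variance Student's t-test
(Welch by flag), with SD and SEM both emitted — published figure
legends are ambiguous between the two, so plots default to SEM and the
choice is documented rather than asserted. Significance tiers are
*** p < 0.001, ** p < 0.01, n.s. otherwise; no p < 0.05 tier is defined.
No multiple-testing correction is applied by default (pairwise stars);
Holm correction can be layered externally on the returned p-values.

## Pipeline and provenance

`run_pipeline` executes simulate/load → PIV → decomposition → fit →
report, writing the TIFF stack, long vector and sample CSVs, a JSON
provenance record (software version, seed, calibration, PIV settings,
per-pair valid/replaced counts, pooling counts, fit results) and
optional figures. Reruns with the same config and seed are
bit-identical (asserted by checksum). The temporal projection tints
each normalized frame with a time-indexed colormap entry (default
`rainbow`) and max-composites the channels: static structures collect
every hue and converge to white, moving structures leave colored
trails.

## Scale of the bundled benchmarks

Synthetic benchmarks and the acceptance script run at desk scale —
128×128 px, 5–8 frames, 3–5 replicates per group — so the whole suite
completes in well under a minute of PIV time. The discrimination test
(fast radial flow, peak 1.5 px/frame, vs 10× slower) mirrors the
wild-type-versus-inhibited contrast qualitatively; its velocity numbers
are properties of the stated synthetic world, not of any published
measurement.
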