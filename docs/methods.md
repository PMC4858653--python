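# Methods

## Acquisition model

A detected SEM signal is modelled as pure Poisson electron counting: for a
pixel with true normalized intensity `v ∈ [0, 1]` scanned for dwell `t`
seconds, the simulator draws `k ~ Poisson(dose_rate · t · v)` and records
`k / (dose_rate · t)`. The recorded gray value is therefore an unbiased
estimate of `v` with standard deviation `√(v / (dose_rate · t))`, i.e.
noise ∝ 1/√dwell — the regime of shot-noise-limited imaging at constant
beam current. Systematic effects (drift, PSF deformation, detector
nonlinearity, charging) are deliberately excluded: in the operating
conditions this package targets they are negligible against the counting
noise, and including them would entangle the filtering tests with
registration questions.

`dose_rate` defaults to 2×10⁹ electrons/s at unit intensity, i.e. ≈ 2000
expected counts for a 1 µs dwell at full brightness — a plausible
calibration for a few-hundred-pA probe with partial collection efficiency.
It is configurable; no published counts-per-dwell calibration exists for
the reference instrument, so this is a documented assumption, and all
quantitative checks in the test suite are ratios that do not depend on it
(SNR scaling exponents, SNR ratios at equal average dwell, mixing-factor
contracts).

One seeded generator is created per simulate call and per-pixel draws are
made in row-major order, so results are bit-reproducible and independent of
internal vectorization. Gray values stay floating point in [0, 1]
internally; 16-bit quantization happens only at file I/O, keeping
quantization noise out of the filtering analysis.

## Phantoms

`make_phantom` emulates polished two-phase metallographic sections: a
bright matrix (intensity 0.8) with dark inclusions (0.2), either roundish
nodules (randomly placed, mildly elliptical, radius ≈ 1/20 of the image
side) or thin curved lamellae (length ≈ 1/4 side, thickness 3–7 px). Phase
boundaries are blurred with a σ = 1 px Gaussian point spread so edges are
not single-pixel steps, and a ±0.05 low-frequency shading field (one-period
sinusoids with random phase) emulates uneven illumination/detector gain.
The phase-label map is kept alongside the intensity truth so tests can
measure boundary coverage and per-phase noise.

What the phantoms do **not** model: texture inside phases, more than two
phases, inclusion clustering, topographic contrast, or features at the
resolution limit. Passing tests therefore demonstrate the method's
behaviour for sparse-gradient specimens with large connected smooth
regions — the class it is designed for — and say nothing about densely
textured samples (e.g. most biological tissue), for which the masked
low-pass filter is explicitly unsuitable.

## Mask generation

Edges are detected as the magnitude `√(gx² + gy²)` of first-order
Gaussian-derivative convolutions at scale σ (reflective boundary extension,
no non-maximum suppression). Thresholding builds a 256-bin equal-width
histogram over [min, max] of the gradient image, accumulates counts from
the highest bin downward, and picks the bin edge whose cumulative count
best approximates `A · n_pixels`; the HIA is `grad ≥ threshold`, so ties in
the threshold bin are all included and the realized fraction is within one
bin's population of the target. Alternatively a fixed gradient threshold
can be applied directly (`threshold_by_value`), letting the HIA size vary —
useful across a slice series where structure density changes.

Working presets per initial dwell (wider kernels and larger HIA for noisier
initial scans): 100 ns → (σ = 6, A = 20 %), 300 ns → (3, 15 %),
1 µs → (2.5, 15 %), 3 µs → (2, 10 %); `recommend_settings` returns the
nearest preset on a log-dwell scale. As a rule of thumb the initial dwell
should give a contrast SNR (smallest between-phase gray-level difference
over pooled within-phase noise std, `contrast_snr`) of roughly 1.4–2.3 —
well under the Rose criterion of 4–5, because the detector integrates over
extended structures and tolerates false positives.

The "closed shapes around every boundary" criterion is exposed as a
diagnostic (`boundary_coverage` against a reference label map) rather than
an automatic gate; interactive use relies on the realized-fraction and
threshold report. `close_mask_holes` provides morphological closing with a
pixel-center disk (every offset within radius + ½, so radius 1 is the full
3×3 neighbourhood and bridges diagonal gaps); closing is forced extensive
by OR-ing the input back in, which also neutralizes border erosion.

## Scan patterns and dose budget

`build_pattern` emits one visit point per HIA pixel in row-major order;
blanking between non-adjacent consecutive points is implicit (the simulator
only needs visited pixels). The stream dialect is ASCII: magic `s16`, pass
count, point count, then `dwell_ticks x y` per point with a 100 ns tick,
0-based x = column / y = row, origin top-left. Dwells are rounded to the
nearest tick on write and returned tick-exact on read; round trips are
bit-exact for tick-multiple dwells. The dialect is self-consistent and
testable but intentionally not claimed to be compatible with any vendor's
scan-generator format, whose tick and DAC conventions are not public.

The dose bookkeeping is `t_avg = t_initial + A · t_sparse` — exact
arithmetic, checked to equality for the benchmark budget
300 ns + 0.1 × 27 µs = 3 µs.

## Adaptive filter

Kernel construction per filter-region pixel: discrete 2D Gaussian of width
σ sampled at pixel centers, zeroed beyond Euclidean radius 3σ (stencil side
2·ceil(3σ)+1); weights on HIA pixels zeroed; 4-connected flood fill from
the center over filter-region pixels within the stencil window, zeroing
everything unreachable; renormalization to unit sum. 4-connectivity is
chosen so a one-pixel-wide diagonal HIA strip still isolates the far patch
— the strip exists precisely to separate phases. Intensity is preserved
exactly (weights sum to 1), output pixels depend only on values within
Chebyshev radius ceil(3σ), and no HIA value can leak into the filter
region.

Border handling (a free design choice): the stencil is clipped to in-bounds
pixels and renormalized, consistent with the mask-multiply-renormalize
scheme. Degenerate support — a filter-region pixel whose flood fill
reaches nothing but itself (fully enclosed by HIA) — falls back to the raw
initial value and is counted in a warning; such pixels indicate the mask
needs closing, and passing the raw value is the least-wrong deterministic
choice.

Two implementations are maintained: a pure-Python per-pixel reference
(`method="direct"`) and the default accelerated path (`method="fast"`)
that uses FFT convolution for pixels whose stencil window contains no HIA
(where the restricted kernel equals the plain clipped Gaussian) and a
compiled per-pixel BFS for the rest. The fast path is asserted equal to
the reference within 1e-10 in the test suite.

Kernel width matters: moderate σ (≈1–5 px) leaves band-limited residual
structure at wavelengths around 5 px that reads as a visible artifact
texture covering only the filter region. The regression test runs σ = 10
on the benchmark phantom and requires the radially averaged power spectrum
of the filter-region residual to have no peak above 3× its band median in
the 4–6 px wavelength band; σ = 1.5 violates this bound, reproducing the
artifact the large-kernel recommendation avoids.

## Noise-level adaptation

With a large σ the filter region becomes essentially noise-free while the
HIA keeps the residual noise of its `t_sparse` rescan; the visible texture
mismatch is removed by mixing the raw initial signal back in:
`p_final = i · p_initial + (1 − i) · p_filtered` with
`i = √(t_initial / t_sparse)`. Since noise std ∝ 1/√dwell, `i` is exactly
the sparse-to-initial noise ratio, so the filter region ends up with
residual noise `i · σ_initial = σ_sparse`, matching the HIA. The mixing is
applied in the filter region only; HIA pixels take the sparse values
verbatim (no boundary feathering — a deliberate non-goal). An alternative
reading — mixing inside the HIA instead — is internally inconsistent with
the goal of raising the filter region's noise to the HIA's level and is not
implemented.

Contract checks: with t_initial = 300 ns and t_sparse = 30 µs (i = 0.1) the
filter-region residual std is 0.1× the initial scan's within 15 %, and the
filter-region and HIA residual stds agree within 20 % when both are
measured on matrix-phase pixels. The phase restriction is deliberate:
Poisson noise is intensity-dependent and the HIA contains the dark
inclusion phase, so an unstratified comparison would mix noise levels of
different intensities and measure composition, not adaptation.

## Metrics and comparator

Pixel error: per-pixel absolute difference as % of the reference maximum
(mean/std/max); absolute rather than signed, otherwise the max and std
columns lose meaning. SNR = mean(reference) / std(image − reference):
signal taken from the reference ("signal only"), noise as the difference
image. PSNR = 10·log₁₀(range²/MSE). SSIM uses the conventional K₁ = 0.01,
K₂ = 0.03 with an 11×11 Gaussian-weighted window (σ = 1.5), mean over
windows (via scikit-image; verified against a brute-force windowed oracle).
Zero-noise comparisons return +inf sentinels.

The uniform-scan comparator is a Perona–Malik anisotropic diffusion
(explicit 4-neighbour scheme, conduction g(d) = exp(−(d/κ)²), default 200
iterations, κ = 0.02 in normalized intensity, step 0.2 — stable for
step ≤ 0.25). It is a generic edge-preserving diffusion, functionally
comparable to, but not bit-compatible with, specific plugin
implementations; κ = 0.02 maps a typical "edge threshold 5" on an 8-bit
scale into [0, 1].

`run_comparison` mirrors the benchmarking protocol: adaptive without/with
adaptation, uniform at `t_avg`, and uniform + diffusion, all evaluated
against a simulated 60 µs high-dwell reference scan.

## Problem sizes and tolerances

The benchmark experiments use a 512×512 phantom with 20 nodular inclusions
(HIA ≈ 10 %), which gives ≥ 2×10⁵ pixel draws per condition — residual-std
estimates are then precise to well under 1 %, so the stochastic tolerances
(2 % on SNR-scaling ratios, 15–20 % on adaptation contracts) are dominated
by model effects, not sampling error. Monte-Carlo repetition tests use
100–200 repetitions at 64–256² sizes. Flood-fill and kernel identities are
exact (1e-12 on weight sums, 1e-10 between filter implementations).
Hypothesis-based property tests run derandomized with fixed profiles.

## Known limitations

- Small isolated features (≈1 px, low contrast) missed by the edge detector
  are erased by the filter; the method is unsuitable when such features are
  the objects of interest.
- The filter assumes large connected filter-region shapes; highly
  fragmented masks degrade it (mitigate with `close_mask_holes`).
- Textured filter regions violate the low-pass assumption; inpainting-style
  reconstruction would be needed instead.
- The simulator omits drift between the two passes; on real instruments at
  high magnification, drift correction would be required before fusion.
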