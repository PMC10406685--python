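# Methods

This note records the model, the numerical choices and the known
limitations of the package, in the order data flows through it.

## Signal model and processing conventions

Time-domain 2D signals are sums of exponentially damped complex
sinusoids with additive complex Gaussian noise,

    f(t1, t2) = Σ_k A_k exp((i2π f1_k − R2₁_k) t1) exp((i2π f2_k − R2₂_k) t2) + ε,

with one complex value per t1 increment (States-equivalent); a "NUS
point" therefore means one complex indirect increment, which is how
schedules are counted throughout. Synthetic data is generated with zero
phase, so the displayed spectrum is the real part of the complex 2D
transform; no automatic phase correction is implemented (real-data
phase parameters can be applied upstream, but estimating them is out of
scope).

All transforms are unitary, so Parseval's identity holds exactly and
white noise keeps its standard deviation across a transform. Frequency
axes run from high to low Hz with increasing index; ppm values are
carrier_ppm + Hz / base_frequency(MHz). Default processing is
cosine-squared apodization in both dimensions and zero-filling to twice
the acquired points. These processing parameters were an open choice —
nothing forces cos²/2× — and they are configurable; what matters is
that the conventional path (`ft2d`), the CS path and the DCS add-back
always share one configuration, which the code enforces.

## Poisson-gap schedules

Gaps between consecutive sampled points are Poisson draws whose mean is
modulated by sin(π/2 · t/N) (normalized to mean ~1 over the grid), so
late evolution times are sampled more sparsely. The rate is adjusted
multiplicatively and the draw repeated until exactly M points land in
[0, N−1]; overshooting draws are discarded wholesale rather than
clipped, preserving the gap statistics. Index 0 is always sampled —
the first increment is needed for alignment and for the nested-schedule
rule. Nested (subset) schedules are produced by Poisson-gap subsampling
of the parent's positions.

## IST reconstruction

Each ω2 column (after direct-dimension FT) is reconstructed by
iterative soft thresholding with hard data consistency:

1. FFT the current full-grid estimate,
2. soft-threshold the spectrum at τ_k,
3. inverse FFT,
4. restore the measured time points to their measured values.

The threshold follows a continuation schedule τ_k = τ₀ · ρ^k with τ₀
the per-column initial spectral maximum and ρ = 0.98 over the default
200 iterations. Both halves of that choice matter: the schedule must
fall *slowly* (at ρ = 0.95 the iterate cannot track the threshold and
peak heights come out several percent low) and must end *low*
(0.98²⁰⁰ ≈ 0.018 of the initial maximum; stopping at ~13% visibly
suppresses heights). With ρ = 0.98 the noiseless 1- and 3-peak test
columns reconstruct with sub-1% height error and r > 0.999 against the
full-data FT. Iterations stop early when the relative change of the
estimate falls below 1e-6 (an all-zero input therefore returns
immediately), and the returned estimate reproduces the measured data
exactly by construction.

The virtual echo (on by default) extends each column to 2N points with
v[L−t] = conj(v[t]), the center counted once (2M−1 sampled points).
For phased data this makes the spectrum real and roughly twice as
sparse. The t=0 point keeps its (possibly complex) value; its imaginary
part only adds a constant imaginary offset to the spectrum, which the
real-part output discards.

After IST, the data-consistent time-domain estimate is apodized,
zero-filled and transformed exactly as a fully sampled FID would be, so
a fully sampled input reproduces `ft2d` to rounding error.

## Alignment (reference → target)

The correction is estimated on the first t1 increments only and applied
uniformly to all rows of the reference: an exhaustive search over
integer spectral-point shifts (default −10..+10 on the 2× zero-filled
grid) and Gaussian broadenings σ ∈ {0, 0.25, …, 5} Hz, minimizing the
l2 norm of the residual between the corrected reference and the target
increment. Broadening is implemented as a time-domain Gaussian envelope
exp(−2π²σ²t²) — exactly equivalent to convolving the spectrum with a
unit-area Gaussian of standard deviation σ Hz (also reported as FWHM =
2.355σ). The shift is a time-domain linear phase ramp, exact on the
circular grid, so constructed shift/broadening pairs are recovered
exactly (shift) and to the grid step (σ). Amplitude is *not* fitted:
the dilution factor is supplied by the caller (the default synthetic
study uses 0.9, the volume ratio of its emulated titration). Ties in
the search break toward the smaller |shift| and smaller σ. Only the
direct dimension is corrected.

Limitation: with noisy inputs the grid search is biased toward larger
σ, because broadening also smooths the reference's noise and thereby
lowers the residual. At the generator's default SNR the single first
increment has a 1D SNR of only ~6 (the 2D SNR is built by coherent
averaging over t1), and the fitted σ comes out ~1 grid step high
(2.25 Hz for a true 1 Hz). This costs DCS little — the difference stays
sparse and the end-to-end results are unaffected — but σ values from
low-SNR increments should be read as effective, not physical,
linewidth corrections.

## DCS assembly

S_B^rec = S_diff^rec + S_A^full is computed literally in that order, so
the additivity identity is exact to the bit, and a target identical to
its reference reproduces S_A^full exactly at any sampling level (the
difference is exactly zero and IST maps zero to zero). If the reference
is itself undersampled, it is CS-reconstructed first; the nested-
schedule rule (schedule(B) ⊆ schedule(A)) is enforced with a dedicated
error.

## Synthetic series generator

The generator emulates a variable-temperature HSQC study of an IDP
titrated with liposomes: 100 amide peaks, a 256-point indirect grid
(2.7 kHz width, ~94 ms maximum evolution), 15 temperatures from 15 to
43 °C in 2 °C steps. The direct dimension covers the amide ¹H region
(1.5 kHz, 128 complex points, ~85 ms) — a direct resolution at which a
1 Hz Gaussian broadening is measurable — rather than a full-width ¹H
axis, keeping runtimes to minutes on one core. Reference
amplitudes are flat in temperature (an optional linear decline is
available); target amplitudes follow per-peak tanh profiles whose
transition temperatures rise linearly from 24 to 30 °C along the
sequence, with baseline y_scale + y_shift = 1 (every residue free at
low temperature) and bound-state plateau 0.2. The target additionally
carries a 2-spectral-point direct-dimension shift, 1 Hz extra Gaussian
broadening and the 0.9 dilution relative to the reference.

Noise: `snr` (default 100) is defined on the processed spectrum — the
median noiseless reference peak height over the spectral noise standard
deviation. Because apodization and zero-filling attenuate white noise,
the generator measures the attenuation of the processing chain on a
noise-only data set and scales the time-domain σ accordingly. The
series is bit-reproducible from its spec (seed included).

What the generator does *not* model: exchange dynamics, relaxation
dispersion, temperature-dependent chemical-shift drift along the
series, lineshape non-idealities, or any real liposome physics — only
amplitude/shift/width phenomenology. Passing tests therefore
demonstrate the correctness and the qualitative trade-offs of the
reconstruction and analysis machinery, not quantitative agreement with
any particular experimental data set.

## Intensity analysis

Peak heights are grid maxima within ±window points of the assigned
position (window 1 by default; the end-to-end workflow uses 3 to cover
the configured inter-sample shift). Visibility requires both heights
above a noise threshold, by default 3× the standard deviation of a
signal-free corner box (the generator keeps peaks within ±45% of both
spectral widths, so the corner is clean; real data should declare a
region). Sigmoid fits use SciPy's trust-region-reflective least squares
with bounds 0.05 < x_scale < 0.8, 20 < x_shift < 40 °C, y_scale within
[half, 2×] the observed y range and y_shift within min(y) ± 0.1;
initial guesses are x_scale 0.3, x_shift at the median temperature,
y_scale the y range, y_shift min(y). The fit residual is normalized by
‖y‖₂, matching the normalized peak-height residual convention.

Rejection filters, in order: fewer than six visible points;
x_scale ≤ 0.08 (quasi-linear profile); "transition too small" — read as
the *second* and *penultimate* visible points of the profile differing
by less than a factor of two (larger/smaller); relative residual > 0.1.
Residue numbers are parsed as the first integer in a peak label
("A069N-H" → 69); unparseable labels are kept with a null residue and a
warning.

## Problem sizes used in tests and the acceptance script

Column-level checks run at the full 256-point indirect grid. The
CS-vs-DCS head-to-head uses 50 peaks on a 256×64 grid, 20 schedule/
noise realizations per sampling level; the end-to-end study runs the
full default series (100 peaks, 256×128, 15 temperatures) at 64-of-256
sampling. These sizes were chosen so the entire suite and the
acceptance script each complete in a few minutes on a single core while
exercising the method at the study's indirect-dimension resolution.

## Known limitations

* No automatic phasing; data is assumed phased (or synthetic).
* The IST variant is this package's own continuation-schedule
  implementation; other IST implementations will differ in the last
  decimals of residuals even at matched iteration counts.
* Indirect-dimension (ω1) alignment is not performed.
* The Varian and NMRPipe readers cover a documented subset of each
  format (enough for this package's writers and plain 2D data); exotic
  header layouts are out of scope.
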