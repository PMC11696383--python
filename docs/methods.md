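# Methods

This note documents the models, conventions and numerical choices behind
`proteospike`, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite uses.

## Data model

A **recording** is a single uniformly sampled channel — potential in mV or
temperature in °C — with time in seconds and an optional stimulus label
(the alphabet character projected onto the sample). Uniformity is enforced
at a relative tolerance of 1e-6; the sampling interval is inferred as the
median spacing, because logger rates are not carried in the CSV files the
package reads. The caller declares the channel kind explicitly; no unit
auto-detection is attempted, since silently confusing mV with °C is a worse
failure mode than an extra argument.

The **profile table** holds, per character A–Z, seven-number summaries
(Q1, Q2, Q3, mean, max, min, SD) of spike amplitudes (mV) and inter-spike
periods (s). The packaged reference table transcribes the published
statistics verbatim. One published row (the period summary for 'H') contains
a quartile inversion (Q3 = 10923.00 s < Q2 = 10983.50 s); the transcription
keeps the printed values, and the loader therefore validates ordering
strictly only for user-supplied tables. Downstream computations use only
means, maxima and SDs, none of which are affected.

## Spike analysis

**Baseline removal.** Three estimators: a centered moving median (default,
window 500 s), a least-squares line, and a pre-stimulus mean. The moving
median is the default detrending before peak picking because spikes are
sparse: with spike widths of tens of seconds and periods of hundreds to
thousands, spike samples are a small minority of any window, and the median
tracks drift without being pulled up by the spikes. The window must span at
least 3 samples. A residual bias remains when spikes occupy a large fraction
of the window (short periods, wide spikes) or when drift is strongly
curved inside the window; both grow with window length, so the default is a
compromise at 25× the default spike width.

**Peak semantics.** A sample is a peak candidate iff it exceeds its left
neighbour and is at least its right neighbour — the leftmost sample of a
plateau, a deterministic and order-stable tie-break. Prominence is standard
topographic prominence: height minus the higher of the two minima separating
the peak from the nearest strictly higher sample (or the record edge) on
each side. Among surviving peaks closer than `min_separation` (default 10 s)
the higher wins, ties to the earlier. The brute-force O(n²) re-derivation of
these rules in the test suite is the contract's oracle.

**Detection thresholds.** The noise scale σ̂ is estimated robustly as the
normal-consistent median absolute deviation of the first differences divided
by √2 (white noise adds in quadrature across a difference; spikes are sparse
in the difference sequence). Both the prominence floor and the height floor
default to 5σ̂. The height floor is not redundant: prominence alone cannot
control false positives in long records, because a tall noise sample
inherits a large prominence from the ordinary excursions around it — in
2×10⁷ samples of pure N(0, σ) noise, a 5σ prominence-only threshold admits
on the order of 10⁵ spurious peaks, while the combined floors admit fewer
than ten. "Amplitude" is the detrended height at the peak sample, not the
prominence; the two differ when spikes ride on residual structure.

**Summaries.** Quartiles use linear interpolation of order statistics (the
type-7 convention, numpy's default), switchable to the midpoint convention;
the published tables do not state their convention and the raw data needed
to distinguish the two is not available. SD uses the n−1 denominator
(defined as 0 for n = 1). Period statistics require at least two peaks.

## Synthetic generator

The generator emulates what the analysis assumes and nothing more: spike
events with i.i.d. amplitudes and i.i.d. inter-event intervals, rendered as
unit-peak Gaussian bumps on a deterministic baseline plus white Gaussian
noise. Log-normal distributions are used for both quantities: they are
positive, and the published period summaries are strongly right-skewed
(e.g. a mean of 2034.88 s against a median of 847.00 s for 'A'), which a
normal cannot produce. Moment matching uses μ = ln(m²/√(v+m²)),
σ² = ln(1+v/m²); zero variance degenerates to a point mass. The published
min/max columns are treated as descriptive, not as truncation bounds —
clipping would bias the recovered means.

Defaults: spike width 20 s (no published single-spike shape parameters
exist; the only contract downstream relies on is peak height = amplitude),
additive noise SD 0.05 mV, sampling interval 1 s, neutral baseline
(offset = drift = sinusoid = 0; tests exercising detrending set these
explicitly). Temperature co-traces use the same machinery with small
amplitudes (of order 0.1–0.9 °C) and a slow drift, and background
subtraction is an elementwise difference of grid-matched recordings.

Randomness flows through numpy's PCG64 (`default_rng`), with separate
deterministic child streams for event sampling and noise rendering, so a
config is reproducible bit-for-bit across runs and platforms.

What the generator does **not** emulate: waveform-shape differences between
characters (characters differ only through their amplitude/period moments),
serial correlation between successive intervals, slow nonstationarity of
spiking rate, electrode artifacts, and quantization. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it assumes, not that real recordings satisfy those assumptions.

Microsphere diameters are i.i.d. normal draws truncated at zero (scipy's
truncated normal); at the default mean 1600 nm, SD 200 nm the truncation is
negligible.

## Recognition

The threshold rule assigns a character to its own class when its mean
amplitude and mean period *strictly* exceed A_th and P_th, and otherwise
rejects it. The published construction has no else-branch, so rejects are
tallied per true class outside the 26×26 count matrix, preserving its
shape; recall counts a class's rejects in its denominator (they are true
instances of the class), while precision is the usual column ratio.
Undefined ratios (zero denominator) are reported as NaN, never as 0.
A_th and P_th have no published values and are therefore required
parameters with no silent default.

The nearest-profile classifier z-scores (mean amplitude, mean period)
across the 26 references and assigns the nearest reference by Euclidean
distance, ties alphabetically; a constant feature (zero SD) is dropped from
the distance. Note that 'D' and 'H' have nearly coincident reference
profiles (17.26 mV / 11 756 s vs 15.62 mV / 11 816 s), so confusions between
them are expected at small event counts.

## Boolean gates

Mean amplitudes and periods are min-max normalized across the 26 characters
(degenerate ranges are an error), then thresholded with strict inequalities.
The characterization defines separate amplitude- and period-NOT gates, but
the published summary has a single NOT row satisfied by all 26 characters,
described as "small magnitude or brief duration"; the package's combined
NOT is therefore the disjunction (A < T_A) ∨ (P < T_P), switchable to the
conjunction. With the default thresholds T_A = T_P = 1.0 the disjunction
reproduces the published gate counts (0, 0, 26, 26, 26) exactly, whereas
the conjunction would exclude the amplitude and period argmax characters
(normalized value exactly 1). The defaults are the minimal thresholds
consistent with all five published counts; the values actually used for the
published table are not stated.

## Morphology

Scott's rule is implemented as w = c·σ̂·n^(−1/5) with c = 1 and σ̂ the n−1
sample SD; the constant is exposed because variants of the rule differ in
it, and the single published bandwidth (w = 135.05798) cannot be
reverse-engineered without the raw diameter sample. KDE evaluation is the
direct Gaussian-kernel sum (valid down to n = 1); the default grid spans
the data range ±5 bandwidths, wide enough for the trapezoidal integral to
equal 1 within 1e-3. Tukey fences are Q1 − 1.5·IQR and Q3 + 1.5·IQR,
deliberately *unclamped* to the data extremes — the published whisker
values equal the unclamped fences, not observed data points — and outliers
are the samples outside them.

## Spectral

Filters are Butterworth (default order 4), applied forward–backward
(`sosfiltfilt`) for exactly zero phase so spike timing is undistorted; the
two passes square the magnitude response, making the effective attenuation
at the nominal cutoff −6 dB rather than −3 dB. No filter family, order or
cutoff is published; these defaults favour a flat passband. Low- and
high-pass outputs at the same cutoff are power-complementary, not
amplitude-complementary, so their sum reconstructs the input only away from
the cutoff region (verified to 2% for tones a decade away). The spectrum is
a one-sided periodogram in dB (10·log₁₀), rectangular window by default,
which conserves energy exactly (Parseval); bins with zero power map to −∞.

## Problem sizes and tolerances

The reproduction suite recomputes the gate counts, table extrema and fences
exactly, and runs the full generator→detection closure for the letter-A
parameters at 10 000 events, 1 s sampling (≈2×10⁷ samples), recovering the
configured 2.65 mV mean amplitude within 2%. The remaining statistical
suites use reduced sizes chosen to keep the full test run under a minute
while leaving Monte-Carlo error well inside the asserted bands: parameter
recovery at 150–400 events over up to 5 seeds (assertions at 3 standard
errors plus a 0.05 mV allowance for the known small positive bias from
noise-maximum selection at the peak sample), and end-to-end 26-character
recognition at 40 events per character on a 5 s grid over 2–3 seeds
(asserted well above the 1/26 chance level, and at chance when all
characters are generated from identical parameters). Detection equals its
brute-force oracle on 200 random instances of length ≤ 1000 plus a
derandomized property suite over integer-valued signals, which maximize tie
and plateau coverage.

## Known limitations

- The recovered mean amplitude carries a small positive bias (≈1% at noise
  SD 0.05 mV) because the detected peak sample is the maximum of several
  noisy samples near the bump top; it shrinks with the noise level.
- Moving-median detrending biases heights when spikes are dense relative to
  the window.
- The generator's independence assumptions (see above) are untested against
  real recordings.
- Gate results depend on strict-vs-nonstrict inequality for characters
  sitting exactly at a normalized extremum; the package follows the strict
  convention throughout.
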