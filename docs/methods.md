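# Methods

This note documents the models and estimators in gammakit, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before comparing
outputs across software.

## Data model

Recordings are uniformly sampled single-channel traces (LFP in volts,
membrane current in pA, membrane potential in mV; 10 kHz throughout).
Time is held internally as integer sample index plus rate — seconds appear
only at the API boundary — so 60-s windows slice without floating-point
drift.  Analysis windows are half-open `[start, start+dur)` and return
exactly `round(dur·rate)` samples, letting windows tile a recording without
duplication.  Units are declared in metadata, never guessed; LFPs in volts
put integrated gamma powers on the 1e-10–1e-9 V² scale customary for
slice recordings.

## Spectral estimation

Power spectra are averaged modified periodograms: 8192-sample windows,
Hann-tapered (taper power-corrected), 50% overlap, mean-detrended.  The
per-bin quantity is *total power* (density × bin width, V²), so summing
bins over a band gives integrated band power directly and the whole
spectrum sums to the trace variance (Parseval holds within 5% for any
finite-variance input; property-tested).  Frequency resolution at 10 kHz
is 10 000/8192 ≈ 1.22 Hz.  Gamma power = band sum over 20–80 Hz.  A V²/Hz
density view is available.  Averaging and tapering are the package's
choice for variance reduction; plain single-window FFTs of the same
segments differ only in estimator variance, not in calibration.

## Band-pass filter

LFP pre-filtering reproduces the common acquisition-software cascade: a
single-pole RC high-pass applied forward-backward (zero phase; its
amplitude response therefore enters squared) followed by a Gaussian FIR
low-pass, each specified by its −3 dB point (15–60 Hz for rhythmicity
analysis, 20–60 Hz before phase extraction).  The analytic amplitude
response is exposed as `bandpass_gain(f, f_hp, f_lp)` and the measured
sine gain matches it to 1%.  Note that the cascade is *not* flat in the
middle of the band: a 40 Hz sine through (15, 60) keeps ≈ 0.75 of its
amplitude.  This does not bias ratio-based quantities (Cr, percent
changes, phase), but absolute filtered amplitudes should not be compared
against unfiltered ones.

## Coefficient of rhythmicity

The ±100 ms autocorrelogram of the filtered segment is the biased,
lag-0-normalized autocovariance (r(0)=1, exactly symmetric).  Because a
signed correlation trough would push (α−β)/(α+β) out of [0, 1], the trace
is rescaled affinely to r01 = (r+1)/2 before extraction — the minimal
convention under which Cr spans [0, 1] as stated for this statistic.  β is
r01 at the first local minimum at positive lag, α at the first local
maximum beyond it; the peak lag is one oscillation period, so
1000/peak-lag (ms) estimates the oscillation frequency and is
cross-checked against the spectral peak (default tolerance 5 Hz).

Numerics: candidate extrema are located on a 1-ms moving-average-smoothed
trace (suppresses sample-level jitter; ties break toward the smaller lag),
then both value and lag are refined on the *raw* trace with three-point
parabolic interpolation — reporting smoothed values would bias Cr by
~2×10⁻³.  The lag-0 sample is excluded from refinement (it is a
delta-like normalization spike).  On closed-form damped-cosine
autocorrelograms e^(−τ/τd)·cos(2π·40τ) the extracted α, β, lags and Cr
match the true analytic extrema (solving tan(ωτ) = −1/(ωτd)) to 1e-3
across τd ∈ {10, 25, 50, 100} ms.  A trace with no extrema in range is
degenerate (Cr = 0, not rhythmic), not an error.  The rhythmicity gate is
Cr ≥ 0.01 as printed in the source analysis; it is surprisingly permissive
(white noise sits near 0.003 but well under 0.05) and is configurable.

## Spike–field phase coupling

The instantaneous gamma phase is the angle of the analytic signal
(Hilbert transform) of the 20–60 Hz-filtered LFP, with the cycle peak at
phase 0 (≡ 2π) and the trough at ±π, stored wrapped to [0, 2π).  Segments
are reflection-padded by 1 s before filtering and transforming and the
padding discarded; residual edge error is confined to ~0.5 s per end
(`trim_s`), and in the interior the phase of a pure in-band cosine is
reproduced to < 0.01 rad.  Spikes are detected by amplitude threshold
(first suprathreshold sample per crossing, 2 ms refractory merge) and each
spike takes the phase of the nearest sample — at 10 kHz and ≤ 60 Hz the
lookup error is ≤ 0.019 rad, below every other error source.

Coupling summaries per recording:

* **Rayleigh test** of circular uniformity, p = exp(√(1+4n+4(n²−Rn²)) −
  (1+2n)); recordings with p ≥ 0.05 in either epoch are excluded from
  phase metrics, and exclusions are listed in the report, never silent.
  Type-I error is calibrated (0.050 ± 0.01 at n = 50 over 10⁴ draws).
* **Preferred angle** = circular mean of spike phases (the fitted Gaussian
  μ is reported alongside; "averaging the phase distribution" is read as
  the circular mean because it is robust to fit failures).
* **Half-width** = full width at half maximum, 2√(2 ln 2)·σ, of a Gaussian
  fitted to the 36-bin (10°) peak-normalized phase histogram, rotated so
  the circular mean sits at the domain centre before a linear-domain
  least-squares fit of a·G(θ; μ, σ) + c with a > 0, c ≥ 0.  G includes the
  ±2π images of the Gaussian: without them the wrapped tails of wide
  distributions are absorbed into the baseline and σ is under-estimated by
  ~10% at σ = 1.5 rad.  "Half-width" here is the FULL width at half
  maximum — half-widths of 3.4–5 rad exceed π and are impossible as HWHM
  on a 2π support.  On wrapped-normal samples (n = 2000) the mean
  recovered FWHM is within 7% of 2.355σ for σ ≤ 1.5 rad and monotone in σ;
  a single-angle sample returns ≤ one bin width.  The estimator's
  sensitivity degrades for circular std ≳ 1.3 rad, where a von Mises
  density is nearly cosine-shaped and width information migrates into the
  baseline term — see the generator notes below.

## Synaptic-event detection

A slowly varying baseline (median over 500 ms windows on a 50 ms grid,
linearly interpolated) is removed and the trace rectified by polarity
(inward = negative-going).  Candidate events are peaks of a lightly
smoothed trace (Gaussian σ = 0.1 ms) exceeding the amplitude threshold in
height, with prominence at half the threshold; a pedestal-subtracted
amplitude filter then re-imposes the full threshold per event.  The split
thresholds matter for events riding on a predecessor's decay: the first
event of a close pair has a shallow dip toward its (larger) successor and
a full-prominence criterion would discard it.  The event onset is the
10%-of-rise crossing (clamped to 1.5 ms below the half-rise point so
baseline noise runs cannot drag it early); amplitude is read from a
0.2-ms-smoothed trace near the peak, relative to the local pedestal;
charge transfer is the trapezoidal integral of the baseline-subtracted
current from onset until the trace returns to 1% of the rise (events cut
off by the record end are flagged and integrated to the end).  Events with
onsets closer than `min_iei` are merged into the first.

Scored against generator ground truth (25 ± 5 pA events at 20 Hz in
σ = 2 pA noise, 60 s, ±2 ms bipartite matching, `min_iei` = 2 ms) the
detector reaches recall ≈ 0.96 and precision ≈ 1.0 with < 2% amplitude
bias and zero false positives on pure noise; the recall ceiling is set by
genuinely fused events (two Poisson arrivals within 2 ms, ~4% at 20 Hz),
which no single-trace detector can split.  With the default
`min_iei` = 5 ms the merge rule alone caps recall near 0.90 at this event
rate, which is why the benchmark runs at 2 ms.  Noiseless exponential
events recover charge A·τ within 2%.  Summaries (frequency, mean
amplitude, mean IEI, summed charge) are computed in half-open 1-min bins;
window summaries are unweighted means over complete bins.  Charge is
reported both as per-bin sums (matching the hundreds-of-pC magnitudes of
window totals) and per-event means.

## Group statistics

Paired contrasts use the one-tailed Wilcoxon matched-pairs signed-rank
test with the *exact* null (generating-polynomial enumeration over sign
assignments, ties via mid-ranks) for n ≤ 25, normal approximation with
continuity correction above; zero differences are dropped.  Unpaired
contrasts use the one-tailed Mann–Whitney U with the exact permutation
null (all C(n+m, n) assignments, mid-ranks for ties) for n+m ≤ 20.
Exactness is load-bearing: with all n pairs changing in one direction the
one-tailed p is exactly 2⁻ⁿ, which is what published small-n slice
experiments print (0.0313, 0.0156, 0.0039).  Percent changes are computed
per recording and averaged (mean ± SEM), with the pooled ratio of group
means reported alongside; time courses are normalized to the mean of the
first five 1-min control bins (idempotent; the normalized control mean is
exactly 1).  Significance is fixed at p = 0.05; no multiplicity
correction is applied, matching the analysis this package models.

## Synthetic-data generator

The generator is the test bed: every estimator must recover the
generating parameter closed-loop (band power within 10%, preferred angle
within 0.1 rad, FWHM within 7% in the calibrated range, rates within 10%,
PSC amplitude within 5%).

* **LFP**: gamma(t) = σγ·[x(t)cos(2πf₀t) − y(t)sin(2πf₀t)] with x, y
  independent unit-variance Ornstein–Uhlenbeck processes of correlation
  time τ_env — so the gamma autocorrelation is *exactly*
  σγ²e^(−|τ|/τ_env)cos(2πf₀τ), the damped-cosine family with the
  closed-form Cr — plus Gaussian 1/f^β background (β = 1, spectrum
  flattened below 1 Hz).  Defaults: f₀ = 35 Hz, σγ = 29 µV (≈ 8.4e-10 V²,
  the control gamma-power scale), noise 10 µV.  τ_env defaults to 0.1 s:
  the Lorentzian linewidth 1/(2πτ_env) then keeps ≥ 95% of gamma power
  inside the 20–80 Hz integration band (at τ_env = 25 ms, ~17% would leak
  out and break the generator's power contract).  A consequence is that
  control traces are strongly rhythmic (Cr ≈ 0.85 after filtering) —
  more regular than typical slice gamma; Cr *contrasts* remain valid
  because Cr is strictly monotone in τ_env.
* **Spikes**: inhomogeneous Poisson thinning with intensity
  λ(t) = r₀·e^(κcos(φ(t)−μ))/I₀(κ), φ being the package's own measured
  instantaneous phase of the generated LFP; marginal rate stays at r₀ and
  the phase distribution converges to von Mises(μ, κ); 2 ms refractory.
* **PSCs**: Poisson event times, difference-of-exponential kinetics
  (τ_rise = 0 allowed → instantaneous rise), truncated-normal amplitudes,
  additive Gaussian noise; ground-truth event list returned for scoring.
* **Experiments**: paired control/treatment epochs per recording, with
  between-recording lognormal scale jitter (CV 0.3) and epoch-to-epoch
  lognormal jitter (CV 0.05).  The epoch jitter is essential: without
  within-recording measurement variability a paired design detects *any*
  ratio ≠ 1 at p = 2⁻ⁿ regardless of effect size, and "control changes by
  ≈ 0%" would be vacuous.  Condition presets scale the treatment epoch:
  acute amyloid-β (power ×0.60, half-width ×1.30 via κ re-solved from the
  target circular std, firing ×0.53, PSC amplitude ×0.771), capsaicin
  rescue (all ×1.0), rescue + antagonist (≈ amyloid-β), plus an
  interface-chamber preset (power ×0.358) and a cell-attached preset
  (firing ×1.29, reflecting the recording-configuration-dependent firing
  increase).  Baseline locking is κ = 2 (control FWHM ≈ 1.8 rad) — tighter
  than the ~3.4 rad of the recordings this emulates — because the
  Gaussian-fit half-width estimator loses contrast sensitivity for
  circular std ≳ 1.3 rad; the *ratio* of the half-width effect is
  preserved, the absolute level is not.

What the generator does not emulate: spike waveforms (spike times are
generated directly), theta-gamma nesting and other cross-frequency
structure, non-stationary drift beyond the epoch jitter, correlated noise
between LFP and intracellular channels, electrode artifacts, and true
inter-animal hierarchy (recordings are exchangeable).  Passing closed-loop
tests therefore demonstrates estimator correctness under the stated
statistical structure, not robustness to every pathology of real data.

## Pipeline and determinism

Protocols: `lfp_power_cr` (gamma power + Cr on a 60-s segment per epoch),
`spike_phase` (5-min epochs: power, 1-min-binned firing rate, preferred
angle, half-width, Rayleigh gate), `psc` (1-min-binned event metrics).
Test directions are per metric (reductions one-tailed "less", half-width
"greater"; preferred-angle contrast uses Mann–Whitney, as in the design
this mirrors).  Reports carry per-recording before/after metrics, group
mean ± SEM, per-recording percent changes, test statistics, and the
excluded-recordings list with reasons; serialization sorts keys and uses
repr-exact floats, so identical config + seed reproduces reports
byte-for-byte.  Plots (spectra, spectrograms, polar phase plots, the
triple-cycle phase histogram) are generated artifacts only.

Problem sizes in the shipped tests and acceptance script — 60-s power
segments, 30–300-s phase epochs, 8–10 recordings per condition, 100-seed
calibration loops — are chosen to exercise every code path at the
statistical power the contrasts need while keeping a full run in the
low minutes.

## Known limitations

* The half-width estimator saturates for very dispersed phase
  distributions (circular std ≳ 1.3 rad); comparisons in that regime
  should use the circular standard deviation directly (exposed as
  `circular_std`).
* The PSC detector does not deconvolve: events fused within ~2 ms count
  as one, and decay-time fitting is not implemented (`decay_tau_ms` is a
  placeholder field).
* The RC+Gaussian filter cascade attenuates mid-band amplitudes (see
  above); all shipped analyses are ratio- or phase-based and unaffected.
* ABF/vendor-format import is out of scope; recordings enter as CSV+JSON
  or via the generator.
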