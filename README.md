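# gammakit

Quantitative analysis of hippocampal gamma oscillations and their
pharmacological modulation, for electrophysiologists working with local
field potential (LFP) and patch-clamp recordings from slice preparations
(e.g. kainate-activated CA3).  The package re-implements, as a tested and
reusable pipeline, the measurements used to characterize how amyloid-β
degrades network gamma activity and how TrpV1-receptor agonism rescues it:

* **Gamma band power** — averaged 8192-point Hann periodograms of 60-s LFP
  segments; gamma power = Σ of per-bin power over 20–80 Hz (V²).
* **Coefficient of rhythmicity** — from the ±100 ms autocorrelogram of the
  15–60 Hz band-passed LFP, rescaled to r01 = (r+1)/2:
  **Cr = (α − β)/(α + β)**, with α the second peak and β the first trough;
  Cr ∈ [0, 1], higher = more rhythmic, and 1000/peak-lag cross-checks the
  spectral peak frequency.
* **Spike–field phase coupling** — Hilbert instantaneous phase of the
  20–60 Hz LFP (cycle peak ≡ 0, trough ≡ ±π); per-spike phase angles,
  preferred angle (circular mean), Rayleigh test gate (p < 0.05), and the
  full width at half maximum of a Gaussian fitted to the peak-normalized
  phase histogram — wider firing windows mean desynchronized cells.
* **Synaptic currents** — EPSC/IPSC detection on voltage-clamp traces
  (running-median baseline, threshold + prominence), with amplitude,
  inter-event interval, and charge transfer (∫ baseline-subtracted current)
  in 1-min bins.
* **Group statistics** — exact one-tailed Wilcoxon matched-pairs and
  Mann–Whitney U tests (with n unidirectional pairs the Wilcoxon p is
  exactly 2⁻ⁿ: 0.0313 at n=5, 0.0156 at n=6, 0.0039 at n=8), percent-change
  reporting, and control-window normalization of 1-min time courses.
* **Synthetic data** — a generator that emulates the recordings' structure
  (OU-modulated narrowband gamma + 1/f background, von-Mises phase-locked
  Poisson spikes, PSC trains with ground truth) and condition-level effect
  ratios (acute amyloid-β: power ×0.60, firing ×0.53, half-width ×1.30;
  capsaicin rescue: ×1.0), so every estimator can be validated closed-loop.

## Worked example

Simulate an acute amyloid-β experiment (10 slices, paired control/treatment
epochs) and run the LFP power/rhythmicity protocol:

```bash
gammakit run --condition abeta --protocol lfp_power_cr --n 10 --seed 42 --out report.json
```

prints

```
gamma_power: n=10 p=0.0009766 significant=True
cr: n=10 p=0.0009766 significant=True
```

and `report.json` holds the group summary; for gamma power:

```
n = 10, percent change = 40.3 ± 1.6 % (mean ± SEM),
W = 0.0, one-tailed p = 0.0009765625
```

i.e. the pipeline measures a ~40% gamma-power reduction (the injected
effect ratio is 0.60) and the exact Wilcoxon matched-pairs test returns the
minimal attainable one-tailed p for 10 unidirectional pairs, 2⁻¹⁰.  A
`control` or `abeta_cp` (rescue) run reports a percent change near 0 and
p > 0.05.

The same analyses are available as library calls (`gammakit.power_spectrum`,
`integrated_power`, `coefficient_of_rhythmicity`, `instantaneous_phase`,
`phase_distribution`, `detect_psc`, `wilcoxon_one_tailed`, ...) and as
further CLI subcommands (`power`, `rhythm`, `phase`, `events`, `compare`,
`simulate`) operating on two-column `time_s,value` CSV recordings with a
JSON metadata sidecar.

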