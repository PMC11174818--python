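# Methods

## Cohort model

A study dataset pairs, per subject, a resting recording R (eyes closed,
180 s) and a task recording T (serial subtraction, 60 s) over the 19
monopolar 10–20 channels (Fp1, Fp2, F3, F4, Fz, F7, F8, C3, C4, Cz,
P3, P4, Pz, T3, T4, T5, T6, O1, O2) at 500 samples/s, in microvolts.
This canonical channel order is fixed and indexes every matrix output.
A performance manifest scores each subject by mean correct subtractions
per minute and assigns groups G (good) and B (bad); G\* is the subset of
G with score ≥ 26. The cutoff, not a rank count, defines G\* so the
rule transfers unchanged to synthetic cohorts; on the packaged
reference manifest both definitions coincide (11 subjects, scores
34.59–26). Two subjects flagged excluded in the manifest (short
recordings) never enter analysis, leaving 25 G and 9 B subjects.

EDF ingestion (via `mne`) matches electrode labels case-insensitively
after stripping non-alphanumerics, drops reference/ECG channels, and
converts to µV. Internally cohorts round-trip through per-recording
compressed arrays plus a manifest CSV.

## Band filtering

Theta, alpha and beta are half-open intervals [4, 8), [8, 13) and
[13, 30) Hz — the printed band edges are shared, and the half-open
convention removes double counting (8 Hz belongs to alpha, 13 Hz to
beta). Each band-pass is a Butterworth design of total order 20,
realized as ten cascaded second-order sections; a direct-form
realization of this order is numerically unstable, while the SOS
cascade keeps all poles strictly inside the unit circle. The
maximally flat passband leaves peak magnitudes unbiased. The design
contract, checked analytically from the coefficients in the test
suite, is ≤ 1 dB deviation at the band's geometric center and ≥ 40 dB
attenuation one octave outside each edge (the realized designs exceed
100 dB there).

Filtering is causal single-pass, not zero-phase: both criteria depend
only on magnitudes, so phase is immaterial, and a causal filter matches
online use. The first `settle_s` seconds (default 2 s) of filter output
are flagged as start-up transient and excluded from correlation and
spectral computations. The step-response residual of the narrow theta
band is about 1 % of the input amplitude at 2 s and continues to decay
exponentially; this residual is negligible against in-band signal
content. Filter specifications serialize to JSON (family, order, band
edges, rate) for bit-reproducible reruns.

## Spectral peaks

The spectrum estimator is a single full-length DFT with rectangular
window, one-sided, with amplitude normalization 2/N on interior bins
(1/N at DC and Nyquist). A sinusoid with an integer number of periods
in the window then yields exactly its amplitude at its bin, for any
window length. The length invariance is essential: resting (≈178 s
after transient removal) and task (≈58 s) spectra are compared on one
axis, and an unnormalized comparison would be confounded by length. No
Welch averaging or tapering is applied — peak magnitude, not spectral
density, is the feature. The per-band peak is the maximum magnitude
over bins with f_low ≤ f < f_high, ties broken toward the lowest
frequency; the search is restricted to the filtered signal's own band,
ignoring out-of-band leakage residue.

## Range-limit classification

For each (channel, band, group), the per-subject peak magnitudes in R
and in T form two closed intervals [min, max]. The pair discriminates
when the intervals are disjoint; a shared endpoint counts as overlap.
Subject statuses use the group-referenced rules with inclusive
comparisons: FP if a subject's task value ≤ max over **all** resting
values, FN if a resting value ≥ min over **all** task values, TP =
n − FN, TN = n − FP. Consequently FP = FN = 0 exactly when the task
interval lies strictly above the resting interval — the expected
orientation, since task spectral peaks exceed resting ones in the
discriminating bands. A disjoint configuration with the ranges in the
*opposite* orientation would instead yield FP = FN = n; the
classification rules are deliberately one-sided. Group medians are
reported alongside the ranges but play no role in the decision; no
partial-overlap tolerance is applied — disjointness is binary.

## Performance measures

Accuracy = (TP+TN)/(TP+FP+TN+FN), precision = TP/(TP+FP), F1 =
2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), and MCC =
(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with percentages on
[0, 100]. Specificity has two modes: the default `table_consistent`
uses the standard TN/(TN+FP) (under which specificity reduces to
100·(n−FP)/n, consistent with all reconciled reference values); the
alternative `paper_literal` mode applies TN/(TN+FN) as printed in the
source formulation. Any zero denominator yields NaN with a logged
reason, never a silent 0; sklearn's zero-division conventions for MCC
are therefore not reproduced, and tests compare only where the defining
denominator is nonzero. Display rounding is integer percentages and
two-decimal MCC; stored values are full precision.

## Correlation discrimination

The Pearson coefficient is evaluated with population standard
deviations (divisor n), exactly as the defining sum; the divisors
cancel, so it agrees with the sample coefficient. All 171 unordered
pairs are computed per subject, state and signal type (raw plus three
bands). A constant channel has no defined correlation: such pairs are
recorded as NaN with a warning and excluded from counts rather than
treated as zero, since a constant channel carries no connectivity
information.

The conjugate conditions use strict inequalities (a value equal to the
threshold satisfies neither). Count matrices are 19×19 symmetric with
empty diagonal. Pair ranking maximizes |N ∩ M| with ties broken by
canonical pair order; confidence is 100·|N ∩ M|/group size. The
threshold sweep counts, per signal type and threshold, the pairs whose
subject count reaches a configurable minimum (default ≥ 1 subject);
the counting criterion is a reporting choice and is recorded in the
run's provenance block. Raw-signal correlations use the unfiltered
acquisition-band series.

## Synthetic cohorts

The generator reproduces exactly the second-order structure the
analysis measures, with every controlled quantity recorded as ground
truth:

* **Spectral peaks** are set by one sinusoid per (channel, band, state)
  whose amplitude is drawn uniformly from a configurable range
  (designated discriminative channels: task 8–10 µV vs. resting
  1–2 µV; everything else 1–2 µV in both states). Sinusoid frequencies
  snap to the 0.5 Hz grid nearest each band's geometric center (theta
  5.5, alpha 10.0, beta 19.5 Hz), so any analysis window spanning an
  even integer number of seconds contains an integer number of periods
  and the closed-form peak magnitude (peak = drawn amplitude) is exact
  under the default 2 s transient discard.
* **Pair correlations** are set per (band, state) through a 19×19
  target correlation matrix — designated pairs (default: F4–F7 and
  F3–F8 in beta, resting 0.9 vs. task 0.1) over a uniform 0.3
  baseline — applied by the (eigenvalue-clipped) Cholesky factor to
  band-limited unit-variance noises. Band-limited noise is white noise
  passed through the same order-20 band-pass used by the analysis, so
  generator and analyzer agree on band definitions by construction.
  Each channel's per-band noise has standard deviation 3 µV, a
  realistic band-limited EEG background scale that keeps designated
  resting correlations above 0.5 after dilution by the sinusoidal and
  white-noise components.
* **White measurement noise** of 1 µV standard deviation is added.
* **Manifest scores** are drawn uniformly within group intervals
  matching the reference cohort's reported statistics (G: 21 ± 7.4,
  B: 7 ± 3.6 operations/min), with configurable G/B and G\* fractions
  defaulting to the reference proportions (25/34 and 11/25).

Defaults are the study conditions: 500 samples/s, 180 s resting, 60 s
task, 34 subjects. Tests run reduced configurations (typically 250 or
125 samples/s and windows of a few tens of seconds) passed explicitly
to `SynthSpec`; the acceptance script runs an 11-subject cohort at the
full default conditions.

Two realism limits matter when interpreting passing tests. First, only
second-order structure is emulated — no 1/f background, artifacts, or
nonstationarity — so perfect synthetic recovery does not bound
performance on real recordings. Second, the band components are
band-limited by IIR filtering and so retain spectral skirts: adjacent
bands leak a few percent of variance into each analysis window,
diluting realized cross-channel correlations slightly below their
targets (the strict mixing identity a²/(a²+b²) = ρ is exact for the
isolated two-series generator). Noise-floor peak magnitudes are also
window-length dependent (≈ 2σ/√N per bin), which is why null-effect
checks use sinusoid-dominated spectra.

## Numerical and degenerate-input choices

Pearson values are clipped to [−1, 1] against round-off; empty
selections, incomplete cohorts (a subject missing one state), duplicate
manifest ids, negative scores, rate mismatches and Nyquist-violating
band edges all raise typed errors naming the offending element.
Pipeline outputs are deterministic given the seed: rerunning a
configuration reproduces every analysis CSV byte for byte. Each run
writes a provenance block (config hash, seed, and the exercised
choices: filter family/order/phase, spectrum normalization, band-edge
convention, specificity mode, pair-counting criterion, G\* cutoff).

## Problem sizes

The default test suite uses cohorts of 2–14 subjects at 125–500
samples/s with recordings of 2–40 s, chosen so every property is
exercised at desk scale; the acceptance script's cohort is 11 subjects
at the full 500 Hz / 180 s / 60 s conditions. Monte-Carlo checks use
200–300 replicates; null-effect disjointness is checked over 20 seeds.

## Known limitations

* Real-database reproduction requires downloading the public EDF
  recordings; absolute peak magnitudes depend on the chosen
  normalization and are comparable only within this package's own
  convention.
* The FP/FN rules are group-referenced and one-sided (task above
  resting); cohorts where mental load *lowers* spectral peaks would
  need the orientation reversed.
* With very small groups (n ≤ 3, e.g. G\* within a 10-subject synthetic
  cohort) range disjointness arises by chance with non-trivial
  probability; discriminator lists for such groups should be read
  accordingly.
* The threshold-sweep pair-counting criterion is a reporting
  convention (≥ k subjects), configurable because the underlying
  reporting rule is ambiguous; comparisons across runs should fix it.
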