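# Methods

This note documents the models, defaults and numerical choices behind
`hipponav`, and what the synthetic benchmark does and does not establish.

## Behavioural simulator

The virtual-driving task is modelled at the level that matters for speed
decoding: the speed trajectory. A three-state Markov key-press policy
(accelerate / coast / turn) with exponential dwell times (means 4, 2 and
1.5 s) drives first-order kinematics on a 0.05-s grid:

- accelerating: dv/dt = +`accel` (default 10 units/s²), clipped at `v_max`
  (50 units/s);
- otherwise: dv/dt = −`friction` (5 units/s²), clipped at 0;
- turning above `v_tip` (35 units/s) risks a tip-over with hazard 0.5/s,
  which zeroes the speed for `tip_delay_s` (2 s) — the mechanism that makes a
  driver regulate speed and guarantees time in the slow bins.

The policy is a stand-in for a human player, whose key presses no model
reproduces; the dwell means were chosen once so that a default 652-s session
occupies every 10-units/s speed bin with at least a few percent of its time
(seed 1: 25/9/11/11/43%). The number of accelerate key presses does not scale
with speed, mirroring the task's hold-to-accelerate control.

## sEEG generative model

Each channel is

```
x_c(t) = σ·pink(t) + a_θ (1 + g_θ v(t)/v_max) sin(2π f_θ,c t + φ_c)
                   + a_γ (1 + g_γ v(t)/v_max) sin(2π f_γ,c t + ψ_c)
```

with per-channel carrier frequencies drawn uniformly from 4–8 Hz and
60–90 Hz, phases uniform, and v(t) the behavioural speed linearly
interpolated onto the 1024-Hz grid. `pink(t)` is unit-variance 1/f-power
noise synthesized by spectral shaping (amplitude ∝ f^(−1/2), random phases,
zero DC), matching the broadband background of field potentials without
fitting an autoregressive model. Defaults: a_θ = 1.0, a_γ = 0.3,
g_θ = g_γ = 0.5, σ = 1.0. The carriers are fixed-frequency sinusoids so the
band envelopes are analytically checkable.

Two caveats bound what the benchmark shows. First, the coupling gains are
free parameters, not estimates of human hippocampal physiology; no published
quantitative speed–power coupling exists to calibrate them. With the default
amplitudes the theta-band SNR is far higher than in patient data, so coupled
sessions saturate near AUC 1.0 — the benchmark validates machinery
(calibration, recovery, monotonicity, bookkeeping), not attainable clinical
effect sizes. Second, the generator omits epileptiform artifacts, line noise,
non-stationarities and behaviour-correlated confounds (e.g. turning
intensity) present in real recordings; passing tests therefore says nothing
about decoding accuracy on patients.

## Feature pipeline

Order is fixed and pinned by tests: per-channel linear detrend → band-pass →
Hilbert envelope → 1-s windows with 0.5-s hop (window means of envelope and
of speed; only complete half-open windows [t, t+1) kept, so T seconds yield
⌊(T−1)/0.5⌋+1 windows) → natural log (guard ε = 1e−12) → per-column z-score
(sample SD, n−1) across all windows of the session.

The band filter is a 4th-order Butterworth **band-pass** applied forward and
reverse (zero phase, effective order 8) with reflected edge padding; the
envelope is the magnitude of the analytic signal (FFT Hilbert transform,
zero-padded to a fast length). A pure 6-Hz tone recovers its amplitude within
2% over the central 80% of a 10-s signal; a 30-Hz tone leaks under 0.5% — the
numerically verified stop-band of this design. Non-hippocampal channels are
excluded before feature extraction; feature count is 2 × hippocampal
channels.

Z-scoring spans the whole session and therefore precedes the
cross-validation split. This matches the analysis being reproduced; because
the transform is per-column affine and AUC is rank-based, it cannot by itself
create class information, but users wanting strict fold hygiene can normalize
within training folds themselves.

## Labelling

- *Extreme deciles*: exactly ⌊0.1·N⌋ slowest and fastest windows, ranked by
  window-mean speed, ties broken toward earlier windows; classes are exactly
  balanced and the selection is invariant to monotone transforms of speed.
  With massively tied speeds the classes are filled in time order and a
  warning is logged.
- *Bins*: five 10-units/s bins, half-open except the top bin closed at 50;
  every unordered pair of populated bins (≥ 2 windows each) is one binary
  task with natural, unbalanced sizes — AUC is prevalence-insensitive and
  LDA tolerates imbalance.

## Decoder

Two-class LDA with the pooled within-class covariance S = Z'Z/n computed on
class-centered rows, shrunk toward the scaled identity ν·I (ν = tr(S)/p) by
the closed-form Ledoit–Wolf intensity λ = min(b², d²)/d², where
d² = ‖S−νI‖²_F and b² = n⁻² Σᵢ ‖zᵢzᵢ'−S‖²_F. λ is parameter-free, lies in
[0, 1], matches an independent brute-force implementation to 1e−10 and
sklearn's estimator to 1e−10, vanishes for well-sampled anisotropic data,
and keeps Σ̂ invertible even with duplicated features. Weights
w = Σ̂⁻¹(μ₁−μ₀), threshold b = w·(μ₀+μ₁)/2 (equal priors — the decile task
is balanced and AUC ignores the threshold).

Cross-validation is stratified 10-fold with seeded shuffling; each sample is
scored exactly once out-of-fold, and one ROC/AUC is computed from the pooled
scores by a tie-grouping threshold sweep whose trapezoidal area equals the
Mann–Whitney statistic exactly.

**Fold policy matters.** With temporally autocorrelated features,
interleaved random folds let the decoder exploit windows adjacent to its
training data; on zero-coupling sessions this inflates the *absolute* null
AUC to ≈ 0.62. The alternative `folds="contiguous"` (temporally blocked CV)
suppresses the leakage (null mean ≈ 0.47, the mild pessimism typical of
blocked CV). The default remains stratified, matching the analysis being
reproduced; either way the permutation test below is calibrated, because the
null distribution is built with the identical pipeline — absolute AUCs
should be read against the permutation null, not against 0.5.

## Permutation inference

Surrogates rotate the windowed speed sequence by an offset drawn uniformly
from {20, …, N−20} (the 20-window ≈ 10-s guard exceeds plausible envelope
autocorrelation), then re-derive labels and re-run the full cross-validated
decoder with the same fold seed, so only the neural–behaviour alignment is
broken. Shifting the speeds (not post-hoc labels) preserves the label
sequence's run-length structure; the same offset applies to all tasks within
one permutation, preserving cross-task dependence for maxT. Defaults: 1000
permutations; add-one p-values p = (1+#{null ≥ obs})/(1+B), which never
return zero; family-wise correction via the permutation maxima (maxT),
order-invariant and dominating the raw p-values. The default test is
one-sided (above-chance decoding); a two-sided option assesses both tails
against max/min-T and doubles the smaller tail probability. The gap–accuracy
pattern across pairwise tasks is a Pearson correlation with the t-transform
p-value at n−2 degrees of freedom.

Calibration was verified by Monte Carlo: over 200 zero-coupling sessions the
decile-task significance rate at α = 0.05 falls inside the binomial band
[0.01, 0.09], and over 20 coupled sessions (g_θ = 0.5) every session is
flagged significant with mean AUC ≈ 1, monotone in the gain.

## Problem sizes in the test suite

Monte-Carlo properties use deliberately compact study sizes chosen once:
calibration uses 180-s, 6-channel sessions with 200 permutations; recovery
and monotonicity use 300-s, 8-channel sessions; the gap–accuracy check uses
one full default session. The calibration property is size-invariant by
construction (the null is self-referential), and the recovery margins are
enormous at the default SNR, so the compact sizes do not weaken the checks.

## Degenerate inputs and tie-breaks

Zero-variance feature columns abort normalization with the column named;
singular covariance is only possible at λ = 0 and raises with advice; decile
selection requires ⌊fraction·N⌋ ≥ 1 and 2⌊fraction·N⌋ ≤ N; fold counts are
reduced (with a warning) when the smaller class has fewer than k samples;
bins with fewer than two windows are skipped from the pairwise family with a
warning. All writers emit byte-deterministic text (17-significant-digit
floats, fixed key order), and the end-to-end pipeline is a pure function of
its config: stage seeds are derived by hashing (run seed, stage name).
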