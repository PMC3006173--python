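# Methods

## Problem and model

The decoder recovers the target direction of a center-out arm movement
(8 classes, 45° apart) from trial-epoched multichannel LFP. Its central
assumption is that direction is encoded in the *spatial correlation
structure* of the signal — the covariance between channels — rather
than in single-channel amplitudes, and that this structure varies
smoothly with direction (neighboring targets have similar covariance
patterns). Two sub-bands carry the information: the delta band
(0.3–4 Hz raw amplitude), whose inter-channel covariance is
direction-dependent, and the upper gamma band (48–200 Hz), whose
envelope gain is direction-tuned per channel.

## Preprocessing

Pipeline order per trial: mean removal → (1 kHz only) 220 Hz low-pass
and decimation to 500 Hz → band-pass → envelope (all bands above delta)
→ 30 Hz anti-alias low-pass → decimation to 100 Hz. All filters are
linear-phase FIR (Blackman window), applied forward only with the
output advanced by N/2 samples; the band-pass therefore leaves
passband components phase-aligned with the input while using each
sample only once (causal hardware chains can apply the same filters).

**Filter orders.** The window method puts −6 dB exactly on the cutoff
at any order, so the order only sets the transition width. Defaults at
the 500 Hz working rate: 744 taps (delta), 500 (4–10 Hz), 700 (14–22
and 22–30 Hz), 300 (48–200 Hz). These satisfy the −6 dB ± 0.05 cutoff
and unity-midband contracts everywhere except the 0.3 Hz lower delta
edge, which would require ~14 000 taps — longer than any trial epoch.
That edge is deliberately left soft: the recording chain's hardware
high-pass and the per-trial mean removal already suppress energy below
0.3 Hz. When no explicit order is given, the main-lobe rule
N = ceil_even(5.5·fs/Δf) with Δf = min(high−low, max(0.2·low, 2 Hz))
applies.

**Edges.** Trials are zero-padded for the forward pass; the first and
last N/2 samples of each stage are transient-contaminated. The summed
transient half-width is recorded on each band tensor (`edge_ms`,
≈ 0.9 s for the delta band) so feature windows can avoid it; the
default peri-movement window (0–1000 ms) stays clear of it because the
simulated epoch includes the task's 800 ms post-movement hold.

**Time–frequency maps** use a trial-averaged spectrogram (256 ms Hann
windows, 75 % overlap), expressed as percent power change against the
mean baseline power per frequency.

## CSP features

For a binary contrast, per-trial channel covariances over the analysis
window (sample covariance, ddof = 1) are trace-normalized — removing
trial-to-trial global amplitude — averaged per side, and optionally
shrunk toward the scaled identity, (1−γ)Σ + γ(trΣ/C)I. Shrinkage
defaults to γ = 0.05 when the channel count exceeds the smaller side's
trial count (rank-deficiency regime), else 0. The spatial filters
solve Σ₁w = λ(Σ₁+Σ₂)w via `scipy.linalg.eigh`; eigenvalues are the
fraction of composite variance captured by class 1 and lie in [0, 1];
columns are scaled so Wᵀ(Σ₁+Σ₂)W = I and sign-fixed (largest-magnitude
element positive) for backend-independent determinism. Features are
log var(wᵀX) for the m = 3 largest and m = 3 smallest eigenvectors;
since var(wᵀX) = wᵀΣw at matching ddof, the implementation evaluates
features directly on precomputed trial covariances, applying the same
γ there, which also keeps filters that fall in the null space of a
rank-deficient trial covariance (e.g. duplicated channels in resampled
subsets) finite.

## Classifier bank and ECOC fusion

Contrasts for even K: all K(K−1)/2 unordered pairs, then every
contiguous arc of 2..K/2 directions versus its diametric opposite,
a contrast and its side-swap counted once — 28 + 12 = 40 for K = 8.
Group contrasts pool their member directions' trials; trials outside a
contrast are excluded (CSP is strictly binary). Each contrast gets one
CSP model per band and a single Fisher discriminant on the concatenated
features (6 per band), with within-class covariance shrinkage
γ_FLD = 0.1 (12-dimensional features on tens of trials need
conditioning). The margin convention is wᵀf − b > 0 toward the
positive set; the code matrix has +1/−1/0 accordingly, class scores
are s = −My and the decision is argmin s with ties broken toward the
lowest class index. Margins are used raw: soft decoding dominates hard
Hamming decoding and degrades gracefully. With oracle margins (±1 per
the code row) every class decodes correctly — a pure property of M
that the tests verify exhaustively.

## Evaluation protocol

10 repetitions of stratified 10-fold cross-validation; the whole
pipeline, CSP fitting included, is refit inside every fold and every
sliding-window position, so no spatial statistics leak from test
trials. Decoding power is pooled over all fold × repetition
predictions (trace of the accumulated confusion matrix over its sum);
ρ_T is the mean of per-fold Fisher–Lee circular correlations. A
constant predicted-angle sequence makes ρ_T undefined; it is returned
as 0 with a degeneracy flag so sweep series remain plottable.
Comparisons and confidence intervals use the Nadeau–Bengio corrected
resampled t-test: Var(mean) = σ̂²(1/J + n_test/n_train), df = J−1,
with J = folds × repetitions. Delay-period information is tested by
summing per-fold ρ_T over the sweep positions whose windows end inside
the delay interval and testing the sum against zero with the same
correction.

Sliding-window protocols: cue-aligned 500 ms windows stepping 100 ms
from −500 ms to windows ending at +1200 ms; movement-aligned 1000 ms
windows from −1400 ms to windows ending at +1000 ms. Positions are
derived from start/step/end and however many result are reported. The
rate of change is the first difference of ρ_T per 100 ms; its summary
reports the peak and the first post-peak time below half peak (None
for non-decaying series).

Channel-subset curves resample channels **with replacement** (the
resulting duplicate-channel degeneracies are handled by the shrinkage
path above, enforced at γ ≥ 0.05); trial-subset curves keep class
balance. Cross-session transfer fits once on pooled training sessions
and evaluates once on pooled held-out sessions, requiring identical
usable-channel sets.

## Spike decoding

Sorted spike times are binned at 2 ms, giving 500 Hz count series that
enter the identical sub-band pipeline (same bands, same envelope rule)
with units in place of channels. The baseline is a multi-class LDA
with covariance shrinkage toward scaled identity (γ = 0.5 default;
`sklearn` lsqr solver) on per-unit counts in 200 ms windows stepped by
100 ms. Both routes are reported; no ordering between them is asserted
— which wins depends on unit count and trial budget.

## Synthetic sessions

The generator plants exactly the structure the decoder assumes, with
effect sizes as explicit knobs:

- **Delta**: J = 6 band-limited (0.3–4 Hz) unit-variance Gaussian
  sources mixed into C channels by A(θ,t) = (1−e·r(t))A₀ +
  e·r(t)·Σₚ vM(θ; φₚ, κ)Aₚ — a von Mises-weighted (κ = 2) blend of
  8 fixed random patterns, so the channel covariance varies smoothly
  and 360°-periodically with direction; e = `delta_effect` = 0.8.
- **Gamma**: independent 48–200 Hz carriers per channel with gain
  b_c(1 + `gamma_depth`·cos(θ−φ_c)·r(t)), b_c ~ U(0.5, 1),
  `gamma_depth` = 0.5.
- **Ramp** r(t): 0 through the 800 ms baseline, `delay_leak` (= 0.3)
  from cue onset through the delay, rising linearly over the last
  300 ms of the delay to 1 at movement onset, 1 through movement and
  hold. Both planted effects follow it, making the information onset a
  controllable ground truth.
- **Noise**: spatially correlated pink noise (common fraction 0.3) of
  SD `noise_sigma` = 2.5, plus an optional 60 Hz tone on chosen
  channels for exercising the line-noise screen.
- **Spikes**: inhomogeneous Poisson, rate
  base·(1 + mod·cos(θ−θ_pref))·r(t), θ_pref uniform; times drawn by
  inverting the cumulative rate.

Epoch timing follows the instructed-delay task (800 baseline / 600 cue
/ 900 delay / 1000 movement / 800 hold ms at 1 kHz; t = 0 at movement
onset). The default geometry is 32 channels and 40 trials per class —
past the knee of the channel-count curve while desk-scale. The noise
level was fixed once so that the standard configuration decodes in the
realistic high-accuracy regime (cross-validated DP ≈ 0.85–0.92, ρ_T ≈
0.91–0.95, errors overwhelmingly on adjacent directions) rather than
saturating at DP = 1, which would hide the adjacency structure.

What the generator does **not** emulate: volume conduction and laminar
source geometry, non-Gaussian artifacts, behavioral variability in
epoch durations (trials are time-locked and equal length), electrode
loss, and any amplitude nonstationarity other than the structured
drift option. Passing recovery tests therefore shows the pipeline
correctly exploits direction-dependent covariance and envelope tuning
under realistic noise — not that real cortical recordings meet those
assumptions.

Session drift jitters the mixing-pattern phases and gamma gains by
Gaussian SD `drift` per (seed, session index); session 0 is the
undrifted reference, and trial noise is independent across sessions
regardless. All outputs are bit-reproducible from the seed.

## Numerical choices and degenerate inputs

- Sample variance/covariance use ddof = 1 throughout, keeping the
  covariance and projection routes exactly equal.
- Generalized eigenvalues are clipped to [0, 1] against rounding;
  a singular composite covariance raises an error advising shrinkage.
- FLD falls back to least squares if the shrunk within-class
  covariance is still singular.
- Zero-variance corrected-t denominators (up to fp rounding) return
  t = 0, p = 1 for zero mean difference and ±inf, p = 0 otherwise.
- Windows are validated against the epoch and must hold ≥ 2 samples;
  sweep errors name the offending window position.
- Ties in ECOC scores resolve to the lowest class index.

## Problem sizes

Default test and example workloads use the 32-channel, 40-trials/class
session for end-to-end checks (10×10 CV ≈ 25 s on one core thanks to
covariance-domain feature evaluation) and 12–16-channel,
10–15-trials/class sessions for structural tests; sweeps in tests use
2–3 repetitions, which leaves the corrected t-test with J = 20–30
scores. These sizes are the package's own defaults for desk-scale
verification; all protocols accept larger inputs unchanged.

## Known limitations

- The 0.3 Hz delta edge is not sharply resolved (see Filter orders).
- Multi-class CSP variants (joint diagonalization) and adaptive/
  recursive CSP for trajectory decoding are out of scope.
- No streaming/online mode; the pipeline is trial-epoched.
- ρ_T on 8 discrete angles is a coarse statistic at small n; per-fold
  values at 10-fold test sizes (~32 trials) are noisy, which the
  corrected t-test partially absorbs.
- The line-noise screen is a convenience heuristic (median-broadband
  ratio), not a substitute for inspecting real recordings.
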