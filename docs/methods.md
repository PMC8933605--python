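# Methods notes

This note records the model, the defaults that matter, the numerical
choices, what the synthetic generator does and does not emulate, and the
places where the design was genuinely open.

## Pipeline

Raw epoched recordings (trials × channels × samples, µV, with sampling rate
fs, channel labels and one class label per trial) pass through four fixed
preprocessing steps: common average reference (CAR), analysis-interval
extraction (0-based inclusive sample indices; seconds in configs are
converted by fs and rounded to the nearest sample, so 3.5–7 s at 250 Hz is
876 samples), zero-phase band-pass filtering, and channel selection.  CAR
is computed over all channels present at call time, before any subsetting.

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), per channel per trial.  Zero-phase filtering matters
because the connectivity measure is phase-sensitive; the filter family and
order are a package choice (standard EEG practice).  Band edges follow the
conventional rhythm bands α 8–13, β 13–30, β₁ 13–21, β₂ 21–30 Hz; shared
edges (13 Hz, 21 Hz) belong to both adjacent bands, including in the
spectral grids below.

Caveat: CAR makes a full montage exactly rank-deficient (channels sum to
zero), so the per-trial MVAR regression is singular unless a strict channel
subset is selected afterwards — which is how the method is used on real
montages.  Pipeline configurations that keep every channel should set
`car: false`; the fitting code detects the degeneracy and raises rather
than producing garbage.

## MVAR fitting and order selection

Each trial (per band) is fit with an MVAR(p) model by ordinary least
squares on the stacked lag regression, without an intercept (inputs are CAR
referenced and band-passed, hence zero-mean).  The residual covariance is
the maximum-likelihood (1/T) estimate, consistent with its use inside the
order criterion.  The order is chosen by the Schwarz Bayesian Criterion

    SBC(p) = ln det Σ̂_p + (ln K_eff / K_eff) · N² · p,

with all candidate orders fitted on a common effective span (samples
p_max..K−1) so their criteria are comparable; ties break toward the smaller
order.  `select_order_sbc` scans 1..20 by default.

Within the adaptive search, a single per-band order is needed so the
truncation grid m = 1..p is common across trials.  Default: the median of
per-trial SBC picks; an alternative mode selects on the trial-concatenated
signal.  The search caps the scan at p_max = 5 by default.  Rationale:
zero-phase band-pass filtering leaves an oversampled, nearly deterministic
narrowband signal on which SBC degenerates — the residual determinant keeps
shrinking with order, so the selected order always hits whatever cap is set
(we verified this up to 34 channels) — and fits at large p are dominated by
the common filter dynamics, which makes the truncated spectral
factorization hypersensitive to irrelevant spectral detail.  Orders up to 5
cover the informative range for band-limited epochs while keeping the m
grid meaningful; the cap is a config field (`p_max`) for data that warrant
more.

## DDTF

For a fitted model, the order-m spectral coefficient matrix is

    B^m(f) = −I + Σ_{r=1..m} A(r) e^{−j2πfrΔt},   Δt = 1/fs,  1 ≤ m ≤ p,

with B⁰(f) = −I.  The printed definition of this quantity in the DTF
literature variant we implement is internally inconsistent as published (a
bare −Σ_{r=0..m} with A(0) = I would contradict both B⁰ = −I and the
claimed DTF equivalence at m = p); the convention above satisfies both, and
since it differs from the classical A̅(f) = I − Σ A(r)e^{−jωr} only by a
global sign, every |H|²-derived quantity is identical to the classical DTF
at full order.  This equivalence is enforced by test against an
independently coded DTF oracle (max abs difference < 1e−10).

H^m(f) = [B^m(f)]⁻¹ is computed per frequency on an integer-Hz grid
covering the band inclusive of both edges (the band average divides by
f_high − f_low + 1, i.e. 6/18/9/10 points for α/β/β₁/β₂).  Matrices with
reciprocal condition number below 1e−12 raise a near-singular error naming
the frequency — failing loudly beats emitting garbage flows.  θ² = |H|² is
row-normalized to γ² (each row of γ² sums to 1 by construction) and
averaged over the band grid to the adjacency matrix Ῡ; entry (l, s) is the
flow from channel s to channel l.

Self-terms are retained throughout, exactly as the feature definitions are
written.  A consequence worth stating plainly: with full row normalization
and self-terms included, every inflow is identically 1, so information flow
equals outflow elementwise and the fused 2N-vector carries the outflow
information twice.  This degeneracy is implemented as defined (the
reference analysis does not remark on it); an `exclude_self` flag removes
diagonal terms before normalization for exploration, in which case the
three flow vectors are genuinely distinct.

## Evaluation and the adaptive search

Features are scored by an SVM (RBF kernel, C = 1, variance-scaled
bandwidth) under stratified 10-fold cross-validation repeated 10 times;
repeat r shuffles with seed `seed + r`, and features are z-scored on
training folds only (no leakage).  The reported accuracy is the mean over
repeats.  All randomness flows from the single user seed.

The search runs in two stages: score α and β over every m in 1..p; if the
best α accuracy is at least the best β accuracy, report the α winner and
stop, otherwise also score β₁ and β₂ and report the best of {β, β₁, β₂}.
Within a stage, exact accuracy ties break toward the smaller m and then the
narrower band (fewer grid points, then lower f_low).  The narrow-band
preference is deliberate: the refinement stage exists to localize the
responsive rhythm within β, and a wide band always retains at least the
information of its sub-bands, so on an exact tie the sub-band is the
sharper, equally supported answer.  (A wide-band-first preference makes the
refinement stage unreachable whenever accuracies saturate, which we
observed systematically on clean synthetic data.)

Kappa uses p_e = 0.5 for balanced two-class designs; for unbalanced labels
p_e is computed from squared class proportions, since the 0.5 premise only
holds for equal class counts.  The pooled two-sample t-test uses the
textbook pooled-variance statistic with df = n_a + n_b − 2 and a one-sided
decision (reject when P{T > t} ≤ 0.05); zero pooled variance is handled
explicitly (t = 0, p = 0.5 on equal means; p = 0 on a positive shift).

## Synthetic ground truth

`generate_mvar_epochs` simulates each trial independently from the MVAR
recursion with a discarded burn-in of 10·p samples (removes
initial-condition transients so stationarity holds), Cholesky-correlated
innovations, and class-interleaved trial order (any prefix stays balanced).
Stability is enforced via the companion-matrix spectral radius.

All presets use 4 channels, fs = 250 Hz, 876 samples/trial (the 3.5 s
analysis-window length typical for motor-imagery epochs), unit innovation
variance, and peak directed-coupling gain 0.5.

A design point we measured rather than assumed: a *constant* lag
coefficient is a broadband coupling — its directed-transfer footprint is
substantial in every rhythm band (with a lag-1 coefficient of 0.5 the true
band-averaged flow differs between classes by ≥ 0.27 in all four bands),
so "class-dependent coupling in band X" cannot be realized by a single lag
weight.  The presets therefore shape the coupling as an FIR kernel across
lags: a Hamming-windowed band-pass design convolved with exact unit-circle
notch pairs at the centres of the bands that must stay silent, scaled so
the peak transfer gain is 0.5.  The classification presets
(`alpha_coupling`, `beta2_coupling`) use two independent driver→receiver
pairs whose drivers carry an AR(2) resonance (ρ = 0.9) at the target band
centre; the class label adds/removes the target-band kernel on both edges,
while *both* classes carry nuisance coupling on the same edges in the two
non-target bands, with peak gain re-drawn uniformly per trial and band from
[0, 0.25].  The nuisance is what makes band selection non-trivial: without
it, the wide β band solves the β₂ problem equally well for free.
`direction_flip` is simpler — two 10.5 Hz oscillators (ρ = 0.8) with a
single lag-1 coupling of 0.5 whose direction is the class label — and is
used for direction-recovery checks.

What the generator does *not* emulate: volume conduction/field spread, 1/f
background spectra, artifacts, nonstationarity within a trial, and
electrode-level measurement noise.  Passing tests therefore demonstrate
the correctness of the estimator chain and the band-selection logic on
data satisfying the model's assumptions, not robustness to real-EEG
violations of them.  In particular, on this clean synthetic data the best
truncation order tends to sit at the top of the m grid, whereas on real
motor-imagery recordings the discriminative information concentrates at
m = 1–2; the truncation behaves differently when the fitted model is exact
than when it is an approximation to a non-AR process.

## Problem sizes

Defaults used by the test suite and examples: 50 trials per class, 4
channels, 876 samples, 10×10-fold CV, p_max = 5.  The full suite runs in
well under a minute on one CPU; the end-to-end adaptive search on a preset
takes a few seconds.

## Known limitations

* The CAR/rank interaction described above requires either channel
  subsetting or `car: false`.
* The evaluation assumes exactly two classes (as does the kappa
  convention); multi-class extension is out of scope.
* GDF/EDF ingestion is deliberately not part of the core: the documented
  container (`.npy` + YAML sidecar, or a directory of delimited text
  matrices) is the interface, and an EEG I/O library can be layered on top.
* Time-varying (adaptive/Kalman) MVAR variants, ffDTF/dDTF/partial
  coherence, and non-SVM classifiers are out of scope.
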