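# ddtfnet

Directed brain functional networks from epoched EEG via the **dynamic
directed transfer function (DDTF)**, with network-feature extraction and
SVM evaluation for two-class motor-imagery classification.

## The problem

During motor imagery, spatially distributed cortical areas exchange
information, and the direction and strength of that exchange differs
between imagined tasks (e.g. left vs right hand).  The classical directed
transfer function (DTF) captures this: fit one multivariate autoregressive
(MVAR) model to all channels jointly,

    x(t) = Σ_{r=1..p} A(r) x(t−r) + e(t),

move to the frequency domain via A̅(f) = I − Σ_r A(r) e^{−j2πfrΔt}, invert
it to get the transfer matrix H(f), and read the directed influence of
channel *s* on channel *l* from θ²_{ls}(f) = |H_{ls}(f)|², row-normalized to

    γ²_{ls}(f) = θ²_{ls}(f) / Σ_q θ²_{lq}(f)  ∈ [0, 1].

Two things about motor-imagery EEG make the plain DTF suboptimal: the
responsive rhythm band (α 8–13 Hz, β 13–30 Hz, β₁ 13–21 Hz, β₂ 21–30 Hz)
varies across subjects, and the signal is markedly non-stationary in the
frequency domain.  The DDTF addresses both by (i) truncating the spectral
sum at a *variable* order m ≤ p,

    B^m(f) = −I + Σ_{r=1..m} A(r) e^{−j2πfrΔt},   H^m(f) = [B^m(f)]⁻¹,

and (ii) selecting the band and m per subject by classification accuracy.
At m = p the DDTF coincides exactly with the classical DTF (B differs from
A̅ only by a global sign, which |H|² cannot see).

Band-averaged γ² values form the weighted directed adjacency matrix Ῡ of a
brain functional network (entry (l, s) = flow s → l).  Its row sums
(**inflow**), column sums (**outflow**) and their ratio (**information
flow**) per channel are fused into the feature vector
F = [IF₁..IF_N, OUT₁..OUT_N] ∈ R^{2N}, scored by an RBF-kernel SVM under
10×10-fold cross-validation.  A two-stage search compares α against β and,
only if β wins, refines into β₁/β₂.  Agreement is summarized by Cohen's
kappa k = (p₀ − p_e)/(1 − p_e) with p_e = 0.5 for balanced designs, and
methods are compared by a pooled two-sample t-test.

The package is aimed at BCI / EEG-connectivity researchers who want a
transparent, fully tested reference implementation of this pipeline plus a
ground-truth MVAR simulator to validate it against.

## Worked example

```python
import numpy as np
from ddtfnet import (BANDS, SearchConfig, adaptive_search, bandpass_filter,
                     compute_adjacency, feature_vector, fit_mvar,
                     make_two_class_dataset)

# two classes that differ only in upper-beta-band directed coupling
rec = make_two_class_dataset("beta2_coupling", seed=7, n_trials_per_class=50)

trial = bandpass_filter(rec, BANDS["beta2"]).data[0]
model = fit_mvar(trial, 5); model.fs = rec.fs
am = compute_adjacency(trial, BANDS["beta2"], m=2, model=model,
                       channels=rec.channels)
print(np.array_str(am.values, precision=3, suppress_small=True))

res = adaptive_search(rec, SearchConfig(seed=7))
print(f"best band: {res.best_band}, m = {res.best_m}, "
      f"accuracy = {res.best_accuracy:.2f}%, kappa = {res.kappa:.2f}")
```

prints

```
[[0.974 0.021 0.    0.004]
 [0.014 0.984 0.    0.002]
 [0.003 0.    0.953 0.043]
 [0.001 0.001 0.014 0.985]]
best band: beta2, m = 5, accuracy = 100.00%, kappa = 1.00
```

The adjacency matrix is row-stochastic (each row sums to 1); the visible
off-diagonal mass in row 2 at column 1 (and row 4 at column 3) is the
injected driver→receiver coupling of the preset.  The search scores α and β
first, finds β stronger, refines into β₁/β₂ and reports the upper beta band
— exactly where the preset hides the class difference — at 100 % mean
10×10-fold accuracy (kappa 1.0).

## Command line

The same pipeline is scriptable via the `ddtf` tool:

```sh
ddtf simulate --preset beta2_coupling --seed 7 --out sim
printf 'data: sim\nseed: 7\noutdir: out\ncar: false\n' > cfg.yaml
ddtf search --config cfg.yaml
```

writes `out/results.json` (full accuracy table, best band/m, kappa),
per-trial-averaged adjacency TSVs and the winning feature CSV, every file
stamped with the configuration hash.  `simulate`, `preprocess`,
`connectivity`, `features` and `evaluate` run the individual stages on each
other's files.  Exit codes: 0 success, 2 invalid input/config, 3 numerical
failure.

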