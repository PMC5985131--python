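# Methods

## Signal model and assumptions

The abdominal recording is modelled as a noiseless linear instantaneous
mixture `X = A S` of statistically independent, non-Gaussian sources:
the maternal ECG, the fetal ECG, and broadband electromyographic
activity. The assumptions this rests on — stationary mixing over the
record, at least as many channels as sources, at most one Gaussian
source — are standard for ICA-based fetal ECG extraction. Baseline
wander and sensor noise violate the noiseless assumption, which is why
the pipeline removes the baseline first and why separation quality is
specified separately for noiseless and 40 dB-noise conditions.

After centring, whitening uses the eigendecomposition of the sample
covariance (1/n convention) in the symmetric (ZCA) form
`Z = E D^{-1/2} E^T X̄`. Any whitening matrix is equivalent for ICA up
to a rotation; the symmetric form is used because its transform is easy
to reason about (it is the unique symmetric positive-definite inverse
square root). Eigenvalues below `1e-10 ×` the largest one raise a
rank-deficiency error rather than being silently truncated: a
rank-deficient abdominal montage means a disconnected or duplicated
electrode and should be surfaced, not worked around.

## The fixed-point iteration and its overrelaxed variant

Non-Gaussianity is measured through the negentropy proxy with the
quartic contrast, `g(y) = y³`. Stationary directions satisfy the
Kuhn–Tucker condition `F(w) = E{z g(wᵀz)} − β w = 0` with
`β = E{wᵀz·g(wᵀz)}`; the approximate Newton step on `F` uses the scalar
Jacobian `jf = E{g′(wᵀz)} − β` and simplifies, for white data, to the
conventional update `w ← E{z g(wᵀz)} − E{g′(wᵀz)} w` (normalised).

The accelerated variant chooses an overrelaxation factor once per
component, from the random initial vector: over the grid
`α_k = 1 + k/N` (k = 1..N−1, N = 100), candidates must strictly
decrease the residual of the overrelaxed Newton step,
`‖F(w − α_k Δw)‖² < ‖F(w)‖²` with `Δw = F/jf`, and the admissible
candidate minimising `‖F(w − α_k Δw)‖` wins. The residual (including β)
is fully re-evaluated at each trial point. Two deliberate choices in
degenerate cases: if no candidate is admissible — in particular at an
already-converged point — the factor falls back to `α = 1`, the plain
Newton step; and a residual already at floating-point noise
(`‖F‖ < 1e-12`) short-circuits to the same fallback, since any measured
"decrease" there is round-off. An opt-in flag re-selects α at every
iteration instead of once.

The two-stage update applies α in a predictor and re-evaluates the
derivative expectation at the predicted direction in a corrector:

```
w'  = E{z g(wᵀz)} − α E{g′(wᵀz)} w        (predictor)
w'' = E{z g(wᵀz)} − E{g′(w'ᵀz)} w         (corrector)
w   = w'' / ‖w''‖
```

The predictor is renormalised before the corrector evaluates
`g′(w'ᵀz)`. This is a load-bearing numerical choice: the corrector
coefficient `E{g′(u ᵀz)} = 3‖u‖²` on white data scales quadratically
with the predictor's raw norm, and left unnormalised it dominates the
corrector for spiky (high-kurtosis) sources — the iteration then stalls
at its starting direction and never separates. With the predictor
normalised the iteration is well behaved.

The same identity `E{g′(uᵀz)} = 3` for any unit `u` on exactly-white
data has a second consequence worth stating plainly: the corrector then
coincides with the conventional fixed-point step, so with the cubic
contrast the accelerated and conventional iterations follow identical
trajectories from identical starting vectors. The convergence
comparison in the test suite is therefore expected to show equal — not
strictly smaller — median iteration counts for the accelerated method,
and does. A genuine per-iteration advantage of the overrelaxation
scheme would require a contrast whose derivative expectation is not
fixed by the whitening constraint (e.g. `tanh`), which this package
deliberately does not implement.

Both updates share the remaining machinery: sign-invariant convergence
`min(‖w⁺−w‖, ‖w⁺+w‖) < ε` (fixed points are defined up to sign, and a
±w oscillation must not mask convergence), default `ε = 1e-4` and at
most 1000 iterations per component; Gram–Schmidt deflation against
accepted rows after every update; all expectations are full-sample
means; every random initial vector comes from one seeded generator, and
a degenerate update or singular Jacobian re-randomises the start (up to
5 times per component) before giving up with a partial result.

## QRS detection

Pan–Tompkins with the classic stage chain. Filters are applied
forward–backward (zero phase) so stage delays do not bias R-peak
timing; the moving-window integral is centred for the same reason.
Detected peaks are refined to the extremum of the absolute band-passed
signal within ±40 ms and a refractory period is enforced after
refinement. Two parameter sets:

| parameter          | adult   | fetal    |
|--------------------|---------|----------|
| band-pass          | 5–15 Hz | 10–25 Hz |
| integration window | 150 ms  | 80 ms    |
| refractory         | 200 ms  | 150 ms   |
| search-back threshold | 0.5·T1 | 0.25·T1 |

The fetal set reflects the narrower, faster fetal QRS. Its lower
search-back threshold and the rhythm gate on search-back (a candidate
must lie within ±35% of the running RR average of the predicted
position) exist for the post-cancellation regime: a fetal beat that
coincided with a maternal QRS survives template subtraction with
reduced amplitude, and recovering it without admitting noise peaks
requires both the lower threshold and the positional gate. All
thresholds adapt to running signal/noise estimates, so detection is
invariant to amplitude scaling; squaring makes it polarity-invariant.

## Maternal cancellation and channel selection

The maternal component among the separated sources is the one whose
detected rhythm falls in 40–120 bpm with the smallest RR coefficient of
variation (ties broken by larger kurtosis). Cancellation then operates
on the baseline-corrected *observed* channels, not on the ICA sources:
the maternal beat windows (100 ms before to 150 ms after each R) are
stacked per channel and the rank-2 SVD reconstruction is subtracted
inside each window, with 10 ms raised-cosine cross-fades at the window
edges to avoid subtraction steps. Rank 2 captures the mean maternal
beat plus its dominant mode of variation; windows extending past the
record bounds are dropped and counted. The fetal channel is the
residual channel whose 100–180 bpm beats have the largest eigenvalue
SNR over ±50 ms segments.

Known artefact of these window defaults: the maternal T-wave peak
(~230 ms after R) lies outside the cancellation window, so a T-wave
residual survives in the cancelled channels; and a fetal R-peak within
~15 ms of a maternal R is attenuated by the subtraction (its projection
onto the template subspace is removed with the template). The first is
mostly harmless to detection (the fetal band-pass attenuates T-wave
frequencies); the second is the dominant cause of missed fetal beats
and is intrinsic to beat-aligned template subtraction.

## Evaluation

Beat segments are standardised columns of `U` (zero mean, unit
variance); `SNR_Eig = λ_max/(Σλ − λ_max)` over eigenvalues of `UᵀU`,
`SNR_RMS = η/(1−η)` where η is the mean pairwise inner product of the
additionally unit-norm columns — i.e. a mean Pearson correlation, a
normalisation chosen so η is scale-free. Rank-one segment sets return
an infinity sentinel; non-positive η floors the SNR at 0 with a
warning. Beat matching is greedy nearest-neighbour one-to-one within
±50 ms (a common fetal-QRS tolerance), and Sens/PPA/F1 are reported as
percentages rounded to two decimals. The Amari index of `W · A_white`
(normalised to [0, 1], zero iff a scaled permutation) is the
separation-quality oracle used in tests, where the true mixing is
known.

## The synthetic generator

`synth_ecg` builds each ECG source as a sum of per-beat Gaussian P, Q,
R, S, T templates placed at RR intervals `60/hr × (1 + jitter)` with
Gaussian jitter (default 3%), so R-peak ground truth is exact by
construction. Defaults emulate the labour-monitoring setting: 1 kHz
sampling, 60 s records, maternal 80 bpm with adult wave widths, fetal
140 bpm with ~55%-scaled widths, maternal-to-fetal peak-to-peak ratio
4.5 at the strongest channel (per-channel spread ×0.8–1.25, keeping
every channel inside the physiological 2–10 range), four channels.
The two remaining mixed sources are white Laplace "EMG" noise:
super-Gaussian, as surface EMG is, which keeps the square mixing
identifiable and a clean record full-rank. After mixing, each channel
receives white sensor noise (σ = 0.02), 0.3 Hz sinusoidal baseline
wander (amplitude 0.5, comparable to the fetal ECG), and optionally a
powerline tone (off by default). Everything is reproducible bit-exactly
from the seed.

What the generator does **not** model: electrode-motion artefacts,
uterine EMG bursts, time-varying mixing (fetal movement), morphological
variability beyond Gaussian-template shape, and rhythm pathologies.
Passing tests therefore demonstrate correctness of the algorithms under
the stationary linear-mixture model, not clinical performance on labour
records.

## Problem sizes used in the test suite

Separation-quality checks run 100 seeded 20 s, 4-channel mixtures per
method and noise level; the end-to-end recovery check runs 50 seeded
60 s records; the convergence comparison runs 100 paired random
initialisations on one 60 s record; unit-level fixed-point checks use a
200 000-sample two-source mixture, where the empirical fixed point sits
within O(1/√n) of the population one. The acceptance script uses the
10-repeat benchmark protocol on one 60 s record plus 10 further seeded
records pooled for detection statistics.

## Known limitations

* With the cubic contrast the overrelaxation machinery cannot improve
  per-iteration convergence (see above); it is retained for fidelity to
  the two-stage scheme and becomes meaningful only under contrasts with
  data-dependent derivative expectations.
* Template cancellation attenuates fetal beats coincident with maternal
  R-peaks; sensitivity on records with rational rate ratios (locked
  rhythms) would degrade.
* WFDB and EDF containers require external readers (`wfdb`,
  `pyedflib`); the package's own interchange format is CSV.
* The maternal/fetal rate bands (40–120 / 100–180 bpm) overlap in
  100–120 bpm; a maternal rhythm in that range could in principle be
  claimed as fetal if the true fetal component were absent — the
  maternal component is selected first and its channel-space waveform
  cancelled, which in practice resolves the ambiguity.
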