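# fetalica

Noninvasive fetal electrocardiography: a pregnant patient's abdominal
electrodes record a mixture in which the maternal ECG is 2–10 times
larger than the fetal one, on top of baseline wander, muscle noise and
mains interference. `fetalica` extracts the fetal ECG and its R-peaks
from such multichannel abdominal recordings, for researchers and
engineers working on fetal heart-rate monitoring.

## Method

The observed channels are modelled as a linear instantaneous mixture
`X = A S` of independent sources. The pipeline runs, in order:

1. **Baseline removal** — each channel's baseline is estimated with a
   3rd-order 5 Hz low-pass Butterworth filter (applied forward–backward,
   zero phase) and subtracted.
2. **Centring and PCA whitening** — `Z = E D^{-1/2} E^T X̄`, where `E`,
   `D` are the eigenvectors/eigenvalues of the sample covariance.
3. **Deflationary FastICA** — each unmixing direction `w` maximises the
   non-Gaussianity of `y = wᵀz` via the fixed-point iteration with the
   cubic nonlinearity `g(y) = y³`:

   `w ← E{z g(wᵀz)} − E{g′(wᵀz)} w`, `w ← w/‖w‖`,

   with sign-invariant convergence `min(‖w⁺−w‖, ‖w⁺+w‖) < ε` and
   Gram–Schmidt deflation between components. An accelerated variant
   selects an overrelaxation factor `α ∈ (1, 2)` by grid search
   (`α_k = 1 + k/N`, `N = 100`) minimising the Kuhn–Tucker residual
   `‖F(w − α Δw)‖` of the overrelaxed Newton step, then iterates a
   two-stage predictor/corrector update.
4. **Maternal R-peak detection** — Pan–Tompkins (band-pass, derivative,
   squaring, moving-window integration, adaptive dual thresholds with
   rhythm-gated search-back) on the separated component with the most
   regular rhythm in the 40–120 bpm band.
5. **SVD template cancellation** — windows around every maternal R-peak
   are stacked per channel; the rank-2 SVD reconstruction (the coherent
   maternal waveform) is subtracted inside each window.
6. **Fetal channel selection and detection** — the residual channel
   whose 100–180 bpm beats are most self-consistent (largest eigenvalue
   SNR) yields the fetal signal and R-peaks.

Extraction quality is scored by two beat-consistency SNRs on the matrix
`U` of standardised beat segments — `SNR_Eig = λ_max/(Σλ − λ_max)` over
eigenvalues of `UᵀU`, and `SNR_RMS = η/(1−η)` with `η` the mean pairwise
segment correlation — and by beat-detection `Sens`, `PPA` and `F1`
against reference annotations.

A seeded simulator (`fetalica.synthetic`) generates abdominal mixtures
with known mixing matrix and ground-truth maternal/fetal R-peaks, so the
whole pipeline is testable without clinical data.

## Worked example

```sh
fetalica --seed 7 simulate --out rec.csv --truth truth.json
fetalica --seed 7 extract --input rec.csv --out-dir out
fetalica evaluate --fetal out/fetal_signal.csv --reference ref_beats.csv --tol-ms 50
```

The first command writes a 60 s, 4-channel synthetic abdominal record
(maternal 80 bpm, fetal 140 bpm) plus its ground truth; the second runs
the pipeline and prints

```
extracted 140 fetal beats (total ICA iterations 12)
```

i.e. all four sources separated in 12 fixed-point iterations total, and
140 fetal beats found. Evaluating against the ground-truth fetal beats
(`ref_beats.csv` holds the `fetal_beats` of `truth.json` as
`sample_index,time_s` rows) prints

```json
{
  "TP": 139, "FP": 1, "FN": 1,
  "Sens": 99.29, "PPA": 99.29, "F1": 99.29,
  "SNR_Eig": 1.3259, "SNR_RMS": 1.1017
}
```

— 139 of 140 true fetal beats recovered within ±50 ms with one false
detection, and beat-consistency SNRs above 1 (beat energy exceeds
residual noise).

The same flow is available as a library:

```python
from fetalica import PipelineConfig, extract_fecg
from fetalica.synthetic import SynthConfig, synth_abdominal

record = synth_abdominal(SynthConfig(seed=7))
result = extract_fecg(record.recording, PipelineConfig())
print(len(result.fetal_beats), result.separation.total_iterations)
```

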