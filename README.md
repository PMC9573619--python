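# nirsbreath

Respiratory-pattern monitoring from a chest-worn near-infrared spectroscopy
(NIRS) sensor. A NIRS optode on the sternum records oxygenated-hemoglobin
concentration change (ΔO₂Hb, μM) at 10 Hz; respiration and the cardiac pulse
are both visible in that trace. `nirsbreath` turns such recordings into
breath-by-breath respiratory features and classifies the breathing condition
— free baseline breathing, inspiratory-loaded breathing (a dyspnea model) or
rapid-shallow breathing at 25 breaths/min (a tachypnea model) — the
building blocks of a wearable screen for pneumonia-like respiratory
dysfunction.

## Method

For each protocol condition segment of the O₂Hb trace:

1. **Detrend** — fit and subtract a 6th-order least-squares polynomial in
   time, removing slow drifts while leaving the respiratory band intact.
2. **Breath detection** — suppress the ~1 Hz cardiac pulsation with a
   zero-phase low-pass, estimate the average inter-peak distance from a
   first-pass extremum search, re-detect maxima (and minima, on the inverted
   signal) with that distance as the minimum peak separation, then remove
   consecutive same-type extrema so minima and maxima strictly alternate.
3. **Features** — per breath (a consecutive-minima pair): breathing interval
   `Tᵢ = t(minᵢ₊₁) − t(minᵢ)` and breathing depth
   `Dᵢ = O₂Hb(maxᵢ) − O₂Hb(minᵢ)`. Intervals outside the per-participant,
   per-condition band mean ± 1.96·SD are excluded together with their depths
   (95% tolerance band, single pass).
4. **Windows** — features are averaged over non-overlapping 1-minute windows
   (3 per baseline, 5 per 5-minute condition), alongside the window's mean
   raw ΔO₂Hb level ("O₂Hb signal amplitude").
5. **Classification** — a 100-tree random forest (unbounded depth) over the
   three window features, evaluated with 100 stratified random 80:20 splits;
   support-weighted accuracy and F1 are averaged over repeats, and a
   four-row feature-ablation table compares the full triple with each pair.

Because chest-NIRS study data are not openly available, the package includes
a synthetic-waveform generator with known ground truth (breath times,
depths, condition offsets, cardiac pulsation, drift, noise) that emulates
the five-stage protocol: 3 min baseline, then 5 min each of loaded
breathing, recovery, rapid breathing, recovery.

## Worked example

```python
from nirsbreath import CohortConfig, RunConfig, run_pipeline, ablation_summary

cfg = RunConfig(cohort=CohortConfig(n_participants=5, seed=0),
                seed=0, repeats=20)
res = run_pipeline(cfg)
print(res.feature_matrix.head(4).to_string(index=False))
print(ablation_summary(res.ablation).to_string(index=False))
print(res.counts)
```

prints

```
participant condition  window_index  interval_mean_s  depth_mean  o2hb_amplitude    label
        P00  baseline             0         3.500000    0.373644        0.615928 baseline
        P00  baseline             1         3.470588    0.425235        0.598434 baseline
        P00  baseline             2         3.486667    0.392317        0.424460 baseline
        P00    loaded             0         5.820000    1.140091        1.247503 loaded

                       features  weighted_accuracy  f1_score
depth, interval, o2hb_amplitude                1.0       1.0
                depth, interval                1.0       1.0
       interval, o2hb_amplitude                1.0       1.0
          depth, o2hb_amplitude                1.0       1.0

{'breaths_detected': 1972, 'breaths_excluded': 57, 'windows_expected': 115,
 'windows_dropped': 0, 'feature_rows': 65, 'breaths_kept': 1915}
```

Participant P00 breathes freely at ~17 breaths/min (3.5-s intervals, ~0.4 μM
deep); under inspiratory load the intervals lengthen to ~5.8 s and depths
rise to ~1.1 μM, with an elevated O₂Hb level. On this small 5-participant
cohort every feature pairing separates the three conditions almost
perfectly; the hardest pairing (depth + amplitude, without the interval)
only drops below 1.0 on the full 21-participant cohort. About 3% of breaths
fall outside the 95% interval band and are excluded.

The same run is available from the shell:

```sh
nirsbreath simulate --out cohort/ --seed 0          # recordings + ground truth
nirsbreath run --seed 0 --out results/              # full experiment
nirsbreath classify --in results/features.csv --out report.json --seed 0
```

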