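# Methods

## Signal model and scope

The package operates on concentration time series as a continuous-wave NIRS
device exports them: ΔO₂Hb, ΔHHb and ΔTHb in μM change from a session
reference (plus optional TSI in %), uniformly sampled at `fs` (default
10 Hz). Conversion from raw optical intensities (Beer–Lambert), spatially
resolved saturation, and device acquisition are out of scope. The chest
ΔO₂Hb trace is modelled as

    O₂Hb(t) = level(condition) + respiration(t) + cardiac(t) + drift(t) + ε(t)

where respiration is a ~0.2–0.5 Hz oscillation whose period and amplitude
carry the physiological information, cardiac is a ~1 Hz pulsation, drift is
slow and large, and ε is broadband noise. The analysis extracts the
respiratory component per protocol condition and summarises it in 1-minute
windows.

## Segmentation

A protocol schedule is an ordered list of (condition, duration). Segment k
spans samples [round(Σ_{j<k} dⱼ·fs), round(Σ_{j≤k} dⱼ·fs)), half-open, which
partitions the scheduled span without gaps or overlaps even when
duration × fs is not an integer. Indices are 0-based throughout; times are
seconds; concentrations stay in device units (the pipeline never needs
absolute concentration). Rows with non-finite values are dropped and logged
at read time rather than interpolated — downstream peak detection assumes
contiguous sampling, and with 10 Hz data the loss of isolated samples is
negligible next to a ~30-sample breath.

## Detrending

Each condition segment's O₂Hb trace is detrended by fitting a 6th-order
least-squares polynomial in time and subtracting it. The fit uses a time
axis mapped to [−1, 1] (`numpy.polynomial.Polynomial.fit`) because a raw
6th-order Vandermonde system over a 300-s axis is numerically ill
conditioned. Detrending is per segment, not per recording: respiratory
statistics are computed per condition, and a single whole-record fit would
let one condition's trend bleed into another's. Any polynomial of order ≤ 6
is annihilated to < 1e-6 relative amplitude; the respiratory band passes
through essentially unattenuated (a 6th-order polynomial over ≥ 180 s cannot
track a ≥ 0.2 Hz oscillation).

## Breath detection

1. **Cardiac suppression.** A zero-phase (forward–backward) 4th-order
   Butterworth low-pass at 0.8 Hz removes the cardiac pulsation before any
   extremum search. 0.8 Hz sits between the fastest breathing of interest
   (25 breaths/min ≈ 0.42 Hz) and the slowest plausible resting heart rate
   (~50 beats/min ≈ 0.83 Hz); zero-phase filtering keeps extremum positions
   undelayed. This is a detection aid on the already-detrended signal, not a
   replacement for the polynomial detrend. Config `cardiac_cutoff_hz`
   (default 0.8; 0 disables). Without it, cardiac ripple and noise wiggles
   contaminate the spacing estimate and the extremum lists badly enough to
   corrupt the recovered rate on realistic synthetic data.
2. **Spacing estimation.** A first-pass `scipy.signal.find_peaks` with a
   prominence floor of 0.25 × the segment SD (config
   `prominence_sd_fraction`) finds candidate maxima, and minima on the
   negated signal; the mean gap between consecutive same-type extrema is
   the average peak spacing. Fewer than two candidates on both polarities
   raises an "insufficient oscillation" error.
3. **Constrained detection.** The average spacing, multiplied by a safety
   factor κ = 0.5 (config `spacing_multiplier`), is passed as the minimum
   peak separation; among conflicting peaks the higher-amplitude one wins
   (`find_peaks` distance semantics). Halving the spacing prevents
   within-condition rate variability from suppressing genuine breaths. The
   same prominence floor is applied here to reject low-amplitude wiggles
   that happen to clear the separation.
4. **Alternation.** In the time-merged extremum sequence, every run of
   consecutive same-type extrema is reduced to its most extreme member, so
   minima and maxima strictly alternate. The step is idempotent.

Breath amplitudes are read off the cardiac-suppressed working signal that
produced the indices, so indices and values are mutually consistent; reading
the unsmoothed signal at smoothed-signal extrema would add a positively
biased noise term to every depth.

## Features and filtering

One breath per consecutive-minima pair: interval = minima time difference;
depth = value at the unique intervening maximum minus the value at the
starting minimum (non-negative by construction at true extrema). The 95%
exclusion rule is interpreted as a tolerance band on individual breaths:
intervals outside mean ± 1.96·SD (sample SD, n−1; single pass, not iterated)
of the same participant-condition table are excluded along with their
depths. A confidence interval of the *mean* would shrink with n and exclude
nearly every breath on long segments, which cannot be the intent; band
exclusion keys on the interval only, and a zero-SD table excludes nothing.
Tables with fewer than 3 breaths skip filtering with a warning.

"O₂Hb signal amplitude" is the within-window mean of the raw
(non-detrended) ΔO₂Hb — the condition-dependent level shift, which is
deliberately distinct from breathing depth. An alternative definition
(`amplitude_mode="oscillation"`: mean per-breath peak-to-trough on the raw
signal) is provided for sensitivity analysis; `raw_mean` is the default.

Windows are non-overlapping 60-s spans (`window_s`); a segment yields
floor(duration/60) windows and a partial tail is dropped, giving 3 windows
for the 3-min baseline and 5 for each 5-min condition. A breath belongs to
the window containing its starting minimum. Windows with zero surviving
breaths are dropped and logged.

## Classification

A `RandomForestClassifier` with 100 trees and no depth limit is evaluated
over 100 repeats of a random 80:20 row split. Splits are stratified by class
(config `stratify`, default true): with 13 windows per participant an
unstratified 20% fold can occasionally lose a class outright. Row-wise
splitting matches the repeated-random-partition design; participant-grouped
splitting (`group_by_participant`) is available and recommended for real
cohorts, since row-wise splits let windows from one subject appear on both
sides (an optimistic-bias caveat documented here deliberately). The master
seed expands to per-repeat (split, forest) seeds via
`numpy.random.SeedSequence.generate_state`, so repeats are independent and
the whole evaluation is reproducible. Weighted accuracy is implemented as
support-weighted per-class recall and asserted equal to the overall
fraction-correct on every call; weighted F1 is the support-weighted
per-class F1. The ablation evaluates the feature triple and all three
pairs with identical splits per repeat (a paired comparison). Recovery
stages are processed through the feature pipeline but label-masked out of
classification.

## Synthetic cohort

The generator emulates the five-stage protocol (3/5/5/5/5 min) for
`n_participants` = 21 by default. Per participant and condition:

| parameter | baseline | loaded | rapid | recovery 1/2 |
|---|---|---|---|---|
| rate (breaths/min) | U(12, 20) | baseline × N(0.65, 0.06) | 25 (fixed) | baseline |
| per-breath rate jitter SD | 0.8 | 0.8 | 0.4 | 0.8 |
| depth mean (μM) | 0.40 | 1.00 | 0.70 | 0.45 / 0.42 |
| depth SD between / within (μM) | 0.08 / 0.06 | 0.18 / 0.12 | 0.12 / 0.08 | 0.08 / 0.06 |
| O₂Hb offset (μM) | 0 ± 0.2 | 1.5 ± 0.35 | 1.0 ± 0.30 | 0.5 / 0.4 |

Each breath is an asymmetric raised cosine (inspiration:expiration time
ratio 1:2) from 0 up to its depth and back; its starting minimum time and
depth are the ground truth. Shared components: cardiac sinusoid at
N(1.1, 0.1) Hz, 0.05 μM amplitude; random-walk drift with 0.003 μM/sample
steps; a smooth random cubic trend scaled to 0.5 μM; white noise of 0.04 μM;
HHb = −0.4 × respiration plus noise (anti-correlation for I/O realism only —
the analysis uses O₂Hb alone); THb = O₂Hb + HHb. Effect sizes were chosen
so the three classified conditions are separable but overlapping: the
interval is lowest and tightest for rapid breathing, depth and O₂Hb level
are lowest at baseline, and the depth+amplitude pairing (without the
interval) is the weakest feature set. Per-participant streams derive from
the master seed via `SeedSequence([seed, participant_index])`, so cohorts
regenerate byte-identically.

What the generator does **not** emulate: motion artifacts, optode-coupling
changes, non-sinusoidal cardiac morphology and heart-rate variability,
breath-holds or sighs, inter-condition transients, and any biophysical
coupling between breathing effort and hemodynamics beyond the configured
offsets. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — not that it is robust to every artifact of real
chest-NIRS data.

## Numerical choices and degenerate inputs

Boundary extrema: a breath minimum exactly at a segment edge cannot be a
local extremum and is not detected; edge effects only shorten the breath
list (the first interval needs two minima). Flat signals yield empty peak
sets; empty windows and sub-3-breath tables degrade with warnings, not
errors. Separation distances round to ≥ 1 sample. CSV round-trips use 10
decimal places (tolerance 1e-9 against μM-scale values). Problem sizes in
the test-suite: the full 21-participant, 100-repeat evaluation runs in
about a minute on one CPU; quick modes (fewer participants, repeats, trees)
cover the orchestration paths.

## Known limitations

* The peak-spacing estimate is a single global mean per segment; strongly
  bimodal breathing within one condition would blur it.
* Depth is measured on the detrended, cardiac-suppressed signal, so very
  shallow breaths (< ~2× noise floor) can fall below the prominence floor
  and be missed.
* The amplitude feature's definition (window mean of raw ΔO₂Hb) is one of
  two defensible readings; both are implemented, and conclusions that hinge
  on amplitude should be checked under `amplitude_mode="oscillation"`.
* Row-wise 80:20 splitting shares participants across folds; use
  `group_by_participant=True` for subject-level generalisation claims.
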