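"""Protocol-structured synthetic NIRS recordings with known ground truth.

Each recording emulates the statistical structure of a chest-optode ΔO₂Hb
trace across the five-stage breathing protocol:

* a respiratory oscillation built breath-by-breath from asymmetric
  raised-cosine pulses (inspiration:expiration time ratio 1:2), with
  per-breath jittered period and depth — the minima mark breath starts;
* a condition-dependent ΔO₂Hb level offset (loaded and rapid breathing
  raise the chest O₂Hb level relative to free baseline breathing);
* a cardiac sinusoid near 1 Hz, clearly visible at 10 Hz sampling;
* slow drift (random walk plus a smooth polynomial trend) and additive
  white noise.

HHb is generated as an anti-correlated fraction of the respiratory
component (for I/O realism only; the analysis uses O₂Hb alone), and
THb = O₂Hb + HHb. The ground truth records every breath's minimum time and
depth per condition, which the test-suite oracles compare against
pipeline estimates.

Default effect sizes make the three classified conditions separable but
overlapping: the breathing interval is shortest and tightest for rapid
breathing (25 breaths/min by metronome); depth and O₂Hb level are lowest at
baseline and higher under load and tachypnea.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import (NirsRecording, ProtocolSchedule, default_protocol,
                        write_nirs_csv)


@dataclass
class ConditionParams:
    """Generator parameters for one protocol condition.

    ``rate_bpm`` fixes the breathing rate (breaths/min); if None the rate is
    the participant's sampled free rate times ``rate_factor`` (itself
    jittered across participants by ``rate_factor_sd``). Depth parameters
    are μM: ``depth_mean_um`` ± ``depth_between_sd_um`` across participants,
    ± ``depth_within_sd_um`` breath-to-breath. ``offset_mean_um`` ±
    ``offset_sd_um`` is the condition's ΔO₂Hb level.
    """

    rate_bpm: float | None = None
    rate_factor: float = 1.0
    rate_factor_sd: float = 0.0
    rate_jitter_sd_bpm: float = 0.8
    depth_mean_um: float = 0.4
    depth_between_sd_um: float = 0.08
    depth_within_sd_um: float = 0.06
    offset_mean_um: float = 0.0
    offset_sd_um: float = 0.2


def default_conditions() -> dict[str, ConditionParams]:
    """Per-condition defaults for the five-stage protocol.

    Baseline breathes freely (12–20 breaths/min, sampled per participant),
    loaded breathing is slower and markedly deeper with an elevated O₂Hb
    level, rapid breathing follows the 25 breaths/min metronome with a tight
    rate and intermediate depth/level, and the recovery stages resemble
    baseline with a residual level offset.
    """
    return {
        "baseline": ConditionParams(
            depth_mean_um=0.40, depth_between_sd_um=0.08, depth_within_sd_um=0.06,
            offset_mean_um=0.0, offset_sd_um=0.2),
        "loaded": ConditionParams(
            rate_factor=0.65, rate_factor_sd=0.06,
            depth_mean_um=1.00, depth_between_sd_um=0.18, depth_within_sd_um=0.12,
            offset_mean_um=1.5, offset_sd_um=0.35),
        "recovery1": ConditionParams(
            depth_mean_um=0.45, depth_between_sd_um=0.08, depth_within_sd_um=0.06,
            offset_mean_um=0.5, offset_sd_um=0.25),
        "rapid": ConditionParams(
            rate_bpm=25.0, rate_jitter_sd_bpm=0.4,
            depth_mean_um=0.70, depth_between_sd_um=0.12, depth_within_sd_um=0.08,
            offset_mean_um=1.0, offset_sd_um=0.30),
        "recovery2": ConditionParams(
            depth_mean_um=0.42, depth_between_sd_um=0.08, depth_within_sd_um=0.06,
            offset_mean_um=0.4, offset_sd_um=0.25),
    }


@dataclass
class CohortConfig:
    """Study-level generator configuration (defaults emulate the protocol)."""

    n_participants: int = 21
    fs: float = 10.0
    schedule: ProtocolSchedule = field(default_factory=default_protocol)
    conditions: dict[str, ConditionParams] = field(default_factory=default_conditions)
    baseline_rate_range_bpm: tuple[float, float] = (12.0, 20.0)
    cardiac_freq_hz: float = 1.1
    cardiac_freq_sd_hz: float = 0.1
    cardiac_amp_um: float = 0.05
    drift_walk_sd_um: float = 0.003
    trend_scale_um: float = 0.5
    noise_sd_um: float = 0.04
    hhb_fraction: float = 0.4
    hhb_noise_sd_um: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in self.schedule.condition_names:
            if name not in self.conditions:
                raise ValueError(f"no generator parameters for condition {name!r}")
        for key in ("cardiac_amp_um", "drift_walk_sd_um", "trend_scale_um",
                    "noise_sd_um", "hhb_noise_sd_um"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0")


def noiseless(cfg: CohortConfig) -> CohortConfig:
    """A copy of ``cfg`` with cardiac, drift, trend, additive noise and all
    breath-to-breath jitter switched off (clean test conditions)."""
    conds = {name: replace(p, rate_jitter_sd_bpm=0.0, depth_within_sd_um=0.0)
             for name, p in cfg.conditions.items()}
    return replace(cfg, conditions=conds, cardiac_amp_um=0.0,
                   drift_walk_sd_um=0.0, trend_scale_um=0.0, noise_sd_um=0.0)


@dataclass
class ConditionTruth:
    """Ground truth for one participant-condition."""

    min_times_s: np.ndarray      # absolute breath-start (minimum) times
    depths_um: np.ndarray        # per-breath depths, aligned with min_times_s
    offset_um: float
    rate_mean_bpm: float


@dataclass
class GroundTruth:
    participant_id: str
    conditions: dict[str, ConditionTruth]


def _breath_pulse(tau: np.ndarray, period: float, depth: float) -> np.ndarray:
    """Asymmetric raised-cosine breath: 0 → depth over the first third of the
    period (inspiration), back to 0 over the remaining two thirds."""
    ti = period / 3.0
    out = np.empty_like(tau)
    rising = tau < ti
    out[rising] = 0.5 * depth * (1.0 - np.cos(np.pi * tau[rising] / ti))
    out[~rising] = 0.5 * depth * (
        1.0 + np.cos(np.pi * (tau[~rising] - ti) / (period - ti)))
    return out


def generate_recording(
    cfg: CohortConfig, participant_index: int, seed: int | None = None
) -> tuple[NirsRecording, GroundTruth]:
    """Generate one participant's recording and its ground truth.

    Deterministic given (seed, participant_index); the per-participant RNG
    stream is derived from the master seed so cohort members are independent.
    """
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(master),
                                                        int(participant_index)]))
    fs = cfg.fs
    durations = np.array([d for _, d in cfg.schedule.stages])
    boundaries = np.rint(np.cumsum(np.concatenate([[0.0], durations])) * fs)
    boundaries = boundaries.astype(int)
    n = int(boundaries[-1])

    base_rate = rng.uniform(*cfg.baseline_rate_range_bpm)

    resp = np.zeros(n)
    offsets = np.zeros(n)
    truth: dict[str, ConditionTruth] = {}
    for (name, dur), lo, hi in zip(cfg.schedule.stages, boundaries[:-1],
                                   boundaries[1:]):
        p = cfg.conditions[name]
        if p.rate_bpm is not None:
            rate_mean = p.rate_bpm
        else:
            factor = p.rate_factor
            if p.rate_factor_sd > 0:
                factor = max(rng.normal(p.rate_factor, p.rate_factor_sd), 0.3)
            rate_mean = base_rate * factor
        depth_mean = max(rng.normal(p.depth_mean_um, p.depth_between_sd_um), 0.1)
        offset = rng.normal(p.offset_mean_um, p.offset_sd_um)
        offsets[lo:hi] = offset

        seg_dur = (hi - lo) / fs
        t = 0.0
        min_times, depths = [], []
        while True:
            rate = max(rng.normal(rate_mean, p.rate_jitter_sd_bpm), 4.0)
            period = 60.0 / rate
            if t + period > seg_dur:
                break
            depth = max(rng.normal(depth_mean, p.depth_within_sd_um), 0.05)
            i0 = lo + int(np.ceil(t * fs - 1e-9))
            i1 = lo + int(np.ceil((t + period) * fs - 1e-9))
            i1 = min(i1, hi)
            tau = np.arange(i0 - lo, i1 - lo) / fs - t
            resp[i0:i1] = _breath_pulse(tau, period, depth)
            min_times.append(lo / fs + t)
            depths.append(depth)
            t += period
        truth[name] = ConditionTruth(
            min_times_s=np.array(min_times),
            depths_um=np.array(depths),
            offset_um=float(offset),
            rate_mean_bpm=float(rate_mean),
        )

    tt = np.arange(n) / fs
    cardiac = np.zeros(n)
    if cfg.cardiac_amp_um > 0:
        f_c = max(rng.normal(cfg.cardiac_freq_hz, cfg.cardiac_freq_sd_hz), 0.5)
        cardiac = cfg.cardiac_amp_um * np.sin(
            2 * np.pi * f_c * tt + rng.uniform(0, 2 * np.pi))
    walk = (np.cumsum(rng.normal(0.0, cfg.drift_walk_sd_um, n))
            if cfg.drift_walk_sd_um > 0 else np.zeros(n))
    trend = np.zeros(n)
    if cfg.trend_scale_um > 0:
        x = np.linspace(-1.0, 1.0, n)
        coef = rng.normal(0.0, 0.5, size=3)
        trend = cfg.trend_scale_um * (coef[0] * x + coef[1] * x**2
                                      + coef[2] * x**3)
    noise = (rng.normal(0.0, cfg.noise_sd_um, n)
             if cfg.noise_sd_um > 0 else np.zeros(n))

    o2hb = offsets + resp + cardiac + walk + trend + noise
    hhb = -cfg.hhb_fraction * resp + (
        rng.normal(0.0, cfg.hhb_noise_sd_um, n)
        if cfg.hhb_noise_sd_um > 0 else np.zeros(n))
    pid = f"P{participant_index:02d}"
    rec = NirsRecording(
        participant_id=pid, fs=fs,
        channels={"O2Hb": o2hb, "HHb": hhb, "THb": o2hb + hhb},
    )
    return rec, GroundTruth(participant_id=pid, conditions=truth)


def generate_cohort(
    cfg: CohortConfig, out_dir: str | Path | None = None, seed: int | None = None
) -> tuple[list[tuple[NirsRecording, GroundTruth]], pd.DataFrame]:
    """Generate the full cohort; optionally write CSVs plus a manifest.

    Returns the list of (recording, truth) pairs and the manifest table
    (participant, seed, and file paths when written).
    """
    master = cfg.seed if seed is None else seed
    pairs = [generate_recording(cfg, i, seed=master)
             for i in range(cfg.n_participants)]
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (rec, truth) in enumerate(pairs):
        row = {"participant": rec.participant_id, "master_seed": int(master),
               "participant_index": i}
        if out is not None:
            rec_path = out / f"{rec.participant_id}_recording.csv"
            write_nirs_csv(rec, rec_path)
            truth_path = out / f"{rec.participant_id}_truth.csv"
            write_ground_truth_csv(truth, truth_path)
            row["recording_file"] = rec_path.name
            row["truth_file"] = truth_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return pairs, manifest


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    """Per-breath ground truth as CSV (condition, min_time_s, depth_um, offset)."""
    frames = []
    for name, ct in truth.conditions.items():
        frames.append(pd.DataFrame({
            "condition": name,
            "min_time_s": ct.min_times_s,
            "depth_um": ct.depths_um,
            "offset_um": ct.offset_um,
            "rate_mean_bpm": ct.rate_mean_bpm,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10f")
    return Path(path)
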