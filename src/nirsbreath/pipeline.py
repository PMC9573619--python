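"""End-to-end orchestration: simulate/load → segment → detrend → detect →
features → windows → classify.

A single run reproduces the full experiment on a synthetic cohort: every
recording is segmented by the protocol schedule; each segment's O₂Hb trace
is polynomial-detrended, breaths are detected with the alternation
constraint, per-breath features are CI-filtered and aggregated into
1-minute windows; the window feature matrix (classified conditions only)
feeds the random-forest ablation. All stages are seeded from one master
seed, and per-stage counts (breaths detected / excluded, windows dropped)
are accumulated in the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .breath_detection import (DEFAULT_CARDIAC_CUTOFF_HZ,
                               DEFAULT_PROMINENCE_SD_FRACTION,
                               DEFAULT_SPACING_MULTIPLIER,
                               InsufficientOscillationError, detect_breaths,
                               suppress_cardiac)
from .classify import (ClassificationReport, ablation_summary, feature_ablation)
from .features import (DEFAULT_CI_LEVEL, DEFAULT_WINDOW_S,
                       compute_breath_features, filter_outliers_ci,
                       window_aggregate)
from .preprocess import DEFAULT_DETREND_ORDER, detrend_polynomial
from .signal_io import (read_nirs_csv, segment_by_protocol,
                        write_feature_matrix)
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("nirsbreath")


@dataclass
class RunConfig:
    """Everything one experiment run needs, serializable to/from YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest: str | None = None      # read recordings from this manifest CSV
    detrend_order: int = DEFAULT_DETREND_ORDER
    spacing_multiplier: float = DEFAULT_SPACING_MULTIPLIER
    prominence_sd_fraction: float = DEFAULT_PROMINENCE_SD_FRACTION
    cardiac_cutoff_hz: float = DEFAULT_CARDIAC_CUTOFF_HZ
    ci_level: float = DEFAULT_CI_LEVEL
    window_s: float = DEFAULT_WINDOW_S
    amplitude_mode: str = "raw_mean"
    n_trees: int = 100
    max_depth: int | None = None
    train_fraction: float = 0.8
    repeats: int = 100
    stratify: bool = True
    group_by_participant: bool = False
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cohort = CohortConfig(**cohort_raw) if isinstance(cohort_raw, dict) \
            else cohort_raw
        cfg = cls(cohort=cohort, **raw)
        return cfg


@dataclass
class PipelineResult:
    feature_matrix: pd.DataFrame          # classified conditions only
    full_feature_table: pd.DataFrame      # all conditions incl. recovery
    ablation: list[ClassificationReport]
    counts: dict


def extract_features(
    rec, schedule, cfg: RunConfig, counts: dict
) -> pd.DataFrame:
    """Feature rows for one recording (all conditions; recovery label-masked)."""
    frames = []
    for seg in segment_by_protocol(rec, schedule):
        raw = seg.channels["O2Hb"]
        det = detrend_polynomial(raw, rec.fs, order=cfg.detrend_order)
        try:
            peaks = detect_breaths(
                det.detrended, rec.fs,
                spacing_multiplier=cfg.spacing_multiplier,
                prominence_sd_fraction=cfg.prominence_sd_fraction,
                cardiac_cutoff_hz=cfg.cardiac_cutoff_hz)
        except InsufficientOscillationError as err:
            raise InsufficientOscillationError(
                f"[breath_detection] {rec.participant_id}/{seg.condition_name}: "
                f"{err}") from err
        # depths are read off the same cardiac-suppressed working signal
        # the detector used, so extremum indices and amplitudes agree
        working = suppress_cardiac(det.detrended, rec.fs, cfg.cardiac_cutoff_hz)
        bt = compute_breath_features(peaks, working, rec.fs)
        bt = filter_outliers_ci(bt, level=cfg.ci_level)
        counts["breaths_detected"] += len(bt)
        counts["breaths_excluded"] += int(bt["excluded"].sum())
        label = (seg.condition_name
                 if seg.condition_name in schedule.classification_labels
                 else "")
        rows = window_aggregate(
            bt, seg, raw, rec.fs, window_s=cfg.window_s,
            participant_id=rec.participant_id, label=label,
            amplitude_mode=cfg.amplitude_mode)
        expected = int(seg.duration_s // cfg.window_s)
        counts["windows_expected"] += expected
        counts["windows_dropped"] += expected - len(rows)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def _load_cohort_from_manifest(manifest_path: str, fs: float):
    base = Path(manifest_path).parent
    manifest = pd.read_csv(manifest_path)
    recs = []
    for _, row in manifest.iterrows():
        recs.append(read_nirs_csv(
            base / row["recording_file"],
            column_map={"O2Hb": "O2Hb", "HHb": "HHb", "THb": "THb"},
            fs=fs, participant_id=str(row["participant"])))
    return recs


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full experiment; deterministic given the master seed.

    Writes ``features.csv``, ``report.json`` (the 4-row ablation) and
    ``run_log.json`` to ``cfg.out_dir`` when set.
    """
    counts = {"breaths_detected": 0, "breaths_excluded": 0,
              "windows_expected": 0, "windows_dropped": 0}
    schedule = cfg.cohort.schedule
    if cfg.manifest is not None:
        recs = _load_cohort_from_manifest(cfg.manifest, cfg.cohort.fs)
    else:
        cohort = replace(cfg.cohort, seed=cfg.seed)
        pairs, _ = generate_cohort(cohort)
        recs = [rec for rec, _ in pairs]

    tables = [extract_features(rec, schedule, cfg, counts) for rec in recs]
    full = pd.concat(tables, ignore_index=True)
    fm = full.loc[full["label"] != ""].reset_index(drop=True)
    counts["feature_rows"] = len(fm)
    counts["breaths_kept"] = counts["breaths_detected"] - counts["breaths_excluded"]
    logger.info("pipeline counts: %s", counts)

    reports = feature_ablation(
        fm, seed=cfg.seed, n_trees=cfg.n_trees, max_depth=cfg.max_depth,
        train_fraction=cfg.train_fraction, repeats=cfg.repeats,
        stratify=cfg.stratify, group_by_participant=cfg.group_by_participant)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_matrix(fm, out / "features.csv")
        with open(out / "report.json", "w") as fh:
            json.dump({"ablation": [r.to_dict() for r in reports],
                       "seed": cfg.seed}, fh, indent=2)
        with open(out / "run_log.json", "w") as fh:
            json.dump(counts, fh, indent=2)
        summary = ablation_summary(reports)
        logger.info("ablation summary:\n%s", summary.to_string(index=False))

    return PipelineResult(feature_matrix=fm, full_feature_table=full,
                          ablation=reports, counts=counts)
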