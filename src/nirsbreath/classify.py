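"""Random-forest classification of breathing conditions from window features.

The classifier separates the three breathing conditions (free baseline,
inspiratory-loaded, rapid-shallow) from three features per 1-minute window:
mean breathing interval, mean breathing depth, and O₂Hb signal amplitude.
Evaluation follows a repeated random-split protocol: 100 stratified 80:20
row splits, a 100-tree forest with unbounded depth fitted per split, and
support-weighted accuracy/F1 averaged over the repeats. A feature-ablation
table evaluates the full triple and each pair of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import GroupShuffleSplit, train_test_split

#: Feature-name → feature-matrix column.
FEATURE_COLUMNS = {
    "interval": "interval_mean_s",
    "depth": "depth_mean",
    "o2hb_amplitude": "o2hb_amplitude",
}

#: Ablation rows: the full triple, then each pair (depth+interval,
#: interval+amplitude, depth+amplitude).
ABLATION_SUBSETS = (
    ("depth", "interval", "o2hb_amplitude"),
    ("depth", "interval"),
    ("interval", "o2hb_amplitude"),
    ("depth", "o2hb_amplitude"),
)


def weighted_accuracy(y_true, y_pred) -> float:
    """Support-weighted mean of per-class recall.

    Mathematically identical to the overall fraction correct; the identity is
    asserted on every call as an internal consistency check.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if len(yt) == 0:
        raise ValueError("empty label vectors")
    classes, support = np.unique(yt, return_counts=True)
    recalls = np.array([np.mean(yp[yt == c] == c) for c in classes])
    wacc = float(np.sum(support / len(yt) * recalls))
    assert abs(wacc - np.mean(yt == yp)) < 1e-12, \
        "weighted recall must equal fraction-correct"
    return wacc


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 scores."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if len(yt) == 0:
        raise ValueError("empty label vectors")
    return float(f1_score(yt, yp, average="weighted", zero_division=0))


@dataclass
class ClassificationReport:
    """Repeated-split evaluation summary for one feature subset."""

    feature_subset: tuple[str, ...]
    weighted_accuracy: float
    weighted_f1: float
    per_repeat_accuracy: list[float]
    per_repeat_f1: list[float]
    confusion: np.ndarray = field(repr=False)  # summed over repeats
    classes: tuple[str, ...] = ()
    n_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "feature_subset": list(self.feature_subset),
            "weighted_accuracy": self.weighted_accuracy,
            "weighted_f1": self.weighted_f1,
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "per_repeat_f1": self.per_repeat_f1,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n_rows": self.n_rows,
        }


def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    """Counter-based per-repeat seed derivation from the master seed."""
    return np.random.SeedSequence(seed).generate_state(2 * repeats) % (2**31)


def train_eval_rf(
    fm: pd.DataFrame,
    features: tuple[str, ...] = ("interval", "depth", "o2hb_amplitude"),
    n_trees: int = 100,
    max_depth: int | None = None,
    train_fraction: float = 0.8,
    repeats: int = 100,
    seed: int = 0,
    stratify: bool = True,
    group_by_participant: bool = False,
) -> ClassificationReport:
    """Repeated random-split random-forest evaluation.

    Each repeat draws a fresh 80:20 row split (stratified by class unless
    ``stratify`` is false; grouped by participant if ``group_by_participant``
    — no subject appears in both folds, recommended for real studies but off
    by default to match row-wise splitting), fits a forest of ``n_trees``
    unbounded-depth trees, and scores the held-out fold. The report averages
    weighted accuracy and weighted F1 over repeats and sums the confusion
    matrices. Deterministic given ``seed``.
    """
    if not features:
        raise ValueError("empty feature subset")
    unknown = [f for f in features if f not in FEATURE_COLUMNS]
    if unknown:
        raise ValueError(f"unknown features {unknown}; "
                         f"choose from {sorted(FEATURE_COLUMNS)}")
    y = fm["label"].to_numpy(str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("feature matrix must contain at least 2 classes")
    if len(fm) < 10:
        raise ValueError(f"feature matrix too small: {len(fm)} rows")
    X = fm[[FEATURE_COLUMNS[f] for f in features]].to_numpy(float)
    groups = fm["participant"].to_numpy(str) if group_by_participant else None

    seeds = _repeat_seeds(seed, repeats)
    accs, f1s = [], []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for r in range(repeats):
        split_seed, forest_seed = int(seeds[2 * r]), int(seeds[2 * r + 1])
        if group_by_participant:
            gss = GroupShuffleSplit(n_splits=1, train_size=train_fraction,
                                    random_state=split_seed)
            tr, te = next(gss.split(X, y, groups))
            Xtr, Xte, ytr, yte = X[tr], X[te], y[tr], y[te]
        else:
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_fraction, random_state=split_seed,
                stratify=y if stratify else None)
        clf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                     random_state=forest_seed, n_jobs=1)
        clf.fit(Xtr, ytr)
        yp = clf.predict(Xte)
        accs.append(weighted_accuracy(yte, yp))
        f1s.append(weighted_f1(yte, yp))
        conf += confusion_matrix(yte, yp, labels=classes)

    return ClassificationReport(
        feature_subset=tuple(features),
        weighted_accuracy=float(np.mean(accs)),
        weighted_f1=float(np.mean(f1s)),
        per_repeat_accuracy=[float(a) for a in accs],
        per_repeat_f1=[float(v) for v in f1s],
        confusion=conf,
        classes=tuple(classes),
        n_rows=len(fm),
    )


def feature_ablation(
    fm: pd.DataFrame, seed: int = 0, **kwargs
) -> list[ClassificationReport]:
    """Evaluate the full feature triple and each pair, in fixed row order.

    All four subsets are evaluated with the same master seed, so each repeat
    uses identical train/test splits across subsets (a paired comparison).
    Extra keyword arguments are forwarded to :func:`train_eval_rf`.
    """
    return [train_eval_rf(fm, features=subset, seed=seed, **kwargs)
            for subset in ABLATION_SUBSETS]


def ablation_summary(reports: list[ClassificationReport]) -> pd.DataFrame:
    """Four-row summary table (features, weighted accuracy, F1 score)."""
    return pd.DataFrame({
        "features": [", ".join(r.feature_subset) for r in reports],
        "weighted_accuracy": [r.weighted_accuracy for r in reports],
        "f1_score": [r.weighted_f1 for r in reports],
    })
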