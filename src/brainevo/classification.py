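"""Two-group SVM protocol: train on healthy vs AD features, score evolved.

Each topology feature is classified separately at each threshold (4 x 11
independent one-dimensional classifiers). Training values are z-scored on
training statistics; the stored scaler transforms the evolved values. The
classifier is a linear-kernel maximum-margin SVM with C = 1 — the
smallest-assumption choice for 21-sample one-dimensional problems. Accuracy
is the fraction of evolved networks assigned to the AD class; boundary ties
go to AD (deterministic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import DegenerateFeatureError, InvalidArgumentError
from .metrics import TopologyProfile
from .synthetic import AD, HEALTHY

FEATURES = (
    "global_efficiency",
    "clustering_coefficient",
    "edge_count",
    "transitivity",
)


@dataclass(frozen=True)
class FeatureSample:
    """One subject's value of one topology feature at one threshold."""

    value: float
    label: str
    subject_id: str
    threshold: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise InvalidArgumentError("feature value must be finite")
        if self.label not in (HEALTHY, AD):
            raise InvalidArgumentError(f"label must be {HEALTHY!r} or {AD!r}")


@dataclass(frozen=True)
class TrainingSet:
    samples: tuple[FeatureSample, ...]
    feature: str
    threshold: float
    mean: float
    sd: float

    def zscore(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


@dataclass(frozen=True)
class ClassifierReport:
    feature: str
    threshold: float
    n_evolved: int
    n_classified_ad: int

    @property
    def accuracy(self) -> float:
        return self.n_classified_ad / self.n_evolved


def build_training_set(
    profiles: list[TopologyProfile], feature: str, threshold: float
) -> TrainingSet:
    """One sample per healthy/AD subject at the threshold, plus the scaler."""
    if feature not in FEATURES:
        raise InvalidArgumentError(f"unknown feature {feature!r}")
    cell = [p for p in profiles if p.threshold == threshold and p.group in (HEALTHY, AD)]
    labels = {p.group for p in cell}
    if labels != {HEALTHY, AD}:
        raise InvalidArgumentError(
            f"both groups must be present at threshold {threshold} (got {sorted(labels)})"
        )
    samples = tuple(
        FeatureSample(
            value=float(getattr(p, feature)),
            label=p.group,
            subject_id=p.subject_id,
            threshold=threshold,
        )
        for p in cell
    )
    values = np.array([s.value for s in samples])
    mean, sd = float(values.mean()), float(values.std())
    if sd == 0:
        raise DegenerateFeatureError(
            f"feature {feature!r} has zero spread at threshold {threshold}"
        )
    return TrainingSet(samples=samples, feature=feature, threshold=threshold, mean=mean, sd=sd)


def train_and_classify(train: TrainingSet, evolved_values) -> ClassifierReport:
    """Fit the linear SVM on the two groups and label the evolved values."""
    by_label = {lab: sum(s.label == lab for s in train.samples) for lab in (HEALTHY, AD)}
    if min(by_label.values()) < 2:
        raise InvalidArgumentError("need at least 2 samples per class")
    X = train.zscore([s.value for s in train.samples])[:, None]
    if np.ptp(X) == 0:
        raise DegenerateFeatureError("all training values identical; classes are inseparable")
    y = np.array([1 if s.label == AD else 0 for s in train.samples])
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    evolved = np.asarray(evolved_values, dtype=float)
    if evolved.ndim != 1:
        raise InvalidArgumentError("evolved_values must be one-dimensional")
    decision = clf.decision_function(train.zscore(evolved)[:, None])
    if clf.classes_[1] != 1:  # pragma: no cover - sklearn sorts classes ascending
        decision = -decision
    n_ad = int((decision >= 0).sum())  # boundary ties go to AD
    return ClassifierReport(
        feature=train.feature,
        threshold=train.threshold,
        n_evolved=evolved.size,
        n_classified_ad=n_ad,
    )


def accuracy_table(reports: list[ClassifierReport]) -> pd.DataFrame:
    """11 threshold rows x 4 feature columns plus an ``average`` row, in %."""
    by_cell = {(r.threshold, r.feature): r for r in reports}
    thresholds = sorted({r.threshold for r in reports})
    missing = [
        (t, f) for t in thresholds for f in FEATURES if (t, f) not in by_cell
    ]
    if missing:
        raise InvalidArgumentError(f"missing accuracy cells: {missing[:4]}...")
    rows = {
        f"{t:.2f}": [100.0 * by_cell[(t, f)].accuracy for f in FEATURES] for t in thresholds
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURES))
    table.loc["average"] = table.mean(axis=0)
    table.index.name = "threshold"
    return table
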