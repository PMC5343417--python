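"""LOOCV random-forest classification of side and gender.

Each specimen is predicted by a random forest (50 trees by default) trained
on the shape-model coefficients (or, optionally, the cut-plane
morphometrics) of all remaining specimens.  The complete leave-one-out sweep
is repeated (100 iterations by default) with fresh forest randomness; the
"median classification probability" is the median over iterations of the
per-sweep accuracy fraction.  A step-wise scheme predicts side first, then
gender with a forest trained only on specimens of the *predicted* side;
the combined prediction succeeds only if both labels are correct.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .sections import Morphometrics

__all__ = [
    "SpecimenRecord",
    "AccuracySummary",
    "feature_matrix",
    "loocv_random_forest",
    "stepwise_side_then_gender",
]


@dataclass
class SpecimenRecord:
    """Unit of statistics/classification: labels + features of one specimen."""

    specimen_id: str
    gender: str  # F | M
    side: str  # L | R
    coefficients: np.ndarray | None = None
    morphometrics: dict[str, Morphometrics] = field(default_factory=dict)

    def label(self, which: str) -> str:
        if which == "side":
            return self.side
        if which == "gender":
            return self.gender
        raise ValueError("label must be 'side' or 'gender'")


@dataclass
class AccuracySummary:
    """Per-iteration LOOCV accuracies and their summary."""

    accuracies: np.ndarray
    median_accuracy: float
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count, pooled
    n_iterations: int
    seed: int
    mean_predicted_probability: float = float("nan")

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must be fractions in [0, 1]")
        self.accuracies = acc


def feature_matrix(records: list[SpecimenRecord], source: str = "coefficients") -> np.ndarray:
    """Stack specimen features; ``source`` is 'coefficients' or 'morphometrics'."""
    if source == "coefficients":
        rows = [np.asarray(r.coefficients, float) for r in records]
        if any(r is None for r in rows):
            raise ValueError("records lack shape-model coefficients")
    elif source == "morphometrics":
        rows = []
        for r in records:
            if not r.morphometrics:
                raise ValueError(f"record {r.specimen_id} lacks morphometrics")
            rows.append(np.concatenate([
                [m.width, m.depth, m.perimeter, m.area]
                for _, m in sorted(r.morphometrics.items())
            ]))
    else:
        raise ValueError("feature source must be 'coefficients' or 'morphometrics'")
    X = np.asarray(rows, float)
    if X.ndim != 2:
        raise ValueError("inconsistent feature lengths across records")
    return X


def _check_two_classes(labels: np.ndarray, context: str) -> None:
    if len(set(labels.tolist())) < 2:
        raise ValueError(f"{context}: need at least two classes")


def loocv_random_forest(
    records: list[SpecimenRecord],
    label: str,
    n_trees: int = 50,
    n_iterations: int = 100,
    seed: int = 0,
    feature_source: str = "coefficients",
) -> AccuracySummary:
    """Repeated leave-one-out cross-validation with a random forest.

    Each iteration runs one complete LOOCV sweep (every specimen held out
    once) with forest random states derived from ``seed``; the per-sweep
    accuracy fraction is one sample of the classification probability.
    Deterministic for a given seed.
    """
    X = feature_matrix(records, feature_source)
    y = np.asarray([r.label(label) for r in records])
    _check_two_classes(y, f"label {label!r}")
    counts = Counter(y.tolist())
    if min(counts.values()) < 2:
        raise ValueError(f"label {label!r}: every class needs >= 2 specimens")

    rng = np.random.default_rng(seed)
    n = len(records)
    accuracies = np.empty(n_iterations)
    confusion: Counter = Counter()
    prob_sum, prob_n = 0.0, 0
    for it in range(n_iterations):
        correct = 0
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(X[mask], y[mask])
            pred = clf.predict(X[i: i + 1])[0]
            proba = clf.predict_proba(X[i: i + 1])[0]
            prob_sum += float(proba[list(clf.classes_).index(y[i])])
            prob_n += 1
            confusion[(str(y[i]), str(pred))] += 1
            correct += int(pred == y[i])
        accuracies[it] = correct / n
    return AccuracySummary(
        accuracies=accuracies,
        median_accuracy=float(np.median(accuracies)),
        confusion=dict(confusion),
        n_iterations=n_iterations,
        seed=seed,
        mean_predicted_probability=prob_sum / prob_n,
    )


def stepwise_side_then_gender(
    records: list[SpecimenRecord],
    n_trees: int = 50,
    n_iterations: int = 100,
    seed: int = 0,
    feature_source: str = "coefficients",
) -> AccuracySummary:
    """Step-wise LOOCV: predict side, then gender within the predicted side.

    The gender forest for a held-out specimen is trained only on the
    remaining specimens of the *predicted* side; the combined prediction
    counts as correct only if both labels match.
    """
    X = feature_matrix(records, feature_source)
    side = np.asarray([r.side for r in records])
    gender = np.asarray([r.gender for r in records])
    _check_two_classes(side, "side")
    _check_two_classes(gender, "gender")

    rng = np.random.default_rng(seed)
    n = len(records)
    accuracies = np.empty(n_iterations)
    confusion: Counter = Counter()
    for it in range(n_iterations):
        correct = 0
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            side_clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
            )
            side_clf.fit(X[mask], side[mask])
            side_pred = side_clf.predict(X[i: i + 1])[0]

            stratum = mask & (side == side_pred)
            strat_genders = set(gender[stratum].tolist())
            if len(strat_genders) < 2:
                raise ValueError(
                    f"predicted-side stratum {side_pred!r} contains a single "
                    "gender class; cannot train the step-wise gender forest"
                )
            gender_clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
            )
            gender_clf.fit(X[stratum], gender[stratum])
            gender_pred = gender_clf.predict(X[i: i + 1])[0]

            truth = f"{gender[i]}{side[i]}"
            pred = f"{gender_pred}{side_pred}"
            confusion[(truth, pred)] += 1
            correct += int(truth == pred)
        accuracies[it] = correct / n
    return AccuracySummary(
        accuracies=accuracies,
        median_accuracy=float(np.median(accuracies)),
        confusion=dict(confusion),
        n_iterations=n_iterations,
        seed=seed,
    )
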