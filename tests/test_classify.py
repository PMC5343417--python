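import numpy as np
import pytest
from scipy import stats as sps

from radshape.classify import (
    SpecimenRecord,
    feature_matrix,
    loocv_random_forest,
    stepwise_side_then_gender,
)
from radshape.sections import Morphometrics


def make_records(features, genders, sides):
    return [
        SpecimenRecord(specimen_id=f"s{i:03d}", gender=g, side=s, coefficients=f)
        for i, (f, g, s) in enumerate(zip(features, genders, sides))
    ]


def separable_records(n_per_class=20, gap=10.0, seed=0, label="side"):
    """Two Gaussian clouds separated by ``gap`` times their SD."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1.0, (2 * n_per_class, 5))
    X[n_per_class:, 0] += gap
    if label == "side":
        sides = ["L"] * n_per_class + ["R"] * n_per_class
        genders = list(np.where(rng.random(2 * n_per_class) < 0.5, "F", "M"))
    else:
        genders = ["F"] * n_per_class + ["M"] * n_per_class
        sides = list(np.where(rng.random(2 * n_per_class) < 0.5, "L", "R"))
    return make_records(X, genders, sides)


class TestLOOCV:
    def test_separable_classes_reach_perfect_median_accuracy(self):
        records = separable_records(n_per_class=20, gap=10.0, seed=1)
        summary = loocv_random_forest(records, "side", n_iterations=5, seed=0)
        assert summary.median_accuracy == 1.0

    def test_permuted_labels_fall_to_chance(self):
        """Shuffled labels on the same data: accuracy within the central
        99% binomial band around 0.5 for n=40."""
        records = separable_records(n_per_class=20, gap=10.0, seed=1)
        rng = np.random.default_rng(7)
        sides = np.array([r.side for r in records])
        rng.shuffle(sides)
        for r, s in zip(records, sides):
            r.side = str(s)
        summary = loocv_random_forest(records, "side", n_iterations=5, seed=0)
        lo, hi = sps.binom.ppf([0.005, 0.995], 40, 0.5) / 40
        assert lo <= summary.median_accuracy <= hi

    def test_determinism_under_seed(self):
        records = separable_records(n_per_class=5, gap=3.0, seed=2)
        a = loocv_random_forest(records, "side", n_iterations=3, seed=9)
        b = loocv_random_forest(records, "side", n_iterations=3, seed=9)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.confusion == b.confusion

    def test_single_class_rejected(self):
        records = separable_records(n_per_class=5, label="gender")
        for r in records:
            r.side = "L"
        with pytest.raises(ValueError, match="two classes"):
            loocv_random_forest(records, "side", n_iterations=1)

    def test_accuracy_beats_permuted_labels_on_separable_data(self):
        records = separable_records(n_per_class=10, gap=8.0, seed=3)
        true_acc = loocv_random_forest(records, "side", n_iterations=2, seed=0)
        rng = np.random.default_rng(5)
        sides = np.array([r.side for r in records])
        rng.shuffle(sides)
        for r, s in zip(records, sides):
            r.side = str(s)
        perm_acc = loocv_random_forest(records, "side", n_iterations=2, seed=0)
        assert true_acc.median_accuracy > perm_acc.median_accuracy


class TestStepwise:
    @staticmethod
    def planted_records(n=40, seed=0, noise=False):
        """Side on feature 0, gender on feature 1, disjoint supports."""
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1.0, (n, 4))
        sides, genders = [], []
        for i in range(n):
            side = "L" if i % 2 == 0 else "R"
            gender = "F" if (i // 2) % 2 == 0 else "M"
            if not noise:
                X[i, 0] += 12.0 if side == "L" else -12.0
                X[i, 1] += 12.0 if gender == "F" else -12.0
            sides.append(side)
            genders.append(gender)
        return make_records(X, genders, sides)

    def test_planted_features_give_perfect_combined_accuracy(self):
        records = self.planted_records(n=24, seed=1)
        summary = stepwise_side_then_gender(records, n_iterations=3, seed=0)
        assert summary.median_accuracy == 1.0

    def test_pure_noise_lands_near_two_coin_flips(self):
        """Independent side and gender guesses: combined accuracy ~ 0.25."""
        records = self.planted_records(n=40, seed=2, noise=True)
        summary = stepwise_side_then_gender(records, n_iterations=5, seed=0)
        # central 99.9% band of Binomial(200, 0.25) on the pooled iterations
        pooled = summary.accuracies.mean()
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 200, 0.25) / 200
        assert lo <= pooled <= hi

    def test_determinism(self):
        records = self.planted_records(n=16, seed=3)
        a = stepwise_side_then_gender(records, n_iterations=2, seed=4)
        b = stepwise_side_then_gender(records, n_iterations=2, seed=4)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_combined_accuracy_close_to_product_when_independent(self):
        """With clean side and noisy gender, combined ~ side_acc * gender_acc."""
        rng = np.random.default_rng(8)
        n = 40
        X = rng.normal(0, 1.0, (n, 4))
        sides = ["L" if i < n // 2 else "R" for i in range(n)]
        genders = [("F" if rng.random() < 0.5 else "M") for _ in range(n)]
        X[: n // 2, 0] += 12.0
        records = make_records(X, genders, sides)
        side_acc = loocv_random_forest(records, "side", n_iterations=5, seed=0)
        gender_acc = loocv_random_forest(records, "gender", n_iterations=5, seed=0)
        combined = stepwise_side_then_gender(records, n_iterations=5, seed=0)
        product = side_acc.median_accuracy * gender_acc.median_accuracy
        assert combined.median_accuracy <= min(side_acc.median_accuracy, 1.0)
        assert abs(combined.median_accuracy - product) < 0.15


def test_morphometrics_feature_source():
    rng = np.random.default_rng(0)
    records = []
    for i in range(12):
        big = i < 6
        m = {
            lab: Morphometrics(
                width=(33.0 if big else 29.0) + rng.normal(0, 0.2),
                depth=22.0, perimeter=80.0, area=470.0,
            )
            for lab in ("distal", "middle", "proximal")
        }
        records.append(SpecimenRecord(
            specimen_id=f"m{i}", gender="M" if big else "F",
            side="L" if i % 2 else "R", morphometrics=m,
        ))
    X = feature_matrix(records, "morphometrics")
    assert X.shape == (12, 12)
    summary = loocv_random_forest(
        records, "gender", n_iterations=2, seed=0, feature_source="morphometrics"
    )
    assert summary.median_accuracy == 1.0
    assert summary.accuracies.shape == (2,)
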