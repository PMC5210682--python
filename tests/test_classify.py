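import numpy as np
import pytest

from fractodim import (
    FDRecord,
    FractalDimensionClassifier,
    SplitSpec,
    cross_subtype_grid,
    evaluate_binary,
    evaluate_multiclass,
    split_records,
    train_binary,
    train_multiclass,
)
from fractodim.classify import ALL_SUBTYPES, harmonic_f1

from conftest import make_records


def rec(fd, label="benign", subtype=None, mag="40x", image_id=None):
    subtype = subtype or ("A" if label == "benign" else "DC")
    return FDRecord(
        image_id=image_id or f"{label}-{fd}",
        magnification=mag,
        label=label,
        subtype=subtype,
        fd=fd,
    )


class TestFDRecord:
    def test_subtype_label_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FDRecord(image_id="x", magnification="40x", label="benign", subtype="DC", fd=1.5)
        with pytest.raises(ValueError, match="unknown subtype"):
            FDRecord(image_id="x", magnification="40x", label="benign", subtype="ZZ", fd=1.5)


class TestSplitRecords:
    def test_even_split(self):
        records = [rec(1.5 + i / 100, "benign", image_id=f"b{i}") for i in range(10)]
        records += [rec(1.2 + i / 100, "malignant", image_id=f"m{i}") for i in range(10)]
        train, test = split_records(records, SplitSpec(fraction=0.5, seed=3))
        assert len(train) == len(test) == 10
        assert sum(r.label == "benign" for r in train) == 5

    def test_floor_rule_on_odd_stratum(self):
        records = [rec(1.5 + i / 100, "benign", image_id=f"b{i}") for i in range(7)]
        records += [rec(1.2, "malignant", image_id="m0"), rec(1.25, "malignant", image_id="m1")]
        train, test = split_records(records, SplitSpec(fraction=0.5, seed=0))
        assert sum(r.label == "benign" for r in train) == 3
        assert sum(r.label == "benign" for r in test) == 4

    def test_deterministic_and_disjoint(self, gaussian_records):
        spec = SplitSpec(fraction=0.5, seed=42)
        t1, v1 = split_records(gaussian_records, spec)
        t2, v2 = split_records(gaussian_records, spec)
        assert [r.image_id for r in t1] == [r.image_id for r in t2]
        ids_train = {r.image_id for r in t1}
        ids_test = {r.image_id for r in v1}
        assert not ids_train & ids_test
        assert ids_train | ids_test == {r.image_id for r in gaussian_records}

    def test_small_stratum_named_in_error(self):
        records = [rec(1.5, "benign"), rec(1.6, "benign"), rec(1.2, "malignant")]
        with pytest.raises(ValueError, match="malignant"):
            split_records(records, SplitSpec(seed=0))


class TestBinaryClassifier:
    def test_separable_training_set(self):
        train = [rec(1.9, "benign"), rec(1.95, "benign"),
                 rec(1.3, "malignant"), rec(1.35, "malignant")]
        model = train_binary(train)
        assert 1.35 < model.threshold_ < 1.9
        X = np.array([[r.fd] for r in train])
        y = np.array([r.label for r in train])
        assert (model.predict(X) == y).all()

    def test_orientation_learned_from_data(self):
        low_malignant = train_binary(
            [rec(1.9, "benign"), rec(1.95, "benign"),
             rec(1.3, "malignant"), rec(1.35, "malignant")]
        )
        high_malignant = train_binary(
            [rec(1.3, "benign"), rec(1.35, "benign"),
             rec(1.9, "malignant"), rec(1.95, "malignant")]
        )
        assert low_malignant.orientation_ == -1
        assert high_malignant.orientation_ == +1
        assert low_malignant.predict([[1.2]])[0] == "malignant"
        assert high_malignant.predict([[1.2]])[0] == "benign"

    def test_threshold_close_to_accuracy_optimum(self, rng):
        """On 200 Gaussian records per class the SVM's implied threshold
        sits within 0.05 of the brute-force accuracy-maximizing cut."""
        records = make_records(rng, n_per_class=200, mean_benign=1.8,
                               mean_malignant=1.5, sd=0.05)
        model = train_binary(records)
        fds = np.array([r.fd for r in records])
        labels = np.array([r.label for r in records])
        candidates = np.sort(fds)
        cuts = (candidates[:-1] + candidates[1:]) / 2
        accs = [
            np.mean((fds < c) == (labels == "malignant")) for c in cuts
        ]
        best_cut = cuts[int(np.argmax(accs))]
        assert model.threshold_ == pytest.approx(best_cut, abs=0.05)

    def test_one_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_binary([rec(1.5, "benign"), rec(1.6, "benign")])

    def test_predictions_equal_threshold_rule_exhaustively(self, rng):
        """SVM/threshold equivalence: over a dense fd grid the model's
        predictions match a sign comparison against threshold_."""
        records = make_records(rng, n_per_class=50)
        model = train_binary(records)
        grid = np.linspace(1.0, 2.0, 2001).reshape(-1, 1)
        pred = model.predict(grid)
        rule = np.where(
            model.orientation_ * (grid[:, 0] - model.threshold_) >= 0,
            "malignant",
            "benign",
        )
        assert (pred == rule).all()

    def test_tie_at_threshold_is_malignant(self, rng):
        model = train_binary(make_records(rng, n_per_class=20))
        assert model.predict([[model.threshold_]])[0] == "malignant"


class TestEvaluateBinary:
    def test_perfect_predictions(self):
        test = [rec(1.9, "benign"), rec(1.3, "malignant")]
        model = train_binary(
            [rec(1.85, "benign"), rec(1.95, "benign"),
             rec(1.25, "malignant"), rec(1.35, "malignant")]
        )
        report = evaluate_binary(model, test)
        assert report.tp_rate == report.tn_rate == report.f1 == report.accuracy == 1.0

    @pytest.mark.parametrize(
        "tp, tn, expected_f1",
        [
            (0.990, 0.968, 0.979),
            (0.983, 0.090, 0.165),
            (0.974, 0.090, 0.165),
            (0.940, 0.146, 0.253),
        ],
    )
    def test_harmonic_formula_on_published_rate_pairs(self, tp, tn, expected_f1):
        assert round(harmonic_f1(tp, tn), 3) == expected_f1

    def test_f1_symmetric_under_rate_swap(self, rng):
        for _ in range(50):
            a, b = rng.random(2)
            assert harmonic_f1(a, b) == pytest.approx(harmonic_f1(b, a), abs=1e-15)
        assert harmonic_f1(0.0, 0.0) == 0.0

    def test_rates_recomputable_from_confusion_counts(self, rng, gaussian_records):
        train, test = split_records(gaussian_records, SplitSpec(seed=9))
        report = evaluate_binary(train_binary(train), test)
        c = report.confusion
        assert report.tp_rate == c["tp"] / (c["tp"] + c["fn"])
        assert report.tn_rate == c["tn"] / (c["tn"] + c["fp"])
        assert report.accuracy == (c["tp"] + c["tn"]) / report.n_test
        assert report.f1 == harmonic_f1(report.tp_rate, report.tn_rate)

    def test_missing_class_rejected(self, rng):
        model = train_binary(make_records(rng, n_per_class=10))
        with pytest.raises(ValueError, match="both classes"):
            evaluate_binary(model, [rec(1.5, "benign")])


class TestParameterRecovery:
    def test_four_sd_separation_gives_high_f1(self, rng):
        """Classes 4 sd apart are nearly Bayes-separable: F1 >= 0.95."""
        records = make_records(rng, n_per_class=200, mean_benign=1.75,
                               mean_malignant=1.55, sd=0.05)
        train, test = split_records(records, SplitSpec(seed=1))
        report = evaluate_binary(train_binary(train), test)
        assert report.f1 >= 0.95

    def test_zero_separation_gives_chance_level(self, rng):
        """Identical class distributions: accuracy statistically
        indistinguishable from coin flipping (binomial 3-sigma band)."""
        records = make_records(rng, n_per_class=300, mean_benign=1.65,
                               mean_malignant=1.65, sd=0.05)
        train, test = split_records(records, SplitSpec(seed=2))
        report = evaluate_binary(train_binary(train), test)
        n = report.n_test
        assert abs(report.accuracy - 0.5) <= 3 * 0.5 / np.sqrt(n)


class TestMulticlass:
    def test_separated_subtype_recovered_perfectly(self):
        train = [rec(1.2 + i / 100, "benign", "A", image_id=f"a{i}") for i in range(5)]
        train += [rec(1.8 + i / 100, "benign", "F", image_id=f"f{i}") for i in range(5)]
        model = train_multiclass(train)
        test = [rec(1.21, "benign", "A", image_id="t0"), rec(1.82, "benign", "F", image_id="t1")]
        report = evaluate_multiclass(model, test)
        assert report.accuracy == 1.0

    def test_shuffled_labels_score_at_chance(self, rng):
        """With fd independent of subtype, 8 balanced subtypes score
        ~1/8 accuracy (generous Monte-Carlo band)."""
        records = []
        for i in range(400):
            subtype = ALL_SUBTYPES[i % 8]
            label = "benign" if subtype in ("A", "F", "PT", "TA") else "malignant"
            records.append(
                FDRecord(image_id=f"r{i}", magnification="40x", label=label,
                         subtype=subtype, fd=float(rng.normal(1.6, 0.1)))
            )
        train, test = split_records(records, SplitSpec(seed=3, stratify_by="subtype"))
        report = evaluate_multiclass(train_multiclass(train), test)
        assert report.accuracy <= 0.25

    def test_strong_separation_gives_high_accuracy(self):
        records = []
        for k, subtype in enumerate(ALL_SUBTYPES):
            label = "benign" if k < 4 else "malignant"
            for i in range(10):
                records.append(
                    FDRecord(image_id=f"{subtype}{i}", magnification="40x",
                             label=label, subtype=subtype,
                             fd=1.1 + 0.1 * k + 0.001 * i)
                )
        train, test = split_records(records, SplitSpec(seed=4, stratify_by="subtype"))
        report = evaluate_multiclass(train_multiclass(train), test)
        assert report.accuracy >= 0.9
        assert sum(sum(row.values()) for row in report.confusion.values()) == report.n_test

    def test_unseen_subtype_warned_and_counted_wrong(self):
        train = [rec(1.2 + i / 100, "benign", "A", image_id=f"a{i}") for i in range(5)]
        train += [rec(1.8 + i / 100, "malignant", "DC", image_id=f"d{i}") for i in range(5)]
        model = train_multiclass(train)
        test = [rec(1.5, "benign", "PT", image_id="p0")]
        with pytest.warns(UserWarning, match="PT"):
            report = evaluate_multiclass(model, test)
        assert report.accuracy == 0.0

    def test_nearest_mean_baseline_agrees_on_separated_data(self):
        train = [rec(1.2, "benign", "A", image_id="a0"), rec(1.22, "benign", "A", image_id="a1"),
                 rec(1.8, "malignant", "DC", image_id="d0"), rec(1.82, "malignant", "DC", image_id="d1")]
        model = train_multiclass(train, scheme="nearest_mean")
        assert model.predict([[1.25], [1.79]]).tolist() == ["A", "DC"]


class TestCrossSubtypeGrid:
    def test_pair_test_sets_exclude_training_subtypes(self, gaussian_records):
        results, mean_f1 = cross_subtype_grid(gaussian_records)
        assert len(results) == 16
        pairs = {(bt, mt) for bt, mt, _ in results}
        assert len(pairs) == 16
        # grid mean equals the arithmetic mean of per-pair F1 values
        assert mean_f1 == pytest.approx(np.mean([r.f1 for _, _, r in results]))
        n_total = len(gaussian_records)
        for bt, mt, report in results:
            n_pair = sum(r.subtype in (bt, mt) for r in gaussian_records)
            assert report.n_train == n_pair
            assert report.n_test == n_total - n_pair

    def test_missing_subtype_rejected(self, rng):
        records = [r for r in make_records(rng, n_per_class=20) if r.subtype != "PT"]
        with pytest.raises(ValueError, match="PT"):
            cross_subtype_grid(records)

    def test_exchangeable_subtypes_give_similar_f1(self, rng):
        """When every subtype shares its class's fd distribution the 16
        pair scores spread only by sampling noise."""
        records = make_records(rng, n_per_class=200, mean_benign=1.75,
                               mean_malignant=1.55, sd=0.05)
        results, mean_f1 = cross_subtype_grid(records)
        f1s = [rep.f1 for _, _, rep in results]
        assert np.ptp(f1s) < 6 * np.std(f1s) + 1e-9
        assert mean_f1 > 0.9
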