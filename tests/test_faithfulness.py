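import math

import numpy as np
import pytest

import pddbench as pb
from pddbench.faithfulness import FaithfulnessConfig


@pytest.fixture(scope="module")
def eval_setup(reference_model, synth_splits):
    _, _, test = synth_splits
    sub = test.subset(range(40))
    atts = pb.record_attributions(reference_model, sub, "integrated_gradients", seed=0)
    return reference_model, sub, atts


def constant_model(n_features, classes=("A", "B")):
    def proba(X):
        return np.full((X.shape[0], len(classes)), 1.0 / len(classes))

    return pb.FunctionModel(proba, classes)


class TestSelectRationale:
    @pytest.mark.parametrize(
        "F,k,expected",
        [(250, 1, 3), (50, 50, 25), (10, 100, 10), (7, 1, 1)],
    )
    def test_size_is_ceil_with_floor_one(self, F, k, expected):
        vec = np.arange(F, dtype=float)
        assert len(pb.select_rationale(vec, k)) == expected

    def test_descending_importance_ties_by_index(self):
        vec = np.array([0.5, 0.9, 0.5, 0.1])
        np.testing.assert_array_equal(pb.select_rationale(vec, 75), [1, 0, 2])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            pb.select_rationale(np.ones(4), 0)


class TestMetricIdentities:
    def test_constant_model_all_zero(self, rng):
        X = rng.random((10, 6))
        labels = ["A", "B"] * 5
        atts = rng.random((10, 6))
        m = constant_model(6)
        cfg = FaithfulnessConfig(seed=0)
        for fn in (pb.sufficiency, pb.comprehensiveness, pb.sensitivity):
            vals = fn(m, X, labels, atts, cfg)
            assert all(v == pytest.approx(0.0, abs=1e-12) for v in vals.values())

    def test_k100_sufficiency_identity(self, eval_setup):
        model, sub, atts = eval_setup
        cfg = FaithfulnessConfig(b_levels=(100,))
        vals = pb.sufficiency(model, sub.values, sub.labels, atts, cfg)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vals.values())

    def test_k100_comprehensiveness_full_removal(self, eval_setup):
        model, sub, atts = eval_setup
        cfg = FaithfulnessConfig(b_levels=(100,))
        vals = pb.comprehensiveness(model, sub.values, sub.labels, atts, cfg)
        zero = model.predict_proba(np.zeros((1, sub.n_attributes)))[0]
        base = model.predict_proba(sub.values)
        for c, v in vals.items():
            j = model.class_index(c)
            idx = [i for i, l in enumerate(sub.labels) if l == c]
            expected = np.mean([base[i, j] - zero[j] for i in idx])
            assert v == pytest.approx(expected, abs=1e-12)

    def test_sigma_zero_sensitivity_is_zero(self, eval_setup):
        model, sub, atts = eval_setup
        cfg = FaithfulnessConfig(sigma=0.0)
        vals = pb.sensitivity(model, sub.values, sub.labels, atts, cfg)
        assert all(v == 0.0 for v in vals.values())

    def test_sensitivity_deterministic_given_seed(self, eval_setup):
        model, sub, atts = eval_setup
        cfg = FaithfulnessConfig(seed=5)
        a = pb.sensitivity(model, sub.values, sub.labels, atts, cfg)
        b = pb.sensitivity(model, sub.values, sub.labels, atts, cfg)
        assert a == b

    def test_noising_ignored_features_changes_nothing(self):
        """Sensitivity is zero when only model-ignored features carry importance."""
        from scipy.special import expit

        def proba(X):
            p = expit(2 * X[:, 0])
            return np.column_stack([1 - p, p])

        m = pb.FunctionModel(proba, ("neg", "pos"))
        rng = np.random.default_rng(0)
        X = rng.random((8, 3))
        atts = np.tile([0.0, 1.0, 0.5], (8, 1))  # rationale always features 1, 2
        cfg = FaithfulnessConfig(b_levels=(50,), sigma=0.3, seed=1)
        vals = pb.sensitivity(m, X, ["pos"] * 4 + ["neg"] * 4, atts, cfg)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vals.values())


class TestOrderingProperties:
    def test_informed_rationales_beat_random(self, reference_model, synth_splits):
        """True-importance rationales: lower sufficiency, higher comprehensiveness,
        than random rationales, in most seeded trials (paired simulation)."""
        _, _, test = synth_splits
        sub = test.subset(range(40))
        atts = pb.record_attributions(reference_model, sub, "integrated_gradients", seed=0)
        cfg = FaithfulnessConfig(seed=0)
        wins_s = wins_c = 0
        trials = 8
        for t in range(trials):
            rng = np.random.default_rng(t)
            rand_atts = rng.random(atts.shape)
            s_true = np.mean(list(pb.sufficiency(reference_model, sub.values, sub.labels, atts, cfg).values()))
            s_rand = np.mean(list(pb.sufficiency(reference_model, sub.values, sub.labels, rand_atts, cfg).values()))
            c_true = np.mean(list(pb.comprehensiveness(reference_model, sub.values, sub.labels, atts, cfg).values()))
            c_rand = np.mean(list(pb.comprehensiveness(reference_model, sub.values, sub.labels, rand_atts, cfg).values()))
            wins_s += int(s_true <= s_rand)
            wins_c += int(c_true >= c_rand)
        assert wins_s >= trials - 1
        assert wins_c >= trials - 1


class TestReportAggregation:
    def test_printed_row_average(self):
        per_class = {
            "comprehensiveness": dict(
                zip(
                    ["272.4", "250.0", "272", "244.9", "70.7", "401.9", "285.9", "70.54", "38.9", "8.45"],
                    [0.391, 0.596, 0.489, 1.00, 0.390, 0.194, 0.269, 0.435, 0.474, 0.820],
                )
            )
        }
        report = pb.faithfulness_report(per_class)
        assert round(report.averages["comprehensiveness"], 3) == 0.506

    def test_identical_values_average_to_value(self):
        report = pb.faithfulness_report({"sufficiency": {"a": 0.3, "b": 0.3}})
        assert report.averages["sufficiency"] == pytest.approx(0.3)

    def test_average_invariant_to_class_order(self):
        vals = {"a": 0.1, "b": 0.7, "c": 0.4}
        r1 = pb.faithfulness_report({"sensitivity": vals})
        r2 = pb.faithfulness_report({"sensitivity": dict(reversed(list(vals.items())))})
        assert r1.averages == r2.averages

    def test_mismatched_class_sets_rejected(self):
        with pytest.raises(ValueError, match="class set"):
            pb.faithfulness_report({"sufficiency": {"a": 0.1}, "sensitivity": {"b": 0.2}})


class TestWindowCurves:
    def test_window_count_is_ceil(self, eval_setup):
        model, sub, atts = eval_setup
        cfg = FaithfulnessConfig(window=5)
        curves = pb.window_curves(model, sub.values, sub.labels, atts, cfg)
        expected = math.ceil(sub.n_attributes / 5)
        assert all(len(v) == expected for v in curves.values())

    def test_constant_model_flat_zero_curves(self, rng):
        X = rng.random((8, 10))
        atts = rng.random((8, 10))
        curves = pb.window_curves(constant_model(10), X, ["A", "B"] * 4, atts, FaithfulnessConfig())
        for v in curves.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_single_important_feature_dominates_first_window(self):
        from scipy.special import expit

        def proba(X):
            p = expit(4 * X[:, 0] - 1)
            return np.column_stack([1 - p, p])

        m = pb.FunctionModel(proba, ("neg", "pos"))
        rng = np.random.default_rng(3)
        X = rng.random((12, 10))
        atts = np.tile(np.linspace(1.0, 0.1, 10), (12, 1))  # feature 0 ranked first
        cfg = FaithfulnessConfig(window=5)
        curves = pb.window_curves(m, X, ["pos"] * 12, atts, cfg)
        comp = curves[("pos", "comprehensiveness")]
        assert comp[0] > comp[1:].max()

    def test_fewer_features_than_window_warns(self, rng):
        X = rng.random((4, 3))
        atts = rng.random((4, 3))
        with pytest.warns(UserWarning, match="window"):
            curves = pb.window_curves(constant_model(3), X, ["A", "B"] * 2, atts, FaithfulnessConfig(window=5))
        assert all(len(v) == 1 for v in curves.values())


class TestEvaluateFaithfulness:
    def test_full_report_structure(self, eval_setup):
        model, sub, atts = eval_setup
        report = pb.evaluate_faithfulness(model, sub.values, sub.labels, atts, FaithfulnessConfig(seed=2))
        assert set(report.per_class) == {"sufficiency", "comprehensiveness", "sensitivity"}
        classes = set(report.per_class["sufficiency"])
        assert report.curves and all(c in classes for c, _ in report.curves)
        frame = report.to_frame("integrated_gradients")
        assert "Average" in frame.columns
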