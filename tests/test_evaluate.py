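"""Bland-Altman agreement, metrics, grouped / stratified / nested
cross-validation and report generation."""

import json

import numpy as np
import pytest

from monohip import (AgreementResult, CVSpec, LinearROM, ModelEvaluation,
                     NaiveROM, ValidityCriterion, bland_altman,
                     check_validity, classification_report, group_kfold,
                     nested_cv, regression_metrics, stratified_group_kfold,
                     train_predict)
from monohip.evaluate import audit_folds, report, write_report


class TestBlandAltman:
    def test_identity_zero_bias_zero_range(self):
        ref = np.array([30.0, 35.0, 40.0])
        res = bland_altman(ref, ref)
        assert res.bias == 0.0 and res.loa_range == 0.0

    def test_constant_offset(self):
        ref = np.array([30.0, 35.0, 40.0])
        res = bland_altman(ref + 5.0, ref)
        assert res.bias == pytest.approx(5.0)
        assert res.sd_diff == pytest.approx(0.0)
        assert res.loa_range == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # d = (-2, 0, 2): bias 0, sample SD 2 (n-1), LoA +/- 3.92
        res = bland_altman(np.array([28.0, 35.0, 42.0]),
                           np.array([30.0, 35.0, 40.0]))
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(2.0)
        assert res.loa_low == pytest.approx(-3.92)
        assert res.loa_high == pytest.approx(3.92)
        assert res.loa_range == pytest.approx(7.84)

    def test_constant_shift_property(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(40.0, 8.0, size=50)
        for c in (-7.5, 0.0, 3.25):
            res = bland_altman(ref + c, ref)
            assert res.bias == pytest.approx(c)
            assert res.loa_range == pytest.approx(0.0, abs=1e-9)

    def test_loa_range_consistency_invariant(self):
        rng = np.random.default_rng(1)
        res = bland_altman(rng.normal(size=100), rng.normal(size=100))
        assert res.loa_range == pytest.approx(2 * 1.96 * res.sd_diff,
                                              abs=1e-9)
        assert res.loa_low <= res.bias <= res.loa_high

    def test_mismatched_or_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestCheckValidity:
    @pytest.mark.parametrize("rng_range,expected", [
        (26.8, True),    # below the criterion
        (27.8, False),   # strict inequality at the criterion
        (30.5, False)])  # above the criterion
    def test_strict_threshold(self, rng_range, expected):
        sd = rng_range / (2 * 1.96)
        res = AgreementResult(bias=0.0, sd_diff=sd, loa_low=-rng_range / 2,
                              loa_high=rng_range / 2, loa_range=rng_range,
                              n=10)
        assert check_validity(res, ValidityCriterion(27.8)) is expected

    def test_default_criterion_is_27_8(self):
        assert ValidityCriterion().max_loa_range == 27.8

    def test_non_positive_criterion_rejected(self):
        with pytest.raises(ValueError):
            ValidityCriterion(0.0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        ref = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(ref, ref)
        assert m["mae"] == 0.0 and m["rmse"] == 0.0 and m["r2"] == 1.0

    def test_mean_prediction_zero_r2(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(np.full(4, ref.mean()), ref)
        assert m["r2"] == pytest.approx(0.0)

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(2)
        p, r = rng.normal(size=64), rng.normal(size=64)
        m = regression_metrics(p, r)
        assert m["mae"] == pytest.approx(np.mean(np.abs(p - r)), abs=1e-12)
        assert m["rmse"] == pytest.approx(
            np.sqrt(np.mean((p - r) ** 2)), abs=1e-12)
        ss_res = np.sum((p - r) ** 2)
        ss_tot = np.sum((r - r.mean()) ** 2)
        assert m["r2"] == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert m["pearson_r"] == pytest.approx(
            np.corrcoef(p, r)[0, 1], abs=1e-12)


class TestGroupKFold:
    def test_ten_groups_two_per_fold(self):
        groups = np.repeat([f"g{i}" for i in range(10)], 3)
        folds = group_kfold(groups, k=5, seed=0)
        audit_folds(folds, groups, len(groups))
        for _, test in folds:
            assert len(set(groups[test])) == 2

    def test_row_order_invariance_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        groups = np.repeat([f"g{i}" for i in range(8)], 4)
        shuffled = rng.permutation(len(groups))
        f1 = group_kfold(groups, k=4, seed=5)
        f2 = group_kfold(groups[shuffled], k=4, seed=5)
        sets1 = [frozenset(groups[t]) for _, t in f1]
        sets2 = [frozenset(groups[shuffled][t]) for _, t in f2]
        assert sets1 == sets2

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            group_kfold(np.array(["a", "a", "b"]), k=5)


class TestStratifiedGroupKFold:
    def test_single_class_reduces_to_group_kfold_structure(self):
        groups = np.repeat([f"g{i}" for i in range(10)], 4)
        classes = np.ones(len(groups), dtype=int)
        folds = stratified_group_kfold(groups, classes, k=5)
        audit_folds(folds, groups, len(groups))
        sizes = sorted(len(t) for _, t in folds)
        assert sizes == [8, 8, 8, 8, 8]

    def test_class_shares_close_to_global(self):
        rng = np.random.default_rng(4)
        n_groups = 30
        rows, classes = [], []
        for g in range(n_groups):
            size = rng.integers(5, 15)
            cls = rng.choice([1, 2, 3], p=[0.2, 0.45, 0.35])
            rows += [f"g{g}"] * size
            classes += [cls] * size
        groups = np.array(rows)
        classes = np.array(classes)
        folds = stratified_group_kfold(groups, classes, k=5)
        audit_folds(folds, groups, len(groups))
        global_share = np.bincount(classes, minlength=4)[1:] / len(classes)
        for _, test in folds:
            share = np.bincount(classes[test], minlength=4)[1:] / len(test)
            assert np.abs(share - global_share).max() <= 0.15


class TestNestedCV:
    @staticmethod
    def _factory(params, X, y):
        if params.get("model") == "naive":
            return NaiveROM(y).fit()
        return LinearROM(y, X).fit()

    def test_single_point_grid_equals_plain_group_cv(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 2))
        y = X @ [2.0, -1.0] + rng.normal(0, 0.2, 120)
        groups = np.repeat([f"g{i}" for i in range(12)], 10)
        spec = CVSpec(outer_folds=5, inner_folds=4, seed=0)
        out = nested_cv(self._factory, X, y, groups,
                        grid=[{"model": "linear"}], spec=spec)
        folds = group_kfold(groups, k=5, seed=0)
        oof = train_predict(lambda Xt, yt: LinearROM(yt, Xt).fit(),
                            X, y, groups, folds, standardize=False)
        np.testing.assert_allclose(out["oof_pred"], oof, atol=1e-9)

    def test_generating_model_chosen_on_most_folds(self):
        # low noise: the linear model must beat the naive constant in
        # essentially every outer fold
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 2))
        y = X @ [3.0, 1.5] + rng.normal(0, 0.1, 150)
        groups = np.repeat([f"g{i}" for i in range(15)], 10)
        out = nested_cv(self._factory, X, y, groups,
                        grid=[{"model": "naive"}, {"model": "linear"}],
                        spec=CVSpec(seed=1))
        chosen = [rec["params"]["model"] for rec in out["folds"]]
        assert sum(c == "linear" for c in chosen) >= 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            nested_cv(self._factory, np.zeros((10, 1)), np.zeros(10),
                      np.arange(10), grid=[])

    def test_outer_folds_pass_audit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 1))
        y = rng.normal(size=60)
        groups = np.repeat([f"g{i}" for i in range(10)], 6)
        out = nested_cv(self._factory, X, y, groups,
                        grid=[{"model": "naive"}], spec=CVSpec(seed=2))
        audit_folds(out["outer_folds"], groups, len(y))


class TestClassificationReport:
    def test_perfect_predictions(self):
        ref = np.array([1, 2, 3, 1, 2, 3])
        rep = classification_report(ref, ref)
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0
        np.testing.assert_array_equal(np.diag(rep.confusion), [2, 2, 2])

    def test_all_one_class_on_balanced_data(self):
        ref = np.array([1, 2, 3] * 4)
        pred = np.ones(12, dtype=int)
        rep = classification_report(pred, ref)
        assert rep.accuracy == pytest.approx(1 / 3)

    def test_matches_hand_tallied_matrix(self):
        rng = np.random.default_rng(8)
        ref = rng.integers(1, 4, size=60)
        pred = rng.integers(1, 4, size=60)
        rep = classification_report(pred, ref)
        manual = np.zeros((3, 3), dtype=int)
        for r, p in zip(ref, pred):
            manual[r - 1, p - 1] += 1
        np.testing.assert_array_equal(rep.confusion, manual)
        assert rep.confusion.sum() == 60
        assert rep.accuracy == pytest.approx(np.trace(manual) / 60)


class TestReport:
    @staticmethod
    def _evaluation(name="mlr"):
        pred = np.array([30.0, 36.0, 41.0, 44.0])
        ref = np.array([31.0, 35.0, 40.0, 45.0])
        agr = bland_altman(pred, ref)
        return ModelEvaluation(name=name, agreement=agr,
                               metrics=regression_metrics(pred, ref),
                               valid=check_validity(agr))

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError):
            report([])

    def test_json_round_trip(self, tmp_path):
        ev = self._evaluation()
        write_report([ev], tmp_path)
        payload = json.loads((tmp_path / "report.json").read_text())
        stored = payload["models"]["mlr"]["agreement"]
        assert stored["bias"] == pytest.approx(ev.agreement.bias)
        assert stored["loa_range"] == pytest.approx(
            ev.agreement.loa_range)
        assert (tmp_path / "report.md").exists()

    def test_markdown_table_lists_models(self):
        _, md = report([self._evaluation("a"), self._evaluation("b")])
        assert "| a |" in md and "| b |" in md
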