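"""WRMSD objective, dataset prediction, CMA-ES parameter fitting."""

import numpy as np
import pytest

from xcevolve.cmaes import cmaes_minimize
from xcevolve.fitting import (
    DataPoint,
    DatasetEvaluator,
    EnergyDataset,
    FitConfig,
    evaluate_functional,
    fit_parameters,
    predict_datapoints,
    used_parameters,
    wrmsd,
)
from xcevolve.functionals import HARTREE_TO_KCAL, b97_program, exc_semilocal
from xcevolve.programs import (
    Instruction,
    InstructionProgram,
    Symbol,
    SymbolicFunctional,
)
from xcevolve.synth import b97_demo_fixture


class TestWrmsd:
    def test_perfect_predictions_give_zero(self, toy_dataset):
        split = toy_dataset.splits["train"]
        refs = [dp.reference for dp in split]
        assert wrmsd(refs, split) == 0.0

    def test_hand_value_single_weighted_point(self):
        dp = DataPoint("d", (("a", 1.0),), reference=1.0, data_type="T",
                       weight=4.0)
        assert wrmsd([1.5], [dp]) == pytest.approx(1.0)

    def test_weight_homogeneity(self, toy_dataset):
        split = toy_dataset.splits["train"]
        doubled = [DataPoint(dp.id, dp.terms, dp.reference, dp.data_type,
                             2 * dp.weight) for dp in split]
        pred = [dp.reference + 0.3 for dp in split]
        assert wrmsd(pred, doubled) == pytest.approx(
            np.sqrt(2) * wrmsd(pred, split))

    def test_three_point_hand_computation(self):
        dps = [
            DataPoint("a", (("s", 1.0),), 0.0, "T", 1.0),
            DataPoint("b", (("s", 1.0),), 0.0, "T", 10.0),
            DataPoint("c", (("s", 1.0),), 0.0, "T", 100.0),
        ]
        pred = [1.0, 2.0, 3.0]
        want = np.sqrt((1 * 1 + 10 * 4 + 100 * 9) / 3)
        assert wrmsd(pred, dps) == pytest.approx(want)

    def test_empty_split_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            wrmsd([], [])


class TestPrediction:
    def test_zero_functional_predicts_only_offsets(self, toy_dataset):
        ws = (Symbol("x2", "feature"), Symbol("F", "variable"))
        empty = InstructionProgram(workspace=ws)
        fun = SymbolicFunctional({"x": empty, "css": empty, "cos": empty})
        toy_dataset.offsets["a"] = 3.0
        toy_dataset.offsets["b"] = 1.0
        pred = predict_datapoints(fun, {}, toy_dataset, "train")
        np.testing.assert_allclose(pred, [3.0, 2.0])

    def test_self_difference_is_zero(self, small_dataset, b97_truth):
        fun, params = b97_truth
        dp = DataPoint("self", (("sys000", 1.0), ("sys000", -1.0)), 0.0,
                       "TCE", 1.0)
        pred = predict_datapoints(fun, params, small_dataset, [dp])
        assert pred[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_system_prediction_composes_exc(self, small_dataset,
                                                   b97_truth):
        fun, params = b97_truth
        dp = DataPoint("one", (("sys001", 1.0),), 0.0, "TCE", 1.0)
        pred = predict_datapoints(fun, params, small_dataset, [dp])
        want = HARTREE_TO_KCAL * exc_semilocal(
            small_dataset.systems["sys001"], fun, params)
        assert pred[0] == pytest.approx(want, rel=1e-12)

    def test_fast_evaluator_matches_reference_predictor(self, small_dataset,
                                                        b97_truth):
        fun, params = b97_truth
        off = {k: v + 0.1 for k, v in params.items()}   # nonzero residuals
        ev = DatasetEvaluator(small_dataset)
        for split in ("train", "validation", "test"):
            for p in (params, off):
                naive = predict_datapoints(fun, p, small_dataset, split)
                j_naive = wrmsd(naive, small_dataset.splits[split])
                assert float(ev.split_wrmsd(fun, p, split)) == pytest.approx(
                    j_naive, rel=1e-9, abs=1e-9)

    def test_unresolved_label_is_an_error(self, toy_dataset):
        with pytest.raises(ValueError, match="unknown system"):
            EnergyDataset(
                systems=dict(toy_dataset.systems),
                splits={"train": [DataPoint("x", (("nope", 1.0),), 0.0,
                                            "T", 1.0)]},
            )


class TestCmaes:
    def test_quadratic_bowl_is_solved(self):
        rng = np.random.default_rng(0)
        target = np.array([1.5, -2.0, 0.25])
        res = cmaes_minimize(
            lambda X: np.sum((X - target) ** 2, axis=1),
            x0=np.zeros(3), sigma0=0.5, rng=rng)
        np.testing.assert_allclose(res.x, target, atol=1e-5)

    def test_solution_respects_bounds(self):
        rng = np.random.default_rng(1)
        res = cmaes_minimize(
            lambda X: np.sum((X - 20.0) ** 2, axis=1),
            x0=np.zeros(2), sigma0=0.5, rng=rng, bounds=(-10, 10))
        assert np.all(res.x <= 10.0) and res.x[0] == pytest.approx(10.0, abs=1e-6)

    def test_rosenbrock_two_dim(self):
        rng = np.random.default_rng(2)
        f = lambda X: (1 - X[:, 0]) ** 2 + 100 * (X[:, 1] - X[:, 0] ** 2) ** 2
        res = cmaes_minimize(f, np.zeros(2), 0.3, rng, max_evals=20000)
        np.testing.assert_allclose(res.x, [1.0, 1.0], atol=1e-3)


class TestFitParameters:
    def test_zero_parameter_form_skips_the_optimizer(self, small_dataset):
        ws = (Symbol("x2", "feature"), Symbol("F", "variable"))
        empty = InstructionProgram(workspace=ws)
        fun = SymbolicFunctional({"x": empty, "css": empty, "cos": empty})
        res = fit_parameters(fun, small_dataset, FitConfig(seed=0))
        assert res.n_evals == 1 and np.isfinite(res.j_train)

    def test_unused_declared_parameters_are_excluded(self, b97_truth):
        fun, _ = b97_truth
        assert used_parameters(fun) == ("c0", "c1", "c2", "gam")
        ws = (Symbol("x2", "feature"), Symbol("c", "parameter"),
              Symbol("unused", "parameter"), Symbol("F", "variable"))
        prog = InstructionProgram(workspace=ws, instructions=(
            Instruction("add", "F", ("F", "c")),))
        empty = InstructionProgram(workspace=ws)
        fun2 = SymbolicFunctional({"x": prog, "css": empty, "cos": empty})
        assert used_parameters(fun2) == ("c",)

    def test_noiseless_parameter_recovery(self, small_dataset, b97_truth):
        """Fitting the generator's own form recovers its enhancement factor
        pointwise to 1e-3 over the training feature range."""
        fun, params = b97_truth
        res = fit_parameters(
            fun, small_dataset,
            FitConfig(n_restarts=5, seed=4, max_evals=4000,
                      stop_when_below=1e-9))
        scale = np.sqrt(np.mean([dp.reference ** 2 for dp
                                 in small_dataset.splits["train"]]))
        assert res.j_train < 1e-6 * scale
        from xcevolve.programs import execute_program
        x2 = np.geomspace(1e-4, 1e4, 200)
        got = execute_program(fun.programs["x"], {"x2": x2}, res.params)
        want = execute_program(fun.programs["x"], {"x2": x2}, params)
        np.testing.assert_allclose(got, want, atol=1e-3)

    def test_fitted_parameters_stay_inside_the_box(self, small_dataset,
                                                   b97_truth):
        fun, _ = b97_truth
        res = fit_parameters(fun, small_dataset,
                             FitConfig(n_restarts=2, seed=1, max_evals=600))
        assert all(-10.0 <= v <= 10.0 for v in res.params.values())

    def test_best_over_restarts_is_monotone_in_restart_count(self,
                                                             small_dataset,
                                                             b97_truth):
        fun, _ = b97_truth
        js = []
        for n in (1, 2, 4):
            res = fit_parameters(
                fun, small_dataset,
                FitConfig(n_restarts=n, seed=123, max_evals=400))
            js.append(res.j_train)
        assert js[1] <= js[0] and js[2] <= js[1]

    def test_evaluate_reports_all_three_splits(self, small_dataset, b97_truth):
        fun, params = b97_truth
        report = evaluate_functional(fun, params, small_dataset)
        assert set(report) == {"train", "validation", "test"}
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in report.values())


class TestDatasetIO:
    def test_save_load_round_trip(self, tmp_path, small_dataset, b97_truth):
        small_dataset.save(tmp_path / "d")
        again = EnergyDataset.load(tmp_path / "d")
        assert set(again.systems) == set(small_dataset.systems)
        for name in ("train", "validation", "test"):
            assert [dp.id for dp in again.splits[name]] == \
                [dp.id for dp in small_dataset.splits[name]]
        fun, params = b97_truth
        np.testing.assert_allclose(
            predict_datapoints(fun, params, again, "train"),
            predict_datapoints(fun, params, small_dataset, "train"),
            rtol=1e-12,
        )
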