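import json

import numpy as np
import pandas as pd
import pytest

from qsarpipe.activity import ModelingTable
from qsarpipe.errors import ModelingError
from qsarpipe.modeling import (
    QsarModel,
    correlation_filter,
    fit_mlr,
    loo_cross_validate,
    predict,
    published_models,
    rank_candidates,
    regression_metrics,
    rmse,
    select_features,
    stepwise_mlr_select,
)
from qsarpipe.synthetic import SyntheticSpec, generate_linear_dataset

from _oracles import loo_brute


def as_table(df, cell="HuCCA-1"):
    return ModelingTable(cell, df)


class TestMetrics:
    def test_perfect_agreement(self):
        r, e = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)
        assert e == 0.0

    def test_paper_pairs_hucca(self, fixture):
        pairs = fixture.pairs_for("HuCCA-1")
        r, e = regression_metrics(pairs["exp_pic50"], pairs["loo_pred_pic50"])
        assert len(pairs) == 13
        assert r == pytest.approx(0.8957, abs=0.001)
        assert e == pytest.approx(0.2562, abs=0.001)

    def test_paper_pairs_molt3(self, fixture):
        pairs = fixture.pairs_for("MOLT-3")
        _, e = regression_metrics(pairs["exp_pic50"], pairs["loo_pred_pic50"])
        assert len(pairs) == 20
        assert e == pytest.approx(0.2070, abs=0.001)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert rmse(obs, pred) == pytest.approx(rmse(obs[perm], pred[perm]))
        r1, _ = regression_metrics(obs, pred)
        r2, _ = regression_metrics(obs[perm], pred[perm])
        assert r1 == pytest.approx(r2)

    def test_r_affine_invariance(self):
        rng = np.random.default_rng(1)
        obs, pred = rng.normal(size=15), rng.normal(size=15)
        r1, _ = regression_metrics(obs, pred)
        r2, _ = regression_metrics(obs, 3.5 * pred + 2.0)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_constant_observed(self):
        with pytest.raises(ModelingError, match="constant"):
            regression_metrics([1.0, 1.0, 1.0], [0.5, 1.5, 1.0])
        assert rmse([1.0, 1.0], [1.0, 2.0]) == pytest.approx(np.sqrt(0.5))

    def test_too_few_pairs(self):
        with pytest.raises(ModelingError):
            regression_metrics([1.0], [1.0])


class TestCorrelationFilter:
    def test_response_copy_retained(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=30))
        X = pd.DataFrame({"same": y.to_numpy(), "noise": rng.normal(size=30)})
        trace = correlation_filter(X, y)
        assert "same" in trace.survivors
        assert trace.survivors["same"] == pytest.approx(1.0)

    def test_noise_dropped(self):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=100))
        X = pd.DataFrame({"noise": rng.normal(size=100)})
        trace = correlation_filter(X, y)
        assert "noise" not in trace.survivors

    def test_boundary_retained(self):
        # construct |r| exactly at threshold by passing threshold = |r|
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=50))
        x = 0.7 * y + rng.normal(size=50)
        X = pd.DataFrame({"x": x})
        r = float(np.corrcoef(x, y)[0, 1])
        trace = correlation_filter(X, y, threshold=abs(r))
        assert "x" in trace.survivors  # >= rule keeps the boundary value

    def test_constant_column_warned(self, caplog):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame({"const": [5.0] * 4, "good": y.to_numpy()})
        with caplog.at_level("WARNING"):
            trace = correlation_filter(X, y)
        assert "const" in trace.dropped_constant
        assert "good" in trace.survivors

    def test_too_few_rows(self):
        y = pd.Series([1.0, 2.0])
        with pytest.raises(ModelingError, match="3 rows"):
            correlation_filter(pd.DataFrame({"x": [1.0, 2.0]}), y)


class TestStepwise:
    def test_single_informative_recovered(self):
        spec = SyntheticSpec(n=30, coefficients={"R7m": 1.0}, noise_sigma=0.1,
                             n_noise=4, ranges={"R7m": (0.0, 3.0)})
        df, _ = generate_linear_dataset(spec, seed=42)
        trace = stepwise_mlr_select(df.drop(columns="pic50"), df["pic50"])
        assert trace.selected == ["R7m"]

    def test_no_candidate_passes(self):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=25))
        X = pd.DataFrame({f"n{i}": rng.normal(size=25) for i in range(3)})
        trace = stepwise_mlr_select(X, y, p_enter=1e-6)
        assert trace.selected == []
        assert isinstance(trace.to_text(), str)

    def test_collinear_duplicate_picks_first(self):
        spec = SyntheticSpec(n=40, coefficients={"R7m": 2.0}, noise_sigma=0.1,
                             ranges={"R7m": (0.0, 2.0)})
        df, _ = generate_linear_dataset(spec, seed=5)
        X = pd.DataFrame({"a": df["R7m"], "b": df["R7m"]})
        trace = stepwise_mlr_select(X, df["pic50"])
        assert trace.selected == ["a"]  # tie broken by column order

    def test_refuses_overparameterized_entry(self):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=4))
        X = pd.DataFrame({f"x{i}": rng.normal(size=4) for i in range(5)})
        trace = stepwise_mlr_select(X, y)
        assert len(trace.selected) <= 1

    def test_final_p_values_below_removal_threshold(self):
        import statsmodels.api as sm
        spec = SyntheticSpec(n=30, coefficients={"Lop": 1.5, "R7m": 3.0},
                             noise_sigma=0.2, n_noise=3)
        df, _ = generate_linear_dataset(spec, seed=8)
        X, y = df.drop(columns="pic50"), df["pic50"]
        trace = stepwise_mlr_select(X, y)
        assert trace.selected
        design = sm.add_constant(X[trace.selected].to_numpy())
        res = sm.OLS(y.to_numpy(), design).fit()
        assert all(p < 0.10 for p in res.pvalues[1:])

    def test_trace_replays_to_same_model(self):
        spec = SyntheticSpec(n=25, coefficients={"Lop": 1.0, "R7m": 5.0},
                             noise_sigma=0.3, n_noise=4)
        df, _ = generate_linear_dataset(spec, seed=12)
        X, y = df.drop(columns="pic50"), df["pic50"]
        t1 = stepwise_mlr_select(X, y)
        t2 = stepwise_mlr_select(X, y)
        assert t1.selected == t2.selected
        assert t1.steps == t2.steps


class TestFitMlr:
    def test_exact_linear_data(self):
        x = np.linspace(0, 5, 10)
        df = pd.DataFrame({"x1": x, "pic50": 2 * x - 3})
        model, report = fit_mlr(as_table(df), ["x1"])
        assert model.intercept == pytest.approx(-3.0, abs=1e-10)
        assert model.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert report.rmse_tr == pytest.approx(0.0, abs=1e-10)
        assert report.r_tr == pytest.approx(1.0)

    def test_parameter_recovery_simulation(self):
        """Mean estimates over replicates sit within 3 SE of the truth."""
        truth = {"RDF105m": 0.08, "MATS7m": 5.0}
        spec = SyntheticSpec(n=24, coefficients=truth, intercept=-1.75,
                             noise_sigma=0.4)
        est = {k: [] for k in truth}
        for rep in range(500):
            df, _ = generate_linear_dataset(spec, seed=1000 + rep)
            model, _ = fit_mlr(as_table(df), list(truth))
            for k in truth:
                est[k].append(model.coefficients[k])
        for k, beta in truth.items():
            arr = np.array(est[k])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - beta) < 3 * se

    def test_underdetermined(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 0.0, 2.0],
                           "c": [0.5, 1.5, 2.5], "pic50": [1.0, 2.0, 3.0]})
        with pytest.raises(ModelingError):
            fit_mlr(as_table(df), ["a", "b", "c"])

    def test_rank_deficient_reports_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "b": [2.0, 4.0, 6.0, 8.0, 10.0],
                           "pic50": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.raises(ModelingError, match="rank-deficient"):
            fit_mlr(as_table(df), ["a", "b"])

    def test_self_consistency(self):
        spec = SyntheticSpec(n=20, coefficients={"Lop": 1.1, "R7m": 9.0},
                             noise_sigma=0.3)
        df, _ = generate_linear_dataset(spec, seed=77)
        table = as_table(df)
        model, report = fit_mlr(table, ["Lop", "R7m"])
        for cid in table.data.index:
            row = table.data.loc[cid]
            assert model.predict_one(row) == pytest.approx(report.fitted[cid],
                                                           rel=1e-10)


class TestLoo:
    def test_noiseless_linear(self):
        spec = SyntheticSpec(n=12, coefficients={"R7m": 4.0}, noise_sigma=0.0)
        df, _ = generate_linear_dataset(spec, seed=3)
        report = loo_cross_validate(as_table(df), ["R7m"])
        assert report.r_cv == pytest.approx(1.0)
        assert report.rmse_cv == pytest.approx(0.0, abs=1e-10)

    def test_determinism(self):
        spec = SyntheticSpec(n=15, coefficients={"Lop": 1.0}, noise_sigma=0.4)
        df, _ = generate_linear_dataset(spec, seed=21)
        r1 = loo_cross_validate(as_table(df), ["Lop"])
        r2 = loo_cross_validate(as_table(df), ["Lop"])
        assert (r1.loo_predictions == r2.loo_predictions).all()

    def test_matches_naive_oracle_on_random_tables(self):
        def ols_fit(X, y):
            design = np.column_stack([np.ones(len(y)), X])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            return beta[0], beta[1:]

        for rep in range(50):
            spec = SyntheticSpec(n=12 + rep % 8,
                                 coefficients={"Lop": 1.0, "R7m": 4.0},
                                 noise_sigma=0.35, n_noise=1)
            df, _ = generate_linear_dataset(spec, seed=500 + rep)
            names = ["Lop", "R7m", "noise1"]
            report = loo_cross_validate(as_table(df), names)
            expected = loo_brute(df[names].to_numpy(), df["pic50"].to_numpy(),
                                 ols_fit)
            np.testing.assert_allclose(report.loo_predictions.to_numpy(),
                                       expected, rtol=1e-8, atol=1e-10)

    def test_too_few_rows(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.3, 1.9, 0.1, 2.2],
                           "pic50": [1.0, 2.1, 2.9, 4.2]})
        with pytest.raises(ModelingError):
            loo_cross_validate(as_table(df), ["a", "b"])


class TestPublishedModels:
    def test_coefficients(self):
        models = published_models()
        assert models["HuCCA-1"].coefficients["R5e+"] == -84.0157
        assert models["HuCCA-1"].coefficients["nArCOOR"] == 1.0288
        assert models["HuCCA-1"].intercept == 0.8738
        assert models["HepG2"].intercept == -1.7524
        assert models["HepG2"].notes  # sign discrepancy is documented
        assert models["A549"].coefficients == {"MATS8v": 1.5979, "nArCOOR": 0.9251}
        assert models["MOLT-3"].coefficients == {"Lop": 1.0649, "R7m": 10.3977}

    def test_every_model_two_descriptors(self):
        for model in published_models().values():
            assert len(model.coefficients) == 2
            assert model.source == "published"

    def test_worked_predictions(self):
        models = published_models()
        assert round(predict(models["HuCCA-1"], {"R5e+": 0.057, "nArCOOR": 0}), 3) == -3.915
        assert round(predict(models["HuCCA-1"], {"R5e+": 0.022, "nArCOOR": 1}), 3) == 0.054
        assert round(predict(models["MOLT-3"], {"Lop": 0.983, "R7m": 0.537}), 3) == 0.947

    def test_missing_descriptor_named(self):
        with pytest.raises(ModelingError, match="R5e"):
            predict(published_models()["HuCCA-1"], {"nArCOOR": 1})

    def test_json_round_trip(self, tmp_path):
        model = published_models()["MOLT-3"]
        path = tmp_path / "m.json"
        model.to_json(str(path))
        back = QsarModel.from_json(str(path))
        assert back == model
        assert json.loads(path.read_text())["cell_line"] == "MOLT-3"


class TestRanking:
    def test_hucca_fixture_top_is_8n(self, fixture):
        preds = fixture.printed_predictions
        sub = preds[preds["cell_line"] == "HuCCA-1"]
        ranked = rank_candidates(dict(zip(sub["compound_id"], sub["pic50"])))
        assert ranked.iloc[0]["compound_id"] == "8N"
        assert ranked.iloc[0]["predicted_class"] == "highly active"

    def test_hepg2_fixture_order(self, fixture):
        preds = fixture.printed_predictions
        sub = preds[preds["cell_line"] == "HepG2"]
        ranked = rank_candidates(dict(zip(sub["compound_id"], sub["pic50"])))
        assert list(ranked["compound_id"][:2]) == ["1P", "7F"]

    def test_single_candidate(self):
        ranked = rank_candidates({"X": -0.4})
        assert ranked.iloc[0]["rank"] == 1
        assert ranked.iloc[0]["predicted_class"] == "moderately active"

    def test_tie_break_by_id(self):
        ranked = rank_candidates({"B": 1.0, "A": 1.0, "C": 2.0})
        assert list(ranked["compound_id"]) == ["C", "A", "B"]

    def test_empty(self):
        with pytest.raises(ModelingError):
            rank_candidates({})


class TestEndToEndRecovery:
    def test_pipeline_recovers_support_and_cv_band(self):
        """filter -> stepwise -> fit -> LOO on synthetic tables at study scale."""
        truth = {"RDF105m": 0.104, "MATS7m": 7.8}
        spec = SyntheticSpec(n=24, coefficients=truth, intercept=-1.7,
                             noise_sigma=0.4, n_noise=8,
                             feature_correlation=0.6)
        hits, r_cvs = 0, []
        reps = 60
        for rep in range(reps):
            df, _ = generate_linear_dataset(spec, seed=9000 + rep)
            table = as_table(df)
            trace = select_features(table)
            if sorted(trace.selected) == sorted(truth):
                hits += 1
                report = loo_cross_validate(table, trace.selected)
                r_cvs.append(report.r_cv)
        assert hits / reps >= 0.8
        assert 0.6 <= np.mean(r_cvs) <= 0.93
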