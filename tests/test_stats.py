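import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from vrphen.features import FEATURE_NAMES
from vrphen.scales import MEASURES
from vrphen.stats import (
    EMPTY_MARK,
    StatsError,
    StepwiseConfig,
    backward_stepwise,
    correlation_screen,
    correlations_to_frame,
    models_to_frame,
    ols_fit,
    pearson_with_p,
    run_inference,
    vif,
    write_reports,
)


def feature_frame(rng, n, index=None):
    data = rng.normal(0.0, 1.0, (n, 7))
    idx = index if index is not None else [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame(data, columns=FEATURE_NAMES, index=idx)


def score_frame(rng, n, index=None):
    data = rng.normal(0.0, 1.0, (n, 11))
    idx = index if index is not None else [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame(data, columns=MEASURES, index=idx)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10
        assert n == 10

    def test_known_four_point_example(self):
        # closed-form two-sided p from the t distribution with 2 df is exactly 0.2
        r, p, n = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="zero variance"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError, match="length mismatch"):
            pearson_with_p([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_direct_covariance_computation(self, rng):
        for _ in range(20):
            x = rng.normal(0, 3, 15)
            y = rng.normal(0, 3, 15)
            r, _, _ = pearson_with_p(x, y)
            assert r == pytest.approx(oracles.pearson_r(x, y), abs=1e-12)


class TestScreen:
    def test_produces_all_77_records(self, rng):
        records = correlation_screen(feature_frame(rng, 30), score_frame(rng, 30))
        assert len(records) == 77
        frame = correlations_to_frame(records)
        assert set(frame["feature"]) == set(FEATURE_NAMES)
        assert set(frame["measure"]) == set(MEASURES)

    def test_records_sorted_by_feature_then_descending_abs_r(self, rng):
        records = correlation_screen(feature_frame(rng, 40), score_frame(rng, 40))
        by_feature = {}
        for rec in records:
            by_feature.setdefault(rec.feature, []).append(abs(rec.r))
        assert list(by_feature) == list(FEATURE_NAMES)  # feature blocks in order
        for vals in by_feature.values():
            assert vals == sorted(vals, reverse=True)

    def test_planted_pair_is_flagged(self, rng):
        feats = feature_frame(rng, 60)
        scores = score_frame(rng, 60)
        scores["adhd_hyperactivity"] = (
            3.0 * feats["average_speed"] + rng.normal(0, 0.5, 60)
        )
        records = correlation_screen(feats, scores)
        rec = next(
            r
            for r in records
            if r.feature == "average_speed" and r.measure == "adhd_hyperactivity"
        )
        assert rec.significant and rec.r > 0.9

    def test_small_or_constant_pairs_reported_not_dropped(self, rng):
        feats = feature_frame(rng, 5)
        scores = score_frame(rng, 5)
        scores["ari_parent"] = 1.0  # constant
        records = correlation_screen(feats, scores)
        assert len(records) == 77
        bad = [r for r in records if not r.computable]
        assert {r.measure for r in bad} == {"ari_parent"}


class TestOls:
    def test_exact_line(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        fit = ols_fit(X, [0.0, 1.0, 2.0])
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.coef["x"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.normal(0, 1, (40, 4)), columns=list("abcd"))
            y = rng.normal(0, 1, 40)
            fit = ols_fit(X, y)
            b0, betas = oracles.ols_normal_equations(X, y)
            assert fit.intercept == pytest.approx(b0, abs=1e-8)
            np.testing.assert_allclose(list(fit.coef.values()), betas, atol=1e-8)

    def test_null_pvalues_are_uniform(self, rng):
        # y independent of X: coefficient p-values should be U(0,1)
        pvals = []
        for _ in range(200):
            X = pd.DataFrame({"a": rng.normal(0, 1, 25), "b": rng.normal(0, 1, 25)})
            y = rng.normal(0, 1, 25)
            fit = ols_fit(X, y)
            pvals.extend(fit.pvalues.values())
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.001
        assert abs(np.mean(np.array(pvals) < 0.05) - 0.05) < 0.03

    def test_rank_deficiency_names_dependent_columns(self, rng):
        a = rng.normal(0, 1, 30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(0, 1, 30)})
        with pytest.raises(StatsError, match=r"\['a', 'b'\]"):
            ols_fit(X, rng.normal(0, 1, 30))

    def test_too_few_observations_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (4, 4)), columns=list("abcd"))
        with pytest.raises(StatsError, match="n > k\\+1"):
            ols_fit(X, rng.normal(0, 1, 4))


class TestVif:
    def test_orthogonal_design_is_all_ones(self):
        X = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        assert vif(X) == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}

    def test_correlation_0_9_closed_form(self):
        # construct two columns with sample correlation exactly 0.9
        n = 40
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - b.mean()
        b -= a * np.dot(a, b) / np.dot(a, a)  # residualize
        b /= b.std(ddof=1)
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        X = pd.DataFrame({"x1": a, "x2": x2})
        got = vif(X)
        assert np.corrcoef(a, x2)[0, 1] == pytest.approx(0.9, abs=1e-12)
        assert got["x1"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-9)
        assert got["x2"] == pytest.approx(5.2631578947, rel=1e-6)

    def test_duplicated_column_is_infinite(self, rng):
        a = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": a, "b": a.copy()})
        got = vif(X)
        assert np.isinf(got["a"]) and np.isinf(got["b"])

    def test_single_predictor_is_one_by_convention(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 10)})
        assert vif(X) == {"a": 1.0}

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        X = pd.DataFrame(rng.normal(0, 1, (50, 4)), columns=list("abcd"))
        X["b"] += 0.8 * X["a"]
        ours = vif(X)
        design = sm.add_constant(X.to_numpy())
        for j, c in enumerate(X.columns, start=1):
            assert ours[c] == pytest.approx(
                variance_inflation_factor(design, j), rel=1e-8
            )


class TestStepwise:
    def test_planted_predictor_is_recovered(self, rng):
        X = feature_frame(rng, 500)
        y = 2.0 * X["total_distance"] + rng.normal(0, 0.5, 500)
        res = backward_stepwise(X, y)
        assert res.predictors == ["total_distance"]
        planted_r2 = 1.0 - 0.25 / y.var()
        assert res.r2 == pytest.approx(planted_r2, abs=0.02)
        assert not res.empty_model

    def test_all_noise_design_yields_empty_model(self, rng):
        # deterministic fixture: independent noise everywhere
        X = feature_frame(np.random.default_rng(2024), 80)
        y = np.random.default_rng(99).normal(0, 1, 80)
        res = backward_stepwise(X, y)
        assert res.empty_model
        assert res.predictors == []
        assert res.r2 == 0.0
        assert res.intercept == pytest.approx(float(np.mean(y)))

    def test_p_remove_one_keeps_the_full_model(self, rng):
        X = feature_frame(rng, 60)
        y = rng.normal(0, 1, 60)
        cfg = StepwiseConfig(p_enter=1.0, p_remove=1.0)
        res = backward_stepwise(X, y, cfg)
        assert res.predictors == list(FEATURE_NAMES)

    def test_p_remove_zero_empties_the_model(self, rng):
        X = feature_frame(rng, 60)
        y = 2.0 * X["average_speed"] + rng.normal(0, 0.1, 60)
        cfg = StepwiseConfig(p_enter=0.0, p_remove=0.0)
        res = backward_stepwise(X, y, cfg)
        assert res.empty_model

    def test_perfectly_collinear_pair_pre_dropped(self, rng):
        X = feature_frame(rng, 100)
        X["total_distance"] = 450.0 * X["average_speed"]
        y = 3.0 * X["average_speed"] + rng.normal(0, 0.5, 100)
        res = backward_stepwise(X, y)
        dropped = [t["predictor"] for t in res.trace if t["action"] == "drop_collinear"]
        assert dropped == ["total_distance"]
        assert "average_speed" in res.predictors
        assert "total_distance" not in res.predictors

    def test_trace_records_every_removal(self, rng):
        X = feature_frame(rng, 200)
        y = 1.5 * X["acceleration"] + rng.normal(0, 1, 200)
        res = backward_stepwise(X, y)
        removed = [t["predictor"] for t in res.trace if t["action"] == "remove"]
        assert set(removed) | set(res.predictors) >= set(FEATURE_NAMES) - {
            p for t in res.trace if t["action"] == "drop_collinear"
            for p in [t["predictor"]]
        }
        assert all(t["p"] > 0.10 for t in res.trace if t["action"] == "remove")

    def test_small_n_starts_from_marginal_ranking(self, rng):
        X = feature_frame(rng, 7)
        y = rng.normal(0, 1, 7)
        res = backward_stepwise(X, y)
        assert any(t["action"] == "reduced_start" for t in res.trace)

    def test_config_guards(self):
        with pytest.raises(ValueError, match="p_enter"):
            StepwiseConfig(p_enter=0.2, p_remove=0.1)

    def test_vif_reported_only_for_retained(self, rng):
        X = feature_frame(rng, 300)
        y = X["average_speed"] + 0.8 * X["acceleration"] + rng.normal(0, 0.5, 300)
        res = backward_stepwise(X, y)
        assert set(res.vif) == set(res.predictors)
        assert all(res.pvalues[c] <= 0.10 for c in res.predictors)


class TestRunInference:
    def test_end_to_end_on_generated_tables(self, rng):
        feats = feature_frame(rng, 50)
        scores = score_frame(rng, 50)
        scores["adhd_hyperactivity"] = 2 * feats["total_distance"] + rng.normal(
            0, 0.5, 50
        )
        result = run_inference(feats, scores)
        assert len(result.correlations) == 77
        assert len(result.models) == 11
        assert list(result.descriptives["measure"]) == list(MEASURES)
        model = result.models["adhd_hyperactivity"]
        assert model is not None and "total_distance" in model.predictors

    def test_two_subject_cohort_degrades_gracefully(self, rng):
        feats = feature_frame(rng, 2)
        scores = score_frame(rng, 2)
        result = run_inference(feats, scores)
        assert all(not r.computable for r in result.correlations)
        assert all(m is None for m in result.models.values())
        assert len(result.refusals) == 11
        assert len(result.descriptives) == 11

    def test_duplicate_subject_ids_rejected(self, rng):
        feats = feature_frame(rng, 4, index=["A", "A", "B", "C"])
        scores = score_frame(rng, 4, index=["A", "B", "C", "D"])
        with pytest.raises(StatsError, match="duplicate"):
            run_inference(feats, scores)


class TestReports:
    def test_written_files_parse_and_render_dashes(self, rng, tmp_path):
        feats = feature_frame(rng, 40)
        scores = score_frame(rng, 40)
        result = run_inference(feats, scores)
        paths = write_reports(tmp_path, result)
        desc = pd.read_csv(paths["descriptives"])
        assert len(desc) == 11
        corr = pd.read_csv(paths["correlations"])
        assert len(corr) == 77
        models = pd.read_csv(paths["models_csv"])
        assert set(models["outcome"]) == set(MEASURES)
        # pure-noise outcomes produce at least one dash row
        empty_rows = models[models["predictor"] == EMPTY_MARK]
        assert (empty_rows[["beta", "p", "r2", "vif"]] == EMPTY_MARK).all().all()
        assert paths["trace"].read_text().strip()

    def test_models_frame_dash_convention(self, rng):
        X = feature_frame(rng, 60)
        y = rng.normal(0, 1, 60)
        res = backward_stepwise(X, y)
        frame = models_to_frame({"null_outcome": res})
        if res.empty_model:
            assert frame.iloc[0]["predictor"] == EMPTY_MARK
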