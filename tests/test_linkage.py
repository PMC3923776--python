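"""Polygon series assembly, screening, covariate models, stepwise build."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from spatregime.errors import InvalidConfigError, SingularFitError
from spatregime.gridding import GriddedField, PeriodPartition, RegionSet
from spatregime.linkage import (
    build_polygon_series,
    fit_covariate_model,
    fit_single_covariate,
    spearman_screen,
    ssb_sst_model,
    stepwise_recruitment_model,
)
from spatregime.report import format_stepwise_report
from spatregime.simulate import GeneratorConfig, generate_polygon_series


def _grid(years, value_fn, res=1.0):
    lons = np.array([0.5, 1.5, 2.5, 3.5])
    lats = np.array([51.5, 51.5, 52.5, 52.5])
    values = np.array(
        [[value_fn(lo, la, y) for y in years] for lo, la in zip(lons, lats)],
        dtype=float,
    )
    return GriddedField(lons, lats, np.asarray(years), values, res)


@pytest.fixture
def simple_regions():
    return RegionSet(
        regions={"A": box(0, 51, 2, 53), "B": box(2, 51, 4, 53)},
        nurseries={"A": box(0.2, 51.2, 1.8, 52.8), "B": box(2.2, 51.2, 3.8, 52.8)},
    )


class TestBuildPolygonSeries:
    def test_constant_fields_give_constant_series(self, simple_regions):
        years = np.arange(1989, 2000)
        recruit = _grid(years, lambda lo, la, y: 4.0, res=1.0)
        sst = _grid(years, lambda lo, la, y: 9.0)
        part = PeriodPartition(1990, 1999, (1995,))
        series = build_polygon_series(
            recruit, {"sst": sst}, simple_regions, part
        )
        assert (series["recruitment"] == 4.0).all()
        assert (series["sst"] == 9.0).all()
        assert set(series["region"]) == {"A", "B"}

    def test_lag_pairing_uses_previous_years_window(self, simple_regions):
        # field value equals its year: period 1990-1994 must average
        # 1989-1993
        years = np.arange(1989, 2000)
        recruit = _grid(years, lambda lo, la, y: 1.0)
        cov = _grid(years, lambda lo, la, y: float(y))
        part = PeriodPartition(1990, 1999, (1995,))
        series = build_polygon_series(
            recruit, {"cov": cov}, simple_regions, part, lag_years=1
        )
        first = series[series["year"] == 1990]["cov"].iloc[0]
        assert first == pytest.approx(np.mean(np.arange(1989, 1994)))
        second = series[series["year"] == 1996]["cov"].iloc[0]
        assert second == pytest.approx(np.mean(np.arange(1994, 1999)))

    def test_region_without_nursery_nodes_rejected(self):
        # nursery polygon misses every grid node
        regions = RegionSet(
            regions={"A": box(0, 51, 4, 53)},
            nurseries={"A": box(0.9, 51.9, 1.1, 52.1)},
        )
        years = np.arange(1989, 1995)
        recruit = _grid(years, lambda lo, la, y: 1.0)
        with pytest.raises(InvalidConfigError, match="nursery"):
            build_polygon_series(
                recruit, {}, regions, PeriodPartition(1990, 1994, ())
            )


class TestSpearman:
    def test_self_correlation_is_one(self, polygon_series):
        series, _ = polygon_series
        out = spearman_screen(series, [("ssb", "ssb")])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, polygon_series):
        series, _ = polygon_series
        series = series.assign(neg_ssb=-series["ssb"])
        out = spearman_screen(series, [("ssb", "neg_ssb")])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        # 10 points, no ties: rho = 1 - 6 sum(d^2) / (n(n^2-1))
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        df = pd.DataFrame({"x": x, "y": y, "region": "A"})
        out = spearman_screen(df, [("x", "y")])
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        rho = 1 - 6 * np.sum((rx - ry) ** 2) / (10 * 99)
        assert out["rho"].iloc[0] == pytest.approx(rho, abs=1e-12)

    def test_constant_variable_flagged_not_raised(self, polygon_series):
        series, _ = polygon_series
        series = series.assign(const=1.0)
        out = spearman_screen(series, [("ssb", "const")])
        assert out["flag"].iloc[0] == "constant-variable"
        assert np.isnan(out["rho"].iloc[0])

    def test_sst_drives_ratio_negatively(self, polygon_series):
        series, _ = polygon_series
        out = spearman_screen(series, [("sst_spring", "calanus_ratio")])
        assert out["rho"].iloc[0] < 0

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3], "region": "A"})
        from spatregime.errors import InvalidInputError

        with pytest.raises(InvalidInputError):
            spearman_screen(df, [("x", "y")])


class TestSingleCovariate:
    def test_quadratic_generator_fully_explained(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "region": np.tile(list("AB"), n // 2),
                "year": np.arange(n),
                "recruitment": 1.0 + 0.5 * x - 0.3 * x**2,
                "cov": x,
            }
        )
        model, _ = fit_single_covariate(df, "cov", cv=False)
        assert model.explained_deviance_pct == pytest.approx(100.0, abs=1e-6)

    def test_independent_covariate_near_zero_cv_deviance(self, rng):
        n = 2000
        df = pd.DataFrame(
            {
                "region": np.tile(list("ABCD"), n // 4),
                "year": np.arange(n),
                "recruitment": rng.normal(0, 1, n),
                "cov": rng.normal(0, 1, n),
            }
        )
        model, summary = fit_single_covariate(
            df, "cov", n_replicates=20, seed=3
        )
        assert abs(100.0 * summary.mean_d2_adj) < 3.0

    def test_binomial_family_for_ratio_response(self, polygon_series):
        series, _ = polygon_series
        model, _ = fit_single_covariate(
            series, "sst_spring", response="calanus_ratio",
            family="binomial", cv=False,
        )
        assert model.family == "binomial"
        assert 0 < model.explained_deviance_pct < 100
        # warm water depresses the cold-water species share
        assert model.marginal_sign("sst_spring") == -1

    def test_degree_cap(self, polygon_series):
        series, _ = polygon_series
        with pytest.raises(InvalidConfigError):
            fit_single_covariate(series, "ssb", degree=3)

    def test_constant_covariate_raises_in_strict_fit(self, polygon_series):
        series, _ = polygon_series
        series = series.assign(const=2.0)
        with pytest.raises(SingularFitError):
            fit_covariate_model(series, "recruitment", [("const", 2)])


class TestStepwise:
    def test_full_recovery_selects_all_three_groups(self):
        series, truth = generate_polygon_series(GeneratorConfig(), seed=5)
        model, trace = stepwise_recruitment_model(
            series, ["calanus_ratio", "c_helgolandicus"], seed=5
        )
        sel = trace.selected_covariates
        assert sel[0] == "ssb"
        assert "calanus_ratio" in sel
        assert "sst_spring" in sel
        assert model.marginal_sign("ssb") == truth["marginal_signs"]["ssb"]
        assert (
            model.marginal_sign("sst_spring")
            == truth["marginal_signs"]["sst_spring"]
        )

    def test_zero_effects_leave_steps_empty(self):
        series, _ = generate_polygon_series(
            GeneratorConfig(effect_shares={}), seed=6
        )
        model, trace = stepwise_recruitment_model(
            series, ["calanus_ratio", "c_helgolandicus"], seed=6
        )
        assert trace.selected_covariates == ["ssb"]
        zoop_steps = [s for s in trace.steps if s.name.startswith("zoop")]
        assert all(s.selected is None for s in zoop_steps)

    def test_final_model_nests_single_covariate_components(self):
        series, _ = generate_polygon_series(GeneratorConfig(), seed=7)
        model, trace = stepwise_recruitment_model(
            series, ["calanus_ratio"], seed=7
        )
        for cov, _deg in model.terms:
            single, _ = fit_single_covariate(series, cov, cv=False)
            assert (
                model.explained_deviance_pct
                >= single.explained_deviance_pct - 1e-9
            )

    def test_trace_reproducible_bit_for_bit(self):
        series, _ = generate_polygon_series(GeneratorConfig(), seed=8)
        reports = []
        for _ in range(2):
            _, trace = stepwise_recruitment_model(
                series, ["calanus_ratio", "c_helgolandicus"], seed=8
            )
            reports.append(format_stepwise_report(trace))
        assert reports[0] == reports[1]

    def test_gain_floor_is_three_percent(self):
        series, _ = generate_polygon_series(GeneratorConfig(), seed=9)
        _, trace = stepwise_recruitment_model(
            series, ["calanus_ratio", "c_helgolandicus"], seed=9
        )
        for step in trace.steps:
            for cand in step.candidates:
                if cand["significant"] and step.name != "ssb":
                    assert cand["gain_pct"] >= 3.0

    def test_polygon_factor_harmless_when_intercepts_shared(self, rng):
        # all regions share one intercept: dropping the polygon factor
        # moves explained deviance by < 1 point
        n = 400
        x = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "region": np.tile(list("ABCD"), n // 4),
                "year": np.arange(n),
                "recruitment": 2.0 + 0.8 * x + rng.normal(0, 0.5, n),
                "ssb": x,
            }
        )
        with_poly = fit_covariate_model(
            df, "recruitment", [("ssb", 2)], polygon_effect=True
        )
        without = fit_covariate_model(
            df, "recruitment", [("ssb", 2)], polygon_effect=False
        )
        assert abs(
            with_poly.explained_deviance_pct - without.explained_deviance_pct
        ) < 1.0

    def test_interaction_terms_extend_design(self):
        series, _ = generate_polygon_series(GeneratorConfig(), seed=10)
        base = fit_covariate_model(series, "recruitment", [("ssb", 2)])
        inter = fit_covariate_model(
            series, "recruitment", [("ssb", 2), ("sst_spring", 2)],
            interactions=("polygon:ssb", "product:ssb:sst_spring"),
        )
        assert len(inter.columns) > len(base.columns)
        assert any("*" in c for c in inter.columns)


class TestSsbSstModel:
    def test_quadratic_sst_dependence_recovered(self, rng):
        n = 320
        sst = rng.normal(9.5, 1.0, n)
        df = pd.DataFrame(
            {
                "region": np.tile(list("ABCD"), n // 4),
                "year": np.arange(n),
                "ssb": 3.0 - 0.8 * (sst - 9.5) - 0.2 * (sst - 9.5) ** 2,
                "sst_annual": sst,
            }
        )
        out = ssb_sst_model(df, seed=1, n_replicates=10)
        assert out["explained_deviance_pct"] == pytest.approx(100.0, abs=1e-6)

    def test_independent_sst_near_zero_cv_gain(self, rng):
        n = 800
        df = pd.DataFrame(
            {
                "region": np.tile(list("ABCD"), n // 4),
                "year": np.arange(n),
                "ssb": rng.normal(0, 1, n),
                "sst_annual": rng.normal(9.5, 1, n),
            }
        )
        out = ssb_sst_model(df, seed=2, n_replicates=20)
        assert abs(out["cv_gains"]["sst_annual"]["gain_pct"]) < 3.0

    def test_constant_fbar_contributes_zero_gain(self, rng):
        n = 320
        sst = rng.normal(9.5, 1.0, n)
        df = pd.DataFrame(
            {
                "region": np.tile(list("ABCD"), n // 4),
                "year": np.arange(n),
                "ssb": 3.0 - 0.5 * (sst - 9.5) + rng.normal(0, 0.3, n),
                "sst_annual": sst,
                "exp_neg_fbar": np.exp(-0.7),
            }
        )
        with pytest.warns(UserWarning, match="aliased"):
            out = ssb_sst_model(df, fbar="exp_neg_fbar", seed=3, n_replicates=10)
        assert out["cv_gains"]["exp_neg_fbar"]["gain_pct"] == pytest.approx(
            0.0, abs=1e-9
        )
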