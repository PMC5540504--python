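"""Full-factorial design generation and screening-model quality metrics."""

import numpy as np
import pandas as pd
import pytest

from lysetrack import (
    FactorSpec,
    FactorialScreeningModel,
    code_factors,
    fit_screening_model,
    full_factorial,
    homogenization_screening_factors,
    predict_surface,
    simulate_doe_dataset,
)

TRUE_COEFFS = {
    "intercept": 50.0,
    "biomass_gdcw_per_l": -12.0,
    "cycles": 25.0,
    "biomass_gdcw_per_l:cycles": -6.0,
}


@pytest.fixture
def design():
    return full_factorial(homogenization_screening_factors())


class TestFullFactorial:
    def test_screening_space_has_36_runs(self, design):
        assert len(design.runs) == 3 * 3 * 4
        assert not design.runs.duplicated(subset=design.factor_names).any()

    def test_two_level_factor(self):
        d = full_factorial([FactorSpec("x", (0.0, 1.0))])
        assert len(d.runs) == 2

    def test_contains_the_low_corner(self, design):
        corner = design.runs[
            (design.runs.pressure_bar == 500)
            & (design.runs.biomass_gdcw_per_l == 10)
            & (design.runs.cycles == 0)
        ]
        assert len(corner) == 1

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValueError):
            full_factorial([])


class TestCoding:
    def test_symmetric_three_level_factors(self, design):
        coded = code_factors(design)
        assert set(np.round(coded["pressure_bar"].unique(), 12)) == {-1.0, 0.0, 1.0}
        assert set(np.round(coded["biomass_gdcw_per_l"].unique(), 12)) == {-1.0, 0.0, 1.0}

    def test_four_level_cycles_map(self, design):
        coded = sorted(code_factors(design)["cycles"].unique())
        np.testing.assert_allclose(coded, [-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0])

    def test_constant_factor_rejected(self):
        with pytest.raises(ValueError):
            FactorSpec("x", (2.0, 2.0))

    def test_main_effect_columns_orthogonal(self, design):
        coded = code_factors(design).to_numpy()
        gram = coded.T @ coded
        off = gram - np.diag(np.diag(gram))
        np.testing.assert_allclose(off, 0.0, atol=1e-9)


class TestScreeningFit:
    def test_noise_free_coefficients_recovered(self, design):
        table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=0.0, seed=0)
        model = fit_screening_model(design, table["response"])
        by_term = dict(zip(model.term_names_, model.params_))
        for term, value in TRUE_COEFFS.items():
            assert by_term[term] == pytest.approx(value, abs=1e-9)
        for term in set(model.term_names_) - set(TRUE_COEFFS):
            assert by_term[term] == pytest.approx(0.0, abs=1e-9)
        assert model.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_q2_never_exceeds_r2(self, design):
        rng = np.random.default_rng(17)
        for seed in range(10):
            table = simulate_doe_dataset(
                design, TRUE_COEFFS, noise_sd=float(rng.uniform(0.5, 10)), seed=seed
            )
            model = fit_screening_model(design, table["response"])
            assert model.q2_ <= model.r2_ + 1e-12

    def test_q2_matches_explicit_leave_one_out_refits(self, design):
        """PRESS via the leverage shortcut equals brute-force LOO refitting."""
        table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=3.0, seed=5)
        y = table["response"].to_numpy()
        model = fit_screening_model(design, y)
        X = design.runs[design.factor_names].to_numpy(dtype=float)
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            sub = FactorialScreeningModel(factors=design.factors).fit(X[keep], y[keep])
            press += (y[i] - sub.predict(X[i : i + 1])[0]) ** 2
        sstot = np.sum((y - y.mean()) ** 2)
        assert model.q2_ == pytest.approx(1.0 - press / sstot, rel=1e-9)

    def test_null_pressure_effect_yields_large_p_value(self, design):
        hits = 0
        for seed in range(50):
            table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=3.0, seed=seed)
            model = fit_screening_model(design, table["response"])
            if model.p_value("pressure_bar") > 0.05:
                hits += 1
        assert hits >= 45

    def test_coefficient_error_shrinks_with_noise(self, design):
        errors = []
        for sd in (4.0, 0.5):
            errs = []
            for seed in range(5):
                table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=sd, seed=seed)
                model = fit_screening_model(design, table["response"])
                by_term = dict(zip(model.term_names_, model.params_))
                errs.append(abs(by_term["cycles"] - TRUE_COEFFS["cycles"]))
            errors.append(np.mean(errs))
        assert errors[1] < errors[0]

    def test_rank_deficiency_names_aliased_terms(self):
        factors = [FactorSpec("a", (0.0, 1.0)), FactorSpec("b", (0.0, 1.0))]
        runs = pd.DataFrame(
            {"run_id": [1, 2, 3, 4], "a": [0, 0, 1, 1], "b": [0, 0, 1, 1]}
        )
        from lysetrack.doe import DoEDesign

        design = DoEDesign(runs=runs, factors=factors)
        with pytest.raises(ValueError, match="aliased"):
            fit_screening_model(design, [1.0, 1.1, 2.0, 2.1])

    def test_interactions_can_be_disabled(self, design):
        table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=0.0, seed=0)
        model = fit_screening_model(design, table["response"], interactions=False)
        assert model.term_names_ == ["intercept", *design.factor_names]


class TestPredictSurface:
    @pytest.fixture
    def model(self, design):
        table = simulate_doe_dataset(design, TRUE_COEFFS, noise_sd=0.0, seed=0)
        return fit_screening_model(design, table["response"])

    def test_corner_prediction_equals_fitted_value(self, design, model):
        X = design.runs[design.factor_names].to_numpy(dtype=float)
        pred = model.predict(X[:1])
        grid = predict_surface(
            model,
            ("cycles", np.array([0.0])),
            ("biomass_gdcw_per_l", np.array([10.0])),
            fixed={"pressure_bar": 500.0},
        )
        assert grid.predicted[0, 0] == pytest.approx(pred[0], abs=1e-9)

    def test_pressure_free_model_gives_identical_slices(self, model):
        grids = [
            predict_surface(
                model,
                ("cycles", np.linspace(0, 3, 7)),
                ("biomass_gdcw_per_l", np.linspace(10, 100, 5)),
                fixed={"pressure_bar": p},
            )
            for p in (500.0, 1500.0)
        ]
        np.testing.assert_allclose(grids[0].predicted, grids[1].predicted, atol=1e-9)

    def test_grid_matches_pointwise_loop(self, model):
        ax1 = np.linspace(0, 3, 4)
        ax2 = np.linspace(10, 100, 3)
        grid = predict_surface(
            model, ("cycles", ax1), ("biomass_gdcw_per_l", ax2), fixed={"pressure_bar": 1000.0}
        )
        for i, b in enumerate(ax2):
            for j, c in enumerate(ax1):
                point = model.predict(np.array([[1000.0, b, c]]))[0]
                assert grid.predicted[i, j] == pytest.approx(point, abs=1e-9)

    def test_unknown_factor_rejected(self, model):
        with pytest.raises(KeyError, match="unknown factor"):
            predict_surface(
                model, ("flow_rate", np.array([1.0])), ("cycles", np.array([0.0])),
                fixed={"pressure_bar": 500.0, "biomass_gdcw_per_l": 10.0},
            )

    def test_extrapolation_warns(self, model):
        with pytest.warns(UserWarning, match="extrapolates"):
            predict_surface(
                model,
                ("cycles", np.array([5.0])),
                ("biomass_gdcw_per_l", np.array([55.0])),
                fixed={"pressure_bar": 1000.0},
            )
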