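"""OLS regression engine: oracle equivalence, fit statistics, model reporting.

The solver is checked against two independent routes — a brute-force
normal-equations solve and statsmodels OLS — on small random problems, and
against exact algebra on noiseless synthetic tables.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptp1b_qsar.qsar_regression import (
    InsufficientDataError,
    MLRModel,
    OverParameterizationWarning,
    SingularityError,
    adjusted_r_squared,
    equation_report,
    evaluate_test,
    fit_ols,
    model_selection_grid,
    parse_equation,
    percent,
    predict,
)
from ptp1b_qsar.split_design import SplitSpec, sorted_split
from ptp1b_qsar.synthetic_data import SyntheticSpec, generate_descriptor_table
from ptp1b_qsar.compound_data import DESCRIPTOR_NAMES


def _design_from(table, subset):
    sub = table.subset(subset)
    X = np.column_stack(
        [np.ones(len(sub))] + [[float(getattr(r, d)) for r in sub] for d in DESCRIPTOR_NAMES]
    )
    y = np.array([r.log_ic50 for r in sub])
    return X, y


@pytest.mark.parametrize("seed", range(5))
def test_ols_matches_normal_equations_and_statsmodels(seed):
    """Coefficients agree with two independent solvers within 1e-8."""
    import statsmodels.api as sm

    table, _ = generate_descriptor_table(SyntheticSpec(n=12, sigma=0.3, seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverParameterizationWarning)
        model, stats = fit_ols(table)
    X, y = _design_from(table, table.indices)
    beta_ne = np.linalg.solve(X.T @ X, X.T @ y)  # brute-force normal equations
    np.testing.assert_allclose(model.beta(), beta_ne, atol=1e-8)
    sm_fit = sm.OLS(y, X).fit()
    np.testing.assert_allclose(model.beta(), sm_fit.params, atol=1e-8)
    assert stats.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)


@pytest.mark.parametrize("seed", range(3))
def test_residuals_orthogonal_to_design(flavonoids, seed):
    rng = np.random.default_rng(seed)
    subset = sorted(rng.choice(flavonoids.indices, size=20, replace=False).tolist())
    model, _ = fit_ols(flavonoids, subset)
    X, y = _design_from(flavonoids, subset)
    resid = y - X @ model.beta()
    scale = np.abs(X).max() * np.abs(y).max()
    assert np.abs(X.T @ resid).max() <= 1e-8 * scale


def test_noiseless_synthetic_recovers_beta_exactly():
    table, beta = generate_descriptor_table(SyntheticSpec(n=46, sigma=0.0, seed=3))
    model, stats = fit_ols(table)
    assert stats.r2 == pytest.approx(1.0, abs=1e-12)
    assert model.intercept == pytest.approx(beta["intercept"], abs=1e-9)
    for d in DESCRIPTOR_NAMES:
        assert model.coefficients[d] == pytest.approx(beta[d], abs=1e-9)


def test_insufficient_data_and_overparameterization(flavonoids):
    with pytest.raises(InsufficientDataError):
        fit_ols(flavonoids, flavonoids.indices[:8])
    with pytest.warns(OverParameterizationWarning):
        fit_ols(flavonoids, flavonoids.indices[:12])


def test_rank_deficient_design_names_collinear_column(flavonoids):
    from dataclasses import replace

    from ptp1b_qsar.compound_data import DescriptorTable

    # make TPSA an exact multiple of MW -> collinear pair
    records = [replace(r, tpsa=2.0 * r.mw) for r in flavonoids.records]
    broken = DescriptorTable(records)
    with pytest.raises(SingularityError, match="mw|tpsa"):
        fit_ols(broken, broken.indices)


@pytest.mark.parametrize(
    "r2, n, p, expected",
    [
        (0.3267, 32, 7, 0.1303),
        (0.3611, 34, 7, 0.1891),
        (1.0, 20, 7, 1.0),
    ],
)
def test_adjusted_r_squared_values(r2, n, p, expected):
    assert adjusted_r_squared(r2, n, p) == pytest.approx(expected, abs=5e-5)


def test_adjusted_r_squared_domain():
    with pytest.raises(ValueError):
        adjusted_r_squared(0.5, 8, 7)


@given(
    r2a=st.floats(0.0, 1.0),
    r2b=st.floats(0.0, 1.0),
    n=st.integers(10, 200),
    p=st.integers(1, 7),
)
def test_adjusted_r_squared_monotonicity(r2a, r2b, n, p):
    """Increasing in R² for fixed (n, p); decreasing in p for fixed (R², n)."""
    lo, hi = sorted((r2a, r2b))
    assert adjusted_r_squared(lo, n, p) <= adjusted_r_squared(hi, n, p) + 1e-12
    if n > p + 2 and lo < 1.0:
        assert adjusted_r_squared(lo, n, p + 1) <= adjusted_r_squared(lo, n, p) + 1e-12


def test_constant_model_predicts_intercept(flavonoids):
    model = MLRModel(intercept=1.144, coefficients=dict.fromkeys(DESCRIPTOR_NAMES, 0.0))
    preds = predict(model, flavonoids, flavonoids.indices[:5])
    np.testing.assert_allclose(preds, 1.144)


def test_training_predictions_reproduce_sse(flavonoids):
    split = sorted_split(flavonoids, SplitSpec("naro", 0.25))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverParameterizationWarning)
        model, stats = fit_ols(flavonoids, split.train_indices)
    y_obs = np.array([flavonoids.record(i).log_ic50 for i in split.train_indices])
    y_pred = predict(model, flavonoids, split.train_indices)
    assert float(((y_obs - y_pred) ** 2).sum()) == pytest.approx(stats.sse, rel=1e-10)


def test_evaluate_test_perfect_and_shifted():
    y = [0.1, 0.5, 1.2, 0.8]
    perfect = evaluate_test(y, y)
    assert perfect.r2_det == pytest.approx(1.0) and perfect.r2_corr == pytest.approx(1.0)
    shifted = evaluate_test(y, [v + 0.3 for v in y])
    assert shifted.r2_corr == pytest.approx(1.0)
    assert shifted.r2_det < 1.0


def test_evaluate_test_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        evaluate_test([1.0, 2.0], [1.0, 2.0])
    from ptp1b_qsar.qsar_regression import UndefinedStatisticError

    with pytest.raises(UndefinedStatisticError):
        evaluate_test([1.0, 1.0, 1.0], [0.5, 0.7, 0.9])


def test_grid_has_32_rows_and_naro_peaks_at_25_75(flavonoids):
    grid = model_selection_grid(flavonoids)
    assert len(grid) == 32
    naro = grid[grid.sort_key == "naro"].set_index("ratio")
    assert naro["r2_train"].idxmax() == "25:75"
    # training block of the published naro model-selection table, percent, 2 dp
    assert percent(naro.loc["50:50", "r2_train"]) == 19.89
    assert percent(naro.loc["70:30", "r2_train"]) == 32.67
    assert percent(naro.loc["75:25", "r2_train"]) == 36.11
    assert percent(naro.loc["25:75", "r2_train"]) == 93.25


def test_grid_records_failures_in_row():
    table, _ = generate_descriptor_table(SyntheticSpec(n=6, sigma=0.1, seed=1))
    grid = model_selection_grid(table)
    assert (grid["note"].str.contains("not estimable")).any()
    assert len(grid) == 32


def test_equation_report_matches_published_format():
    model = MLRModel(
        intercept=1.144,
        coefficients={
            "mw": 0.0490, "hba": -6.481, "hbd": -4.669, "nrot": -0.2106,
            "naro": 0.1516, "tpsa": 0.442, "logp": -1.807,
        },
    )
    text = equation_report(model)
    assert text == (
        "LogIC50 = 1.144 + 0.049 × (MW) + -6.481 × (HBA) + -4.669 × (HBD) + "
        "-0.2106 × (nrot) + 0.1516 × (naro) + 0.442 × (TPSA) + -1.807 × (LogP)"
    )
    assert parse_equation(text) == MLRModel(model.intercept, model.coefficients)


def test_zero_model_renders_and_roundtrips():
    zero = MLRModel(intercept=0.0, coefficients=dict.fromkeys(DESCRIPTOR_NAMES, 0.0))
    assert equation_report(zero) == "LogIC50 = 0.000"


def test_equation_roundtrip_on_fitted_model(flavonoids):
    model, _ = fit_ols(flavonoids)
    recovered = parse_equation(equation_report(model, precision=12))
    assert recovered.intercept == pytest.approx(model.intercept, rel=1e-10)
    for d in DESCRIPTOR_NAMES:
        assert recovered.coefficients[d] == pytest.approx(model.coefficients[d], rel=1e-10)
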