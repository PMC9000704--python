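"""Multiple linear regression of LogIC50 on the seven molecular descriptors.

The QSAR model is ordinary least squares with an intercept,

    LogIC50 = β0 + β1·MW + β2·HBA + β3·HBD + β4·nrot + β5·naro + β6·TPSA + β7·LogP,

fitted on a training subset of the compound table and assessed by R² and
adjusted R² (p = 7 predictors throughout). Test-set performance is reported
under both common definitions of a predictive R² — 1 − SSres/SStot about the
test-set mean, and the squared Pearson correlation of predicted with observed
— because the two differ materially for externally applied models. The
package default is the former, the standard external-validation statistic in
QSAR work.

The solver is a numerically stable orthogonal decomposition (SVD-based least
squares), with pivoted-QR rank diagnosis so a rank-deficient design names its
collinear columns instead of silently producing one of many minimizers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .compound_data import DESCRIPTOR_NAMES, DescriptorTable
from .split_design import RATIOS, SORT_KEYS, SplitSpec, enumerate_splits, ratio_label, sorted_split, train_size

__all__ = [
    "MLRModel",
    "FitStats",
    "TestSetStats",
    "SingularityError",
    "InsufficientDataError",
    "UndefinedStatisticError",
    "OverParameterizationWarning",
    "fit_ols",
    "adjusted_r_squared",
    "predict",
    "evaluate_test",
    "model_selection_grid",
    "equation_report",
    "parse_equation",
    "percent",
]

#: Number of predictors in the full descriptor model.
N_PREDICTORS = 7

#: Minimum observations for a fit: intercept + 7 slopes + 1 residual df.
MIN_OBSERVATIONS = N_PREDICTORS + 2


class SingularityError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""


class InsufficientDataError(ValueError):
    """Too few observations to fit the full descriptor model."""


class UndefinedStatisticError(ValueError):
    """A requested statistic is undefined (e.g. zero response variance)."""


class OverParameterizationWarning(UserWarning):
    """Fit has very few residual degrees of freedom; estimates are fragile."""


@dataclass(frozen=True)
class MLRModel:
    """Fitted intercept and the seven descriptor coefficients."""

    intercept: float
    coefficients: dict[str, float]
    fitted_on: SplitSpec | str = "all"

    def __post_init__(self):
        if set(self.coefficients) != set(DESCRIPTOR_NAMES):
            missing = set(DESCRIPTOR_NAMES) - set(self.coefficients)
            extra = set(self.coefficients) - set(DESCRIPTOR_NAMES)
            raise ValueError(
                f"coefficients must map exactly the seven descriptors; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        object.__setattr__(
            self, "coefficients", {d: self.coefficients[d] for d in DESCRIPTOR_NAMES}
        )
        for name, v in self.coefficients.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite coefficient for {name}")

    def beta(self) -> np.ndarray:
        """Intercept followed by the seven slopes, in canonical order."""
        return np.array([self.intercept] + [self.coefficients[d] for d in DESCRIPTOR_NAMES])


@dataclass(frozen=True)
class FitStats:
    """Goodness of fit on the fitted subset."""

    r2: float
    adjusted_r2: float
    n: int
    p: int
    sse: float
    sst: float


@dataclass(frozen=True)
class TestSetStats:
    """Both predictive-R² definitions for an external evaluation.

    ``r2_det``: 1 − SSres/SStot about the observed test-set mean.
    ``r2_corr``: squared Pearson correlation of (observed, predicted).
    ``default`` names which one the package reports as *the* test R².
    """

    r2_det: float
    r2_corr: float
    n: int
    default: str = "det"

    @property
    def r2(self) -> float:
        return self.r2_det if self.default == "det" else self.r2_corr


def _design(table: DescriptorTable, subset: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    sub = table.subset(subset)
    X = np.column_stack(
        [np.ones(len(sub))] + [np.array([float(getattr(r, d)) for r in sub]) for d in DESCRIPTOR_NAMES]
    )
    y = np.array([r.log_ic50 for r in sub])
    return X, y


def fit_ols(
    table: DescriptorTable,
    subset: Sequence[int] | None = None,
    fitted_on: SplitSpec | str = "all",
) -> tuple[MLRModel, FitStats]:
    """Least-squares fit of LogIC50 on the seven descriptors plus intercept.

    ``subset`` is a list of compound indices (defaults to the whole table).
    Raises :class:`InsufficientDataError` below 9 observations and
    :class:`SingularityError` for a rank-deficient design; warns when the fit
    retains fewer residual degrees of freedom than predictors.
    """
    indices = list(subset) if subset is not None else list(table.indices)
    n = len(indices)
    if n < MIN_OBSERVATIONS:
        raise InsufficientDataError(
            f"need at least {MIN_OBSERVATIONS} observations for the "
            f"{N_PREDICTORS}-descriptor model, got {n}"
        )
    X, y = _design(table, indices)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: the trailing pivots index the (near-)dependent columns
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        names = ["intercept"] + list(DESCRIPTOR_NAMES)
        collinear = sorted(names[j] for j in piv[rank:])
        raise SingularityError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {', '.join(collinear)}"
        )
    df_resid = n - X.shape[1]
    if df_resid < N_PREDICTORS:
        warnings.warn(
            f"fit retains only {df_resid} residual degrees of freedom for "
            f"{N_PREDICTORS} predictors; coefficient estimates are fragile",
            OverParameterizationWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("response has zero variance; R² undefined")
    r2 = 1.0 - sse / sst
    adj = adjusted_r_squared(r2, n, N_PREDICTORS)
    model = MLRModel(
        intercept=float(beta[0]),
        coefficients={d: float(b) for d, b in zip(DESCRIPTOR_NAMES, beta[1:])},
        fitted_on=fitted_on,
    )
    return model, FitStats(r2=r2, adjusted_r2=adj, n=n, p=N_PREDICTORS, sse=sse, sst=sst)


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² requires n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def predict(model: MLRModel, table: DescriptorTable, subset: Sequence[int] | None = None) -> np.ndarray:
    """Predicted LogIC50, ŷ = β0 + Σ βᵢxᵢ, ordered as ``subset``."""
    indices = list(subset) if subset is not None else list(table.indices)
    X, _ = _design(table, indices)
    return X @ model.beta()


def evaluate_test(
    y_obs: Sequence[float], y_pred: Sequence[float], default: str = "det"
) -> TestSetStats:
    """Both candidate external-R² definitions for observed vs predicted.

    The two coincide for an in-sample OLS fit but separate for external
    predictions (a constant shift of ŷ leaves the correlation definition at 1
    while degrading the deterministic one). Neither definition reproduces the
    published test-set figures for this dataset; see the methods note.
    """
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yo.shape != yp.shape or yo.ndim != 1:
        raise ValueError("y_obs and y_pred must be equal-length 1-D vectors")
    if yo.size < 3:
        raise ValueError("need at least 3 observations to evaluate")
    if default not in ("det", "corr"):
        raise ValueError("default must be 'det' or 'corr'")
    sstot = float(((yo - yo.mean()) ** 2).sum())
    if sstot == 0:
        raise UndefinedStatisticError("observed values have zero variance")
    ssres = float(((yo - yp) ** 2).sum())
    r2_det = 1.0 - ssres / sstot
    if np.std(yp) == 0:
        r2_corr = 1.0 if np.allclose(yo, yp) else 0.0
    else:
        r2_corr = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    return TestSetStats(r2_det=r2_det, r2_corr=r2_corr, n=int(yo.size), default=default)


def model_selection_grid(table: DescriptorTable) -> pd.DataFrame:
    """Train/evaluate the full descriptor model over all 32 splits.

    One row per (sorting method, ratio) with training R², adjusted R², their
    gap, and both test-R² definitions. Cells that cannot be estimated (too few
    training compounds, degenerate response) carry a note instead of being
    dropped.
    """
    rows = []
    for key in SORT_KEYS:
        for frac in RATIOS:
            spec = SplitSpec(key, frac)
            row: dict = {
                "sort_key": key,
                "ratio": ratio_label(frac),
                "n_train": np.nan,
                "n_test": np.nan,
                "r2_train": np.nan,
                "adj_r2_train": np.nan,
                "gap": np.nan,
                "r2_test_det": np.nan,
                "r2_test_corr": np.nan,
                "note": "",
            }
            try:
                split = sorted_split(table, spec)
                row["n_train"] = len(split.train_indices)
                row["n_test"] = len(split.test_indices)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OverParameterizationWarning)
                    model, stats = fit_ols(table, split.train_indices, fitted_on=spec)
                row["r2_train"] = stats.r2
                row["adj_r2_train"] = stats.adjusted_r2
                row["gap"] = stats.r2 - stats.adjusted_r2
                y_obs = [table.record(i).log_ic50 for i in split.test_indices]
                y_pred = predict(model, table, split.test_indices)
                test = evaluate_test(y_obs, y_pred)
                row["r2_test_det"] = test.r2_det
                row["r2_test_corr"] = test.r2_corr
            except (InsufficientDataError, SingularityError, UndefinedStatisticError, ValueError) as exc:
                row["note"] = f"not estimable: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def percent(x: float, decimals: int = 2) -> float:
    """Value as a percentage, rounded half-up to the printed precision."""
    scaled = x * 100 * 10**decimals
    return math.floor(scaled + 0.5) / 10**decimals if scaled >= 0 else -math.floor(-scaled + 0.5) / 10**decimals


_EQ_TERMS = ("MW", "HBA", "HBD", "nrot", "naro", "TPSA", "LogP")


def equation_report(model: MLRModel, precision: int = 4) -> str:
    """Render the model equation, term order MW, HBA, HBD, nrot, naro, TPSA, LogP."""
    def fmt(v: float) -> str:
        return f"{v:.{precision}g}"

    if all(v == 0 for v in model.coefficients.values()):
        return f"LogIC50 = {fmt(model.intercept) if model.intercept else '0.000'}"
    parts = [fmt(model.intercept)]
    for d, label in zip(DESCRIPTOR_NAMES, _EQ_TERMS):
        parts.append(f"{fmt(model.coefficients[d])} × ({label})")
    return "LogIC50 = " + " + ".join(parts)


def parse_equation(text: str) -> MLRModel:
    """Inverse of :func:`equation_report` (round-trips at rendered precision)."""
    body = text.split("=", 1)[1]
    terms = [t.strip() for t in body.split(" + ")]
    intercept = float(terms[0])
    coeffs = dict.fromkeys(DESCRIPTOR_NAMES, 0.0)
    label_to_name = dict(zip(_EQ_TERMS, DESCRIPTOR_NAMES))
    for term in terms[1:]:
        value, label = term.split(" × ")
        coeffs[label_to_name[label.strip("() ")]] = float(value)
    return MLRModel(intercept=intercept, coefficients=coeffs)
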