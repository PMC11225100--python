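"""Ordinary least squares with closed-form coefficient standard errors.

These are the two competing analysis models fitted to every simulated
dataset of the Monte Carlo study: depression regressed on inflammation
alone (``fit_unadjusted``) and with adiposity as an additional covariate
(``fit_adjusted``). The focal quantity in both is the inflammation
coefficient and its standard error.

The solver is the textbook normal-equations path: beta = (X'X)^-1 X'y,
SE_j = sqrt(sigma2 * [(X'X)^-1]_jj) with sigma2 = RSS/(n-p), two-sided
p-values from the t distribution with the residual degrees of freedom.
It is deliberately lean so that hundreds of thousands of fits per study
stay cheap.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import special

__all__ = [
    "FOCAL_PREDICTOR",
    "CollinearityError",
    "Coefficient",
    "RegressionFit",
    "SchemaError",
    "fit_adjusted",
    "fit_ols",
    "fit_unadjusted",
]

#: Name of the focal predictor in the study's two analysis models.
FOCAL_PREDICTOR = "inflammation"

# Relative eigenvalue threshold below which X'X is treated as singular.
_RANK_RTOL = 1e-10


class CollinearityError(np.linalg.LinAlgError):
    """The design matrix is (numerically) rank deficient."""


class SchemaError(KeyError):
    """A required column is missing from the input table."""


class Coefficient(NamedTuple):
    estimate: float
    se: float
    t: float
    p: float


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """OLS fit: estimates, standard errors, t statistics, p-values.

    ``names`` lists the intercept first, then the predictors in design
    order. ``sigma2`` is the residual variance RSS/(n-p) and ``df_resid``
    the residual degrees of freedom n - (#predictors + 1).
    """

    names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    sigma2: float

    def __getitem__(self, name: str) -> Coefficient:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient named {name!r}") from None
        return Coefficient(
            float(self.estimates[i]), float(self.se[i]), float(self.t[i]), float(self.p[i])
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "se": self.se, "t": self.t, "p": self.p},
            index=list(self.names),
        )


def fit_ols(
    y: np.ndarray | pd.Series,
    predictors: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
) -> RegressionFit:
    """Fit y on the given predictors plus an intercept by least squares.

    ``predictors`` may be a DataFrame (column names are used) or a 2-d
    array with ``names`` supplied. Raises :class:`CollinearityError` on a
    rank-deficient design and :class:`ValueError` when there are not enough
    rows for a positive residual degree of freedom.
    """
    if isinstance(predictors, pd.DataFrame):
        if names is None:
            names = tuple(str(c) for c in predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    yv = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if yv.shape[0] != n:
        raise ValueError("y and predictors must have the same number of rows")
    if len(names) != k:
        raise ValueError("names must match the number of predictor columns")
    if n <= k + 1:
        raise ValueError(
            f"need n > #predictors + 1 for a residual df; got n={n}, predictors={k}"
        )

    design = np.empty((n, k + 1))
    design[:, 0] = 1.0
    design[:, 1:] = X
    G = design.T @ design
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= _RANK_RTOL * eig[-1]:
        raise CollinearityError("design matrix is rank deficient (collinear predictors)")
    cho = sla.cho_factor(G, lower=True, check_finite=False)
    beta = sla.cho_solve(cho, design.T @ yv, check_finite=False)
    resid = yv - design @ beta
    rss = float(resid @ resid)
    df = n - (k + 1)
    sigma2 = rss / df
    Ginv = sla.cho_solve(cho, np.eye(k + 1), check_finite=False)
    var = np.clip(sigma2 * np.diag(Ginv), 0.0, None)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    # two-sided p from the t distribution with df residual degrees of freedom
    p = 2.0 * special.stdtr(df, -np.abs(t))
    return RegressionFit(
        names=("intercept", *names),
        estimates=beta,
        se=se,
        t=t,
        p=p,
        df_resid=df,
        sigma2=sigma2,
    )


def _require_columns(data: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def fit_unadjusted(data: pd.DataFrame) -> RegressionFit:
    """Depression regressed on inflammation alone."""
    _require_columns(data, ["inflammation", "depression"])
    return fit_ols(data["depression"], data[["inflammation"]])


def fit_adjusted(data: pd.DataFrame) -> RegressionFit:
    """Depression regressed on inflammation, controlling for adiposity."""
    _require_columns(data, ["inflammation", "depression", "adiposity"])
    return fit_ols(data["depression"], data[["inflammation", "adiposity"]])
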