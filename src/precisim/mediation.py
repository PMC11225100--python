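"""Simple (single-mediator) mediation with a percentile-bootstrap CI.

The effect-size extraction stage of the study: with x = adiposity,
m = an inflammatory protein and y = depression symptoms, all three
variables are z-standardized and two OLS models are fitted,

    m = a * x + e1
    y = b * m + c' * x + e2

The indirect effect is the product of coefficients a*b, the direct effect
is c', and a*b + c' equals the total x -> y slope exactly for OLS. The
confidence interval for a*b is the percentile bootstrap: resample rows
with replacement, refit both models on the (already standardized) data,
and take empirical quantiles of the resampled products.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import fit_ols

__all__ = [
    "DegenerateScaleError",
    "MediationFit",
    "fit_mediation",
    "zstandardize",
]


class DegenerateScaleError(ValueError):
    """A variable has zero sample variance and cannot be standardized."""


@dataclasses.dataclass(frozen=True)
class MediationFit:
    """Standardized paths, indirect effect, and its bootstrap CI.

    All slopes are standardized betas. ``indirect_hat`` is exactly
    ``a_hat * b_hat``; ``ci_low``/``ci_high`` are percentile-bootstrap
    bounds for the indirect effect at confidence level ``ci_level``.
    ``n_used`` counts rows remaining after listwise deletion over the
    three analysis variables.
    """

    a_hat: float
    a_se: float
    a_p: float
    b_hat: float
    b_se: float
    b_p: float
    c_prime_hat: float
    c_prime_se: float
    c_prime_p: float
    total_hat: float
    total_se: float
    total_p: float
    indirect_hat: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    seed: int
    n_used: int

    def as_frame(self) -> pd.DataFrame:
        """Single-row summary table (the CSV written by the CLI)."""
        return pd.DataFrame([dataclasses.asdict(self)])


def zstandardize(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Return a copy with the named columns scaled to mean 0, sample SD 1.

    The SD uses the n-1 denominator. Other columns are untouched. A
    constant column raises :class:`DegenerateScaleError` naming it.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateScaleError(f"column {col!r} is constant (zero variance)")
        out[col] = (x - x.mean()) / sd
    return out


def _bootstrap_indirect(
    Z: np.ndarray, n_boot: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """Percentile-bootstrap draws of the indirect effect a*b.

    ``Z`` holds standardized columns (x, m, y). Resampled slopes are
    computed from per-resample centered second moments in closed form,
    chunked to bound memory at large n.
    """
    n = Z.shape[0]
    draws = np.empty(n_boot)
    done = 0
    while done < n_boot:
        c = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(c, n))
        R = Z[idx]  # (c, n, 3)
        mean = R.mean(axis=1)
        cross = np.einsum("cni,cnj->cij", R, R) / n - mean[:, :, None] * mean[:, None, :]
        sxx = cross[:, 0, 0]
        sxm = cross[:, 0, 1]
        smm = cross[:, 1, 1]
        smy = cross[:, 1, 2]
        sxy = cross[:, 0, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            a = sxm / sxx
            det = smm * sxx - sxm**2
            b = (smy * sxx - sxy * sxm) / det
        draws[done : done + c] = a * b
        done += c
    return draws


def fit_mediation(
    table: pd.DataFrame,
    x: str = "adiposity",
    m: str = "inflammation",
    y: str = "depression",
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationFit:
    """Fit the standardized simple-mediation model x -> m -> y.

    Rows with a missing value in any of the three analysis columns are
    dropped (listwise deletion); at least 10 complete rows are required.
    The bootstrap is deterministic given ``seed``.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cols = [x, m, y]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    work = table[cols].dropna()
    n_used = len(work)
    if n_used < 10:
        raise ValueError(
            f"need at least 10 complete rows after listwise deletion, got {n_used}"
        )
    z = zstandardize(work, cols)

    fit_a = fit_ols(z[m], z[[x]])
    fit_y = fit_ols(z[y], z[[m, x]])
    fit_total = fit_ols(z[y], z[[x]])
    a_hat, a_se, _, a_p = fit_a[x]
    b_hat, b_se, _, b_p = fit_y[m]
    c_hat, c_se, _, c_p = fit_y[x]
    tot_hat, tot_se, _, tot_p = fit_total[x]

    rng = np.random.default_rng(seed)
    draws = _bootstrap_indirect(z[cols].to_numpy(), n_boot, rng)
    alpha = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(draws, [alpha, 1.0 - alpha])

    return MediationFit(
        a_hat=a_hat,
        a_se=a_se,
        a_p=a_p,
        b_hat=b_hat,
        b_se=b_se,
        b_p=b_p,
        c_prime_hat=c_hat,
        c_prime_se=c_se,
        c_prime_p=c_p,
        total_hat=tot_hat,
        total_se=tot_se,
        total_p=tot_p,
        indirect_hat=a_hat * b_hat,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        n_used=n_used,
    )
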