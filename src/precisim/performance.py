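"""Simulation-study performance metrics with Monte Carlo standard errors.

Given the long results table of the Monte Carlo engine, this module
computes the usual simulation performance measures per scenario and
method — bias, empirical SE, model SE, power — plus the headline metric of
the study: the relative gain in precision of a method versus a reference
method,

    gain% = 100 * ((empSE_ref / empSE_method)^2 - 1),

which is negative when the method is *less* precise than the reference
(the adjusted model's position throughout the study). Monte Carlo standard
errors follow the standard simulation-study conventions: the closed forms
for empirical SE and power, and a leave-one-replication-out jackknife over
the paired estimate streams for the precision gain.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DegenerateVarianceError",
    "PairedSEComparison",
    "SUMMARY_COLUMNS",
    "analytic_precision_loss",
    "compare_se_paired",
    "plot_precision_gain",
    "plot_se_distributions",
    "summarize_performance",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "scenario_label",
    "method",
    "n",
    "n_reps",
    "mean_estimate",
    "bias",
    "empse",
    "empse_mcse",
    "modse",
    "power",
    "power_mcse",
    "precision_gain_pct",
    "precision_gain_mcse",
)


class DegenerateVarianceError(ValueError):
    """An empirical SE (or the variance of paired differences) is zero."""


class PairedSEComparison:
    """Paired t comparison of per-replication standard errors.

    ``statistic`` is t = mean(d) / (SD(d)/sqrt(n_reps)) over the paired
    differences d_r = SE_ref,r - SE_other,r; a negative t means the
    non-reference method's SEs are systematically larger.
    """

    __slots__ = ("statistic", "pvalue", "n_reps", "mean_diff")

    def __init__(self, statistic: float, pvalue: float, n_reps: int, mean_diff: float):
        self.statistic = statistic
        self.pvalue = pvalue
        self.n_reps = n_reps
        self.mean_diff = mean_diff

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PairedSEComparison(statistic={self.statistic:.4g}, "
            f"pvalue={self.pvalue:.4g}, n_reps={self.n_reps})"
        )


def analytic_precision_loss(a: float, convention: str = "unit_residual") -> float:
    """Large-replication limit of the adjusted model's precision loss (%).

    With no direct covariate -> outcome path, adjusting for the exposure's
    ancestor inflates the sampling variance of the focal coefficient by the
    variance-inflation factor 1/(1 - corr(A, M)^2). Expressed as the loss
    100*(1 - empSE_un^2/empSE_adj^2), the limit is ``100*a^2`` when all
    total variances are 1 ("standardized" convention, corr = a) and
    ``100*a^2/(1+a^2)`` under unit residual variances (corr^2 = a^2/(1+a^2)).
    """
    if convention == "standardized":
        if not abs(a) < 1:
            raise ValueError("standardized convention requires |a| < 1")
        return 100.0 * a**2
    if convention == "unit_residual":
        return 100.0 * a**2 / (1.0 + a**2)
    raise ValueError(f"unknown variance convention {convention!r}")


def _jackknife_gain_mcse(est_ref: np.ndarray, est_m: np.ndarray) -> float:
    """Leave-one-replication-out jackknife MCSE of the precision gain."""
    n = est_ref.size
    if n < 3:
        return float("nan")

    def _loo_var(x: np.ndarray) -> np.ndarray:
        s, q = x.sum(), (x**2).sum()
        mean_i = (s - x) / (n - 1)
        ss_i = q - x**2 - (n - 1) * mean_i**2
        return ss_i / (n - 2)

    var_ref_i = _loo_var(est_ref)
    var_m_i = _loo_var(est_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain_i = 100.0 * (var_ref_i / var_m_i - 1.0)
    gain_i = gain_i[np.isfinite(gain_i)]
    if gain_i.size < 3:
        return float("nan")
    return float(np.sqrt((n - 1) / n * np.sum((gain_i - gain_i.mean()) ** 2)))


def summarize_performance(
    results: pd.DataFrame,
    true_value: float | Mapping[str, float],
    ref_method: str = "unadjusted",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (scenario, method) performance summary.

    ``true_value`` is the generating focal coefficient — a single number,
    or a mapping from scenario label to number when the table holds several
    scenarios. ``ref_method`` anchors the precision-gain comparison; its
    own gain is exactly 0. Replications with missing p-values are excluded
    from power with a logged count.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if results.empty:
        return pd.DataFrame(columns=list(SUMMARY_COLUMNS))
    methods = list(dict.fromkeys(results["method"]))
    if ref_method not in methods:
        raise ValueError(f"reference method {ref_method!r} not present in results")

    rows = []
    for label, group in results.groupby("scenario_label", sort=False):
        if isinstance(true_value, Mapping):
            try:
                tv = float(true_value[label])
            except KeyError:
                raise KeyError(f"no true value supplied for scenario {label!r}") from None
        else:
            tv = float(true_value)
        wide_est = group.pivot(index="rep", columns="method", values="estimate")
        ref_est = wide_est[ref_method].to_numpy()
        if np.std(ref_est, ddof=1) == 0.0:
            raise DegenerateVarianceError(
                f"scenario {label!r}: zero empirical SE for reference method"
            )
        for method in methods:
            sub = group[group["method"] == method]
            n_reps = len(sub)
            if n_reps < 2:
                raise ValueError(
                    f"scenario {label!r}, method {method!r}: need >= 2 replications"
                )
            estimates = sub["estimate"].to_numpy()
            ses = sub["se"].to_numpy()
            pv = sub["p"].to_numpy()
            empse = float(np.std(estimates, ddof=1))
            if empse == 0.0:
                raise DegenerateVarianceError(
                    f"scenario {label!r}, method {method!r}: zero empirical SE"
                )
            p_ok = np.isfinite(pv)
            n_dropped = int(n_reps - p_ok.sum())
            if n_dropped:
                logger.warning(
                    "scenario %s, method %s: %d replication(s) with missing "
                    "p-values excluded from power",
                    label,
                    method,
                    n_dropped,
                )
            power = float(np.mean(pv[p_ok] < alpha)) if p_ok.any() else float("nan")
            n_power = int(p_ok.sum())
            if method == ref_method:
                gain, gain_mcse = 0.0, 0.0
            else:
                m_est = wide_est[method].to_numpy()
                paired = np.isfinite(ref_est) & np.isfinite(m_est)
                gain = float(
                    100.0
                    * (
                        np.var(ref_est[paired], ddof=1) / np.var(m_est[paired], ddof=1)
                        - 1.0
                    )
                )
                gain_mcse = _jackknife_gain_mcse(ref_est[paired], m_est[paired])
            rows.append(
                {
                    "scenario_label": label,
                    "method": method,
                    "n": int(sub["n"].iloc[0]),
                    "n_reps": n_reps,
                    "mean_estimate": float(estimates.mean()),
                    "bias": float(estimates.mean() - tv),
                    "empse": empse,
                    "empse_mcse": empse / np.sqrt(2.0 * (n_reps - 1)),
                    "modse": float(np.sqrt(np.mean(ses**2))),
                    "power": power,
                    "power_mcse": float(np.sqrt(power * (1.0 - power) / n_power))
                    if n_power
                    else float("nan"),
                    "precision_gain_pct": gain,
                    "precision_gain_mcse": gain_mcse,
                }
            )
    summary = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    summary.attrs["alpha"] = alpha
    summary.attrs["ref_method"] = ref_method
    return summary


def compare_se_paired(results: pd.DataFrame, ref_method: str = "unadjusted") -> PairedSEComparison:
    """Paired t test of per-replication SEs, reference minus the other method.

    Requires a single-scenario results table with exactly two methods whose
    replication indices match. All-equal differences (zero variance) raise
    :class:`DegenerateVarianceError` — the t statistic is undefined there.
    """
    labels = results["scenario_label"].unique()
    if labels.size != 1:
        raise ValueError("compare_se_paired expects results from a single scenario")
    wide = results.pivot(index="rep", columns="method", values="se")
    methods = [m for m in wide.columns]
    if ref_method not in methods:
        raise ValueError(f"reference method {ref_method!r} not present")
    others = [m for m in methods if m != ref_method]
    if len(others) != 1:
        raise ValueError("expected exactly two methods")
    other = others[0]
    wide = wide.dropna()
    d = wide[ref_method].to_numpy() - wide[other].to_numpy()
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 paired replications")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError(
            "all paired SE differences are identical; paired t is undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * special.stdtr(n - 1, -abs(t)))
    return PairedSEComparison(statistic=t, pvalue=p, n_reps=n, mean_diff=float(d.mean()))


# ---------------------------------------------------------------------------
# Optional plots (cosmetic; matplotlib imported lazily)


def plot_precision_gain(summary: pd.DataFrame, path: str) -> None:
    """Dot plot of precision gain per scenario with +-1.96 MCSE intervals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 + 0.4 * len(summary)))
    ypos = np.arange(len(summary))
    ax.errorbar(
        summary["precision_gain_pct"],
        ypos,
        xerr=1.96 * summary["precision_gain_mcse"].fillna(0.0),
        fmt="o",
        capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(summary["scenario_label"] + " / " + summary["method"])
    ax.set_xlabel("relative gain in precision vs reference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_se_distributions(results: pd.DataFrame, path: str) -> None:
    """Overlaid kernel-density plots of per-method SE distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(dict.fromkeys(results["scenario_label"]))
    fig, axes = plt.subplots(
        len(scenarios), 1, figsize=(7, 2.2 * len(scenarios)), squeeze=False
    )
    for ax, label in zip(axes.ravel(), scenarios):
        group = results[results["scenario_label"] == label]
        for method, sub in group.groupby("method"):
            ses = sub["se"].to_numpy()
            grid = np.linspace(ses.min() * 0.9, ses.max() * 1.1, 200)
            ax.plot(grid, stats.gaussian_kde(ses)(grid), label=method)
            ax.fill_between(grid, stats.gaussian_kde(ses)(grid), alpha=0.25)
        ax.set_title(label)
        ax.set_xlabel("reported SE of the focal coefficient")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
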