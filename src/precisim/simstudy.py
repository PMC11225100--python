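"""The Monte Carlo engine: replicate, fit both models, collect long results.

A :class:`Scenario` is one simulation cell — a protein's chain coefficients
(a, b, c'), a sample size N, and a replication count. For every replication
the engine draws one dataset from the chain DGM and fits the two competing
OLS models (depression on inflammation, with and without adiposity),
recording the focal inflammation coefficient, its standard error and
p-value for each method.

Seeding contract: replication ``r`` of the scenario at position ``s`` in a
study uses ``numpy.random.SeedSequence(master_seed, spawn_key=(s, r))``,
so scenarios can be run in any order (or in parallel) with byte-identical
output, and any single replication's dataset can be regenerated on its own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from . import __version__
from .dag import DagSpec, chain_dag, standardize_residuals, _simulate
from .estimators import CollinearityError, FOCAL_PREDICTOR, fit_ols

if TYPE_CHECKING:  # pragma: no cover
    from .config import StudyConfig

__all__ = [
    "METHODS",
    "RESULT_COLUMNS",
    "ConfigError",
    "Scenario",
    "SimulationError",
    "rep_seed",
    "run_scenario",
    "run_study",
]

logger = logging.getLogger(__name__)

METHODS = ("unadjusted", "adjusted")
RESULT_COLUMNS = ("scenario_label", "n", "rep", "method", "estimate", "se", "p")
VARIANCE_CONVENTIONS = ("unit_residual", "standardized")

#: Abort a scenario when more than this share of replications fail.
MAX_FAILURE_RATE = 0.01


class ConfigError(ValueError):
    """Invalid study configuration (e.g. duplicate scenario labels)."""


class SimulationError(RuntimeError):
    """Too many replications failed to fit."""


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One simulation cell of the study.

    ``a``, ``b`` and ``c_prime`` are the chain path coefficients
    (covariate -> exposure, exposure -> outcome, covariate -> outcome
    direct). ``seed`` is the master seed from which per-replication
    streams are derived.
    """

    label: str
    a: float
    b: float
    n: int
    nsim: int
    c_prime: float = 0.0
    seed: int = 0
    variance_convention: str = "unit_residual"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"scenario {self.label!r}: n must be >= 10, got {self.n}")
        if self.nsim < 1:
            raise ValueError(f"scenario {self.label!r}: nsim must be >= 1")
        for name in ("a", "b", "c_prime"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"scenario {self.label!r}: {name} must be finite")
        if self.variance_convention not in VARIANCE_CONVENTIONS:
            raise ValueError(
                f"unknown variance convention {self.variance_convention!r}; "
                f"expected one of {VARIANCE_CONVENTIONS}"
            )

    def dag(self) -> DagSpec:
        """The chain DGM under this scenario's variance convention."""
        dag = chain_dag(self.a, self.b, self.c_prime)
        if self.variance_convention == "standardized":
            dag = standardize_residuals(dag)
        return dag


def rep_seed(master_seed: int, scenario_index: int, rep: int) -> int:
    """Derived integer seed for one replication (documented formula).

    ``SeedSequence(master_seed, spawn_key=(scenario_index, rep)).generate_state(1)[0]``
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(scenario_index, rep))
    return int(ss.generate_state(1)[0])


def run_scenario(scenario: Scenario, scenario_index: int = 0) -> pd.DataFrame:
    """Run all replications of one scenario.

    Returns the long results table with columns
    ``scenario_label, n, rep, method, estimate, se, p`` — two rows
    (unadjusted, adjusted) per replication, both fitted to the same
    dataset. Replications whose design is rank deficient are skipped with
    a warning; more than 1% failures aborts.
    """
    dag = scenario.dag()
    B = dag.coefficients
    resid_sd = np.sqrt(dag.residual_variances)
    nsim, n = scenario.nsim, scenario.n

    est = np.empty((nsim, 2))
    ses = np.empty((nsim, 2))
    pvals = np.empty((nsim, 2))
    ok = np.zeros(nsim, dtype=bool)
    failures = 0
    for r in range(1, nsim + 1):
        rng = np.random.default_rng(rep_seed(scenario.seed, scenario_index, r))
        data = _simulate(B, resid_sd, n, rng)
        y = data[:, 2]
        try:
            fu = fit_ols(y, data[:, 1:2], names=(FOCAL_PREDICTOR,))
            fa = fit_ols(y, data[:, [1, 0]], names=(FOCAL_PREDICTOR, "adiposity"))
        except CollinearityError:
            failures += 1
            logger.warning(
                "scenario %s: replication %d skipped (rank-deficient design)",
                scenario.label,
                r,
            )
            continue
        cu = fu[FOCAL_PREDICTOR]
        ca = fa[FOCAL_PREDICTOR]
        est[r - 1] = (cu.estimate, ca.estimate)
        ses[r - 1] = (cu.se, ca.se)
        pvals[r - 1] = (cu.p, ca.p)
        ok[r - 1] = True

    if failures > MAX_FAILURE_RATE * nsim:
        raise SimulationError(
            f"scenario {scenario.label!r}: {failures}/{nsim} replications failed"
        )

    reps = np.flatnonzero(ok) + 1
    frames = pd.DataFrame(
        {
            "scenario_label": scenario.label,
            "n": n,
            "rep": np.repeat(reps, 2),
            "method": np.tile(np.array(METHODS, dtype=object), reps.size),
            "estimate": est[ok].ravel(),
            "se": ses[ok].ravel(),
            "p": pvals[ok].ravel(),
        }
    )
    return frames


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scenario_label": pd.Series(dtype=object),
            "n": pd.Series(dtype=int),
            "rep": pd.Series(dtype=int),
            "method": pd.Series(dtype=object),
            "estimate": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "p": pd.Series(dtype=float),
        }
    )


def run_study(
    config: "StudyConfig", out_dir: str | os.PathLike | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run every scenario of a study and optionally write the outputs.

    Returns ``(results, provenance)``: the concatenated long results table
    and a provenance record echoing the configuration and package version.
    With ``out_dir`` set, writes ``results.csv`` and ``provenance.json``
    there. Duplicate scenario labels raise :class:`ConfigError`.
    """
    labels = [s.label for s in config.scenarios]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ConfigError(f"duplicate scenario labels: {dupes}")

    parts = []
    for idx, base in enumerate(config.scenarios):
        scenario = dataclasses.replace(
            base, seed=config.seed, variance_convention=config.variance_convention
        )
        logger.info(
            "running scenario %d/%d: %s (n=%d, nsim=%d)",
            idx + 1,
            len(labels),
            scenario.label,
            scenario.n,
            scenario.nsim,
        )
        parts.append(run_scenario(scenario, scenario_index=idx))
    results = pd.concat(parts, ignore_index=True) if parts else _empty_results()

    provenance = {
        "package": "precisim",
        "version": __version__,
        "seed": config.seed,
        "variance_convention": config.variance_convention,
        "alpha": config.alpha,
        "ref_method": config.ref_method,
        "scenarios": [
            {
                "label": s.label,
                "a": s.a,
                "b": s.b,
                "c_prime": s.c_prime,
                "n": s.n,
                "nsim": s.nsim,
            }
            for s in config.scenarios
        ],
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        results.to_csv(os.path.join(out_dir, "results.csv"), index=False)
        with open(os.path.join(out_dir, "provenance.json"), "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2)
            fh.write("\n")
    return results, provenance
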