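"""Linear-Gaussian directed acyclic graph models.

A :class:`DagSpec` is a fully parametric linear structural equation system:
each node is a linear combination of its parents plus independent Gaussian
noise. The class stores the nodes in a topological order, a strictly
lower-triangular matrix of path coefficients, and one residual variance per
node. From such a specification we can

* compute the exactly implied covariance matrix (path tracing in closed form),
* rescale residual variances so that every variable has unit total variance
  (the "standardized" convention, under which path coefficients are
  standardized betas),
* draw reproducible i.i.d. samples, and
* classify the causal role of a covariate relative to an exposure-outcome
  pair (confounder / mediator / collider / ...), the decision that drives
  covariate-selection advice in epidemiological modelling.

The canonical three-node chain used throughout the package is
``adiposity -> inflammation -> depression``: body fat drives circulating
inflammatory proteins (IL-6, CRP), which in turn predict depression
symptoms, with an optional direct adiposity -> depression path.
"""

from __future__ import annotations

import dataclasses
import enum
import io
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import linalg as sla

__all__ = [
    "CHAIN_NODES",
    "PRESETS",
    "CovarianceMatrix",
    "CovariateRole",
    "DagSpec",
    "GraphStructureError",
    "InfeasibleStandardizationError",
    "chain_dag",
    "classify_covariate",
    "dag_from_yaml",
    "dag_to_yaml",
    "implied_covariance",
    "preset_dag",
    "simulate_dataset",
    "standardize_residuals",
    "to_networkx",
]

#: Canonical node names for the adiposity -> inflammation -> depression chain.
CHAIN_NODES: tuple[str, str, str] = ("adiposity", "inflammation", "depression")

#: Standardized path coefficients for the two inflammatory-protein chains:
#: ``a`` is adiposity -> protein, ``b`` is protein -> depression (given
#: adiposity), ``c_prime`` the direct adiposity -> depression path (null in
#: both fitted models).
PRESETS: dict[str, dict[str, float]] = {
    "il6": {"a": 0.274, "b": 0.125, "c_prime": 0.0},
    "crp": {"a": 0.429, "b": 0.108, "c_prime": 0.0},
}


class GraphStructureError(ValueError):
    """The coefficient matrix is incompatible with the stored node order."""


class InfeasibleStandardizationError(ValueError):
    """A node's explained variance is >= 1, so no positive residual variance
    can bring its total variance to one."""


class CovariateRole(str, enum.Enum):
    """Causal role of a covariate relative to an (exposure, outcome) pair."""

    CONFOUNDER = "confounder"
    MEDIATOR = "mediator"
    COLLIDER = "collider"
    EXPOSURE_ONLY_ANCESTOR = "exposure_only_ancestor"
    OUTCOME_ONLY_ANCESTOR = "outcome_only_ancestor"
    DISCONNECTED = "disconnected"


@dataclasses.dataclass(frozen=True)
class DagSpec:
    """A linear-Gaussian DAG in a fixed topological node order.

    Parameters
    ----------
    node_names
        Unique node names, listed in a topological order (causes before
        effects).
    coefficients
        Square matrix ``B`` with ``B[j, i]`` the path coefficient from node
        ``i`` to node ``j``. Must be strictly lower triangular under the
        stored order; any entry on or above the diagonal would encode an
        edge against the order (a cycle or self-loop).
    residual_variances
        Strictly positive residual (disturbance) variance for each node.
    """

    node_names: tuple[str, ...]
    coefficients: np.ndarray
    residual_variances: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.node_names)
        B = np.array(self.coefficients, dtype=float)
        psi = np.array(self.residual_variances, dtype=float)
        object.__setattr__(self, "node_names", names)
        object.__setattr__(self, "coefficients", B)
        object.__setattr__(self, "residual_variances", psi)

        p = len(names)
        if len(set(names)) != p:
            raise ValueError("node names must be unique")
        if B.shape != (p, p):
            raise ValueError(f"coefficient matrix must be {p}x{p}, got {B.shape}")
        if psi.shape != (p,):
            raise ValueError("residual_variances must have one entry per node")
        if not np.all(np.isfinite(B)):
            raise ValueError("path coefficients must be finite")
        if not (np.all(np.isfinite(psi)) and np.all(psi > 0)):
            raise ValueError("residual variances must be finite and > 0")
        bad = np.argwhere(np.triu(B) != 0.0)
        if bad.size:
            j, i = bad[0]
            raise GraphStructureError(
                f"edge {names[i]} -> {names[j]} contradicts the stored "
                "topological order (cycle or self-loop)"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"node {name!r} is not in the DAG") from None


@dataclasses.dataclass(frozen=True)
class CovarianceMatrix:
    """Symmetric positive semi-definite covariance with named rows/columns."""

    node_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.node_names)
        V = np.array(self.values, dtype=float)
        object.__setattr__(self, "node_names", names)
        object.__setattr__(self, "values", V)
        p = len(names)
        if V.shape != (p, p):
            raise ValueError("covariance dimensions must match node_names")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(V).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names, columns=self.node_names)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        i = self.node_names.index(a)
        j = self.node_names.index(b)
        return float(self.values[i, j])


def chain_dag(
    a: float,
    b: float,
    c_prime: float = 0.0,
    residual_variances: Sequence[float] = (1.0, 1.0, 1.0),
    node_names: Sequence[str] = CHAIN_NODES,
) -> DagSpec:
    """Three-node causal chain X -> M -> Y with optional direct X -> Y path.

    ``a`` is the X -> M coefficient, ``b`` the M -> Y coefficient and
    ``c_prime`` the direct X -> Y coefficient (0 for a pure chain). Default
    node names follow the adiposity/inflammation/depression use case.
    """
    B = np.zeros((3, 3))
    B[1, 0] = a
    B[2, 1] = b
    B[2, 0] = c_prime
    return DagSpec(tuple(node_names), B, np.asarray(residual_variances, dtype=float))


def preset_dag(name: str, variance_convention: str = "unit_residual") -> DagSpec:
    """Return the bundled IL-6 or CRP chain under the requested convention."""
    try:
        coefs = PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    dag = chain_dag(coefs["a"], coefs["b"], coefs["c_prime"])
    if variance_convention == "standardized":
        dag = standardize_residuals(dag)
    elif variance_convention != "unit_residual":
        raise ValueError(f"unknown variance convention {variance_convention!r}")
    return dag


def implied_covariance(dag: DagSpec) -> CovarianceMatrix:
    """Exact model-implied covariance Sigma = (I-B)^-1 Psi (I-B)^-T.

    Equivalent to Wright's path-tracing rules; the reduced form of the
    structural system X = BX + e with Cov(e) = diag(Psi).
    """
    p = dag.n_nodes
    A = np.eye(p) - dag.coefficients
    # A is unit lower triangular, so the solve is exact and cheap.
    Ainv = sla.solve_triangular(A, np.eye(p), lower=True)
    sigma = Ainv @ np.diag(dag.residual_variances) @ Ainv.T
    sigma = (sigma + sigma.T) / 2.0
    return CovarianceMatrix(dag.node_names, sigma)


def standardize_residuals(dag: DagSpec) -> DagSpec:
    """Rescale residual variances so every implied total variance equals 1.

    Path coefficients are kept exactly as given; only the disturbance
    variances change. Under the resulting spec the coefficients are
    standardized betas. Raises :class:`InfeasibleStandardizationError` if a
    node's parents already explain >= 100% of a unit variance.
    """
    p = dag.n_nodes
    B = dag.coefficients
    sigma = np.zeros((p, p))
    psi = np.empty(p)
    for j in range(p):
        bj = B[j, :j]
        explained = float(bj @ sigma[:j, :j] @ bj)
        if explained >= 1.0:
            raise InfeasibleStandardizationError(
                f"node {dag.node_names[j]!r}: parents explain "
                f"{explained:.4f} >= 1 of a unit total variance"
            )
        psi[j] = 1.0 - explained
        cross = bj @ sigma[:j, :j]
        sigma[j, :j] = cross
        sigma[:j, j] = cross
        sigma[j, j] = 1.0
    return DagSpec(dag.node_names, B.copy(), psi)


def _simulate(
    B: np.ndarray, residual_sd: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. rows from the structural system (internal fast path)."""
    p = B.shape[0]
    X = rng.standard_normal((n, p)) * residual_sd
    for j in range(p):
        parents = np.flatnonzero(B[j, :j])
        if parents.size:
            X[:, j] += X[:, parents] @ B[j, parents]
    return X


def simulate_dataset(dag: DagSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` i.i.d. observations of all nodes.

    Each node is its parents' linear combination plus Gaussian noise with
    the node's residual variance. Identical ``(dag, n, seed)`` yields
    bit-identical output.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    data = _simulate(dag.coefficients, np.sqrt(dag.residual_variances), int(n), rng)
    return pd.DataFrame(data, columns=list(dag.node_names))


def to_networkx(dag: DagSpec) -> nx.DiGraph:
    """The DAG as a :class:`networkx.DiGraph` with ``coef`` edge attributes."""
    g = nx.DiGraph()
    g.add_nodes_from(dag.node_names)
    idx = np.argwhere(dag.coefficients != 0.0)
    for j, i in idx:
        g.add_edge(dag.node_names[i], dag.node_names[j], coef=float(dag.coefficients[j, i]))
    return g


def classify_covariate(
    dag: DagSpec, exposure: str, outcome: str, covariate: str
) -> CovariateRole:
    """Classify a covariate's causal role for an exposure-outcome analysis.

    The labels follow the standard covariate-selection taxonomy:

    - ``confounder``: the covariate causes both exposure and outcome through
      directed paths that do not pass through the exposure (a fork).
    - ``mediator``: caused by the exposure and a cause of the outcome
      (sits on a chain between them).
    - ``collider``: caused by both exposure and outcome (an inverted fork);
      adjusting for it opens a spurious path.
    - ``exposure_only_ancestor``: causes the exposure, and every directed
      path from it to the outcome runs through the exposure. Adjusting for
      such a variable cannot remove bias but inflates the variance of the
      exposure coefficient (the adiposity case).
    - ``outcome_only_ancestor``: the symmetric case on the outcome side.
    - ``disconnected``: none of the above.
    """
    for name in (exposure, outcome, covariate):
        dag.index(name)
    if covariate in (exposure, outcome):
        raise ValueError("covariate must differ from exposure and outcome")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")

    g = to_networkx(dag)
    desc = nx.descendants(g, covariate)
    caused_by_exposure = covariate in nx.descendants(g, exposure)
    caused_by_outcome = covariate in nx.descendants(g, outcome)
    causes_exposure = exposure in desc
    causes_outcome = outcome in desc

    g_no_exposure = g.copy()
    g_no_exposure.remove_node(exposure)
    reaches_outcome_avoiding_exposure = (
        covariate in g_no_exposure and outcome in nx.descendants(g_no_exposure, covariate)
    )

    if causes_exposure and reaches_outcome_avoiding_exposure:
        return CovariateRole.CONFOUNDER
    if caused_by_exposure and causes_outcome:
        return CovariateRole.MEDIATOR
    if caused_by_exposure and caused_by_outcome:
        return CovariateRole.COLLIDER
    if causes_exposure:
        return CovariateRole.EXPOSURE_ONLY_ANCESTOR
    if causes_outcome:
        return CovariateRole.OUTCOME_ONLY_ANCESTOR
    return CovariateRole.DISCONNECTED


# ---------------------------------------------------------------------------
# YAML serialization
#
# Schema:
#   nodes: [name, ...]                # topological order
#   edges: [{from: name, to: name, coef: float}, ...]
#   residual_variances: {name: float} # optional, default 1.0


def dag_from_yaml(source: str | IO[str]) -> DagSpec:
    """Parse a DAG specification from a YAML string, path, or open stream."""
    if isinstance(source, str) and "\n" not in source and not source.lstrip().startswith("{"):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, str):
        doc = yaml.safe_load(io.StringIO(source))
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, Mapping) or "nodes" not in doc:
        raise ValueError("DAG YAML must be a mapping with a 'nodes' list")
    names = [str(n) for n in doc["nodes"]]
    pos = {n: i for i, n in enumerate(names)}
    p = len(names)
    B = np.zeros((p, p))
    for edge in doc.get("edges", []) or []:
        src, dst = str(edge["from"]), str(edge["to"])
        for node in (src, dst):
            if node not in pos:
                raise GraphStructureError(f"edge references unknown node {node!r}")
        B[pos[dst], pos[src]] = float(edge.get("coef", 1.0))
    psi = np.ones(p)
    for node, v in (doc.get("residual_variances") or {}).items():
        if str(node) not in pos:
            raise GraphStructureError(f"residual variance for unknown node {node!r}")
        psi[pos[str(node)]] = float(v)
    return DagSpec(tuple(names), B, psi)


def dag_to_yaml(dag: DagSpec, path: str | None = None) -> str:
    """Serialize a DAG to the YAML schema; optionally write it to ``path``."""
    edges = []
    idx = np.argwhere(dag.coefficients != 0.0)
    for j, i in sorted(map(tuple, idx)):
        edges.append(
            {
                "from": dag.node_names[i],
                "to": dag.node_names[j],
                "coef": float(dag.coefficients[j, i]),
            }
        )
    doc = {
        "nodes": list(dag.node_names),
        "edges": edges,
        "residual_variances": {
            n: float(v) for n, v in zip(dag.node_names, dag.residual_variances)
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
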