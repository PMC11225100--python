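"""Linear-Gaussian DAG: implied moments, sampling, standardization, roles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from precisim.dag import (
    CHAIN_NODES,
    CovarianceMatrix,
    CovariateRole,
    DagSpec,
    GraphStructureError,
    InfeasibleStandardizationError,
    chain_dag,
    classify_covariate,
    dag_from_yaml,
    dag_to_yaml,
    implied_covariance,
    simulate_dataset,
    standardize_residuals,
)
from precisim.estimators import fit_ols


def fork_dag():
    """stress -> inflammation, stress -> depression (common cause)."""
    B = np.zeros((3, 3))
    B[1, 0] = 0.5  # stress -> inflammation
    B[2, 0] = 0.5  # stress -> depression
    return DagSpec(("stress", "inflammation", "depression"), B, np.ones(3))


def collider_dag(u=0.5, v=0.5):
    """vaccination -> inflammation <- exercise (common effect)."""
    B = np.zeros((3, 3))
    B[2, 0] = u
    B[2, 1] = v
    return DagSpec(("vaccination", "exercise", "inflammation"), B, np.ones(3))


class TestDagSpecValidation:
    def test_cycle_edge_named_in_error(self):
        B = np.zeros((3, 3))
        B[0, 2] = 0.4  # depression -> adiposity, against the stored order
        with pytest.raises(GraphStructureError, match="depression -> adiposity"):
            DagSpec(CHAIN_NODES, B, np.ones(3))

    def test_self_loop_rejected(self):
        B = np.zeros((2, 2))
        B[1, 1] = 0.1
        with pytest.raises(GraphStructureError):
            DagSpec(("a", "b"), B, np.ones(2))

    @pytest.mark.parametrize("psi", [(1.0, 0.0, 1.0), (1.0, -0.5, 1.0)])
    def test_nonpositive_residual_variance_rejected(self, psi):
        with pytest.raises(ValueError, match="residual variances"):
            chain_dag(0.5, 0.5, residual_variances=psi)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            DagSpec(("a", "a"), np.zeros((2, 2)), np.ones(2))


class TestImpliedCovariance:
    def test_empty_graph_is_identity(self):
        dag = DagSpec(("x", "y", "z"), np.zeros((3, 3)), np.ones(3))
        assert np.allclose(implied_covariance(dag).values, np.eye(3))

    def test_chain_closed_form(self):
        # a=b=.5, unit residuals: Var(M)=1.25, Var(Y)=1.3125, cov(A,M)=.5,
        # cov(A,Y)=.25, cov(M,Y)=.625
        cov = implied_covariance(chain_dag(0.5, 0.5))
        expected = np.array(
            [[1.0, 0.5, 0.25], [0.5, 1.25, 0.625], [0.25, 0.625, 1.3125]]
        )
        assert np.allclose(cov.values, expected)

    def test_chain_cross_covariance_is_indirect_effect(self):
        # cov(adiposity, depression) = a*b = .034 for the IL-6 chain
        cov = implied_covariance(chain_dag(0.274, 0.125))
        assert cov["adiposity", "depression"] == pytest.approx(0.034, abs=5e-4)

    def test_matches_monte_carlo_sample_covariance(self):
        n = 400_000
        dag = chain_dag(0.5, 0.5)
        data = simulate_dataset(dag, n, seed=99)
        sample = np.cov(data.to_numpy().T)
        assert np.abs(sample - implied_covariance(dag).values).max() < 4 / np.sqrt(n)

    def test_invariant_to_consistent_relabeling(self):
        # swapping the two effect nodes of a fork is still topological;
        # named entries must not depend on the storage order
        dag = fork_dag()
        cov = implied_covariance(dag)
        perm = [0, 2, 1]
        permuted = DagSpec(
            tuple(dag.node_names[i] for i in perm),
            dag.coefficients[np.ix_(perm, perm)],
            dag.residual_variances[perm],
        )
        cov_perm = implied_covariance(permuted)
        assert np.allclose(cov_perm.values, cov.values[np.ix_(perm, perm)])
        assert cov_perm["inflammation", "depression"] == pytest.approx(
            cov["inflammation", "depression"]
        )

    def test_covariance_type_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceMatrix(("a", "b"), np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestStandardizeResiduals:
    def test_no_edges_unchanged(self):
        dag = DagSpec(("x", "y"), np.zeros((2, 2)), np.ones(2))
        assert np.allclose(standardize_residuals(dag).residual_variances, 1.0)

    @pytest.mark.parametrize(
        "a, b, expected_psi",
        [
            (0.5, 0.5, (1.0, 0.75, 0.75)),
            (0.274, 0.125, (1.0, 1 - 0.274**2, 1 - 0.125**2)),
        ],
    )
    def test_chain_closed_form(self, a, b, expected_psi):
        std = standardize_residuals(chain_dag(a, b))
        assert np.allclose(std.residual_variances, expected_psi)
        assert np.allclose(std.coefficients, chain_dag(a, b).coefficients)

    def test_round_trip_unit_diagonal(self):
        std = standardize_residuals(chain_dag(0.429, 0.108, 0.3))
        diag = np.diag(implied_covariance(std).values)
        assert np.allclose(diag, 1.0, atol=1e-14)

    def test_infeasible_when_explained_variance_exceeds_one(self):
        with pytest.raises(InfeasibleStandardizationError, match="inflammation"):
            standardize_residuals(chain_dag(1.2, 0.5))


class TestSimulateDataset:
    def test_zero_rows_keeps_columns(self):
        df = simulate_dataset(chain_dag(0.5, 0.5), 0, seed=0)
        assert list(df.columns) == list(CHAIN_NODES)
        assert len(df) == 0

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset(chain_dag(0.5, 0.5), -1, seed=0)

    def test_bit_identical_given_seed(self):
        dag = chain_dag(0.274, 0.125)
        a = simulate_dataset(dag, 100, seed=42)
        b = simulate_dataset(dag, 100, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_dataset(dag, 100, seed=43)
        assert not np.array_equal(a.to_numpy(), c.to_numpy())

    def test_independence_when_all_coefficients_zero(self):
        dag = DagSpec(CHAIN_NODES, np.zeros((3, 3)), np.ones(3))
        corr = simulate_dataset(dag, 10_000, seed=5).corr().to_numpy()
        assert np.abs(corr - np.eye(3)).max() < 0.03

    def test_sample_correlation_under_unit_residual_convention(self):
        # corr(A, M) = a / sqrt(1 + a^2) when residual variances are 1
        df = simulate_dataset(chain_dag(0.429, 0.108), 100_000, seed=7)
        r = np.corrcoef(df["adiposity"], df["inflammation"])[0, 1]
        assert r == pytest.approx(0.429 / np.sqrt(1.184), abs=0.01)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        coefs=st.lists(st.floats(-0.4, 0.4), min_size=6, max_size=6),
        psi=st.lists(st.floats(0.2, 0.5), min_size=4, max_size=4),
        seed=st.integers(0, 2**20),
    )
    def test_sample_covariance_converges_to_implied(self, coefs, psi, seed):
        """Property: sample covariance matches the implied covariance within
        4/sqrt(n) entrywise for random 4-node DAGs. Variances are kept below
        one so the 4/sqrt(n) band is several sampling SDs wide."""
        B = np.zeros((4, 4))
        B[np.tril_indices(4, -1)] = coefs
        dag = DagSpec(("w", "x", "y", "z"), B, np.array(psi))
        n = 40_000
        data = simulate_dataset(dag, n, seed=seed)
        sample = np.cov(data.to_numpy().T)
        assert np.abs(sample - implied_covariance(dag).values).max() < 4 / np.sqrt(n)


class TestClassifyCovariate:
    def test_fundamental_structures(self):
        chain = chain_dag(0.5, 0.5)
        assert (
            classify_covariate(chain, "adiposity", "depression", "inflammation")
            is CovariateRole.MEDIATOR
        )
        fork = fork_dag()
        assert (
            classify_covariate(fork, "inflammation", "depression", "stress")
            is CovariateRole.CONFOUNDER
        )
        coll = collider_dag()
        assert (
            classify_covariate(coll, "vaccination", "exercise", "inflammation")
            is CovariateRole.COLLIDER
        )

    def test_exposure_only_ancestor_in_chain(self):
        # adiposity causes inflammation, reaching depression only through it
        chain = chain_dag(0.274, 0.125)
        assert (
            classify_covariate(chain, "inflammation", "depression", "adiposity")
            is CovariateRole.EXPOSURE_ONLY_ANCESTOR
        )

    def test_outcome_only_ancestor_and_disconnected(self):
        B = np.zeros((4, 4))
        B[3, 0] = 0.5  # z -> outcome
        dag = DagSpec(("z", "lone", "exposure", "outcome"), B, np.ones(4))
        assert (
            classify_covariate(dag, "exposure", "outcome", "z")
            is CovariateRole.OUTCOME_ONLY_ANCESTOR
        )
        assert (
            classify_covariate(dag, "exposure", "outcome", "lone")
            is CovariateRole.DISCONNECTED
        )

    def test_errors(self):
        chain = chain_dag(0.5, 0.5)
        with pytest.raises(KeyError):
            classify_covariate(chain, "inflammation", "depression", "nope")
        with pytest.raises(ValueError):
            classify_covariate(chain, "inflammation", "depression", "inflammation")

    def test_collider_adjustment_induces_spurious_association(self):
        """Marginally independent causes become partially associated once
        their common effect enters the model."""
        data = simulate_dataset(collider_dag(0.6, 0.6), 10_000, seed=11)
        adjusted = fit_ols(data["exercise"], data[["vaccination", "inflammation"]])
        assert abs(adjusted["vaccination"].t) > 2
        # the induced association has the classic negative sign
        assert adjusted["vaccination"].estimate < 0


class TestYaml:
    def test_round_trip(self, tmp_path):
        dag = chain_dag(0.274, 0.125, residual_variances=(1.0, 0.9, 1.1))
        path = tmp_path / "chain.yaml"
        dag_to_yaml(dag, str(path))
        back = dag_from_yaml(str(path))
        assert back.node_names == dag.node_names
        assert np.allclose(back.coefficients, dag.coefficients)
        assert np.allclose(back.residual_variances, dag.residual_variances)

    def test_default_residual_variance_is_one(self):
        text = "nodes: [a, b]\nedges:\n  - {from: a, to: b, coef: 0.5}\n"
        dag = dag_from_yaml(text)
        assert np.allclose(dag.residual_variances, 1.0)
        assert dag.coefficients[1, 0] == 0.5

    def test_unknown_node_in_edge(self):
        text = "nodes: [a, b]\nedges:\n  - {from: a, to: q, coef: 0.5}\n"
        with pytest.raises(GraphStructureError, match="q"):
            dag_from_yaml(text)
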