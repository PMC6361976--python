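import numpy as np
import pandas as pd
import pytest

from splsnet.eqtl import map_cis_eqtl
from splsnet.inference import (
    ConvergenceError,
    NetworkConfig,
    adaptive_lasso,
    fit_network,
    kkt_residual,
    penalized_objective,
    stage1_ridge,
    stage2_fit_gene,
)
from splsnet.synthetic import simulate_dataset
from splsnet.types import ExpressionMatrix, GenotypeMatrix

from _oracles import lasso_sign_enumeration


class TestStage1Ridge:
    def test_lambda_zero_equals_ols(self, rng):
        x = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        fitted, lam = stage1_ridge(x, y, lambda_grid=np.array([0.0]))
        xc = x - x.mean(axis=0)
        beta = np.linalg.lstsq(xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(fitted, xc @ beta + y.mean(), atol=1e-8)

    def test_huge_lambda_shrinks_to_mean(self, rng):
        x = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fitted, _ = stage1_ridge(x, y, lambda_grid=np.array([1e12]))
        assert np.allclose(fitted, y.mean(), atol=1e-6)

    def test_small_system_closed_form(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0])
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(xc.T @ xc + np.eye(2), xc.T @ yc)
        fitted, lam = stage1_ridge(x, y, lambda_grid=np.array([1.0]))
        assert lam == 1.0
        assert np.allclose(fitted, xc @ beta + y.mean(), atol=1e-12)

    def test_empty_instruments_returns_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        fitted, lam = stage1_ridge(np.empty((3, 0)), y)
        assert np.allclose(fitted, 2.0)
        assert np.isnan(lam)

    def test_gcv_picks_from_grid(self, rng):
        x = rng.normal(size=(50, 10))
        y = x[:, 0] + rng.normal(scale=0.1, size=50)
        _, lam = stage1_ridge(x, y)
        assert lam in np.logspace(-4, 4, 25)

    def test_invariant_to_column_order(self, rng):
        x = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        f1, _ = stage1_ridge(x, y)
        f2, _ = stage1_ridge(x[:, ::-1], y)
        assert np.allclose(f1, f2, atol=1e-10)


class TestAdaptiveLasso:
    def test_lambda_zero_equals_ols(self, rng):
        d = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        beta = adaptive_lasso(d, y, np.ones(4), 0.0)
        ols = np.linalg.lstsq(d, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-8)

    def test_above_threshold_all_zero(self, rng):
        d = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        w = np.ones(4)
        lam_max = np.max(np.abs(d.T @ y) / 50)
        beta = adaptive_lasso(d, y, w, lam_max * 1.0001)
        assert np.all(beta == 0)

    def test_orthonormal_soft_threshold_50_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, d = 64, int(rng.integers(2, 9))
            q, _ = np.linalg.qr(rng.normal(size=(n, d)))
            design = q * np.sqrt(n)  # D'D / n = I
            y = rng.normal(size=n)
            w = rng.uniform(0.2, 2.0, size=d)
            lam = float(rng.uniform(0.01, 0.3))
            beta = adaptive_lasso(design, y, w, lam)
            ols = design.T @ y / n
            closed = np.sign(ols) * np.maximum(np.abs(ols) - lam * w, 0.0)
            assert np.allclose(beta, closed, atol=1e-8)

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n, d = 40, int(rng.integers(2, 7))
            design = rng.normal(size=(n, d))
            design[:, 0] *= 3  # unequal scales
            y = design @ rng.normal(size=d) * 0.5 + rng.normal(size=n)
            w = rng.uniform(0.2, 2.0, size=d)
            lam = float(rng.uniform(0.02, 0.5))
            beta = adaptive_lasso(design, y, w, lam)
            oracle_beta, oracle_obj = lasso_sign_enumeration(design, y, w, lam)
            obj = penalized_objective(design, y, beta, w, lam)
            assert obj == pytest.approx(oracle_obj, abs=1e-8)
            assert np.allclose(beta, oracle_beta, atol=1e-6)

    def test_kkt_residual_small(self, rng):
        d = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        w = rng.uniform(0.5, 1.5, size=8)
        beta = adaptive_lasso(d, y, w, 0.1)
        assert kkt_residual(d, y, beta, w, 0.1) <= 1e-6

    def test_unpenalized_columns(self, rng):
        d = rng.normal(size=(50, 3))
        y = d[:, 2] * 2.0 + rng.normal(scale=0.1, size=50)
        beta = adaptive_lasso(d, y, np.ones(3), 10.0, unpenalized=[2])
        assert beta[0] == 0 and beta[1] == 0
        assert beta[2] != 0

    def test_monotone_sparsity_in_lambda(self, rng):
        d = rng.normal(size=(60, 10))
        y = d @ rng.normal(size=10) + rng.normal(size=60)
        w = np.ones(10)
        sizes = []
        for lam in np.geomspace(1e-3, 2.0, 12):
            beta = adaptive_lasso(d, y, w, lam)
            sizes.append(int(np.count_nonzero(beta)))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            adaptive_lasso(np.array([[np.nan]]), np.array([1.0]), np.array([1.0]), 0.1)

    def test_nonconvergence_carries_kkt(self, rng):
        d = rng.normal(size=(30, 4))
        d[:, 1] = d[:, 0] + 1e-12 * rng.normal(size=30)
        y = d[:, 0] + rng.normal(size=30)
        with pytest.raises(ConvergenceError) as err:
            adaptive_lasso(d, y, np.ones(4), 1e-6, max_iter=2)
        assert err.value.kkt_residual >= 0


class TestStage2FitGene:
    def test_null_regulators_rejected(self):
        # no true regulation: selected regulator set empty in >= 90% of reps
        rng = np.random.default_rng(21)
        empty = 0
        reps = 100
        for _ in range(reps):
            n = 200
            instruments = rng.integers(0, 2, size=(n, 4)).astype(float)
            y_hat_others = instruments[:, :3] * 1.0  # other genes' expectations
            own_cis = instruments[:, 3:4]
            y = own_cis[:, 0] * 1.5 + rng.normal(scale=0.3, size=n)
            gamma_col, _ = stage2_fit_gene(y, y_hat_others, own_cis)
            if np.count_nonzero(gamma_col) == 0:
                empty += 1
        assert empty >= 90

    def test_single_regulator_recovered_with_sign(self):
        rng = np.random.default_rng(22)
        good = 0
        reps = 100
        for _ in range(reps):
            n = 200
            x = rng.integers(0, 2, size=(n, 2)).astype(float)
            y_hat_reg = x[:, 0:1]  # the true regulator's fitted expectation
            own_cis = x[:, 1:2]
            y = 0.8 * y_hat_reg[:, 0] + 1.0 * own_cis[:, 0] + rng.normal(scale=0.3, size=n)
            gamma_col, psi_col = stage2_fit_gene(y, y_hat_reg, own_cis)
            if gamma_col[0] > 0 and np.count_nonzero(gamma_col) == 1:
                good += 1
        assert good >= 90

    def test_zero_columns_give_ols_on_cis(self, rng):
        n = 80
        own_cis = rng.integers(0, 2, size=(n, 2)).astype(float)
        y = own_cis @ np.array([1.0, -0.5]) + rng.normal(scale=0.1, size=n)
        y_hat_others = np.zeros((n, 5))
        gamma_col, psi_col = stage2_fit_gene(y, y_hat_others, own_cis)
        assert np.all(gamma_col == 0)
        xc = own_cis - own_cis.mean(axis=0)
        ols = np.linalg.lstsq(xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(psi_col, ols, atol=1e-6)


def _edge_sets(ds, estimate):
    ids = ds.truth.gene_ids
    true = {(ids[i], ids[j]) for i, j in ds.truth.true_edges}
    return true, estimate.edge_set


@pytest.fixture(scope="module")
def fitted(small_dataset):
    cis = map_cis_eqtl(small_dataset.expression, small_dataset.genotypes)
    net = fit_network(small_dataset.expression, small_dataset.genotypes, cis)
    return cis, net


class TestFitNetwork:

    def test_zero_diagonal(self, fitted):
        _, net = fitted
        assert np.all(np.diag(net.gamma.to_numpy()) == 0)
        assert not (net.edges["regulator"] == net.edges["target"]).any()

    def test_psi_restricted_to_selected_cis(self, fitted):
        cis, net = fitted
        allowed = set(zip(cis["marker_id"], cis["gene_id"]))
        nz = net.psi.to_numpy() != 0
        for i, marker in enumerate(net.psi.index):
            for j, gene in enumerate(net.psi.columns):
                if nz[i, j]:
                    assert (marker, gene) in allowed

    def test_sign_consistent_with_coefficient(self, fitted):
        _, net = fitted
        pos = net.edges["coefficient"] > 0
        assert (net.edges.loc[pos, "sign"] == "+").all()
        assert (net.edges.loc[~pos, "sign"] == "-").all()

    def test_worker_count_invariance(self, small_dataset, fitted):
        cis, net1 = fitted
        net4 = fit_network(
            small_dataset.expression,
            small_dataset.genotypes,
            cis,
            NetworkConfig(workers=4),
        )
        pd.testing.assert_frame_equal(net1.gamma, net4.gamma)
        pd.testing.assert_frame_equal(net1.edges, net4.edges)

    def test_gene_order_invariance(self, small_dataset, fitted):
        cis, net = fitted
        expr = small_dataset.expression
        perm = list(expr.data.columns)[::-1]
        expr_perm = ExpressionMatrix(
            data=expr.data[perm],
            genes=expr.genes.set_index("gene_id").loc[perm].reset_index()[
                ["chromosome", "start", "end", "gene_id", "strand"]
            ],
        )
        net_perm = fit_network(expr_perm, small_dataset.genotypes, cis)
        assert net_perm.edge_set == net.edge_set
        # coordinate descent visits columns in a different order, so agreement
        # is to solver tolerance rather than bitwise
        for _, row in net.edges.iterrows():
            assert net_perm.gamma.at[row["regulator"], row["target"]] == pytest.approx(
                row["coefficient"], abs=1e-5
            )

    def test_recovery_on_small_instance(self, small_dataset, fitted):
        _, net = fitted
        true, est = _edge_sets(small_dataset, net)
        tp = len(true & est)
        assert tp / max(len(true), 1) >= 0.7
        assert tp / max(len(est), 1) >= 0.7

    def test_no_edge_null_network(self):
        empty = 0
        for rep in range(10):
            ds = simulate_dataset(
                n=300, p=2, seed=500 + rep, edges_per_gene=0.0, noise_sd=0.2
            )
            cis = map_cis_eqtl(ds.expression, ds.genotypes)
            if cis["gene_id"].nunique() < 2:
                empty += 1  # no fit possible, trivially no spurious edge
                continue
            net = fit_network(ds.expression, ds.genotypes, cis)
            if len(net.edges) == 0:
                empty += 1
        assert empty >= 8

    def test_rejects_single_node(self, small_dataset):
        cis = map_cis_eqtl(small_dataset.expression, small_dataset.genotypes)
        one_gene = cis[cis["gene_id"] == cis["gene_id"].iloc[0]]
        with pytest.raises(ValueError, match="node genes"):
            fit_network(small_dataset.expression, small_dataset.genotypes, one_gene)
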