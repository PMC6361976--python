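"""Two-stage penalized least squares for the structural system Y = Y*Gamma + X*Psi + E.

Stage 1 regresses each node gene's expression on the exogenous instrument
matrix (union of all selected cis markers) by ridge regression, with the
penalty chosen by generalized cross-validation; the fitted values estimate
the conditional expectations E[y | X]. Stage 2 regresses each gene on the
stage-1 fitted values of all *other* node genes plus its own cis genotypes,
with an adaptive-lasso penalty on the gene coefficients only: weights
w_j = 1 / |pilot_j|^gamma from a ridge pilot fit, penalty level chosen by
BIC. Nonzero gene coefficients become directed network edges.

Every per-gene fit is independent, so results are identical for any worker
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from splsnet.eqtl import cis_map_to_dict, impute_missing
from splsnet.types import ExpressionMatrix, GenotypeMatrix, NetworkEstimate

logger = logging.getLogger(__name__)

DEFAULT_RIDGE_GRID = np.logspace(-4, 4, 25)


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the KKT residual."""

    def __init__(self, message: str, kkt_residual: float):
        super().__init__(message)
        self.kkt_residual = kkt_residual


@dataclass(frozen=True)
class NetworkConfig:
    """Tuning knobs for :func:`fit_network`.

    Defaults follow deterministic choices (GCV for ridge, BIC for the lasso
    path) so repeated runs and bootstrap replicates are reproducible.
    """

    ridge_grid: np.ndarray = field(default_factory=lambda: DEFAULT_RIDGE_GRID.copy())
    weight_exponent: float = 1.0
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-2
    penalize_cis: bool = False
    instruments: str = "selected"  # or "all": every marker enters stage 1
    weight_cap: float = 1e8
    tol: float = 1e-8
    max_iter: int = 10_000
    workers: int = 1


def stage1_ridge(
    instruments: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Ridge fit of y on the instrument matrix; returns (fitted values, lambda).

    The intercept is unpenalized: both sides are centered, coefficients are
    (Xc'Xc + lambda*I)^-1 Xc'yc, and the mean of y is added back. Lambda is
    chosen from the grid by generalized cross-validation,
    GCV(lambda) = n * RSS / (n - df)^2 with df = trace of the hat matrix.

    An empty instrument set returns the sample-mean vector with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    x = np.asarray(instruments, dtype=float)
    if x.size == 0 or x.shape[1] == 0:
        logger.warning("empty instrument set; returning the sample mean")
        return np.full(n, y.mean()), float("nan")
    if lambda_grid is None:
        lambda_grid = DEFAULT_RIDGE_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid < 0):
        raise ValueError("ridge penalties must be non-negative")
    xc = x - x.mean(axis=0)
    y_mean = y.mean()
    yc = y - y_mean
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    uty = u.T @ yc
    s2 = s**2
    best = (np.inf, None, None)
    for lam in lambda_grid:
        shrink = np.where(s2 + lam > 0, s2 / (s2 + lam), 0.0)
        fitted_c = u @ (shrink * uty)
        df = shrink.sum()
        rss = float(np.sum((yc - fitted_c) ** 2))
        denom = max(n - df, 1e-12)
        gcv = n * rss / denom**2
        if gcv < best[0]:
            best = (gcv, lam, fitted_c)
    _, lam, fitted_c = best
    return fitted_c + y_mean, float(lam)


def soft_threshold(z: float, threshold: float) -> float:
    """Soft-thresholding operator sign(z) * max(|z| - threshold, 0)."""
    if z > threshold:
        return z - threshold
    if z < -threshold:
        return z + threshold
    return 0.0


def penalized_objective(
    design: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    weights: np.ndarray,
    lam: float,
) -> float:
    """(1/2n) ||y - D beta||^2 + lam * sum_j w_j |beta_j|."""
    n = y.shape[0]
    resid = y - design @ beta
    return float(resid @ resid) / (2 * n) + lam * float(weights @ np.abs(beta))


def kkt_residual(
    design: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    weights: np.ndarray,
    lam: float,
) -> float:
    """Max violation of the stationarity conditions at beta.

    For beta_j = 0 the gradient must satisfy |(1/n) D_j'(y - D beta)| <= lam*w_j;
    for beta_j != 0 it must equal lam * w_j * sign(beta_j).
    """
    n = y.shape[0]
    grad = design.T @ (y - design @ beta) / n
    viol = np.where(
        beta == 0,
        np.maximum(np.abs(grad) - lam * weights, 0.0),
        np.abs(grad - lam * weights * np.sign(beta)),
    )
    # columns with no mass cannot carry a violation
    viol[np.einsum("ij,ij->j", design, design) == 0] = 0.0
    return float(viol.max(initial=0.0))


def adaptive_lasso(
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    lam: float,
    unpenalized: np.ndarray | list[int] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-lasso fit by cyclic coordinate descent.

    Minimizes (1/2n) ||y - D beta||^2 + lam * sum_j w_j |beta_j|. Columns in
    ``unpenalized`` get weight 0. Converges when the largest coefficient
    change in a sweep is below ``tol``; raises :class:`ConvergenceError`
    (carrying the KKT residual) otherwise.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float).copy()
    if not (np.isfinite(design).all() and np.isfinite(y).all() and np.isfinite(weights).all()):
        raise ValueError("non-finite values in design, response or weights")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, d = design.shape
    if unpenalized is not None:
        weights[np.asarray(unpenalized, dtype=int)] = 0.0
    # Gram formulation: each coordinate update is O(d) independent of n
    gram = design.T @ design / n
    cty = design.T @ y / n
    col_norm2 = np.diag(gram).copy()
    beta = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    grad = cty - gram @ beta  # (1/n) D'(y - D beta)
    thresholds = lam * weights
    active = np.arange(d)

    def sweep(indices: np.ndarray) -> float:
        nonlocal grad
        max_change = 0.0
        for j in indices:
            if col_norm2[j] == 0.0:
                continue
            old = beta[j]
            rho = grad[j] + col_norm2[j] * old
            new = soft_threshold(rho, thresholds[j]) / col_norm2[j]
            if new != old:
                grad -= gram[:, j] * (new - old)
                beta[j] = new
                change = abs(new - old)
                if change > max_change:
                    max_change = change
        return max_change

    sweeps = 0
    while sweeps < max_iter:
        full_change = sweep(active)
        sweeps += 1
        if full_change < tol:
            return beta
        # iterate on the current active set before the next full sweep
        nonzero = np.nonzero(beta)[0]
        while sweeps < max_iter:
            if sweep(nonzero) < tol:
                break
            sweeps += 1
    residual = kkt_residual(design, y, beta, weights, lam)
    raise ConvergenceError(
        f"coordinate descent did not converge in {max_iter} sweeps "
        f"(KKT residual {residual:.3e})",
        residual,
    )


def _bic(n: int, rss: float, df: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + np.log(n) * df


def stage2_fit_gene(
    y: np.ndarray,
    y_hat_others: np.ndarray,
    own_cis: np.ndarray,
    config: NetworkConfig = NetworkConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive-lasso selection of one gene's regulators.

    Regresses y on [y_hat_others | own_cis] (all columns and y centered; the
    intercept is implicit). The penalty applies to the y_hat_others
    coefficients only, with adaptive weights w_j = 1/|pilot_j|^gamma from a
    ridge pilot of the same regression (GCV-tuned); pilot coefficients of
    exactly 0 get the configured large weight cap. The penalty level is
    chosen by BIC (df = number of nonzero coefficients) over a log-spaced
    grid descending from the smallest lambda that zeroes every penalized
    column.

    Returns (gamma column over the y_hat_others order, psi column over the
    own_cis order), on the original slope scale.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    y_hat_others = np.asarray(y_hat_others, dtype=float).reshape(n, -1)
    own_cis = np.asarray(own_cis, dtype=float).reshape(n, -1)
    d_reg = y_hat_others.shape[1]
    d_cis = own_cis.shape[1]
    design = np.hstack([y_hat_others, own_cis])
    design_c = design - design.mean(axis=0)
    yc = y - y.mean()

    if d_reg + d_cis == 0:
        return np.zeros(0), np.zeros(0)

    # ridge pilot on the same regression supplies the adaptive weights
    col_norm2 = np.einsum("ij,ij->j", design_c, design_c)
    live = col_norm2 > 0
    pilot = np.zeros(d_reg + d_cis)
    if live.any():
        u, s, vt = np.linalg.svd(design_c[:, live], full_matrices=False)
        uty = u.T @ yc
        s2 = s**2
        best = (np.inf, None)
        for lam in config.ridge_grid:
            shrink = s2 / (s2 + lam)
            rss = float(np.sum((yc - u @ (shrink * uty)) ** 2))
            gcv = n * rss / max(n - shrink.sum(), 1e-12) ** 2
            if gcv < best[0]:
                best = (gcv, lam)
        lam_pilot = best[1]
        pilot[live] = vt.T @ ((s / (s2 + lam_pilot)) * uty)

    weights = np.zeros(d_reg + d_cis)
    penalized = np.arange(d_reg)
    if config.penalize_cis:
        penalized = np.arange(d_reg + d_cis)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(pilot[penalized]) ** config.weight_exponent
    zero_pilot = ~np.isfinite(w)
    if zero_pilot.any():
        logger.debug("capping %d zero-pilot weights", int(zero_pilot.sum()))
        w[zero_pilot] = config.weight_cap
    weights[penalized] = np.minimum(w, config.weight_cap)

    # null-model residual: unpenalized columns fitted freely, so lam_max is
    # the smallest penalty at which every penalized coefficient is zero
    free = np.nonzero(weights == 0)[0]
    resid0 = yc
    if free.size:
        coef_free, *_ = np.linalg.lstsq(design_c[:, free], yc, rcond=None)
        resid0 = yc - design_c[:, free] @ coef_free
    grad0 = np.abs(design_c.T @ resid0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_per_col = np.where(weights > 0, grad0 / weights, 0.0)
    lam_max = float(lam_per_col.max(initial=0.0))
    if lam_max == 0.0:
        beta = adaptive_lasso(
            design_c, yc, weights, 0.0, tol=config.tol, max_iter=config.max_iter
        )
        return beta[:d_reg], beta[d_reg:]

    grid = np.geomspace(lam_max * 1.0001, lam_max * config.lambda_min_ratio, config.n_lambda)
    best = (np.inf, None)
    beta = np.zeros(d_reg + d_cis)
    for lam in grid:
        beta = adaptive_lasso(
            design_c,
            yc,
            weights,
            lam,
            tol=config.tol,
            max_iter=config.max_iter,
            beta0=beta,
        )
        rss = float(np.sum((yc - design_c @ beta) ** 2))
        df = int(np.count_nonzero(beta))
        score = _bic(n, rss, df)
        if score < best[0]:
            best = (score, beta.copy())
    beta = best[1]
    return beta[:d_reg], beta[d_reg:]


def _fit_one_gene(
    j: int,
    node_ids: list[str],
    y: np.ndarray,
    y_hat: np.ndarray,
    cis_cols: np.ndarray,
    config: NetworkConfig,
) -> tuple[int, np.ndarray, np.ndarray]:
    others = np.delete(np.arange(len(node_ids)), j)
    gamma_part, psi_part = stage2_fit_gene(y, y_hat[:, others], cis_cols, config)
    gamma_col = np.zeros(len(node_ids))
    gamma_col[others] = gamma_part
    return j, gamma_col, psi_part


def fit_network(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    cis_table: pd.DataFrame,
    config: NetworkConfig = NetworkConfig(),
) -> NetworkEstimate:
    """Fit the full regulatory network by two-stage penalized least squares.

    Node genes are those with at least one selected cis marker in
    ``cis_table``. Stage 1 predicts each node's expression from the
    instrument matrix (union of all selected cis markers, or every marker
    when ``config.instruments == "all"``); stage 2 selects each node's
    regulators. Per-gene fits are independent, so the result is identical
    for any ``config.workers``.
    """
    if expression.sample_ids != genotypes.sample_ids:
        raise ValueError("expression and genotype samples are not aligned")
    cis_map = cis_map_to_dict(cis_table)
    node_ids = [g for g in expression.data.columns if cis_map.get(g)]
    if len(node_ids) < 2:
        raise ValueError("need at least 2 node genes with selected cis-eQTL")
    imputed = impute_missing(genotypes)
    if config.instruments == "all":
        instrument_ids = list(genotypes.data.columns)
    else:
        selected = {m for g in node_ids for m in cis_map[g]}
        instrument_ids = [m for m in genotypes.data.columns if m in selected]
    instruments = imputed[instrument_ids].to_numpy(dtype=float)

    expr = expression.data[node_ids].to_numpy(dtype=float)
    n = expr.shape[0]
    y_hat = np.empty_like(expr)
    stage1_lambda: dict[str, float] = {}
    for j, gene in enumerate(node_ids):
        y_hat[:, j], stage1_lambda[gene] = stage1_ridge(
            instruments, expr[:, j], config.ridge_grid
        )

    tasks = [
        delayed(_fit_one_gene)(
            j,
            node_ids,
            expr[:, j],
            y_hat,
            imputed[cis_map[node_ids[j]]].to_numpy(dtype=float),
            config,
        )
        for j in range(len(node_ids))
    ]
    if config.workers > 1:
        results = Parallel(n_jobs=config.workers)(tasks)
    else:
        results = [t[0](*t[1], **t[2]) for t in tasks]

    p = len(node_ids)
    gamma = np.zeros((p, p))
    psi_entries: list[tuple[str, str, float]] = []
    for j, gamma_col, psi_part in results:
        gamma[:, j] = gamma_col
        for marker, coef in zip(cis_map[node_ids[j]], psi_part):
            psi_entries.append((marker, node_ids[j], float(coef)))

    gamma_df = pd.DataFrame(gamma, index=node_ids, columns=node_ids)
    marker_ids = [m for m in genotypes.data.columns if any(m == e[0] for e in psi_entries)]
    psi_df = pd.DataFrame(0.0, index=marker_ids, columns=node_ids)
    for marker, gene, coef in psi_entries:
        psi_df.at[marker, gene] = coef
    rows, cols = np.nonzero(gamma)
    edges = pd.DataFrame(
        {
            "regulator": [node_ids[i] for i in rows],
            "target": [node_ids[j] for j in cols],
            "coefficient": gamma[rows, cols],
        }
    )
    edges["sign"] = np.where(edges["coefficient"] > 0, "+", "-")
    logger.info("fit_network: %d nodes, %d edges", p, len(edges))
    return NetworkEstimate(
        gamma=gamma_df, psi=psi_df, edges=edges, stage1_lambda=stage1_lambda
    )


def with_workers(config: NetworkConfig, workers: int) -> NetworkConfig:
    return replace(config, workers=workers)
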