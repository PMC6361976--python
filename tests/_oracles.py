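"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: greedy selection is
re-derived from first principles, the weighted lasso is solved by sign-vector
enumeration, and connected components come from a hand-rolled union-find.
"""

from __future__ import annotations

import itertools

import numpy as np


def greedy_select_oracle(
    pvalues: dict[str, float],
    positions: dict[str, int],
    corr: dict[tuple[str, str], float],
    alpha: float = 0.05,
    corr_max: float = 0.90,
    max_k: int = 3,
) -> list[str]:
    """Hand-coded greedy marker selection.

    Visit significant markers in ascending-p order (ties: leftmost position,
    then id); keep a marker iff |r| < corr_max against everything kept so
    far; stop after max_k.
    """
    candidates = sorted(
        (m for m, p in pvalues.items() if p < alpha),
        key=lambda m: (pvalues[m], positions.get(m, 0), m),
    )
    kept: list[str] = []
    for m in candidates:
        if all(
            abs(corr.get((m, k), corr.get((k, m), 0.0))) < corr_max for k in kept
        ):
            kept.append(m)
        if len(kept) == max_k:
            break
    return kept


def lasso_sign_enumeration(
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, float]:
    """Global minimum of the weighted lasso objective by sign enumeration.

    For every sign pattern s in {-1, 0, +1}^d, the restricted stationarity
    system G_SS b = c_S - lam * w_S * s_S is solved; a candidate is valid if
    the signs match and the zero coordinates satisfy the subgradient bound.
    Returns (argmin, objective). Exponential in d — keep d <= 8.
    """
    n, d = design.shape
    gram = design.T @ design / n
    cty = design.T @ y / n

    def objective(beta: np.ndarray) -> float:
        r = y - design @ beta
        return float(r @ r) / (2 * n) + lam * float(weights @ np.abs(beta))

    best_beta = np.zeros(d)
    best_obj = objective(best_beta)
    for signs in itertools.product((-1, 0, 1), repeat=d):
        s = np.array(signs, dtype=float)
        support = np.nonzero(s)[0]
        if support.size == 0:
            continue
        try:
            b_s = np.linalg.solve(
                gram[np.ix_(support, support)],
                cty[support] - lam * weights[support] * s[support],
            )
        except np.linalg.LinAlgError:
            continue
        if np.any(np.sign(b_s) != s[support]):
            continue
        beta = np.zeros(d)
        beta[support] = b_s
        grad = cty - gram @ beta
        off = np.setdiff1d(np.arange(d), support)
        if np.any(np.abs(grad[off]) > lam * weights[off] + 1e-10):
            continue
        obj = objective(beta)
        if obj < best_obj:
            best_obj = obj
            best_beta = beta
    return best_beta, best_obj


def union_find_components(edges: list[tuple[str, str]]) -> list[set[str]]:
    """Undirected connected components via union-find."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in edges:
        union(a, b)
    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return list(groups.values())
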