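"""Reportable structure from a confident edge set.

Subnetworks are maximal weakly connected components of the directed
confident-edge graph; only components with more than a minimum number of
genes (default: more than 5, i.e. min_size 6) are reported. Edge summaries
count positive and negative regulations; pairwise Pearson correlation
matrices support expression-based validation of a subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from splsnet.types import ExpressionMatrix


@dataclass
class Subnetwork:
    id: int
    genes: list[str]
    edges: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.genes)


def _edge_graph(edges: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    for reg, tgt in zip(edges["regulator"], edges["target"]):
        g.add_edge(reg, tgt)
    return g


def extract_subnetworks(
    edges: pd.DataFrame,
    min_size: int = 6,
    connectivity: str = "weak",
) -> list[Subnetwork]:
    """Connected components of the edge graph with at least min_size genes.

    Components are weakly connected by default (edge direction ignored for
    connectivity); ``connectivity="strong"`` switches to strongly connected
    components. Results are ordered by decreasing size, ties broken by the
    lexicographically smallest gene id, and ids are assigned in that order
    starting from 1.
    """
    if edges.empty:
        return []
    graph = _edge_graph(edges)
    if connectivity == "weak":
        components = nx.weakly_connected_components(graph)
    elif connectivity == "strong":
        components = nx.strongly_connected_components(graph)
    else:
        raise ValueError("connectivity must be 'weak' or 'strong'")
    kept = [sorted(c) for c in components if len(c) >= min_size]
    kept.sort(key=lambda genes: (-len(genes), genes[0]))
    out = []
    for i, genes in enumerate(kept, start=1):
        gene_set = set(genes)
        sub_edges = edges[
            edges["regulator"].isin(gene_set) & edges["target"].isin(gene_set)
        ].reset_index(drop=True)
        out.append(Subnetwork(id=i, genes=genes, edges=sub_edges))
    return out


def summarize_edges(edges: pd.DataFrame) -> tuple[int, int]:
    """(positive, negative) regulation counts from a signed edge list."""
    if "sign" not in edges.columns:
        raise ValueError("edges must carry a 'sign' column")
    signs = edges["sign"]
    bad = set(signs) - {"+", "-"}
    if bad:
        raise ValueError(f"unsigned or invalid edge signs: {sorted(bad)}")
    n_pos = int((signs == "+").sum())
    return n_pos, len(edges) - n_pos


def pairwise_correlation(
    expression: ExpressionMatrix | pd.DataFrame, gene_subset: list[str]
) -> pd.DataFrame:
    """Pearson correlation matrix of the given genes across samples.

    Requires at least 2 genes, at least 3 samples, and nonzero variance for
    every gene (a zero-variance gene is reported by name).
    """
    data = expression.data if isinstance(expression, ExpressionMatrix) else expression
    if len(gene_subset) < 2:
        raise ValueError("need at least 2 genes")
    missing = [g for g in gene_subset if g not in data.columns]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing}")
    sub = data[gene_subset]
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    variances = sub.var(axis=0, ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance genes: {flat}")
    vals = sub.to_numpy(dtype=float)
    corr = np.corrcoef(vals, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=gene_subset, columns=gene_subset)


def membership_table(subnetworks: list[Subnetwork]) -> pd.DataFrame:
    """Tidy (subnetwork_id, gene_id) membership listing."""
    rows = [(s.id, g) for s in subnetworks for g in s.genes]
    return pd.DataFrame(rows, columns=["subnetwork_id", "gene_id"])
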