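"""Core data containers shared across pipeline stages.

Matrices follow the row-per-sample convention throughout: expression is
(samples x genes), genotypes are (samples x markers). Regulatory effects are
stored as a (regulators x targets) matrix with zero diagonal — entry (i, j)
is the effect of gene i on gene j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_MAP_COLUMNS = ["marker_id", "chromosome", "genetic_position", "physical_position"]
GENE_ANNOTATION_COLUMNS = ["chromosome", "start", "end", "gene_id", "strand"]


def validate_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker map table.

    Required columns: marker_id, chromosome, genetic_position (centiMorgans,
    non-negative), physical_position (base pairs, positive). Positions must be
    non-decreasing within each chromosome and marker ids unique.
    """
    missing = [c for c in MARKER_MAP_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if markers["marker_id"].duplicated().any():
        dups = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids: {dups}")
    if (markers["genetic_position"] < 0).any():
        raise ValueError("genetic_position must be non-negative (centiMorgans)")
    if (markers["physical_position"] <= 0).any():
        raise ValueError("physical_position must be positive (base pairs)")
    for chrom, sub in markers.groupby("chromosome", sort=False):
        gp = sub["genetic_position"].to_numpy()
        pp = sub["physical_position"].to_numpy()
        if np.any(np.diff(gp) < 0) or np.any(np.diff(pp) < 0):
            raise ValueError(f"marker positions not sorted on chromosome {chrom!r}")
    return markers


def validate_gene_annotations(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a BED-like gene annotation table (0-based half-open)."""
    missing = [c for c in GENE_ANNOTATION_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene annotation missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if (genes["start"] < 0).any():
        raise ValueError("gene start must be non-negative")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must not exceed end")
    bad = set(genes["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {sorted(bad)}")
    return genes


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes (samples x markers) plus marker coordinates.

    ``data`` holds values in {0, 1} as floats with NaN for missing entries;
    ``markers`` is the validated marker map whose marker_id order matches the
    columns of ``data``.
    """

    data: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        validate_marker_map(self.markers)
        if list(self.data.columns) != list(self.markers["marker_id"]):
            raise ValueError("genotype columns do not match marker map order")
        vals = self.data.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("genotype values must be 0, 1 or missing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (samples x genes) plus gene coordinates."""

    data: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        validate_gene_annotations(self.genes)
        if list(self.data.columns) != list(self.genes["gene_id"]):
            raise ValueError("expression columns do not match gene annotation order")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated regulatory system.

    gamma_true: (p x p) gene-on-gene effects, zero diagonal, (I - Gamma)
    invertible. psi_true: (q x p) cis-genotype effects, at most 3 nonzero
    entries per gene column, each at one of that gene's own cis markers.
    """

    gamma_true: np.ndarray
    psi_true: np.ndarray
    noise_sd: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_true, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("gamma_true must be square")
        if np.any(np.diag(g) != 0):
            raise ValueError("gamma_true must have a zero diagonal")
        p = g.shape[0]
        eye_minus = np.eye(p) - g
        if not np.isfinite(np.linalg.cond(eye_minus)) or np.linalg.matrix_rank(eye_minus) < p:
            raise ValueError("(I - gamma_true) is singular")
        psi = np.asarray(self.psi_true, dtype=float)
        if psi.shape[1] != p:
            raise ValueError("psi_true column count must equal gene count")
        per_gene = (psi != 0).sum(axis=0)
        if np.any(per_gene > 3):
            raise ValueError("each gene may have at most 3 nonzero cis effects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.gamma_true = g
        self.psi_true = psi

    @property
    def n_genes(self) -> int:
        return self.gamma_true.shape[0]

    @property
    def true_edges(self) -> set[tuple[int, int]]:
        """(regulator index, target index) pairs with nonzero effect."""
        rows, cols = np.nonzero(self.gamma_true)
        return set(zip(rows.tolist(), cols.tolist()))


@dataclass
class NetworkEstimate:
    """Fitted structural-equation system.

    gamma: (nodes x nodes) DataFrame, entry (i, j) = estimated effect of gene
    i on gene j, zero diagonal. psi: (markers x nodes) DataFrame of cis
    effects restricted to each gene's selected cis markers. edges: tidy table
    with columns regulator, target, coefficient, sign.
    """

    gamma: pd.DataFrame
    psi: pd.DataFrame
    edges: pd.DataFrame
    stage1_lambda: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.gamma.index) != list(self.gamma.columns):
            raise ValueError("gamma must have identical row and column labels")
        if np.any(np.diag(self.gamma.to_numpy()) != 0):
            raise ValueError("gamma diagonal must be zero")
        for col in ("regulator", "target", "coefficient", "sign"):
            if col not in self.edges.columns:
                raise ValueError(f"edges missing column {col!r}")

    @property
    def nodes(self) -> list[str]:
        return list(self.gamma.index)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))
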