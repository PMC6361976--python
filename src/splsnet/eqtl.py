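"""cis-eQTL mapping: imputation, cis-window regression scan, marker selection.

Per gene, every marker inside the gene body plus a 500 bp upstream window is
tested by simple linear regression; significant markers (p < 0.05 by default,
per-marker, uncorrected) are pruned greedily in ascending-p order so that all
pairwise genotype correlations stay below 0.90 in absolute value, and at most
the three strongest markers are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from splsnet.types import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["marker_id", "slope", "t_statistic", "p_value"]
CIS_TABLE_COLUMNS = ["gene_id", "marker_id", "slope", "t_statistic", "p_value", "rank"]


def impute_missing(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Replace missing genotypes by the per-marker mean of observed values.

    Returns a real-valued (samples x markers) DataFrame; observed entries are
    untouched, so post-imputation column means equal the observed means.
    Raises if any marker has no observed value.
    """
    values = genotypes.data.to_numpy(dtype=float).copy()
    observed = ~np.isnan(values)
    n_observed = observed.sum(axis=0)
    if np.any(n_observed == 0):
        bad = [
            genotypes.data.columns[i]
            for i in np.nonzero(n_observed == 0)[0]
        ]
        raise ValueError(f"markers with no observed genotypes: {bad}")
    col_means = np.nansum(values, axis=0) / n_observed
    rows, cols = np.nonzero(~observed)
    values[rows, cols] = col_means[cols]
    return pd.DataFrame(values, index=genotypes.data.index, columns=genotypes.data.columns)


@dataclass(frozen=True)
class CisWindow:
    gene_id: str
    chromosome: str
    start: int
    end: int


def cis_window(
    gene: pd.Series | dict,
    upstream_bp: int = 500,
    strand_aware: bool = True,
) -> CisWindow:
    """Cis window for a gene: the gene body extended upstream_bp upstream.

    With strand awareness, "upstream" is before the start on the + strand and
    after the end on the - strand; without, the window is extended on both
    sides. Coordinates are 0-based half-open and clamped at 0.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be non-negative")
    start, end = int(gene["start"]), int(gene["end"])
    if strand_aware:
        if gene["strand"] == "+":
            start = max(0, start - upstream_bp)
        else:
            end = end + upstream_bp
    else:
        start = max(0, start - upstream_bp)
        end = end + upstream_bp
    return CisWindow(
        gene_id=str(gene["gene_id"]),
        chromosome=str(gene["chromosome"]),
        start=start,
        end=end,
    )


def scan_cis_eqtl(y: np.ndarray, window_markers: pd.DataFrame) -> pd.DataFrame:
    """Simple-linear-regression scan of one gene against candidate markers.

    For each marker column x, fits y = a + b*x by least squares and tests
    H0: b = 0 with a two-sided t test on n - 2 degrees of freedom. Markers
    with zero genotype variance are skipped with a warning.

    Returns a DataFrame with columns marker_id, slope, t_statistic, p_value
    (one row per retained marker, input order).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the regression scan")
    if window_markers.shape[0] != n:
        raise ValueError("marker rows must align with the expression vector")
    x = window_markers.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    keep = sxx > 0
    if not keep.all():
        skipped = [c for c, k in zip(window_markers.columns, keep) if not k]
        logger.warning("skipping zero-variance markers: %s", skipped)
    yc = y - y.mean()
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = xc.T @ yc
        slope = np.where(keep, sxy / np.where(keep, sxx, 1.0), np.nan)
        rss = np.maximum(syy - slope * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / np.where(keep, sxx, 1.0))
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.where(slope != 0, np.inf, 0.0))
        t = np.where(slope < 0, -np.abs(t), np.abs(t))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame(
        {
            "marker_id": window_markers.columns[keep],
            "slope": slope[keep],
            "t_statistic": t[keep],
            "p_value": p[keep],
        }
    )
    return out


def select_cis_eqtl(
    scan_results: pd.DataFrame,
    genotypes: pd.DataFrame,
    alpha: float = 0.05,
    corr_max: float = 0.90,
    max_k: int = 3,
    marker_positions: pd.Series | None = None,
) -> pd.DataFrame:
    """Greedy selection of up to max_k weakly correlated significant markers.

    Markers with p < alpha are visited in ascending-p order (ties broken by
    genomic position, leftmost first, then marker id); a marker is retained
    only if its absolute genotype correlation with every already-retained
    marker is below corr_max. The first max_k retained markers are returned
    with a 1-based ``rank`` column. An empty result marks the gene as a
    non-node.

    ``genotypes`` must be the complete (imputed) genotype table covering the
    scanned markers.
    """
    sig = scan_results[scan_results["p_value"] < alpha].copy()
    if sig.empty:
        return sig.assign(rank=pd.Series(dtype=int))
    if marker_positions is not None:
        sig["_pos"] = sig["marker_id"].map(marker_positions)
    else:
        sig["_pos"] = 0
    sig = sig.sort_values(["p_value", "_pos", "marker_id"], kind="mergesort")
    retained: list[int] = []
    retained_cols: list[np.ndarray] = []
    for row_idx in sig.index:
        marker = sig.at[row_idx, "marker_id"]
        col = genotypes[marker].to_numpy(dtype=float)
        ok = True
        for other in retained_cols:
            r = np.corrcoef(col, other)[0, 1]
            if abs(r) >= corr_max:
                ok = False
                break
        if ok:
            retained.append(row_idx)
            retained_cols.append(col)
            if len(retained) == max_k:
                break
    out = sig.loc[retained].drop(columns="_pos").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def map_cis_eqtl(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    corr_max: float = 0.90,
    max_k: int = 3,
    upstream_bp: int = 500,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Full cis-eQTL mapping over all genes.

    Imputes genotypes, scans each gene's cis window, and applies the
    significance/correlation/top-k filter. Returns a tidy table with columns
    gene_id, marker_id, slope, t_statistic, p_value, rank; genes absent from
    the table have no selected cis-eQTL and are excluded from the network
    node set.
    """
    if expression.sample_ids != genotypes.sample_ids:
        raise ValueError("expression and genotype samples are not aligned")
    imputed = impute_missing(genotypes)
    markers = genotypes.markers
    positions = markers.set_index("marker_id")["physical_position"]
    n_scanned = n_significant = 0
    chunks = []
    for _, gene in expression.genes.iterrows():
        window = cis_window(gene, upstream_bp=upstream_bp, strand_aware=strand_aware)
        in_window = markers[
            (markers["chromosome"] == window.chromosome)
            & (markers["physical_position"] >= window.start)
            & (markers["physical_position"] < window.end)
        ]["marker_id"]
        if in_window.empty:
            continue
        y = expression.data[gene["gene_id"]].to_numpy(dtype=float)
        scan = scan_cis_eqtl(y, imputed[list(in_window)])
        n_scanned += len(scan)
        n_significant += int((scan["p_value"] < alpha).sum())
        selected = select_cis_eqtl(
            scan,
            imputed,
            alpha=alpha,
            corr_max=corr_max,
            max_k=max_k,
            marker_positions=positions,
        )
        if not selected.empty:
            selected.insert(0, "gene_id", gene["gene_id"])
            chunks.append(selected)
    if chunks:
        table = pd.concat(chunks, ignore_index=True)[CIS_TABLE_COLUMNS]
    else:
        table = pd.DataFrame(columns=CIS_TABLE_COLUMNS)
    logger.info(
        "cis-eQTL mapping: %d marker tests, %d significant, %d genes retained as nodes",
        n_scanned,
        n_significant,
        table["gene_id"].nunique() if not table.empty else 0,
    )
    return table


def cis_map_to_dict(cis_table: pd.DataFrame) -> dict[str, list[str]]:
    """Selected markers per gene, in rank order."""
    out: dict[str, list[str]] = {}
    for gene_id, sub in cis_table.groupby("gene_id", sort=False):
        out[gene_id] = list(sub.sort_values("rank")["marker_id"])
    return out
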