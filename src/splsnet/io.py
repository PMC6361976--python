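"""On-disk formats and end-to-end pipeline orchestration.

All tables are tab-separated text with a header row. Matrices are written
samples-in-rows with the sample id in the first column; missing genotypes
are the literal ``NA``. Marker maps and gene annotations are BED-like TSVs
with 0-based half-open coordinates. Networks are exported as edge-list TSV,
SIF and GraphML. A JSON manifest records every parameter, seed and stage
count so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

import splsnet
from splsnet.analysis import extract_subnetworks, membership_table, summarize_edges
from splsnet.bootstrap import bootstrap_network, confidence_bins, confident_edges
from splsnet.eqtl import map_cis_eqtl
from splsnet.inference import NetworkConfig, fit_network
from splsnet.types import (
    ExpressionMatrix,
    GenotypeMatrix,
    NetworkEstimate,
    validate_gene_annotations,
    validate_marker_map,
)

logger = logging.getLogger(__name__)

NA = "NA"


# ---------------------------------------------------------------------------
# readers


def read_marker_map(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    return validate_marker_map(markers)


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str, "strand": str})
    return validate_gene_annotations(genes)


def read_genotypes(path: str | Path, marker_map_path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV (samples x markers, values 0/1/NA) plus marker map."""
    markers = read_marker_map(marker_map_path)
    data = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    data.index.name = None
    if data.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    vals = data.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype value {vals[i, j]!r} at sample {data.index[i]!r}, "
            f"marker {data.columns[j]!r} in {path}"
        )
    return GenotypeMatrix(data=data, markers=markers)


def read_expression(path: str | Path, annotations_path: str | Path) -> ExpressionMatrix:
    genes = read_gene_annotations(annotations_path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index.name = None
    if data.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return ExpressionMatrix(data=data, genes=genes)


def check_alignment(expression: ExpressionMatrix, genotypes: GenotypeMatrix) -> None:
    """Require identical sample ids in identical order; never realign silently."""
    e, g = expression.sample_ids, genotypes.sample_ids
    if e != g:
        only_e = sorted(set(e) - set(g))
        only_g = sorted(set(g) - set(e))
        if only_e or only_g:
            raise ValueError(
                f"sample mismatch: {len(only_e)} only in expression {only_e[:5]}, "
                f"{len(only_g)} only in genotypes {only_g[:5]}"
            )
        raise ValueError("samples are identical but ordered differently; refusing to realign")


# ---------------------------------------------------------------------------
# writers


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False, label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, index_label=label, na_rep=NA, lineterminator="\n")


def write_matrix(data: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    _write_tsv(data, Path(path), index=True, label=index_label)


def write_marker_map(markers: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(markers, Path(path))


def write_gene_annotations(genes: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(genes, Path(path))


def write_truth_triplets(matrix: np.ndarray, row_ids: list[str], col_ids: list[str], path: str | Path) -> None:
    """Sparse triplet TSV (row_id, col_id, value) of a ground-truth matrix."""
    rows, cols = np.nonzero(matrix)
    frame = pd.DataFrame(
        {
            "row_id": [row_ids[i] for i in rows],
            "col_id": [col_ids[j] for j in cols],
            "value": matrix[rows, cols],
        }
    )
    _write_tsv(frame, Path(path))


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(edges, Path(path))


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """SIF export: regulator <tab> relation <tab> target, relation = sign."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for reg, tgt, sign in edges[["regulator", "target", "sign"]].itertuples(index=False):
            relation = "up" if sign == "+" else "down"
            fh.write(f"{reg}\t{relation}\t{tgt}\n")


def write_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    graph = nx.DiGraph()
    for row in edges.itertuples(index=False):
        attrs = {"sign": row.sign}
        if hasattr(row, "coefficient"):
            attrs["coefficient"] = float(row.coefficient)
        graph.add_edge(row.regulator, row.target, **attrs)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# configuration and orchestration


@dataclass
class RunConfig:
    """Declarative configuration of an end-to-end run.

    Defaults mirror the reference analysis: alpha 0.05, pairwise-correlation
    cap 0.90, at most 3 cis markers per gene, 500 bp upstream window, 10,000
    bootstrap replicates, 80% confidence threshold, subnetworks with more
    than 5 genes.
    """

    expression_path: str = ""
    genotype_path: str = ""
    marker_map_path: str = ""
    gene_annotation_path: str = ""
    out_dir: str = "results"
    alpha: float = 0.05
    corr_max: float = 0.90
    max_k: int = 3
    upstream_bp: int = 500
    strand_aware: bool = True
    ridge_grid_log10_min: float = -4.0
    ridge_grid_log10_max: float = 4.0
    ridge_grid_points: int = 25
    weight_exponent: float = 1.0
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    penalize_cis: bool = False
    instruments: str = "selected"
    B: int = 10_000
    threshold: float = 0.80
    min_size: int = 6
    seed: int = 0
    workers: int = 1

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.corr_max <= 1:
            raise ValueError("corr_max must be in (0, 1]")
        if self.max_k < 1:
            raise ValueError("max_k must be positive")
        if self.upstream_bp < 0:
            raise ValueError("upstream_bp must be non-negative")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be positive")
        if self.workers < 1:
            raise ValueError("workers must be positive")

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            ridge_grid=np.logspace(
                self.ridge_grid_log10_min, self.ridge_grid_log10_max, self.ridge_grid_points
            ),
            weight_exponent=self.weight_exponent,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            penalize_cis=self.penalize_cis,
            instruments=self.instruments,
            workers=self.workers,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    cis_table: pd.DataFrame
    network: NetworkEstimate
    binned_edges: pd.DataFrame
    subnetworks: list
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run map-eqtl -> fit -> bootstrap -> subnetworks and write all outputs.

    Writes, under ``config.out_dir``: cis_eqtl.tsv, edges.tsv, psi.tsv,
    network.sif, network.graphml, bootstrap_edges.tsv, subnetworks.tsv,
    per-subnetwork SIF/GraphML files, and manifest.json. Reruns with the
    same inputs and seed produce byte-identical files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expression = read_expression(config.expression_path, config.gene_annotation_path)
    genotypes = read_genotypes(config.genotype_path, config.marker_map_path)
    check_alignment(expression, genotypes)

    cis_table = map_cis_eqtl(
        expression,
        genotypes,
        alpha=config.alpha,
        corr_max=config.corr_max,
        max_k=config.max_k,
        upstream_bp=config.upstream_bp,
        strand_aware=config.strand_aware,
    )
    _write_tsv(cis_table, out / "cis_eqtl.tsv")

    net_config = config.network_config()
    network = fit_network(expression, genotypes, cis_table, net_config)
    write_edges_tsv(network.edges, out / "edges.tsv")
    write_matrix(network.psi, out / "psi.tsv", index_label="marker_id")
    write_sif(network.edges, out / "network.sif")
    write_graphml(network.edges, out / "network.graphml")

    boot = bootstrap_network(
        expression,
        genotypes,
        cis_table,
        B=config.B,
        seed=config.seed,
        workers=config.workers,
        config=net_config,
    )
    binned = confidence_bins(boot, threshold=config.threshold)
    write_edges_tsv(binned.rename(columns={"modal_sign": "sign"}), out / "bootstrap_edges.tsv")

    confident = confident_edges(binned).rename(columns={"modal_sign": "sign"})
    subnetworks = extract_subnetworks(confident, min_size=config.min_size)
    _write_tsv(membership_table(subnetworks), out / "subnetworks.tsv")
    for sub in subnetworks:
        write_sif(sub.edges, out / f"subnetwork_{sub.id:02d}.sif")
        write_graphml(sub.edges, out / f"subnetwork_{sub.id:02d}.graphml")

    n_pos, n_neg = summarize_edges(network.edges)
    bin_counts = binned["bin"].value_counts().to_dict()
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    # out_dir is excluded so reruns into different directories stay identical
    config_record = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
    }
    manifest = {
        "package_version": splsnet.__version__,
        "config": config_record,
        "seed": config.seed,
        "counts": {
            "samples": expression.n_samples,
            "genes": expression.n_genes,
            "markers": genotypes.n_markers,
            "node_genes": int(cis_table["gene_id"].nunique()) if not cis_table.empty else 0,
            "selected_cis_eqtl": len(cis_table),
            "edges_point_estimate": len(network.edges),
            "edges_positive": n_pos,
            "edges_negative": n_neg,
            "bootstrap_candidate_edges": len(binned),
            "bin_counts": {k: int(v) for k, v in sorted(bin_counts.items())},
            "confident_edges": len(confident),
            "subnetworks": len(subnetworks),
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return PipelineResult(
        cis_table=cis_table,
        network=network,
        binned_edges=binned,
        subnetworks=subnetworks,
        manifest=manifest,
    )
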