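"""Bootstrap assessment of edge reliability.

Each replicate resamples segregants (rows of expression and genotypes,
jointly) with replacement and reruns the full two-stage network fit with the
*same* cis-eQTL selection, so the node set — and hence the edge universe —
is fixed across replicates. Per-edge selection counts over B replicates give
frequencies that are exact multiples of 1/B; confident edges are binned as
[0.80, 0.90), [0.90, 0.95), [0.95, 1.00) and exactly 1.00.

Replicate seeds are derived deterministically from the master seed, so
frequency tables are identical for any worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from splsnet.eqtl import map_cis_eqtl
from splsnet.inference import NetworkConfig, fit_network
from splsnet.types import ExpressionMatrix, GenotypeMatrix, NetworkEstimate

logger = logging.getLogger(__name__)

CONFIDENCE_BINS = ["[0.80,0.90)", "[0.90,0.95)", "[0.95,1.00)", "1.00"]
BELOW_THRESHOLD = "below_threshold"


@dataclass
class BootstrapResult:
    """Per-edge selection counts over B bootstrap replicates.

    ``table`` columns: regulator, target, count, frequency, pos_count,
    neg_count, modal_sign, sign_agreement. ``frequency`` is count / B
    exactly.
    """

    table: pd.DataFrame
    B: int
    seed: int


def _replicate_seed(master_seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def _one_replicate(
    replicate: int,
    master_seed: int,
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    cis_table: pd.DataFrame,
    config: NetworkConfig,
    rescan_eqtl: bool,
    eqtl_kwargs: dict,
) -> pd.DataFrame:
    rng = _replicate_seed(master_seed, replicate)
    n = expression.n_samples
    idx = rng.integers(0, n, size=n)
    sample_ids = [f"bs{k:05d}" for k in range(n)]
    expr_b = ExpressionMatrix(
        data=pd.DataFrame(
            expression.data.to_numpy()[idx],
            index=sample_ids,
            columns=expression.data.columns,
        ),
        genes=expression.genes,
    )
    geno_b = GenotypeMatrix(
        data=pd.DataFrame(
            genotypes.data.to_numpy()[idx],
            index=sample_ids,
            columns=genotypes.data.columns,
        ),
        markers=genotypes.markers,
    )
    table = cis_table
    if rescan_eqtl:
        table = map_cis_eqtl(expr_b, geno_b, **eqtl_kwargs)
    estimate = fit_network(expr_b, geno_b, table, config)
    return estimate.edges[["regulator", "target", "sign"]]


def bootstrap_network(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    cis_table: pd.DataFrame,
    B: int,
    seed: int,
    workers: int = 1,
    config: NetworkConfig = NetworkConfig(),
    rescan_eqtl: bool = False,
    eqtl_kwargs: dict | None = None,
) -> BootstrapResult:
    """Refit the network on B resampled datasets and count edge selections.

    Rows of expression and genotypes are resampled jointly with replacement
    (same sample count as the original data). The cis-eQTL selection is held
    fixed by default; ``rescan_eqtl=True`` redoes it per replicate for
    sensitivity analysis (the node set may then vary). An edge counts as
    selected when its stage-2 coefficient is nonzero, regardless of sign;
    sign agreement is reported separately.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if expression.sample_ids != genotypes.sample_ids:
        raise ValueError("expression and genotype samples are not aligned")
    worker_config = replace(config, workers=1)
    tasks = [
        delayed(_one_replicate)(
            b,
            seed,
            expression,
            genotypes,
            cis_table,
            worker_config,
            rescan_eqtl,
            eqtl_kwargs or {},
        )
        for b in range(B)
    ]
    if workers > 1:
        replicate_edges = Parallel(n_jobs=workers)(tasks)
    else:
        replicate_edges = [t[0](*t[1], **t[2]) for t in tasks]

    counts: dict[tuple[str, str], list[int]] = {}
    for edges in replicate_edges:
        for reg, tgt, sign in edges.itertuples(index=False):
            rec = counts.setdefault((reg, tgt), [0, 0, 0])
            rec[0] += 1
            rec[1 if sign == "+" else 2] += 1
    rows = []
    for (reg, tgt), (total, pos, neg) in sorted(counts.items()):
        modal = "+" if pos >= neg else "-"
        rows.append(
            {
                "regulator": reg,
                "target": tgt,
                "count": total,
                "frequency": total / B,
                "pos_count": pos,
                "neg_count": neg,
                "modal_sign": modal,
                "sign_agreement": max(pos, neg) / total,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "regulator",
            "target",
            "count",
            "frequency",
            "pos_count",
            "neg_count",
            "modal_sign",
            "sign_agreement",
        ],
    )
    logger.info("bootstrap: B=%d, %d candidate edges", B, len(table))
    return BootstrapResult(table=table, B=B, seed=seed)


def assign_bin(frequency: float, threshold: float = 0.80) -> str:
    """Confidence bin for a selection frequency.

    Left-closed right-open bins except the singleton 1.00 bin; frequencies
    below the threshold fall into ``below_threshold``.
    """
    if frequency == 1.0:
        return "1.00"
    if frequency < threshold:
        return BELOW_THRESHOLD
    if frequency < 0.90:
        return "[0.80,0.90)"
    if frequency < 0.95:
        return "[0.90,0.95)"
    return "[0.95,1.00)"


def confidence_bins(result: BootstrapResult, threshold: float = 0.80) -> pd.DataFrame:
    """Annotate the bootstrap edge table with confidence bins.

    Returns the table with a ``bin`` column; edges at or above the threshold
    carry one of [0.80,0.90), [0.90,0.95), [0.95,1.00), 1.00.
    """
    table = result.table.copy()
    table["bin"] = [assign_bin(f, threshold) for f in table["frequency"]]
    return table


def confident_edges(binned: pd.DataFrame) -> pd.DataFrame:
    """Rows of a binned edge table that cleared the confidence threshold."""
    return binned[binned["bin"] != BELOW_THRESHOLD].reset_index(drop=True)


@dataclass
class IntersectionReport:
    """Confident bootstrap edges split by presence in the point estimate."""

    in_point_estimate: pd.DataFrame
    bootstrap_only: pd.DataFrame
    n_positive: int
    n_negative: int


def intersect_with_point_estimate(
    confident: pd.DataFrame, point: NetworkEstimate
) -> IntersectionReport:
    """Partition confident edges by membership in the point-estimate network.

    Positive/negative counts are taken from the point estimate's signs of
    the edges present in both sets.
    """
    point_signs = {
        (r, t): s
        for r, t, s in point.edges[["regulator", "target", "sign"]].itertuples(index=False)
    }
    keys = list(zip(confident["regulator"], confident["target"]))
    in_mask = np.array([k in point_signs for k in keys], dtype=bool)
    in_point = confident[in_mask].reset_index(drop=True)
    only = confident[~in_mask].reset_index(drop=True)
    signs = [point_signs[k] for k, m in zip(keys, in_mask) if m]
    n_pos = sum(1 for s in signs if s == "+")
    n_neg = len(signs) - n_pos
    return IntersectionReport(
        in_point_estimate=in_point,
        bootstrap_only=only,
        n_positive=n_pos,
        n_negative=n_neg,
    )
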