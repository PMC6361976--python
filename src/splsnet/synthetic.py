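"""Simulation of segregant-style genotypes and SEM-consistent expression.

Genotypes model a biparental haploid cross: each chromosome is a Markov
chain along the marker map, with recombination fraction between adjacent
markers derived from their genetic distance via the Haldane map function
r = 0.5 * (1 - exp(-2d)) (d in Morgans). Expression follows the linear
structural system Y = Y*Gamma + X*Psi + E, i.e.
Y = (X*Psi + E) @ inv(I - Gamma), with i.i.d. Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from splsnet.types import (
    ExpressionMatrix,
    GenotypeMatrix,
    SimulationTruth,
    validate_marker_map,
)

logger = logging.getLogger(__name__)

_MAX_NETWORK_ATTEMPTS = 100


def haldane_recombination_fraction(distance_morgans: np.ndarray) -> np.ndarray:
    """Recombination fraction for a genetic distance in Morgans."""
    d = np.asarray(distance_morgans, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def simulate_segregant_genotypes(
    n: int, marker_map: pd.DataFrame, seed: int
) -> GenotypeMatrix:
    """Simulate haploid segregant genotypes along a marker map.

    The first marker of each chromosome is Bernoulli(0.5); subsequent markers
    switch parental origin with the Haldane recombination fraction for the
    adjacent genetic distance. Chromosomes are independent.

    Parameters
    ----------
    n : number of segregants (>= 2).
    marker_map : table with marker_id, chromosome, genetic_position (cM),
        physical_position (bp); sorted within chromosome.
    seed : RNG seed; fixed seed gives identical output.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    validate_marker_map(marker_map)
    if len(marker_map) < 1:
        raise ValueError("marker map must contain at least one marker")
    rng = np.random.default_rng(seed)
    blocks = []
    for _, sub in marker_map.groupby("chromosome", sort=False):
        pos_morgans = sub["genetic_position"].to_numpy(dtype=float) / 100.0
        m = len(pos_morgans)
        geno = np.empty((n, m), dtype=np.int8)
        geno[:, 0] = rng.random(n) < 0.5
        if m > 1:
            r = haldane_recombination_fraction(np.diff(pos_morgans))
            crossovers = rng.random((n, m - 1)) < r
            geno[:, 1:] = (geno[:, [0]] + np.cumsum(crossovers, axis=1)) % 2
        blocks.append(geno)
    values = np.hstack(blocks).astype(float)
    sample_ids = [f"seg{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(values, index=sample_ids, columns=list(marker_map["marker_id"]))
    return GenotypeMatrix(data=data, markers=marker_map.reset_index(drop=True))


def simulate_network(
    p: int,
    edges_per_gene: float,
    effect_low: float,
    effect_high: float,
    acyclic: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Draw a sparse random regulatory-effect matrix with zero diagonal.

    Each ordered gene pair receives an edge independently so that the
    expected out-degree is ``edges_per_gene``; nonzero magnitudes are uniform
    in [effect_low, effect_high] with random sign. When ``acyclic``, edges
    run only from lower to higher gene index (strictly upper-triangular), so
    (I - Gamma) is always invertible. Otherwise draws are rejected and
    resampled until the spectral radius of Gamma is below 1 (at most 100
    attempts).
    """
    if p < 2:
        raise ValueError("p must be at least 2")
    if edges_per_gene < 0:
        raise ValueError("edges_per_gene must be non-negative")
    if not (0 < effect_low <= effect_high):
        raise ValueError("require 0 < effect_low <= effect_high")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_NETWORK_ATTEMPTS):
        if acyclic:
            # only p*(p-1)/2 admissible pairs: double the per-pair rate to
            # keep the expected out-degree at edges_per_gene
            prob = min(1.0, 2.0 * edges_per_gene / (p - 1))
            adj = np.triu(rng.random((p, p)) < prob, k=1)
        else:
            prob = min(1.0, edges_per_gene / (p - 1))
            adj = rng.random((p, p)) < prob
            np.fill_diagonal(adj, False)
        magnitude = rng.uniform(effect_low, effect_high, size=(p, p))
        sign = rng.choice([-1.0, 1.0], size=(p, p))
        gamma = np.where(adj, magnitude * sign, 0.0)
        spectral_radius = np.max(np.abs(np.linalg.eigvals(gamma)))
        if spectral_radius < 1.0 and np.isfinite(np.linalg.cond(np.eye(p) - gamma)):
            return gamma
    raise RuntimeError(
        f"failed to draw an invertible (I - Gamma) in {_MAX_NETWORK_ATTEMPTS} attempts; "
        "reduce edges_per_gene or effect sizes"
    )


def generate_expression(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    gene_cis_assignment: dict[str, list[str]] | None = None,
) -> ExpressionMatrix:
    """Generate expression from the structural system Y = Y*Gamma + X*Psi + E.

    Solves the system as Y = (X @ Psi + E) @ inv(I - Gamma) with E i.i.d.
    Normal(0, noise_sd^2). Gamma[i, j] != 0 means gene i regulates gene j.
    If ``gene_cis_assignment`` is given, every nonzero row of each gene's
    psi column must be one of that gene's assigned markers.
    """
    p = truth.n_genes
    gamma = truth.gamma_true
    psi = truth.psi_true
    if psi.shape[0] != genotypes.n_markers:
        raise ValueError("psi_true row count must equal marker count")
    eye_minus = np.eye(p) - gamma
    cond = np.linalg.cond(eye_minus)
    if not np.isfinite(cond) or 1.0 / cond < np.finfo(float).eps:
        raise ValueError("(I - gamma_true) is singular; expression is undefined")
    gene_ids = truth.gene_ids or [f"gene{j + 1:04d}" for j in range(p)]
    marker_index = {m: i for i, m in enumerate(genotypes.data.columns)}
    if gene_cis_assignment is not None:
        for gene, markers in gene_cis_assignment.items():
            unknown = [m for m in markers if m not in marker_index]
            if unknown:
                raise ValueError(f"cis assignment for {gene!r} references unknown markers {unknown}")
        for j, gene in enumerate(gene_ids):
            allowed = {marker_index[m] for m in gene_cis_assignment.get(gene, [])}
            nonzero_rows = set(np.nonzero(psi[:, j])[0].tolist())
            if not nonzero_rows <= allowed:
                raise ValueError(
                    f"psi column for {gene!r} has effects outside its cis assignment"
                )
    x = genotypes.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("genotypes must be complete; impute or regenerate without missing")
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.noise_sd, size=(genotypes.n_samples, p))
    y = np.linalg.solve(eye_minus.T, (x @ psi + noise).T).T
    data = pd.DataFrame(y, index=genotypes.data.index, columns=gene_ids)
    genes = _gene_annotations_from_assignment(gene_ids, genotypes, gene_cis_assignment)
    return ExpressionMatrix(data=data, genes=genes)


def _gene_annotations_from_assignment(
    gene_ids: list[str],
    genotypes: GenotypeMatrix,
    assignment: dict[str, list[str]] | None,
) -> pd.DataFrame:
    """BED-like annotations placing each gene over its assigned cis markers.

    Genes without an assignment are placed on a synthetic contig so the
    annotation stays well formed.
    """
    markers = genotypes.markers.set_index("marker_id")
    records = []
    for j, gene in enumerate(gene_ids):
        assigned = (assignment or {}).get(gene, [])
        if assigned:
            sub = markers.loc[assigned]
            chrom = sub["chromosome"].iloc[0]
            start = max(0, int(sub["physical_position"].min()) - 10)
            end = int(sub["physical_position"].max()) + 10
        else:
            chrom, start, end = "chrUn", 1000 * j, 1000 * j + 500
        records.append((chrom, start, end, gene, "+"))
    return pd.DataFrame(records, columns=["chromosome", "start", "end", "gene_id", "strand"])


def inject_missing_genotypes(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each genotype entry to missing independently with probability rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = genotypes.data.to_numpy(dtype=float).copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    data = pd.DataFrame(values, index=genotypes.data.index, columns=genotypes.data.columns)
    return GenotypeMatrix(data=data, markers=genotypes.markers)


def make_marker_map(
    n_chromosomes: int = 4,
    markers_per_chromosome: int = 25,
    spacing_cm: float = 10.0,
    spacing_bp: int = 10_000,
) -> pd.DataFrame:
    """Evenly spaced marker map, a stand-in for a genotyping panel."""
    records = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for k in range(markers_per_chromosome):
            records.append(
                (
                    f"{chrom}_m{k + 1:03d}",
                    chrom,
                    k * spacing_cm,
                    1 + k * spacing_bp,
                )
            )
    return pd.DataFrame(
        records,
        columns=["marker_id", "chromosome", "genetic_position", "physical_position"],
    )


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    truth: SimulationTruth
    gene_cis_assignment: dict[str, list[str]]


def simulate_dataset(
    n: int = 112,
    p: int = 30,
    seed: int = 0,
    *,
    marker_map: pd.DataFrame | None = None,
    edges_per_gene: float = 2.0,
    effect_low: float = 0.5,
    effect_high: float = 1.0,
    acyclic: bool = False,
    cis_per_gene: tuple[int, int] = (1, 3),
    cis_effect_low: float = 0.8,
    cis_effect_high: float = 1.2,
    noise_sd: float = 0.3,
    missing_rate: float = 0.0,
) -> SimulatedDataset:
    """Simulate a complete segregant dataset with known network truth.

    Each gene is anchored to a run of 1-3 adjacent markers (its cis-eQTL)
    with positive effects, genes are wired by :func:`simulate_network`, and
    expression is propagated through the structural system. Gene annotations
    cover the assigned markers so the default cis-window scan recovers them.
    """
    if marker_map is None:
        needed = int(np.ceil(p * cis_per_gene[1] / 4)) + 2
        marker_map = make_marker_map(n_chromosomes=4, markers_per_chromosome=max(needed, 8))
    rng = np.random.default_rng(seed)
    genotypes = simulate_segregant_genotypes(
        n, marker_map, seed=int(rng.integers(2**31 - 1))
    )
    gamma = simulate_network(
        p,
        edges_per_gene,
        effect_low,
        effect_high,
        acyclic=acyclic,
        seed=int(rng.integers(2**31 - 1)),
    )
    gene_ids = [f"gene{j + 1:04d}" for j in range(p)]
    marker_ids = list(marker_map["marker_id"])
    q = len(marker_ids)
    # carve non-overlapping marker runs per gene so cis signals are disjoint
    lo, hi = cis_per_gene
    if not (0 <= lo <= hi <= 3):
        raise ValueError("cis_per_gene must satisfy 0 <= low <= high <= 3")
    sizes = rng.integers(lo, hi + 1, size=p)
    if sizes.sum() > q:
        raise ValueError("marker map too small for the requested cis assignments")
    psi = np.zeros((q, p))
    assignment: dict[str, list[str]] = {}
    cursor = 0
    chrom_of = marker_map["chromosome"].to_numpy()
    for j, gene in enumerate(gene_ids):
        k = int(sizes[j])
        # keep a gene's markers on one chromosome
        while k > 0 and cursor + k <= q and len(set(chrom_of[cursor : cursor + k])) > 1:
            cursor += 1
        if cursor + k > q:
            raise ValueError("marker map too small for the requested cis assignments")
        idx = list(range(cursor, cursor + k))
        cursor += k
        assignment[gene] = [marker_ids[i] for i in idx]
        for i in idx:
            psi[i, j] = rng.uniform(cis_effect_low, cis_effect_high)
    truth = SimulationTruth(
        gamma_true=gamma,
        psi_true=psi,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        gene_ids=gene_ids,
        marker_ids=marker_ids,
    )
    expression = generate_expression(genotypes, truth, assignment)
    if missing_rate > 0:
        genotypes = inject_missing_genotypes(
            genotypes, missing_rate, seed=int(rng.integers(2**31 - 1))
        )
    return SimulatedDataset(
        genotypes=genotypes,
        expression=expression,
        truth=truth,
        gene_cis_assignment=assignment,
    )
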