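# splsnet

Gene regulatory network inference from segregant genotype/expression data
via two-stage penalized least squares (2SPLS).

The package implements a complete, reproducible pipeline for genetical
genomics data from a biparental haploid cross:

1. **Synthetic data** (`splsnet.synthetic`) — segregant genotypes simulated
   as per-chromosome Markov chains with Haldane recombination fractions,
   plus expression generated from a linear structural-equation system
   `Y = Y·Γ + X·Ψ + E` with known ground truth, so every downstream stage is
   testable without external data.
2. **cis-eQTL mapping** (`splsnet.eqtl`) — mean imputation of missing
   genotypes; a simple-linear-regression scan of every marker in the gene
   body plus a 500 bp upstream window; greedy ascending-p selection of up to
   3 markers per gene with pairwise genotype correlation kept below 0.90.
3. **Network inference** (`splsnet.inference`) — stage 1: ridge regression
   of each node gene on the instrument matrix (union of selected cis
   markers), penalty chosen by GCV; stage 2: adaptive lasso (cyclic
   coordinate descent, KKT-verified) of each gene on the other genes'
   stage-1 fitted values with its own cis genotypes unpenalized, penalty
   chosen by BIC. Nonzero coefficients are signed directed edges.
4. **Bootstrap confidence** (`splsnet.bootstrap`) — resample segregants with
   replacement, refit the network per replicate (fixed cis selection), and
   bin per-edge selection frequencies as `[0.80,0.90)`, `[0.90,0.95)`,
   `[0.95,1.00)`, `1.00`.
5. **Network analysis** (`splsnet.analysis`) — weakly connected subnetworks
   above a size cutoff (default: more than 5 genes), signed-edge summaries,
   pairwise Pearson correlation matrices.
6. **I/O + CLI** (`splsnet.io`, `splsnet.cli`) — TSV/BED-like readers and
   writers, SIF/GraphML export, JSON manifest; all stages run standalone or
   end to end, byte-for-byte reproducible from (inputs, config, seed).

## CLI

```sh
# simulate a dataset with known truth
splsnet simulate --n 112 --p 30 --seed 1 --out-dir data/

# stage by stage
splsnet map-eqtl --expression data/expression.tsv --genotypes data/genotypes.tsv \
    --markers data/markers.tsv --annotations data/genes.tsv \
    --alpha 0.05 --corr-max 0.90 --max-k 3 --upstream 500 --out cis.tsv
splsnet fit      ... --cis-table cis.tsv --out-dir fit/
splsnet bootstrap ... --cis-table cis.tsv -B 10000 --seed 1 --workers 4 --out boot.tsv
splsnet subnetworks --edges fit/edges.tsv --min-size 6 --out-dir subs/

# or end to end (writes manifest.json with all parameters, seeds and counts)
splsnet run --expression data/expression.tsv --genotypes data/genotypes.tsv \
    --markers data/markers.tsv --annotations data/genes.tsv \
    -B 10000 --seed 1 --out-dir results/
```

Defaults follow the reference analysis: significance 0.05, correlation cap
0.90, max 3 cis markers, 500 bp upstream window, 10,000 bootstrap
replicates, 80% confidence threshold, subnetworks with more than 5 genes.

## File formats

- Expression/genotypes: TSV, samples in rows, header of gene/marker ids,
  sample id in the first column; missing genotype is `NA`.
- Marker map: TSV with `marker_id, chromosome, genetic_position (cM),
  physical_position (bp)`.
- Gene annotations: BED-like TSV with `chromosome, start, end, gene_id,
  strand`, 0-based half-open.
- Networks: edge-list TSV (`regulator, target, coefficient, sign`), SIF,
  GraphML; ground-truth matrices as sparse triplet TSV.
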