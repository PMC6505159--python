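# genomat

Out-of-core genotype matrices and chunked statistical genetics for PLINK 1
filesets.

Biobank-scale genotype data (hundreds of thousands of samples, hundreds of
thousands of variants) is distributed as PLINK `.bed/.bim/.fam` filesets,
usually one per chromosome, and does not fit in memory. `genomat` is a
Python library plus a thin CLI for analysts who need to compute on such
data without ever materializing it:

- **`BedMatrix`** — a read-only, lazy matrix view over a `.bed` fileset.
  Opening parses only the 3-byte header and the `.fam`/`.bim` text
  siblings; element access decodes just the 2-bit-packed bytes of the
  requested variants.
- **`LinkedMatrix`** — virtual concatenation of matrix-like objects by
  rows or columns (e.g. per-chromosome filesets into one genotype matrix),
  with no copying; linked matrices nest.
- **Chunked split-apply-combine** — `chunked_apply`, `crossprod_chunked`
  and friends process row/column chunks with bounded memory, optional
  row/column index subsets (`rows=` / `cols=`), and process-based workers,
  with outputs byte-identical across chunk sizes and worker counts.
- **Statistical genetics** — per-variant summaries (allele frequency, MAF,
  missingness, SD), MAF/call-rate QC gates, single-marker GWAS
  (fast centered least squares, covariate-adjusted OLS, logistic IRLS),
  Hardy–Weinberg chi-square tests, genomic relationship matrices, and
  greedy kinship-threshold pruning of related samples.
- **`SymBlockMatrix`** — a GRM too large for memory is built block-by-block
  over a partition of the samples and stored as B(B+1)/2 upper-triangular
  blocks on disk; the lower triangle is served by virtual transposition.
- **Synthetic data** — generators for filesets with known allele
  frequencies, missingness, QTL effects, heritability and planted
  relatives, so every operation is testable with no external data.

## The core statistics

Genotypes \(x_{ij} \in \{0,1,2\}\) count copies of the A1 allele of
variant *j* in sample *i* (missing calls are NaN in float reads).

**Single-marker scan (rayOLS).** For each variant, over its \(n_j\)
complete cases, center both phenotype and genotype and regress without an
intercept — algebraically the slope of the intercept + SNP model:

\[
\hat\beta_j = \frac{\sum_i (x_{ij}-\bar x_j)(y_i-\bar y)}{\sum_i (x_{ij}-\bar x_j)^2},
\qquad
\mathrm{SE}(\hat\beta_j) = \sqrt{\frac{\mathrm{RSS}_j/(n_j-2)}{\sum_i (x_{ij}-\bar x_j)^2}},
\]

with a two-sided *t* test on \(n_j - 2\) degrees of freedom.

**Genomic relationship matrix.** \(G = WW'/k\), where the columns of
\(W\) are the (optionally centered and SD-scaled) genotypes and \(k\) is
the retained-variant count (or the sum of column variances when not
scaling), so unrelated non-inbred samples have diagonal ≈ 1,
parent–offspring pairs ≈ 0.5, duplicates ≈ 1. The product is accumulated
column-by-column over chunks, \(WW' = \sum_j w_j w_j'\), never holding
\(W\) in memory, and for large *n* it is partitioned into sample blocks:
409,637 samples at block size 20,000 give 21 sets and \(21\cdot22/2=231\)
stored blocks.

**Relatedness pruning.** `find_related(G, cutoff=0.03)` builds the graph
of pairs with \(G_{ab}\ge\) cutoff and greedily removes the
highest-degree vertex (ties to the lowest index) until no edge remains —
so every retained pair relates below the cutoff.

## Worked example

```python
import numpy as np
from genomat import gwas_rayols, link, open_bed, summarize, qc_mask
from genomat.synthetic_data import simulate_genotypes, simulate_phenotype, write_fixture

geno, _ = simulate_genotypes(n=2000, p=1000, maf_law=(0.1, 0.5),
                             missing_rate=0.01, seed=11)
y, causal = simulate_phenotype(geno, n_qtl=5, h2=0.5, seed=11)
print(causal["variant"].tolist())
# [53, 161, 329, 703, 968]       <- planted causal variants

res = gwas_rayols(geno, y, chunk_size=500)
print(res.sort_values("p_value").head(3)[["variant_id", "estimate", "p_value"]])
#      variant_id  estimate        p_value
# 703         703 -1.127167  2.514662e-106
# 329         329  0.609352   1.389141e-69
# 161         161  0.544942   1.656684e-67
```

The three smallest p-values are three of the five planted QTL;
`estimate` is the phenotype change per A1 copy, and under the null the
remaining p-values are uniform. The same call runs unchanged on a
`BedMatrix` or a linked set of per-chromosome filesets. The
`examples/` directory has one narrative script per capability, including
an end-to-end association workflow (`05_full_pipeline_workflow.py`).

The CLI mirrors the library:

```bash
genomat inspect cohort_chr1              # dims, per-chromosome counts
genomat summarize --bed cohort_chr1 --out summary.tsv
genomat gwas --manifest chroms.json --pheno pheno.tsv --trait height \
             --maf-min 0.01 --call-rate-min 0.95 --top-k 1000 --out gwas.tsv
genomat grm build --bed cohort_chr1 --block-size 20000 --store grm_store/
genomat grm related --store grm_store/ --cutoff 0.03 --out related.tsv
```

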