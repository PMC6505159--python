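# Methods

This note documents the models, conventions and numerical choices behind
`genomat`, and what the synthetic study conditions do and do not
establish about behavior on real data.

## Genotype representation

Genotypes count copies of the A1 allele listed in the `.bim` row, the
additive coding PLINK uses for recoding. The `.bed` payload is
variant-major: after the 3-byte header (`6C 1B 01`), each variant stores
`ceil(n/4)` bytes, sample *k* of a byte in bit pair `(2k, 2k+1)` low-order
first (`00`→2, `10`→1, `11`→0, `01`→missing); trailing bits are padding.
Sample-major files (mode byte `00`) are rejected rather than transposed —
PLINK ≥ 1.9 no longer writes them, and silently accepting both layouts
invites misreads.

Missing calls are a single sentinel (−1) in integer reads, mapped to NaN
in any float read. Integer reads stay compact (int8, one byte per
genotype) while float pipelines get the NaN propagation numpy and pandas
expect.

Internally all indices are 0-based, following numpy; every CLI-facing
index file and report is 1-based, following PLINK. The boundary is the
CLI layer — library functions never see 1-based indices.

Sample IDs are formed as `family-ID_within-family-ID` when the family ID
is informative (not `0`, not empty, not equal to the within-family ID),
else the within-family ID alone; a colliding ID gets its row ordinal
appended. The reference tools do not document their disambiguation rule,
so uniqueness-by-suffix is this package's own guarantee; anything joining
on IDs should treat suffixed IDs as a warning sign about the input.

## Linked arrays and subsetting

A `LinkedMatrix` validates only extent conformability at link time, not
dimension-name consistency; duplicate names across nodes are legal (they
occur in the wild) and name lookup resolves to the first match with a
warning. Extraction routes each requested index to its node via a single
`searchsorted` over the cumulative boundaries, gathers per node, and
scatters into the output in request order; correctness does not depend on
that batching. Requests outside any node, or an empty node list, fail
loudly.

Subsetting a `BGDataSet` yields a `MatrixView` holding the base object
plus index arrays — no genotype copy — so "subset then compute" and
"compute with `rows=`/`cols=` arguments" are the same computation, a
property the tests assert directly.

## Chunked computation and determinism

All heavy operations stream column (or row) chunks; resident payload per
worker is O(chunk_size × other extent). The default chunk size is 5,000
columns, the order of magnitude at which per-chunk numpy overhead is
negligible but a 500K-sample chunk still fits comfortably in memory;
every entry point exposes it.

Outputs are byte-identical across chunk sizes and worker counts. Two
mechanisms deliver this, chosen because reproducibility across
parallelization settings is worth minor constraints:

- Per-variant statistics (summaries, single-marker scans, HWE) reduce
  over rows within one chunk only. Chunks are converted to
  column-contiguous (Fortran) layout before reduction, so each column's
  floating-point reduction executes identically whatever the chunk width.
- Cross-products (`get_g`) accumulate one column's outer product at a
  time in global column order; chunking batches only the I/O, so the
  float operation sequence never depends on chunk boundaries. This
  forgoes BLAS-grouped multiplies inside a block — the cost is acceptable
  at the scales the partitioned builder produces per block, and blocks
  themselves are independent tasks that parallelize freely.

The generic `crossprod_chunked` keeps per-chunk matrix products (fast
path) and therefore promises dense-oracle agreement to 1e-10 relative and
run-to-run reproducibility, not bitwise chunk-size invariance; the
documented pipeline outputs do not go through it.

Parallelism is process-based (joblib/loky) over chunk or block tasks with
results collected in task order; no shared mutable state. Functions
raised inside a chunk are re-raised with the chunk coordinates. `fn`
outputs must have a fixed shape per element; ragged outputs are not
combined.

## Single-marker regression

Missing handling is per-variant complete-case (pairwise deletion): each
variant is analysed on the samples where both it and the phenotype are
observed, maximizing n per variant and matching one-SNP-at-a-time
semantics. Consequences: `n_used` varies across variants, and estimates
across variants are not computed on a common sample.

- **rayOLS** centers phenotype and genotype per variant and regresses
  without intercept. Degrees of freedom are `n − 2` (the centering spends
  the intercept's degree of freedom), so its t statistics and p-values are
  identical to the intercept + SNP fit, which the tests verify per
  variant against an independent least-squares solver at 1e-10.
- **OLS with covariates** fits `intercept + covariates + variant` per
  variant via least squares with an explicit rank check; rank-deficient
  designs yield a NaN row flagged `rank_deficient`, exact fits are
  flagged rather than reporting an infinite statistic.
- **Logistic** fits by IRLS (deviance change < 1e-8, ≤ 25 iterations),
  Wald z and normal p for the variant coefficient. Non-convergence and a
  crude separation screen (|coefficient| > 100 or SE > 1000) yield
  flagged NaN rows.

Monomorphic variants and `n < 3` produce flagged NaN rows, never
exceptions — a genome-wide scan should not die on a degenerate column.
No multiple-testing correction is applied by default (the scan reports
raw p-values); a Benjamini–Hochberg helper is provided for callers who
want an adjusted column.

## Genomic relationships

`get_g` computes `G = W W′ / k` with per-column transforms: optional mean
centering, optional division by the column SD (SD-0 columns are dropped
from both the sum and the divisor count), and mean imputation of missing
genotypes (equivalently 0 after centering) — standard practice; a strict
mode errors on missingness instead. The default divisor is the retained
column count when scaling (expected diagonal ≈ 1), the sum of retained
column variances when centering without scaling, else 1. Both divisor
conventions are exposed because reference implementations differ on this
point.

For a partitioned build, per-column means/SDs are computed in one pass
over **all** selected rows and frozen into the store index; every block
then uses identical statistics, which is what makes the assembled matrix
equal the dense GRM (asserted at 1e-10). Recomputing statistics per block
row-subset would silently break that identity. A standalone `get_g` with
`rows2` and no frozen statistics uses the union of the two row sets.

The block store keeps one file per upper-triangular block (`a_b.bin`:
8-byte shape header of two little-endian uint32, then row-major
little-endian float64) plus `index.json` with partition sizes, sample
IDs, the options fingerprint and the frozen column statistics — a
portable, seekable format that any language can read. Blocks are written
in lexicographic order and are bitwise reproducible.

`find_related` uses greedy highest-degree removal with lowest-index
tie-break on the over-cutoff pair graph. Greedy max-degree is
deterministic and near-minimal (it preferentially drops hub samples that
break many pairs); exact minimum vertex cover is NP-hard and the
difference is immaterial for kinship graphs, which are unions of small
cliques. The choice of *which* member of an isolated pair is dropped (the
lower index stays) is this package's convention; other tools may keep the
other member.

## Synthetic study conditions

Generators draw genotypes under Hardy–Weinberg and linkage equilibrium:
variant j has frequency q_j from a fixed value or a uniform range, and
genotypes Binomial(2, q_j) i.i.d. across samples. Default ranges in the
fixture suite: MAF uniform on (0.1, 0.5) (or (0.05, 0.5) where rare
variants matter), missingness 1–2%, planted QC failures at MAF 1/800 and
call rate 0.92 against gates of 1% and 0.95. Phenotypes are additive:
n_qtl standard-normal raw effects, genetic values rescaled to variance h²
(fixture default h² = 0.5, 5 QTL), Gaussian noise of variance 1 − h².
Duplicates are exact row copies; parent–offspring genomes are
gene-dropped (one transmitted allele per variant, one population draw).
Relatedness fixtures use 20,000 variants so that GRM sampling noise
(≈ 1/√p ≈ 0.007) sits well below the 0.03 pruning cutoff — with far
fewer variants the cutoff is indistinguishable from noise and pruning
collapses the cohort, which is a property of the estimator, not a bug.

What passing these conditions does **not** show: behavior under linkage
disequilibrium (no operation here depends on LD, but downstream
interpretation of "independent" variants would), population structure or
admixture (GRM and GWAS calibration are tested on homogeneous samples),
non-additive traits, and informative missingness. All generators are
pure functions of (parameters, seed), using one global seed with fixed
per-purpose substreams so adding a fixture never shifts existing ones.

## Problem sizes

The test and acceptance runs use deliberately modest sizes chosen so each
statistical check has the power it needs and no more: format/round-trip
checks at n ≤ 16, oracle equivalences at 400 × 2,100, GRM sanity at
200 × 5,000, scan calibration at 1,000 samples × 5,000 null variants,
causal-effect recovery at n = 10,000, relatedness at ~260 × 20,000. The
machinery is size-agnostic; these are verification scales, and the
chunked/partitioned paths they exercise are exactly the ones that carry
to biobank scale.

## Known limitations

- `.pgen` (PLINK 2), VCF and BGEN inputs are out of scope; `.bed` writing
  exists primarily to produce valid filesets for testing and small
  exports.
- No mixed-model or probit GWAS, no genomic prediction, no out-of-core
  eigendecomposition of the GRM.
- Linked views are read-only; there is no lazy arithmetic graph.
- The greedy pruning rule is a documented stand-in where reference tools
  leave their algorithm unspecified; removal sets may differ from other
  software even when both satisfy the same post-condition.
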