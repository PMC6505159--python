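"""End-to-end association workflow at synthetic scale.

Chains the standard biobank-style analysis steps on generated data:

 1. link per-chromosome filesets into one genotype matrix
 2. select the analysis cohort (here: a simulated stratum flag)
 3. per-variant summaries
 4. variant filtering (MAF > 1%, call rate > 0.95)
 5. genomic relationships, built as a partitioned block store
 6. identify a mutually unrelated set (relationships < 0.03)
 7. top principal components via SVD on evenly spaced variants
 8. phenotype adjustment for sex and the PCs by least squares
 9. train/test split of the unrelated samples
10. GWAS on the adjusted phenotype (training set only)
11. selection of the top-ranked variants

The final Bayesian-regression / prediction stages of such pipelines are
an external hand-off and not part of this package.
"""

import tempfile
from pathlib import Path

import numpy as np

from genomat import (build_sym_grm, find_related, gwas_rayols, link, open_bed,
                     qc_mask, summarize)
from genomat.synthetic_data import (simulate_genotypes, simulate_phenotype,
                                    write_fixture)

rng = np.random.default_rng(31)

with tempfile.TemporaryDirectory() as d:
    # 1) three chromosomes, 300 samples x 6000 variants each.  Enough
    # variants that GRM sampling noise (~1/sqrt(p)) sits well below the
    # 0.03 relatedness cutoff used in step 6.
    genos = []
    for c in range(3):
        g, _ = simulate_genotypes(300, 6000, maf_law=(0.005, 0.5),
                                  missing_rate=0.01, seed=300 + c)
        write_fixture(g, Path(d) / f"chr{c + 1}", chrom=str(c + 1), prefix="pl")
        genos.append(g)
    X = link([open_bed(Path(d) / f"chr{c + 1}") for c in range(3)], axis="columns")
    print(f"1) linked genotype matrix: {X.shape}")

    # 2) cohort: a simulated 85% stratum
    cohort = np.flatnonzero(rng.random(300) < 0.85)
    print(f"2) analysis cohort: {cohort.size} samples")

    # 3-4) summaries + QC gate on the cohort
    summ = summarize(X, rows=cohort, chunk_size=250)
    keep = qc_mask(summ, maf_min=0.01, call_rate_min=0.95)
    print(f"3-4) QC kept {keep.size} / {X.shape[1]} variants")

    # 5) partitioned GRM over the cohort and filtered variants
    S = build_sym_grm(X, Path(d) / "grm", block_size=100, rows=cohort, cols=keep)
    print(f"5) GRM store: {len(S.partition)} sets, {len(S.blocks)} blocks")

    # 6) unrelated subset at cutoff 0.03 (indices are within the cohort)
    removed = find_related(S, cutoff=0.03)
    unrelated = np.delete(cohort, removed)
    print(f"6) unrelated set: {unrelated.size} samples "
          f"({removed.size} removed at cutoff 0.03)")

    # 7) PCs from an SVD of 100 evenly spaced filtered variants
    spaced = keep[np.linspace(0, keep.size - 1, 100).astype(int)]
    W = X.read(unrelated, spaced)
    W = np.where(np.isnan(W), np.nanmean(W, axis=0), W)
    W = (W - W.mean(0)) / np.where(W.std(0) > 0, W.std(0), 1.0)
    pcs = np.linalg.svd(W, full_matrices=False)[0][:, :5]
    print(f"7) computed {pcs.shape[1]} principal components")

    # 8) phenotype: 5 QTL at h2 = 0.6, then adjust for sex + PCs
    dense = np.concatenate(genos, axis=1)
    y_all, causal = simulate_phenotype(dense, n_qtl=5, h2=0.6, seed=303)
    sex = rng.integers(0, 2, size=300).astype(float)
    y = y_all[unrelated] + 0.5 * sex[unrelated]
    Z = np.column_stack([np.ones(unrelated.size), sex[unrelated], pcs])
    y_adj = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    print("8) adjusted phenotype variance:", round(float(y_adj.var()), 3))

    # 9) train/test split
    perm = rng.permutation(unrelated.size)
    test, train = perm[:50], perm[50:]
    print(f"9) training n = {train.size}, test n = {test.size}")

    # 10) GWAS on the training set, filtered variants only
    res = gwas_rayols(X, y_adj[train], rows=unrelated[train], cols=keep,
                      chunk_size=250)
    print(f"10) scanned {len(res)} variants")

    # 11) top-20 variants by p-value
    top = np.argsort(res["p_value"].to_numpy())[:20]
    top_global = keep[top]
    recovered = set(top_global) & set(causal["variant"])
    print(f"11) top-20 selection recovers {len(recovered)} / 5 causal variants")
    print("    (hand-off point: these variants would feed a genomic-prediction fit)")
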