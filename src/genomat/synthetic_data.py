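"""Synthetic genotype/phenotype fixtures with known ground truth.

Everything in this package is testable without external data: the
generators here produce PLINK filesets with controlled allele frequencies,
missingness, additive QTL effects, heritability, and planted related
pairs, plus a ground-truth JSON recording what was planted.

Model assumptions.  Genotypes are drawn under Hardy-Weinberg equilibrium
and linkage equilibrium: variant j has an A1 frequency q_j from the chosen
law and genotypes Binomial(2, q_j) independent across samples and
variants.  This makes analytic expectations exact (GRM diagonal ~1, HWE
chi-square null, binomial MAF concentration) at the cost of realism in LD
structure — which no operation in this package depends on.  Phenotypes
are additive: a chosen number of causal variants get standard-normal raw
effects, genetic values are rescaled to variance h2 and independent
Gaussian noise of variance 1 - h2 is added.

All generators are pure functions of (parameters, seed).  One global
integer seed feeds a fixed per-purpose substream scheme
(:func:`substream`), so adding a new fixture never perturbs existing
ones.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .bed_io import MISSING, write_bed

__all__ = [
    "substream",
    "simulate_genotypes",
    "simulate_phenotype",
    "plant_relatives",
    "make_fixture_suite",
    "write_fixture",
]

# stable purpose -> substream key; append-only so goldens never move
_PURPOSES = {
    "genotypes": 1,
    "missingness": 2,
    "phenotype": 3,
    "relatives": 4,
    "suite_multichrom": 10,
    "suite_qc": 11,
    "suite_related": 12,
    "suite_gwas": 13,
}


def substream(seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from one global seed."""
    key = _PURPOSES[purpose]
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(key, int(index))))


def simulate_genotypes(
    n: int,
    p: int,
    maf_law=(0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an n x p genotype matrix under HWE with independent variants.

    ``maf_law`` is either a single frequency in (0, 0.5] applied to every
    variant or a (low, high) range sampled uniformly per variant.  Missing
    entries are planted independently at ``missing_rate`` and coded as
    :data:`~genomat.bed_io.MISSING`.  Returns the int8 genotype matrix and
    the true per-variant A1 frequencies.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = substream(seed, "genotypes")
    if np.isscalar(maf_law):
        q = np.full(p, float(maf_law))
    else:
        low, high = maf_law
        q = rng.uniform(low, high, size=p)
    if np.any((q <= 0) | (q > 0.5)):
        raise ValueError("allele frequencies must be in (0, 0.5]")
    geno = rng.binomial(2, q[None, :], size=(n, p)).astype(np.int8)
    if missing_rate > 0:
        miss_rng = substream(seed, "missingness")
        geno[miss_rng.random((n, p)) < missing_rate] = MISSING
    return geno, q


def simulate_phenotype(
    geno: np.ndarray,
    n_qtl: int,
    h2: float,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate an additive quantitative trait on top of ``geno``.

    ``n_qtl`` causal variants are drawn (monomorphic candidates are
    resampled) with standard-normal raw effects; genetic values are scaled
    to variance ``h2`` and Gaussian noise of variance ``1 - h2`` added, so
    the trait has unit variance in expectation.  ``h2 = 0`` yields pure
    noise.  Returns the phenotype vector and the causal table
    (variant index, scaled effect).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    n, p = geno.shape
    if n_qtl > p:
        raise ValueError("n_qtl cannot exceed the number of variants")
    rng = substream(seed, "phenotype")
    X = geno.astype(np.float64)
    X[geno == MISSING] = np.nan
    mono = np.nanstd(X, axis=0) == 0
    candidates = np.flatnonzero(~mono)
    if n_qtl > 0 and candidates.size < n_qtl:
        raise ValueError("not enough polymorphic variants for the requested QTL count")
    noise = rng.normal(size=n)
    if n_qtl == 0 or h2 == 0:
        qtl = rng.choice(candidates, size=n_qtl, replace=False) if n_qtl else np.array([], dtype=int)
        causal = pd.DataFrame({"variant": np.sort(qtl), "effect": np.zeros(len(qtl))})
        return noise, causal
    qtl = np.sort(rng.choice(candidates, size=n_qtl, replace=False))
    raw = rng.normal(size=n_qtl)
    W = X[:, qtl]
    mu = np.nanmean(W, axis=0)
    W = np.where(np.isnan(W), mu[None, :], W) - mu[None, :]
    g = W @ raw
    sd_g = g.std()
    scale = np.sqrt(h2) / sd_g if sd_g > 0 else 0.0
    g_scaled = g * scale
    y = g_scaled + np.sqrt(1.0 - h2) * noise
    causal = pd.DataFrame({"variant": qtl, "effect": raw * scale})
    return y, causal


def plant_relatives(
    geno: np.ndarray,
    n_duplicate_pairs: int = 0,
    n_po_pairs: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Append planted relatives to a genotype matrix.

    Duplicates are exact row copies of distinct existing samples.
    Parent-offspring rows are gene-dropped: at each variant one allele is
    transmitted from the parent (Bernoulli(parent genotype / 2)) and the
    other is drawn at the variant's empirical A1 frequency.  Missing
    parental genotypes fall back to two population draws.  Returns the
    augmented matrix (new rows appended in registry order) and the pair
    registry (kind, original row, new row).
    """
    geno = np.asarray(geno, dtype=np.int8)
    n, p = geno.shape
    total = n_duplicate_pairs + n_po_pairs
    if total > n:
        raise ValueError("not enough existing samples to anchor the requested pairs")
    rng = substream(seed, "relatives")
    anchors = rng.choice(n, size=total, replace=False)
    X = geno.astype(np.float64)
    X[geno == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        q = np.nanmean(X, axis=0) / 2.0
    q = np.where(np.isnan(q), 0.5, q)

    new_rows, registry = [], []
    for k in range(n_duplicate_pairs):
        a = int(anchors[k])
        new_rows.append(geno[a].copy())
        registry.append(("duplicate", a, n + len(new_rows) - 1))
    for k in range(n_po_pairs):
        parent = int(anchors[n_duplicate_pairs + k])
        pg = geno[parent].astype(np.float64)
        observed = pg != MISSING
        transmitted = np.where(
            observed,
            rng.random(p) < pg / 2.0,
            rng.random(p) < q,
        ).astype(np.int8)
        other = (rng.random(p) < q).astype(np.int8)
        child = transmitted + other
        new_rows.append(child)
        registry.append(("parent_offspring", parent, n + len(new_rows) - 1))
    augmented = np.vstack([geno, np.array(new_rows, dtype=np.int8)]) if new_rows else geno
    reg = pd.DataFrame(registry, columns=["kind", "row_a", "row_b"])
    return augmented, reg


def _fileset_tables(n: int, p: int, chrom: str, prefix: str,
                    pos_start: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    fam = pd.DataFrame({
        "family_id": ["0"] * n,
        "within_family_id": [f"{prefix}_s{i + 1}" for i in range(n)],
        "father_id": ["0"] * n,
        "mother_id": ["0"] * n,
        "sex": ["0"] * n,
        "phenotype": ["-9"] * n,
    })
    bim = pd.DataFrame({
        "chrom": [chrom] * p,
        "variant_id": [f"{prefix}_c{chrom}_v{j + 1}" for j in range(p)],
        "cm": [0] * p,
        "pos": np.arange(pos_start, pos_start + p, dtype=np.int64),
        "a1": ["A"] * p,
        "a2": ["G"] * p,
    })
    return fam, bim


def write_fixture(geno: np.ndarray, root: str | os.PathLike, chrom: str = "1",
                  prefix: str = "fx") -> Path:
    """Write a genotype matrix as a PLINK fileset with generated tables."""
    n, p = geno.shape
    fam, bim = _fileset_tables(n, p, chrom, prefix)
    write_bed(geno, root, fam=fam, bim=bim)
    return Path(root)


def make_fixture_suite(out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Generate the standard fixture suite under ``out_dir``.

    Fixtures (each with a ground-truth JSON):

    * ``multichrom``: three per-chromosome filesets of 199 samples x 300
      variants each, plus a manifest and a phenotype TSV — the shape used
      throughout the linked-array examples.
    * ``qc``: 400 samples x 500 variants with exactly 10 planted rare
      variants (below the 1% MAF gate) and 7 low-call-rate variants
      (below the 0.95 call-rate gate).
    * ``related``: 300 base samples with planted duplicate and
      parent-offspring pairs.
    * ``gwas``: 500 samples x 800 variants, 5 causal QTL at h2 = 0.5.

    Regenerating with the same seed reproduces byte-identical filesets.
    Returns the manifest dictionary (paths + ground truth), also written
    as ``suite.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "fixtures": {}}

    # -- multichrom: 3 chromosomes x 300 variants, 199 samples
    n_mc = 199
    roots = []
    rng_truth = {}
    for c in range(3):
        g, q = simulate_genotypes(n_mc, 300, maf_law=(0.05, 0.5),
                                  missing_rate=0.01, seed=_mix(seed, "suite_multichrom", c))
        fam, bim = _fileset_tables(n_mc, 300, str(c + 1), "mc")
        root = out_dir / f"multichrom_chr{c + 1}"
        write_bed(g, root, fam=fam, bim=bim)
        roots.append(str(root))
        rng_truth[f"chr{c + 1}_freqs"] = [float(v) for v in q]
    pheno_rng = substream(seed, "suite_multichrom", 99)
    pheno = pd.DataFrame({
        "sample_id": [f"mc_s{i + 1}" for i in range(n_mc)],
        "trait": pheno_rng.normal(size=n_mc),
    })
    pheno_path = out_dir / "multichrom_pheno.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    from .linked_arrays import save_manifest
    save_manifest(roots, out_dir / "multichrom_manifest.json", axis="columns")
    manifest["fixtures"]["multichrom"] = {
        "roots": roots, "pheno": str(pheno_path),
        "manifest": str(out_dir / "multichrom_manifest.json"),
        "n_samples": n_mc, "n_variants_total": 900,
    }
    _dump_truth(out_dir / "multichrom_truth.json", rng_truth)

    # -- QC edge cases: planted MAF / call-rate failures
    n_qc, p_qc = 400, 500
    g, q = simulate_genotypes(n_qc, p_qc, maf_law=(0.1, 0.5), missing_rate=0.0,
                              seed=_mix(seed, "suite_qc", 0))
    rng = substream(seed, "suite_qc", 1)
    fail_idx = rng.choice(p_qc, size=17, replace=False)
    maf_fail = np.sort(fail_idx[:10])
    call_fail = np.sort(fail_idx[10:])
    for j in maf_fail:  # one alternate allele in 400 samples -> MAF 1/800
        col = np.zeros(n_qc, dtype=np.int8)
        col[rng.integers(n_qc)] = 1
        g[:, j] = col
    for j in call_fail:  # 8% missing -> call rate 0.92
        miss = rng.choice(n_qc, size=int(0.08 * n_qc), replace=False)
        g[miss, j] = MISSING
    root = out_dir / "qc"
    write_fixture(g, root, prefix="qc")
    manifest["fixtures"]["qc"] = {"root": str(root), "n_samples": n_qc, "n_variants": p_qc}
    _dump_truth(out_dir / "qc_truth.json", {
        "maf_fail": [int(j) for j in maf_fail],
        "call_rate_fail": [int(j) for j in call_fail],
    })

    # -- relatedness: planted duplicates and parent-offspring pairs.
    # 20k variants keep GRM noise (~1/sqrt(p)) well below the 0.03 cutoff,
    # so pruning targets the planted pairs rather than sampling noise.
    g, q = simulate_genotypes(300, 20_000, maf_law=(0.1, 0.5), missing_rate=0.0,
                              seed=_mix(seed, "suite_related", 0))
    aug, registry = plant_relatives(g, n_duplicate_pairs=5, n_po_pairs=5,
                                    seed=_mix(seed, "suite_related", 1))
    root = out_dir / "related"
    write_fixture(aug, root, prefix="rel")
    manifest["fixtures"]["related"] = {"root": str(root),
                                       "n_samples": int(aug.shape[0]),
                                       "n_variants": 20_000}
    _dump_truth(out_dir / "related_truth.json", {
        "pairs": registry.to_dict(orient="records"),
    })

    # -- GWAS: additive trait with known causal variants
    n_gw, p_gw = 500, 800
    g, q = simulate_genotypes(n_gw, p_gw, maf_law=(0.1, 0.5), missing_rate=0.01,
                              seed=_mix(seed, "suite_gwas", 0))
    y, causal = simulate_phenotype(g, n_qtl=5, h2=0.5, seed=_mix(seed, "suite_gwas", 1))
    root = out_dir / "gwas"
    write_fixture(g, root, prefix="gw")
    pheno = pd.DataFrame({"sample_id": [f"gw_s{i + 1}" for i in range(n_gw)], "trait": y})
    gw_pheno = out_dir / "gwas_pheno.tsv"
    pheno.to_csv(gw_pheno, sep="\t", index=False)
    manifest["fixtures"]["gwas"] = {"root": str(root), "pheno": str(gw_pheno),
                                    "n_samples": n_gw, "n_variants": p_gw}
    _dump_truth(out_dir / "gwas_truth.json", {
        "causal": causal.to_dict(orient="records"),
        "h2": 0.5,
    })

    (out_dir / "suite.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _mix(seed: int, purpose: str, index: int) -> int:
    """Fold a purpose/index into a derived integer seed below 2**31 so each
    fixture draws from its own substream of the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(_PURPOSES[purpose], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _dump_truth(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2) + "\n")
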