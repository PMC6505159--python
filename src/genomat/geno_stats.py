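"""Statistical-genetics operations over matrix-like genotypes.

All functions here accept any matrix-like genotype object (BedMatrix,
LinkedMatrix, MatrixView, plain array) with values in {0, 1, 2, missing},
run chunked over columns via the split-apply-combine engine, and return
pandas tables.  The heavy per-variant operations — summaries, the rayOLS
single-marker scan, the genomic relationship matrix — are fully vectorized
within chunks, so performance is bounded by the chunk reads.

Statistical conventions
-----------------------
* Genotypes count copies of the A1 allele; ``allele_freq_a1`` is the mean
  genotype over complete cases divided by 2, and MAF = min(q, 1-q).
* Missing handling is per-variant complete-case ("one SNP at a time"):
  each variant is analysed on the samples where both it and the phenotype
  are observed.
* rayOLS centers phenotype and genotype and regresses without intercept;
  this is algebraically the slope of the intercept + SNP model, so the
  residual degrees of freedom are n - 2 and p-values are two-sided t.
* The GRM is ``W W' / k`` where W is the (optionally centered/scaled)
  genotype block; with the default options (center, scale, divide by the
  number of retained variants) the expected diagonal is ~1 for unrelated,
  non-inbred samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chunked_compute import DEFAULT_CHUNK_SIZE, chunk_ranges, parallel_map
from .linked_arrays import node_read, node_shape

__all__ = [
    "GrmOptions",
    "summarize",
    "qc_mask",
    "gwas_rayols",
    "gwas_ols",
    "gwas_logistic",
    "hwe_chisq",
    "hwe_chisq_scan",
    "get_g",
    "find_related",
    "benjamini_hochberg",
]


def _resolve(X, rows, cols):
    n, p = node_shape(X)
    rows = np.arange(n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
    cols = np.arange(p, dtype=np.intp) if cols is None else np.asarray(cols, dtype=np.intp)
    if rows.size and (rows.min() < 0 or rows.max() >= n):
        raise IndexError("row subset out of bounds")
    if cols.size and (cols.min() < 0 or cols.max() >= p):
        raise IndexError("column subset out of bounds")
    return rows, cols


# ---------------------------------------------------------------------------
# summaries and QC

def summarize(geno, rows=None, cols=None, chunk_size: int = DEFAULT_CHUNK_SIZE,
              n_tasks: int = 1) -> pd.DataFrame:
    """Per-variant summary statistics on the selected row subset.

    Returns a DataFrame with one row per selected variant:
    ``allele_freq_a1`` (mean genotype / 2 over complete cases), ``maf``,
    ``freq_missing``, ``sd`` (sample SD, ddof=1, of non-missing genotypes)
    and ``n_nonmissing``.  A variant with no observed genotypes has NaN for
    everything except ``freq_missing`` (= 1).  Deterministic under chunking
    and worker count.
    """
    rows, cols = _resolve(geno, rows, cols)
    if rows.size == 0:
        raise ValueError("summarize requires a non-empty row subset")

    def process(rng):
        start, stop = rng
        # column-contiguous layout: each column's reduction runs identically
        # whatever the chunk width, keeping outputs bitwise chunk-invariant
        block = np.asfortranarray(node_read(geno, rows, cols[start:stop],
                                            dtype=np.float64))
        obs = ~np.isnan(block)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nansum(block, axis=0) / n_obs
            sq = np.nansum(block * block, axis=0)
            var = (sq - n_obs * mean**2) / (n_obs - 1)
        var = np.where(n_obs > 1, np.maximum(var, 0.0), np.nan)
        mean = np.where(n_obs > 0, mean, np.nan)
        freq = mean / 2.0
        return np.column_stack([
            freq,
            np.minimum(freq, 1.0 - freq),
            1.0 - n_obs / rows.size,
            np.sqrt(var),
            n_obs.astype(np.float64),
        ])

    parts = parallel_map(process, chunk_ranges(cols.size, chunk_size), n_workers=n_tasks)
    table = np.concatenate(parts, axis=0) if parts else np.empty((0, 5))
    out = pd.DataFrame(
        table,
        columns=["allele_freq_a1", "maf", "freq_missing", "sd", "n_nonmissing"],
    )
    out["n_nonmissing"] = out["n_nonmissing"].astype(np.int64)
    ids = getattr(geno, "variant_ids", None) or getattr(geno, "col_names", None)
    out.insert(0, "variant_id",
               [ids[j] for j in cols] if ids is not None else cols.astype(np.int64))
    return out


def qc_mask(summary: pd.DataFrame, maf_min: float = 0.01,
            call_rate_min: float = 0.95) -> np.ndarray:
    """Indices (0-based, into the summary's rows) of variants passing
    ``maf > maf_min`` AND ``call rate > call_rate_min`` — strict
    inequalities, so a variant sitting exactly on a threshold is excluded.
    All-missing variants (NaN maf) never pass."""
    if not (0 <= maf_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    maf = summary["maf"].to_numpy(dtype=np.float64)
    call = 1.0 - summary["freq_missing"].to_numpy(dtype=np.float64)
    keep = (maf > maf_min) & (call > call_rate_min)
    keep &= ~np.isnan(maf)
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# single-marker regression

def _result_frame(p: int) -> dict[str, np.ndarray]:
    return {
        "estimate": np.full(p, np.nan),
        "std_error": np.full(p, np.nan),
        "statistic": np.full(p, np.nan),
        "p_value": np.full(p, np.nan),
        "n_used": np.zeros(p, dtype=np.int64),
        "flag": np.array([""] * p, dtype=object),
    }


def _attach_ids(out: pd.DataFrame, geno, cols: np.ndarray, method: str) -> pd.DataFrame:
    ids = getattr(geno, "variant_ids", None) or getattr(geno, "col_names", None)
    out.insert(0, "variant_id",
               [ids[j] for j in cols] if ids is not None else cols.astype(np.int64))
    out["method"] = method
    return out


def gwas_rayols(geno, y, rows=None, cols=None, chunk_size: int = DEFAULT_CHUNK_SIZE,
                n_tasks: int = 1) -> pd.DataFrame:
    """Single-marker scan by centered no-intercept least squares (rayOLS).

    For each variant j, over the n_j samples where both the phenotype and
    the genotype are observed::

        beta_j = sum (x - xbar)(y - ybar) / sum (x - xbar)^2
        s^2    = RSS / (n_j - 2),   SE = sqrt(s^2 / sum (x - xbar)^2)

    with a two-sided t test on n_j - 2 degrees of freedom.  ``y`` may be
    given for all samples of ``geno`` or for the ``rows`` subset.  Variants
    monomorphic in the analysis subset, or with fewer than 3 complete
    cases, get a NaN row with a reason in ``flag`` rather than an error.
    """
    rows, cols = _resolve(geno, rows, cols)
    y = np.asarray(y, dtype=np.float64).ravel()
    n_all, _ = node_shape(geno)
    if y.size == n_all:
        y = y[rows]
    elif y.size != rows.size:
        raise ValueError(
            f"y has length {y.size}; expected {n_all} (all samples) or {rows.size} (subset)"
        )
    y_obs = ~np.isnan(y)

    def process(rng):
        start, stop = rng
        G = np.asfortranarray(node_read(geno, rows, cols[start:stop],
                                        dtype=np.float64))
        mask = ~np.isnan(G) & y_obs[:, None]
        n = mask.sum(axis=0).astype(np.float64)
        # F-order keeps per-column reductions bitwise chunk-width-invariant
        Gm = np.asfortranarray(np.where(mask, G, 0.0))
        ym = np.asfortranarray(np.where(mask, y[:, None], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            xbar = Gm.sum(axis=0) / n
            ybar = ym.sum(axis=0) / n
            sxx = (Gm * Gm).sum(axis=0) - n * xbar**2
            syy = (ym * ym).sum(axis=0) - n * ybar**2
            sxy = (Gm * ym).sum(axis=0) - n * xbar * ybar
            beta = sxy / sxx
            rss = np.maximum(syy - beta * sxy, 0.0)
            s2 = rss / (n - 2)
            se = np.sqrt(s2 / sxx)
            tstat = beta / se
        df = n - 2
        pval = 2.0 * sps.t.sf(np.abs(tstat), np.maximum(df, 1))
        res = _result_frame(stop - start)
        mono = (sxx <= 0) | ~np.isfinite(sxx)
        toofew = n < 3
        ok = ~(mono | toofew)
        res["estimate"][ok] = beta[ok]
        res["std_error"][ok] = se[ok]
        res["statistic"][ok] = tstat[ok]
        res["p_value"][ok] = pval[ok]
        res["n_used"] = n.astype(np.int64)
        res["flag"][toofew] = "too_few_samples"
        res["flag"][mono & ~toofew] = "monomorphic"
        return pd.DataFrame(res)

    parts = parallel_map(process, chunk_ranges(cols.size, chunk_size), n_workers=n_tasks)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(_result_frame(0))
    return _attach_ids(out, geno, cols, "rayOLS")


def gwas_ols(geno, pheno: pd.DataFrame, response: str, covariates=(), rows=None,
             cols=None, chunk_size: int = DEFAULT_CHUNK_SIZE, n_tasks: int = 1) -> pd.DataFrame:
    """Single-marker OLS with covariates: per variant, fit
    ``response ~ intercept + covariates + variant`` on complete cases and
    report the variant's coefficient row (t test, df = n - k - 2 for k
    covariates).  Rank-deficient designs get a NaN row with a flag.

    With no covariates this agrees with :func:`gwas_rayols` variant by
    variant.
    """
    rows, cols = _resolve(geno, rows, cols)
    covariates = list(covariates)
    for name in [response, *covariates]:
        if name not in pheno.columns:
            raise KeyError(f"column {name!r} not found in pheno")
    ysub = pheno[response].to_numpy(dtype=np.float64)
    if ysub.size == node_shape(geno)[0]:
        ysub = ysub[rows]
    Z = pheno[covariates].to_numpy(dtype=np.float64) if covariates else np.empty((len(pheno), 0))
    if Z.shape[0] == node_shape(geno)[0]:
        Z = Z[rows]
    base_obs = ~np.isnan(ysub) & ~np.isnan(Z).any(axis=1)

    def process(rng):
        start, stop = rng
        G = node_read(geno, rows, cols[start:stop], dtype=np.float64)
        res = _result_frame(stop - start)
        for local in range(stop - start):
            x = G[:, local]
            use = base_obs & ~np.isnan(x)
            n = int(use.sum())
            res["n_used"][local] = n
            k = Z.shape[1]
            if n < k + 3:
                res["flag"][local] = "too_few_samples"
                continue
            D = np.column_stack([np.ones(n), Z[use], x[use]])
            rank = np.linalg.matrix_rank(D)
            if rank < D.shape[1]:
                res["flag"][local] = "rank_deficient"
                continue
            coef, _, _, _ = np.linalg.lstsq(D, ysub[use], rcond=None)
            resid = ysub[use] - D @ coef
            rss = float(resid @ resid)
            df = n - k - 2
            s2 = rss / df
            xtx_inv = np.linalg.inv(D.T @ D)
            se = np.sqrt(s2 * xtx_inv[-1, -1])
            beta = coef[-1]
            if se == 0:
                res["estimate"][local] = beta
                res["std_error"][local] = 0.0
                res["flag"][local] = "exact_fit"
                continue
            t = beta / se
            res["estimate"][local] = beta
            res["std_error"][local] = se
            res["statistic"][local] = t
            res["p_value"][local] = 2.0 * sps.t.sf(abs(t), df)
        return pd.DataFrame(res)

    parts = parallel_map(process, chunk_ranges(cols.size, chunk_size), n_workers=n_tasks)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(_result_frame(0))
    return _attach_ids(out, geno, cols, "OLS")


def _irls_logistic(D: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 25) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares.  Returns (coefficients, standard errors, converged)."""
    beta = np.zeros(D.shape[1])
    dev_old = np.inf
    converged = False
    cov = None
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.all(w < 1e-12):
            break
        WD = D * w[:, None]
        H = D.T @ WD
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        beta = beta + cov @ (D.T @ (y - mu))
        eps = 1e-12
        dev = -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
        if abs(dev_old - dev) < tol:
            converged = True
            break
        dev_old = dev
    if cov is None:
        return beta, np.full_like(beta, np.nan), False
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # crude separation check: exploding coefficient or SE
    if converged and (np.any(np.abs(beta) > 1e2) or np.any(se > 1e3)):
        converged = False
    return beta, se, converged


def gwas_logistic(geno, pheno: pd.DataFrame, response: str, covariates=(), rows=None,
                  cols=None, chunk_size: int = DEFAULT_CHUNK_SIZE,
                  n_tasks: int = 1) -> pd.DataFrame:
    """Single-marker logistic regression for a {0,1} response.

    Per variant, ``response ~ intercept + covariates + variant`` is fit by
    IRLS (deviance tolerance 1e-8, at most 25 iterations); the variant
    coefficient is reported with a Wald z statistic and two-sided normal
    p-value.  Non-convergence or (quasi-)separation yields a NaN row with
    a flag.
    """
    rows, cols = _resolve(geno, rows, cols)
    covariates = list(covariates)
    yfull = pheno[response].to_numpy(dtype=np.float64)
    if yfull.size == node_shape(geno)[0]:
        yfull = yfull[rows]
    vals = yfull[~np.isnan(yfull)]
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("logistic response must be coded {0, 1}")
    Z = pheno[covariates].to_numpy(dtype=np.float64) if covariates else np.empty((len(pheno), 0))
    if Z.shape[0] == node_shape(geno)[0]:
        Z = Z[rows]
    base_obs = ~np.isnan(yfull) & ~np.isnan(Z).any(axis=1)

    def process(rng):
        start, stop = rng
        G = node_read(geno, rows, cols[start:stop], dtype=np.float64)
        res = _result_frame(stop - start)
        for local in range(stop - start):
            x = G[:, local]
            use = base_obs & ~np.isnan(x)
            n = int(use.sum())
            res["n_used"][local] = n
            yv = yfull[use]
            if n < Z.shape[1] + 3 or len(np.unique(yv)) < 2 or np.ptp(x[use]) == 0:
                res["flag"][local] = "degenerate"
                continue
            D = np.column_stack([np.ones(n), Z[use], x[use]])
            beta, se, converged = _irls_logistic(D, yv)
            if not converged or not np.isfinite(se[-1]) or se[-1] == 0:
                res["flag"][local] = "non_convergence"
                continue
            z = beta[-1] / se[-1]
            res["estimate"][local] = beta[-1]
            res["std_error"][local] = se[-1]
            res["statistic"][local] = z
            res["p_value"][local] = 2.0 * sps.norm.sf(abs(z))
        return pd.DataFrame(res)

    parts = parallel_map(process, chunk_ranges(cols.size, chunk_size), n_workers=n_tasks)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(_result_frame(0))
    return _attach_ids(out, geno, cols, "logistic")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up); NaNs pass
    through."""
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full_like(p, np.nan)
    ok = np.flatnonzero(~np.isnan(p))
    if ok.size == 0:
        return out
    m = ok.size
    order = ok[np.argsort(p[ok], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium

def hwe_chisq(geno_or_counts) -> tuple[float, float, int]:
    """One-locus Hardy-Weinberg chi-square test (1 df).

    Accepts either a genotype vector with values in {0, 1, 2, NaN/missing}
    or a 3-tuple of genotype counts ``(n0, n1, n2)``.  With allele-frequency
    estimate ``p = (2 n2 + n1) / 2N``, expected counts are
    ``N(1-p)^2, 2Np(1-p), Np^2`` and the statistic is the usual
    sum((obs - exp)^2 / exp).  Monomorphic loci return statistic 0 and
    p-value 1 by convention.
    """
    if isinstance(geno_or_counts, tuple) and len(geno_or_counts) == 3:
        n0, n1, n2 = (float(c) for c in geno_or_counts)
    else:
        arr = np.asarray(geno_or_counts, dtype=np.float64)
        valid = arr[~np.isnan(arr)]
        valid = valid[valid >= 0]  # drop integer MISSING sentinels
        n0, n1, n2 = (float(np.sum(valid == g)) for g in (0, 1, 2))
    N = n0 + n1 + n2
    if N < 1:
        raise ValueError("HWE test requires at least one non-missing genotype")
    p_hat = (2.0 * n2 + n1) / (2.0 * N)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0, 1
    expected = np.array([N * (1 - p_hat) ** 2, 2 * N * p_hat * (1 - p_hat), N * p_hat**2])
    observed = np.array([n0, n1, n2], dtype=np.float64)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return stat, float(sps.chi2.sf(stat, 1)), 1


def hwe_chisq_scan(geno, rows=None, cols=None, chunk_size: int = DEFAULT_CHUNK_SIZE,
                   n_tasks: int = 1) -> pd.DataFrame:
    """Genome-wide HWE scan: :func:`hwe_chisq` per variant via the chunked
    engine.  Returns columns ``statistic`` and ``p_value``."""
    rows, cols = _resolve(geno, rows, cols)

    def process(rng):
        start, stop = rng
        block = node_read(geno, rows, cols[start:stop], dtype=np.float64)
        n0 = np.nansum(block == 0, axis=0).astype(np.float64)
        n1 = np.nansum(block == 1, axis=0).astype(np.float64)
        n2 = np.nansum(block == 2, axis=0).astype(np.float64)
        N = n0 + n1 + n2
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = (2 * n2 + n1) / (2 * N)
            e0 = N * (1 - p_hat) ** 2
            e1 = 2 * N * p_hat * (1 - p_hat)
            e2 = N * p_hat**2
            stat = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
        mono = (p_hat <= 0) | (p_hat >= 1) | ~np.isfinite(p_hat)
        stat = np.where(mono, 0.0, stat)
        pval = np.where(mono, 1.0, sps.chi2.sf(stat, 1))
        return np.column_stack([stat, pval])

    parts = parallel_map(process, chunk_ranges(cols.size, chunk_size), n_workers=n_tasks)
    table = np.concatenate(parts, axis=0) if parts else np.empty((0, 2))
    return pd.DataFrame(table, columns=["statistic", "p_value"])


# ---------------------------------------------------------------------------
# genomic relationships

@dataclass
class GrmOptions:
    """Centering/scaling options for genomic relationship matrices.

    center
        Subtract per-column means.
    scale
        Divide columns by their SD (zero-SD columns are dropped).
    scale_to_avg_diag_one
        Divide the cross-product by the number of retained columns (when
        ``scale``) or by the sum of retained column variances (when not),
        putting the expected diagonal near 1 for unrelated samples.
    impute_missing_to_mean
        Replace missing genotypes by the column mean (0 after centering);
        when off, missing genotypes raise.
    """

    center: bool = True
    scale: bool = True
    scale_to_avg_diag_one: bool = True
    impute_missing_to_mean: bool = True

    def fingerprint(self) -> str:
        return (f"center={self.center},scale={self.scale},"
                f"avg_diag_one={self.scale_to_avg_diag_one},"
                f"impute={self.impute_missing_to_mean}")


def grm_column_stats(geno, rows, cols, chunk_size: int = DEFAULT_CHUNK_SIZE,
                     n_tasks: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-column means and SDs over ``rows`` (complete cases), the frozen
    statistics shared by all blocks of a partitioned GRM build."""
    summ = summarize(geno, rows=rows, cols=cols, chunk_size=chunk_size, n_tasks=n_tasks)
    means = 2.0 * summ["allele_freq_a1"].to_numpy(dtype=np.float64)
    sds = summ["sd"].to_numpy(dtype=np.float64)
    return means, sds


def get_g(
    geno,
    options: GrmOptions | None = None,
    rows=None,
    rows2=None,
    cols=None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    n_tasks: int = 1,
    col_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Genomic relationship matrix (or off-diagonal block) ``W W' / k``.

    W is the genotype block ``geno[rows, cols]`` transformed per column
    according to ``options``; with ``rows2`` the result is the
    ``|rows| x |rows2|`` block ``W_rows W_rows2'`` and both sides share the
    same column statistics.  ``col_stats`` (means, SDs aligned with
    ``cols``) freezes those statistics — this is how a partitioned build
    keeps its blocks mutually consistent; by default they are computed over
    ``rows`` (union with ``rows2`` when given).  The computation streams
    column chunks and accumulates in ascending chunk order, never
    materializing the full block of genotypes.

    Without ``rows2`` the result is symmetric positive semi-definite up to
    floating-point tolerance.
    """
    opts = options or GrmOptions()
    rows, cols = _resolve(geno, rows, cols)
    rows2 = None if rows2 is None else np.asarray(rows2, dtype=np.intp)
    if cols.size < 2:
        raise ValueError("GRM computation requires at least 2 variants")
    if col_stats is None:
        if rows2 is None:
            stat_rows = rows
        else:
            stat_rows = np.unique(np.concatenate([rows, rows2]))
        means, sds = grm_column_stats(geno, stat_rows, cols, chunk_size, n_tasks)
    else:
        means, sds = (np.asarray(a, dtype=np.float64) for a in col_stats)
        if means.size != cols.size or sds.size != cols.size:
            raise ValueError("col_stats must align with the selected columns")

    retained = np.isfinite(sds) & np.isfinite(means)
    if opts.scale:
        retained &= sds > 0
    if not retained.any():
        raise ValueError("all selected columns are constant; GRM is degenerate")

    if opts.scale_to_avg_diag_one:
        if opts.scale:
            k = float(retained.sum())
        else:
            k = float(np.sum(sds[retained] ** 2))
            if k == 0:
                raise ValueError("sum of column variances is zero; GRM is degenerate")
    else:
        k = 1.0

    sym = rows2 is None
    rset = rows
    cset = rows if sym else rows2

    def transform(block, keep_local, cols_local):
        mu = means[cols_local][keep_local]
        sd = sds[cols_local][keep_local]
        B = block[:, keep_local]
        nan = np.isnan(B)
        if nan.any():
            if not opts.impute_missing_to_mean:
                raise ValueError("missing genotypes present; enable impute_missing_to_mean")
            B = np.where(nan, mu[None, :], B)
        if opts.center:
            B = B - mu[None, :]
        if opts.scale:
            B = B / sd[None, :]
        return B

    # Accumulate one column's outer product at a time, in global column
    # order: chunking then only batches I/O, so the float operation sequence
    # — and hence every output byte — is invariant to chunk_size and worker
    # count.  (The memory bound per chunk is unchanged.)
    G = np.zeros((rset.size, cset.size), dtype=np.float64)
    for start, stop in chunk_ranges(cols.size, chunk_size):
        cols_local = np.arange(start, stop, dtype=np.intp)
        keep_local = retained[start:stop]
        if not keep_local.any():
            continue
        Xj = transform(node_read(geno, rset, cols[start:stop], dtype=np.float64),
                       keep_local, cols_local)
        Yj = Xj if sym else transform(
            node_read(geno, cset, cols[start:stop], dtype=np.float64),
            keep_local, cols_local)
        for j in range(Xj.shape[1]):
            G += Xj[:, j, None] * Yj[None, :, j]
    G /= k
    return G


# ---------------------------------------------------------------------------
# relatedness pruning

def _related_pairs(G, cutoff: float) -> list[tuple[int, int]]:
    """All off-diagonal pairs (i < j) with G[i, j] >= cutoff, scanning a
    dense array directly or a matrix-like object in row strips."""
    if isinstance(G, np.ndarray):
        n = G.shape[0]
        iu = np.triu_indices(n, k=1)
        hits = np.flatnonzero(G[iu] >= cutoff)
        return list(zip(iu[0][hits].tolist(), iu[1][hits].tolist()))
    n, m = node_shape(G)
    pairs = []
    strip = max(1, 10_000_000 // max(n, 1))
    for start in range(0, n, strip):
        stop = min(start + strip, n)
        block = node_read(G, np.arange(start, stop), None, dtype=np.float64)
        for local, i in enumerate(range(start, stop)):
            row = block[local]
            js = np.flatnonzero(row[i + 1:] >= cutoff) + i + 1
            pairs.extend((i, int(j)) for j in js)
    return pairs


def find_related(G, cutoff: float = 0.03) -> np.ndarray:
    """Samples to drop so that every retained pair has relationship below
    ``cutoff``.

    Builds the graph of off-diagonal pairs with ``G >= cutoff`` and greedily
    removes the highest-degree vertex (ties broken by lowest index) until no
    edge remains.  Deterministic; returns the sorted 0-based indices of the
    removed samples.  Accepts a dense symmetric array or any symmetric
    matrix-like object (e.g. a SymBlockMatrix).
    """
    n, m = node_shape(G)
    if n != m:
        raise ValueError(f"relationship matrix must be square, got {n} x {m}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adjacency: dict[int, set[int]] = {}
    for i, j in _related_pairs(G, cutoff):
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    removed = []
    while adjacency:
        worst = min(adjacency, key=lambda v: (-len(adjacency[v]), v))
        for other in adjacency[worst]:
            adjacency[other].discard(worst)
            if not adjacency[other]:
                del adjacency[other]
        del adjacency[worst]
        removed.append(worst)
    return np.array(sorted(removed), dtype=np.intp)
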