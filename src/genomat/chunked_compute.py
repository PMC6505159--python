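"""Split-apply-combine engine for matrix-like objects.

Operations on genotype matrices that decompose along rows or columns —
per-variant summaries, single-marker regressions, cross-products — are run
here by loading one chunk at a time, applying an in-memory function, and
aggregating the per-chunk results.  The amount of data resident at once is
bounded by ``chunk_size`` times the non-chunked extent, so arbitrarily
large file-backed matrices can be processed in constant memory.

Determinism contract: chunks are always combined in ascending chunk
ordinal, and parallel workers return results in task order, so every
result is invariant to ``chunk_size`` and ``n_tasks`` (bit-identical for
integer reductions; identical summation order, hence reproducible floats,
for floating-point accumulation).
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed

from .linked_arrays import node_read, node_shape

__all__ = ["DEFAULT_CHUNK_SIZE", "chunk_ranges", "chunked_apply",
           "crossprod_chunked", "parallel_map", "ChunkError"]

#: Default number of columns (or rows) loaded per chunk.
DEFAULT_CHUNK_SIZE = 5000


class ChunkError(RuntimeError):
    """A user function raised while processing a chunk; carries coordinates."""


def chunk_ranges(total: int, chunk_size: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) ranges covering ``total`` positions."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    return [(s, min(s + chunk_size, total)) for s in range(0, total, chunk_size)]


def parallel_map(fn, tasks, n_workers: int = 1) -> list:
    """Apply ``fn`` to each task, preserving task order in the results.

    ``n_workers == 1`` runs inline; otherwise tasks are distributed over
    process-based workers (no shared mutable state).  Result values are
    independent of ``n_workers``.  A worker failure is re-raised with the
    task ordinal in the message.
    """
    tasks = list(tasks)
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if not tasks:
        return []

    def run(ordinal, task):
        try:
            return fn(task)
        except ChunkError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise ChunkError(f"task {ordinal} failed: {exc}") from exc

    if n_workers == 1 or len(tasks) == 1:
        return [run(i, t) for i, t in enumerate(tasks)]
    return Parallel(n_jobs=n_workers, backend="loky")(
        delayed(run)(i, t) for i, t in enumerate(tasks)
    )


def _resolve_subsets(X, rows, cols):
    n, p = node_shape(X)
    rows = np.arange(n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
    cols = np.arange(p, dtype=np.intp) if cols is None else np.asarray(cols, dtype=np.intp)
    if rows.size and (rows.min() < 0 or rows.max() >= n):
        raise IndexError("row subset out of bounds")
    if cols.size and (cols.min() < 0 or cols.max() >= p):
        raise IndexError("column subset out of bounds")
    return rows, cols


def chunked_apply(
    X,
    fn,
    margin: int = 2,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    n_tasks: int = 1,
    rows=None,
    cols=None,
    vectorized: bool = False,
    dtype=np.float64,
) -> np.ndarray:
    """Apply ``fn`` along rows (margin=1) or columns (margin=2) of
    ``X[rows, cols]``, loading ``chunk_size`` rows/columns at a time.

    By default ``fn`` receives one 1-D vector (one row or column, float with
    NaN for missing) and must return a scalar or a fixed-shape array; with
    ``vectorized=True`` it receives the whole 2-D chunk and must return an
    array whose leading axis matches the chunk extent (one result per row
    or column of the chunk).  The combined result stacks per-element results
    along axis 0, in index-set order, identical to applying ``fn`` on the
    materialized subset regardless of ``chunk_size`` or ``n_tasks``.
    """
    if margin not in (1, 2):
        raise ValueError("margin must be 1 (rows) or 2 (columns)")
    rows, cols = _resolve_subsets(X, rows, cols)
    extent = rows.size if margin == 1 else cols.size
    ranges = chunk_ranges(extent, chunk_size)

    def process(rng):
        start, stop = rng
        if margin == 1:
            chunk = node_read(X, rows[start:stop], cols, dtype=dtype)
        else:
            chunk = node_read(X, rows, cols[start:stop], dtype=dtype)
        try:
            if vectorized:
                res = np.asarray(fn(chunk))
                if res.shape[0] != stop - start:
                    raise ValueError(
                        f"vectorized fn returned leading extent {res.shape[0]}, "
                        f"expected {stop - start}"
                    )
                return res
            axis = 0 if margin == 1 else 1
            vecs = np.moveaxis(chunk, axis, 0)
            return np.array([np.asarray(fn(v)) for v in vecs])
        except Exception as exc:  # noqa: BLE001
            which = "rows" if margin == 1 else "columns"
            raise ChunkError(
                f"fn failed on chunk {which}[{start}:{stop}] of the subset: {exc}"
            ) from exc

    parts = parallel_map(process, ranges, n_workers=n_tasks)
    if not parts:
        return np.empty((0,), dtype=dtype)
    return np.concatenate(parts, axis=0)


def crossprod_chunked(
    X,
    Y=None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    n_tasks: int = 1,
    impute_missing: bool = False,
) -> np.ndarray:
    """Compute ``X @ Y.T`` as a sum of per-column-chunk products.

    X (n_x x p) and Y (n_y x p) must share their column count; Y defaults
    to X.  Neither matrix is materialized in full: for each chunk j of
    columns the partial product ``X_j @ Y_j.T`` is accumulated, in ascending
    chunk order so floating-point results are reproducible.  Missing values
    (NaN) raise unless ``impute_missing`` is set, in which case each column's
    missing entries are replaced by that column's observed mean (computed
    per matrix over all its rows).
    """
    if Y is None:
        Y = X
    nx, px = node_shape(X)
    ny, py = node_shape(Y)
    if px != py:
        raise ValueError(f"column-count mismatch: X has {px}, Y has {py}")

    same = Y is X

    def load(M, cols):
        block = node_read(M, None, cols, dtype=np.float64)
        nan = np.isnan(block)
        if nan.any():
            if not impute_missing:
                raise ValueError(
                    "missing values encountered; pass impute_missing=True to "
                    "replace them with column means"
                )
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(block, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            block = np.where(nan, mu[None, :], block)
        return block

    def process(rng):
        start, stop = rng
        cols = np.arange(start, stop, dtype=np.intp)
        Xj = load(X, cols)
        Yj = Xj if same else load(Y, cols)
        return Xj @ Yj.T

    parts = parallel_map(process, chunk_ranges(px, chunk_size), n_workers=n_tasks)
    out = np.zeros((nx, ny), dtype=np.float64)
    for part in parts:  # fixed ascending accumulation order
        out += part
    return out
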