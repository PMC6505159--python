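"""Partitioned symmetric matrices with file-backed upper-triangular blocks.

A genomic relationship matrix over hundreds of thousands of samples cannot
be held in memory, but it factors naturally over a partition of the
samples into B consecutive sets: only the B(B+1)/2 upper-triangular blocks
need to be stored, and any lower-triangle request is served by transposing
the mirrored stored block on the fly.  :class:`SymBlockMatrix` implements
this layout; :func:`build_sym_grm` fills it block by block, with the
per-column centering/scaling statistics computed once over all selected
rows so the blocks are mutually consistent and the assembled matrix equals
the dense GRM.

On-disk layout of a block store directory::

    index.json        partition boundaries, sample IDs, options fingerprint,
                      frozen column statistics
    blocks/a_b.bin    row-major little-endian float64 payload with an
                      8-byte header (two little-endian uint32: rows, cols)

Blocks are computed and written in lexicographic (a, b) order; each block
is an independent task, so a build can be distributed and still produce
identical bytes.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .bed_io import _apply_squeeze, _parse_2d_key
from .chunked_compute import DEFAULT_CHUNK_SIZE, parallel_map
from .geno_stats import GrmOptions, get_g, grm_column_stats
from .linked_arrays import node_shape

__all__ = ["SymBlockMatrix", "make_partition", "n_stored_blocks",
           "build_sym_grm", "sym_extract", "write_block", "read_block"]


def make_partition(n: int, block_size: int) -> list[np.ndarray]:
    """Partition 0..n-1 into consecutive sets of ``block_size``, the final
    set holding the remainder.  Sets are disjoint, covering, and there are
    ``ceil(n / block_size)`` of them."""
    if n < 1 or block_size < 1:
        raise ValueError("n and block_size must be >= 1")
    return [np.arange(s, min(s + block_size, n), dtype=np.intp)
            for s in range(0, n, block_size)]


def n_stored_blocks(B: int) -> int:
    """Number of stored blocks for a B-set partition: B(B+1)/2 (upper
    triangle including the diagonal)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    return B * (B + 1) // 2


def write_block(path: str | os.PathLike, block: np.ndarray) -> None:
    """Write one block: 8-byte header (rows, cols as little-endian uint32)
    followed by the row-major little-endian float64 payload."""
    block = np.ascontiguousarray(block, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(np.array(block.shape, dtype="<u4").tobytes())
        fh.write(block.tobytes())


def read_block(path: str | os.PathLike) -> np.ndarray:
    with open(path, "rb") as fh:
        shape = np.frombuffer(fh.read(8), dtype="<u4")
        payload = np.frombuffer(fh.read(), dtype="<f8")
    return payload.reshape(int(shape[0]), int(shape[1]))


class SymBlockMatrix:
    """Symmetric matrix stored as upper-triangular blocks over a partition.

    ``blocks`` maps ordered pairs (a, b) with a <= b either to in-memory
    arrays or, for a file-backed store, to paths.  Element (i, j) with i in
    set a and j in set b is served from block (min(a,b), max(a,b)),
    transposed when the request addresses the lower triangle, so the object
    behaves as a full symmetric matrix while storing only B(B+1)/2 blocks.
    """

    def __init__(self, partition, blocks, sample_ids=None, store_dir=None):
        self.partition = [np.asarray(s, dtype=np.intp) for s in partition]
        sizes = [s.size for s in self.partition]
        self._starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        self.n = int(sum(sizes))
        covered = np.concatenate(self.partition) if self.partition else np.array([])
        if not np.array_equal(covered, np.arange(self.n)):
            raise ValueError("partition sets must be disjoint, consecutive and covering")
        B = len(self.partition)
        expect = {(a, b) for a in range(B) for b in range(a, B)}
        if set(blocks) != expect:
            raise ValueError(f"expected the {n_stored_blocks(B)} upper-triangular "
                             f"blocks of a {B}-set partition")
        self.blocks = dict(blocks)
        self.sample_ids = list(sample_ids) if sample_ids is not None else None
        self.store_dir = Path(store_dir) if store_dir is not None else None

    # -- store round trip -------------------------------------------------
    @classmethod
    def from_store(cls, store_dir: str | os.PathLike) -> "SymBlockMatrix":
        """Reattach a block store written by :func:`build_sym_grm`."""
        store_dir = Path(store_dir)
        index = json.loads((store_dir / "index.json").read_text())
        sizes = index["partition_sizes"]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        partition = [np.arange(starts[i], starts[i + 1], dtype=np.intp)
                     for i in range(len(sizes))]
        blocks = {}
        for a in range(len(sizes)):
            for b in range(a, len(sizes)):
                blocks[(a, b)] = store_dir / "blocks" / f"{a}_{b}.bin"
        return cls(partition, blocks, sample_ids=index.get("sample_ids"),
                   store_dir=store_dir)

    def _block(self, a: int, b: int) -> np.ndarray:
        blk = self.blocks[(a, b)]
        if isinstance(blk, (str, os.PathLike)):
            return read_block(blk)
        return np.asarray(blk)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def ndim(self) -> int:
        return 2

    @property
    def row_names(self):
        return self.sample_ids

    col_names = row_names

    def _owner(self, idx: np.ndarray) -> np.ndarray:
        ends = np.cumsum([s.size for s in self.partition])
        return np.searchsorted(ends, idx, side="right")

    def read(self, rows=None, cols=None, dtype=np.float64) -> np.ndarray:
        """Extract ``rows x cols`` as a dense array, routing each (set_a,
        set_b) cell group to the stored block and virtually transposing
        lower-triangle requests."""
        rows = np.arange(self.n) if rows is None else np.asarray(rows, dtype=np.intp)
        cols = np.arange(self.n) if cols is None else np.asarray(cols, dtype=np.intp)
        for idx in (rows, cols):
            if idx.size and (idx.min() < 0 or idx.max() >= self.n):
                raise IndexError(f"index out of bounds for {self.n} samples")
        out = np.empty((rows.size, cols.size), dtype=dtype)
        row_owner = self._owner(rows)
        col_owner = self._owner(cols)
        for a in np.unique(row_owner):
            rsel = np.flatnonzero(row_owner == a)
            rloc = rows[rsel] - self._starts[a]
            for b in np.unique(col_owner):
                csel = np.flatnonzero(col_owner == b)
                cloc = cols[csel] - self._starts[b]
                if a <= b:
                    block = self._block(int(a), int(b))
                    out[np.ix_(rsel, csel)] = block[np.ix_(rloc, cloc)]
                else:
                    block = self._block(int(b), int(a))
                    out[np.ix_(rsel, csel)] = block[np.ix_(cloc, rloc)].T
        return out

    def __getitem__(self, key):
        rows, cols, squeeze = _parse_2d_key(key, self.shape)
        return _apply_squeeze(self.read(rows, cols), squeeze)

    def __repr__(self) -> str:
        return (f"SymBlockMatrix({self.n} x {self.n}, {len(self.partition)} sets, "
                f"{len(self.blocks)} stored blocks)")


def sym_extract(S: SymBlockMatrix, rows=None, cols=None) -> np.ndarray:
    """Dense extraction from a partitioned symmetric matrix (equals
    extraction from the assembled dense matrix)."""
    return S.read(rows, cols)


def build_sym_grm(
    geno,
    store_dir: str | os.PathLike,
    block_size: int,
    options: GrmOptions | None = None,
    rows=None,
    cols=None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    n_tasks: int = 1,
) -> SymBlockMatrix:
    """Build a genomic relationship matrix as a file-backed partitioned
    symmetric store.

    The selected samples are partitioned into consecutive sets of
    ``block_size``; for every pair a <= b the block
    ``get_g(rows=set_a, rows2=set_b)`` is computed and persisted as
    ``blocks/a_b.bin``.  Column means/SDs are computed in a first pass over
    all selected rows and frozen into the index, so every block uses
    identical statistics and the assembled matrix equals the dense GRM over
    all rows.  Blocks are independent tasks, computed in lexicographic
    (a, b) order; rebuilding with a different ``n_tasks`` yields identical
    bytes.
    """
    opts = options or GrmOptions()
    n, p = node_shape(geno)
    rows = np.arange(n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
    cols = np.arange(p, dtype=np.intp) if cols is None else np.asarray(cols, dtype=np.intp)
    store_dir = Path(store_dir)
    (store_dir / "blocks").mkdir(parents=True, exist_ok=True)

    means, sds = grm_column_stats(geno, rows, cols, chunk_size=chunk_size, n_tasks=n_tasks)
    sets = make_partition(rows.size, block_size)
    B = len(sets)
    pairs = [(a, b) for a in range(B) for b in range(a, B)]

    def compute(pair):
        a, b = pair
        block = get_g(
            geno, opts,
            rows=rows[sets[a]],
            rows2=rows[sets[b]],
            cols=cols,
            chunk_size=chunk_size,
            col_stats=(means, sds),
        )
        return pair, block

    results = parallel_map(compute, pairs, n_workers=n_tasks)
    blocks = {}
    for (a, b), block in results:
        path = store_dir / "blocks" / f"{a}_{b}.bin"
        write_block(path, block)
        blocks[(a, b)] = path

    ids = getattr(geno, "sample_ids", None) or getattr(geno, "row_names", None)
    sample_ids = [ids[i] for i in rows] if ids is not None else [str(i) for i in rows]
    index = {
        "partition_sizes": [int(s.size) for s in sets],
        "n_samples": int(rows.size),
        "n_variants_selected": int(cols.size),
        "sample_ids": sample_ids,
        "options": opts.fingerprint(),
        "col_means": [float(v) for v in means],
        "col_sds": [float(v) for v in sds],
    }
    (store_dir / "index.json").write_text(json.dumps(index) + "\n")
    return SymBlockMatrix(sets, blocks, sample_ids=sample_ids, store_dir=store_dir)
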