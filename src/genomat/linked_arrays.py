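"""Virtual linked arrays: compose matrix-like objects by rows or columns.

Large genotype collections are commonly stored as one PLINK fileset per
chromosome or per cohort.  A :class:`LinkedMatrix` presents an ordered list
of matrix-like nodes — :class:`~genomat.bed_io.BedMatrix` views, plain numpy
arrays, symmetric block matrices, or other linked matrices — as one virtual
matrix concatenated along a chosen axis, without copying any node's
contents.  Index requests are routed to nodes, split at node boundaries and
re-assembled in the requested order, so a linked matrix behaves like the
materialized concatenation while each node keeps its own storage and
laziness.

A small JSON manifest format (`axis` + ordered fileset roots) lets a linked
genotype matrix over many .bed filesets be declared in config and reopened
reproducibly; see :func:`save_manifest` / :func:`open_manifest`.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .bed_io import MISSING, BedMatrix, _apply_squeeze, _parse_2d_key, open_bed

__all__ = ["LinkedMatrix", "MatrixView", "link", "save_manifest", "open_manifest",
           "node_shape", "node_read"]


def node_shape(node) -> tuple[int, int]:
    """Shape of any supported matrix-like node."""
    s = node.shape
    if len(s) != 2:
        raise ValueError(f"node of type {type(node).__name__} is not 2-D")
    return (int(s[0]), int(s[1]))


def node_read(node, rows=None, cols=None, dtype=np.float64) -> np.ndarray:
    """Extract ``rows x cols`` from any matrix-like node as a dense array.

    Dispatches on capability: objects exposing ``read(rows, cols, dtype)``
    (BedMatrix, LinkedMatrix, SymBlockMatrix, MatrixView) are asked to
    decode lazily; numpy arrays and DataFrames are fancy-indexed.  For float
    dtypes, integer MISSING sentinels become NaN.
    """
    if hasattr(node, "read"):
        return node.read(rows, cols, dtype=dtype)
    if isinstance(node, pd.DataFrame):
        node = node.to_numpy()
    arr = np.asarray(node)
    n, p = arr.shape
    rows = np.arange(n) if rows is None else np.asarray(rows, dtype=np.intp)
    cols = np.arange(p) if cols is None else np.asarray(cols, dtype=np.intp)
    if rows.size and (rows.min() < 0 or rows.max() >= n):
        raise IndexError("row index out of bounds")
    if cols.size and (cols.min() < 0 or cols.max() >= p):
        raise IndexError("column index out of bounds")
    out = arr[np.ix_(rows, cols)]
    if np.issubdtype(np.dtype(dtype), np.floating) and np.issubdtype(out.dtype, np.integer):
        fout = out.astype(dtype)
        fout[out == MISSING] = np.nan
        return fout
    return out.astype(dtype, copy=False)


def _node_names(node, axis: int):
    """Dimension names of a node along axis 0 (rows/samples) or 1 (cols/variants)."""
    if isinstance(node, BedMatrix):
        return node.sample_ids if axis == 0 else node.variant_ids
    for attr in (("row_names", "col_names"), ("sample_ids", "variant_ids")):
        name = getattr(node, attr[axis], None)
        if name is not None:
            return list(name)
    return None


class LinkedMatrix:
    """Ordered matrix-like nodes virtually concatenated by rows or columns.

    Parameters
    ----------
    nodes : sequence of matrix-like
        At least one node; all nodes must agree in extent on the non-linked
        axis.  Nodes may be heterogeneous (a BedMatrix next to an ndarray)
        and may themselves be LinkedMatrix instances (nesting closure).
    axis : {"rows", "columns"}
        The axis along which nodes are concatenated.

    Construction copies no node data and performs no payload reads.
    """

    def __init__(self, nodes, axis: str = "columns"):
        nodes = list(nodes)
        if not nodes:
            raise ValueError("LinkedMatrix requires at least one node")
        if axis not in ("rows", "columns"):
            raise ValueError("axis must be 'rows' or 'columns'")
        self.axis = axis
        self._linked_axis = 0 if axis == "rows" else 1
        other = 1 - self._linked_axis
        shapes = [node_shape(nd) for nd in nodes]
        base = shapes[0][other]
        for ordinal, shp in enumerate(shapes):
            if shp[other] != base:
                raise ValueError(
                    f"node {ordinal} has {shp[other]} "
                    f"{'columns' if other else 'rows'}, expected {base} "
                    f"(all nodes of a {axis}-linked matrix must agree on the other axis)"
                )
        self.nodes = nodes
        extents = np.array([shp[self._linked_axis] for shp in shapes], dtype=np.intp)
        #: cumulative end offsets along the linked axis, strictly increasing
        self.boundaries = np.cumsum(extents)
        self._starts = self.boundaries - extents
        self._other_extent = base

    @property
    def shape(self) -> tuple[int, int]:
        total = int(self.boundaries[-1])
        if self._linked_axis == 0:
            return (total, self._other_extent)
        return (self._other_extent, total)

    @property
    def ndim(self) -> int:
        return 2

    @property
    def row_names(self):
        return self._names(0)

    @property
    def col_names(self):
        return self._names(1)

    def _names(self, axis: int):
        if axis == self._linked_axis:
            parts = [_node_names(nd, axis) for nd in self.nodes]
            if any(p is None for p in parts):
                return None
            return [name for part in parts for name in part]
        return _node_names(self.nodes[0], axis)

    def index_of(self, name: str, axis: int = 1) -> int:
        """Position of ``name`` along ``axis``; first match wins, with a
        warning when the name is duplicated across nodes."""
        names = self._names(axis)
        if names is None:
            raise KeyError("nodes do not expose dimension names on this axis")
        hits = [i for i, nm in enumerate(names) if nm == name]
        if not hits:
            raise KeyError(name)
        if len(hits) > 1:
            warnings.warn(f"name {name!r} is duplicated; resolving to the first match",
                          stacklevel=2)
        return hits[0]

    def locate(self, global_index: int) -> tuple[int, int]:
        """Route a 0-based position along the linked axis to (node ordinal,
        0-based local index)."""
        total = int(self.boundaries[-1])
        if not 0 <= global_index < total:
            raise IndexError(f"index {global_index} out of bounds for extent {total}")
        node = int(np.searchsorted(self.boundaries, global_index, side="right"))
        return node, int(global_index - self._starts[node])

    def read(self, rows=None, cols=None, dtype=np.float64) -> np.ndarray:
        """Extract ``rows x cols`` as a dense array, equal to extraction from
        the materialized concatenation of the nodes."""
        n, p = self.shape
        rows = np.arange(n) if rows is None else np.asarray(rows, dtype=np.intp)
        cols = np.arange(p) if cols is None else np.asarray(cols, dtype=np.intp)
        if rows.size and (rows.min() < 0 or rows.max() >= n):
            raise IndexError("row index out of bounds")
        if cols.size and (cols.min() < 0 or cols.max() >= p):
            raise IndexError("column index out of bounds")
        linked = rows if self._linked_axis == 0 else cols
        out = np.empty((rows.size, cols.size), dtype=dtype)
        if rows.size == 0 or cols.size == 0:
            return out
        # route each linked-axis position to its node, gather per node in
        # contiguous runs of the *request*, then scatter back in request order
        owner = np.searchsorted(self.boundaries, linked, side="right")
        for nd in np.unique(owner):
            sel = np.flatnonzero(owner == nd)
            local = linked[sel] - self._starts[nd]
            if self._linked_axis == 0:
                block = node_read(self.nodes[nd], local, cols, dtype=dtype)
                out[sel, :] = block
            else:
                block = node_read(self.nodes[nd], rows, local, dtype=dtype)
                out[:, sel] = block
        return out

    def __getitem__(self, key):
        rows, cols, squeeze = _parse_2d_key(key, self.shape)
        return _apply_squeeze(self.read(rows, cols), squeeze)

    def __repr__(self) -> str:
        return (f"LinkedMatrix(axis={self.axis!r}, {len(self.nodes)} nodes, "
                f"shape={self.shape})")


def link(nodes, axis: str = "columns") -> LinkedMatrix:
    """Link matrix-like nodes into one virtual matrix along ``axis``."""
    return LinkedMatrix(nodes, axis=axis)


class MatrixView:
    """Lazy row/column subset of a matrix-like object.

    Holds the base object plus index arrays; no genotype data is copied
    until :meth:`read` is called.  Used by
    :func:`genomat.bgdata_container.subset_bgdata`.
    """

    def __init__(self, base, rows=None, cols=None):
        n, p = node_shape(base)
        self.base = base
        self.rows = np.arange(n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
        self.cols = np.arange(p, dtype=np.intp) if cols is None else np.asarray(cols, dtype=np.intp)
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() >= n):
            raise IndexError("row index out of bounds")
        if self.cols.size and (self.cols.min() < 0 or self.cols.max() >= p):
            raise IndexError("column index out of bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows.size, self.cols.size)

    @property
    def ndim(self) -> int:
        return 2

    def read(self, rows=None, cols=None, dtype=np.float64) -> np.ndarray:
        rows = np.arange(self.rows.size) if rows is None else np.asarray(rows, dtype=np.intp)
        cols = np.arange(self.cols.size) if cols is None else np.asarray(cols, dtype=np.intp)
        return node_read(self.base, self.rows[rows], self.cols[cols], dtype=dtype)

    def __getitem__(self, key):
        rows, cols, squeeze = _parse_2d_key(key, self.shape)
        return _apply_squeeze(self.read(rows, cols), squeeze)


def save_manifest(roots, path: str | os.PathLike, axis: str = "columns") -> Path:
    """Write a JSON manifest declaring an ordered list of PLINK fileset roots
    to be linked along ``axis``.  Roots are stored relative to the manifest
    when possible, so the directory relocates cleanly."""
    path = Path(path)
    rels = []
    for root in roots:
        root = Path(root)
        try:
            rels.append(os.path.relpath(root, path.parent))
        except ValueError:
            rels.append(str(root))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"axis": axis, "filesets": rels}, indent=2) + "\n")
    return path


def open_manifest(path: str | os.PathLike) -> LinkedMatrix:
    """Open the filesets listed in a manifest as a LinkedMatrix of BedMatrix
    nodes, in the declared order."""
    path = Path(path)
    spec = json.loads(path.read_text())
    axis = spec.get("axis", "columns")
    roots = [path.parent / r if not os.path.isabs(r) else Path(r) for r in spec["filesets"]]
    if not roots:
        raise ValueError(f"{path}: manifest lists no filesets")
    return LinkedMatrix([open_bed(r) for r in roots], axis=axis)
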