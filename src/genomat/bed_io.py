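"""Reading and writing PLINK 1 binary genotype filesets (.bed/.bim/.fam).

A PLINK 1 fileset stores genotypes in a packed 2-bit binary payload (.bed)
with no metadata of its own; sample and variant information live in the
plain-text .fam and .bim siblings, which must share the .bed file's root
name and directory.  :class:`BedMatrix` is a read-only, lazily evaluated
matrix view over such a fileset: opening it parses only the header and the
two text siblings, and element access decodes just the bytes of the
requested variants.  Genotype values count copies of the A1 allele of the
.bim row (0, 1, 2), matching PLINK's additive recoding; missing calls are
returned as :data:`MISSING` in integer reads and as NaN in float reads.

The payload layout (variant-major mode): after a 3-byte header
``0x6C 0x1B 0x01``, each variant occupies ``ceil(n_samples / 4)`` bytes.
Within a byte, sample ``k`` (k = 0..3) is encoded in bit pair
``(2k, 2k+1)``, low-order pair first: ``00`` = 2 copies of A1, ``10`` =
heterozygous, ``11`` = 0 copies, ``01`` = missing.  Trailing bits of the
final byte per variant are padding and ignored.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "BedMatrix",
    "BedFormatError",
    "open_bed",
    "write_bed",
    "decode_genotype_byte",
    "read_fam",
    "read_bim",
]

#: Sentinel for a missing genotype in integer reads.  Float reads map it to NaN.
MISSING = np.int8(-1)

_MAGIC = bytes([0x6C, 0x1B])
_MODE_VARIANT_MAJOR = 0x01

_FAM_COLUMNS = ["family_id", "within_family_id", "father_id", "mother_id", "sex", "phenotype"]
_BIM_COLUMNS = ["chrom", "variant_id", "cm", "pos", "a1", "a2"]

# bit pair -> genotype code (copies of A1)
_PAIR_TO_CODE = {0b00: 2, 0b01: int(MISSING), 0b10: 1, 0b11: 0}
# genotype code -> bit pair
_CODE_TO_PAIR = {2: 0b00, int(MISSING): 0b01, 1: 0b10, 0: 0b11}


class BedFormatError(ValueError):
    """Raised when a .bed fileset violates the PLINK 1 binary format."""


def _build_decode_table() -> np.ndarray:
    """256 x 4 lookup table: byte value -> genotype codes of its 4 samples."""
    table = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for k in range(4):
            table[byte, k] = _PAIR_TO_CODE[(byte >> (2 * k)) & 0b11]
    return table


_DECODE_TABLE = _build_decode_table()


def decode_genotype_byte(byte: int) -> np.ndarray:
    """Decode one .bed payload byte into the genotype codes of 4 samples.

    Sample ``k`` occupies bit pair ``(2k, 2k+1)``, low-order pair first.
    Total on 0..255; returns an int8 array of length 4 with values in
    {0, 1, 2, MISSING}.
    """
    return _DECODE_TABLE[byte & 0xFF].copy()


def read_fam(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a .fam sample table (6 whitespace-delimited columns, no header)."""
    fam = pd.read_csv(path, sep=r"\s+", header=None, names=_FAM_COLUMNS, dtype=str)
    if fam.shape[1] != 6:
        raise BedFormatError(f"{path}: expected 6 columns in .fam, got {fam.shape[1]}")
    return fam


def read_bim(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a .bim variant table.  Chromosome labels stay strings ('X', 'MT')."""
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=_BIM_COLUMNS,
        dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
    )
    bim["pos"] = bim["pos"].astype(np.int64)
    return bim


def _make_sample_ids(fam: pd.DataFrame) -> list[str]:
    """Sample IDs: ``family_id_within_family_id`` when the family ID carries
    information, else the within-family ID alone; collisions get a row-ordinal
    suffix so IDs are always unique."""
    ids = []
    for fid, iid in zip(fam["family_id"], fam["within_family_id"]):
        if fid not in ("0", "") and fid != iid:
            ids.append(f"{fid}_{iid}")
        else:
            ids.append(str(iid))
    seen: dict[str, int] = {}
    unique = []
    for ordinal, sid in enumerate(ids):
        if sid in seen:
            unique.append(f"{sid}_{ordinal}")
        else:
            seen[sid] = ordinal
            unique.append(sid)
    return unique


class BedMatrix:
    """Read-only matrix view of a PLINK 1 .bed fileset.

    Rows are samples (order of the .fam file), columns are variants (order
    of the .bim file).  Creation parses headers and text siblings only; the
    genotype payload is touched lazily, variant by variant, on read.  The
    view never mutates the underlying file.

    Attributes
    ----------
    path : Path
        The .bed file.
    fam, bim : pandas.DataFrame
        Parsed sample and variant tables.
    sample_ids, variant_ids : list of str
    bytes_read : int
        Cumulative payload bytes decoded, for locality instrumentation.
    """

    def __init__(self, path: str | os.PathLike):
        path = Path(path)
        if path.suffix != ".bed":
            path = path.with_suffix(".bed")
        if not path.is_file():
            raise FileNotFoundError(f"no such .bed file: {path}")
        root = path.with_suffix("")
        fam_path = root.with_suffix(".fam")
        bim_path = root.with_suffix(".bim")
        for sibling in (fam_path, bim_path):
            if not sibling.is_file():
                raise BedFormatError(
                    f"{path}: missing sibling file {sibling.name}; .fam and .bim must "
                    "be in the same directory and share the .bed root name"
                )
        with open(path, "rb") as fh:
            header = fh.read(3)
        if len(header) < 3 or header[:2] != _MAGIC:
            raise BedFormatError(f"{path}: bad magic bytes {header[:2].hex()}, expected 6c1b")
        if header[2] != _MODE_VARIANT_MAJOR:
            raise BedFormatError(
                f"{path}: mode byte {header[2]:#04x}; only variant-major (0x01) files "
                "are supported"
            )
        self.path = path
        self.fam = read_fam(fam_path)
        self.bim = read_bim(bim_path)
        self.n_samples = len(self.fam)
        self.n_variants = len(self.bim)
        self.bytes_per_variant = (self.n_samples + 3) // 4
        self.data_offset = 3
        expected = 3 + self.bytes_per_variant * self.n_variants
        actual = path.stat().st_size
        if actual != expected:
            raise BedFormatError(
                f"{path}: file size {actual} != 3 + ceil({self.n_samples}/4) x "
                f"{self.n_variants} = {expected} (truncated or inconsistent fileset)"
            )
        self.sample_ids = _make_sample_ids(self.fam)
        self.variant_ids = list(self.bim["variant_id"])
        self.bytes_read = 0
        self._fh = None

    # -- lazy file handle; dropped on pickling so views cross process borders
    def _handle(self):
        if self._fh is None:
            self._fh = open(self.path, "rb")
        return self._fh

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_fh"] = None
        return state

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_variants)

    @property
    def ndim(self) -> int:
        return 2

    def __len__(self) -> int:
        return self.n_samples * self.n_variants

    def __repr__(self) -> str:
        return f"BedMatrix({self.path.name!r}, {self.n_samples} samples x {self.n_variants} variants)"

    def _read_variant_bytes(self, j: int) -> bytes:
        fh = self._handle()
        fh.seek(self.data_offset + j * self.bytes_per_variant)
        raw = fh.read(self.bytes_per_variant)
        self.bytes_read += len(raw)
        return raw

    def _decode_column(self, j: int) -> np.ndarray:
        raw = np.frombuffer(self._read_variant_bytes(j), dtype=np.uint8)
        return _DECODE_TABLE[raw].reshape(-1)[: self.n_samples]

    def read(self, rows=None, cols=None, dtype=np.int8) -> np.ndarray:
        """Extract ``rows x cols`` genotypes as an in-memory array.

        Index sets are 0-based, ordered, and may repeat; ``None`` means all.
        Only the payload bytes of the requested variants are read.  Integer
        dtypes keep :data:`MISSING`; float dtypes map it to NaN.
        """
        rows = np.arange(self.n_samples) if rows is None else np.asarray(rows, dtype=np.intp)
        cols = np.arange(self.n_variants) if cols is None else np.asarray(cols, dtype=np.intp)
        if rows.size and (rows.min() < 0 or rows.max() >= self.n_samples):
            raise IndexError(f"row index out of bounds for {self.n_samples} samples")
        if cols.size and (cols.min() < 0 or cols.max() >= self.n_variants):
            raise IndexError(f"column index out of bounds for {self.n_variants} variants")
        out = np.empty((rows.size, cols.size), dtype=np.int8)
        # decode each distinct variant once, then fan out to duplicates
        decoded: dict[int, np.ndarray] = {}
        for out_j, j in enumerate(cols):
            j = int(j)
            if j not in decoded:
                decoded[j] = self._decode_column(j)
            out[:, out_j] = decoded[j][rows]
        if np.issubdtype(np.dtype(dtype), np.floating):
            fout = out.astype(dtype)
            fout[out == MISSING] = np.nan
            return fout
        return out.astype(dtype, copy=False)

    def __getitem__(self, key) -> np.ndarray:
        rows, cols, squeeze = _parse_2d_key(key, self.shape)
        out = self.read(rows, cols)
        return _apply_squeeze(out, squeeze)


def _parse_2d_key(key, shape):
    """Normalize a numpy-style 2-D index into (row array, col array, squeeze axes)."""
    if not isinstance(key, tuple):
        key = (key, slice(None))
    if len(key) != 2:
        raise IndexError("expected at most 2 indices")
    idx, squeeze = [], []
    for axis, (k, n) in enumerate(zip(key, shape)):
        if isinstance(k, (int, np.integer)):
            k = int(k)
            if k < 0:
                k += n
            if not 0 <= k < n:
                raise IndexError(f"index {k} out of bounds for axis {axis} with size {n}")
            idx.append(np.array([k], dtype=np.intp))
            squeeze.append(axis)
        elif isinstance(k, slice):
            idx.append(np.arange(n, dtype=np.intp)[k])
        else:
            arr = np.asarray(k)
            if arr.dtype == bool:
                if arr.size != n:
                    raise IndexError("boolean mask length mismatch")
                arr = np.flatnonzero(arr)
            arr = arr.astype(np.intp)
            arr = np.where(arr < 0, arr + n, arr)
            idx.append(arr)
    return idx[0], idx[1], squeeze


def _apply_squeeze(out, squeeze):
    for axis in sorted(squeeze, reverse=True):
        out = np.squeeze(out, axis=axis)
    if out.ndim == 0:
        return out[()]
    return out


def open_bed(path: str | os.PathLike) -> BedMatrix:
    """Open a PLINK 1 fileset as a lazy :class:`BedMatrix` view.

    ``path`` may be the .bed file or the fileset root.  Raises
    :class:`BedFormatError` on a missing sibling, bad magic/mode bytes, or a
    payload size inconsistent with the .fam/.bim dimensions.
    """
    return BedMatrix(path)


def _default_fam(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": ["0"] * n,
            "within_family_id": [f"sample_{i + 1}" for i in range(n)],
            "father_id": ["0"] * n,
            "mother_id": ["0"] * n,
            "sex": ["0"] * n,
            "phenotype": ["-9"] * n,
        }
    )


def _default_bim(p: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * p,
            "variant_id": [f"variant_{j + 1}" for j in range(p)],
            "cm": [0] * p,
            "pos": np.arange(1, p + 1, dtype=np.int64),
            "a1": ["A"] * p,
            "a2": ["G"] * p,
        }
    )


def write_bed(
    geno: np.ndarray,
    root: str | os.PathLike,
    fam: pd.DataFrame | None = None,
    bim: pd.DataFrame | None = None,
) -> tuple[Path, Path, Path]:
    """Write a genotype matrix as a PLINK 1 fileset (.bed + .bim + .fam).

    ``geno`` is samples x variants with values in {0, 1, 2, MISSING}; float
    input may use NaN for missing.  Emits a variant-major .bed whose
    round trip through :func:`open_bed` / :meth:`BedMatrix.read` reproduces
    ``geno`` exactly.  Returns the three paths written.
    """
    geno = np.asarray(geno)
    if geno.ndim != 2:
        raise ValueError("geno must be 2-D (samples x variants)")
    n, p = geno.shape
    if np.issubdtype(geno.dtype, np.floating):
        codes = np.where(np.isnan(geno), float(MISSING), geno)
        if not np.all(np.isin(codes, [0.0, 1.0, 2.0, float(MISSING)])):
            raise ValueError("genotype values must be in {0, 1, 2, MISSING/NaN}")
        codes = codes.astype(np.int8)
    else:
        codes = geno.astype(np.int8)
        if not np.all(np.isin(codes, [0, 1, 2, int(MISSING)])):
            raise ValueError("genotype values must be in {0, 1, 2, MISSING}")
    fam = _default_fam(n) if fam is None else fam.reset_index(drop=True)
    bim = _default_bim(p) if bim is None else bim.reset_index(drop=True)
    if len(fam) != n:
        raise ValueError(f"fam has {len(fam)} rows but geno has {n} samples")
    if len(bim) != p:
        raise ValueError(f"bim has {len(bim)} rows but geno has {p} variants")

    root = Path(root)
    root.parent.mkdir(parents=True, exist_ok=True)
    bed_path = root.with_suffix(".bed")
    bim_path = root.with_suffix(".bim")
    fam_path = root.with_suffix(".fam")

    # map codes to bit pairs, then pack 4 samples per byte (low-order pair first)
    pair = np.empty((n, p), dtype=np.uint8)
    for code, bits in _CODE_TO_PAIR.items():
        pair[codes == code] = bits
    bpv = (n + 3) // 4
    padded = np.zeros((4 * bpv, p), dtype=np.uint8)
    padded[:n] = pair
    shifted = padded.reshape(bpv, 4, p) << np.array([0, 2, 4, 6], dtype=np.uint8).reshape(1, 4, 1)
    payload = shifted[:, 0, :] | shifted[:, 1, :] | shifted[:, 2, :] | shifted[:, 3, :]
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC + bytes([_MODE_VARIANT_MAJOR]))
        fh.write(payload.T.tobytes())  # variant-major: each variant's bytes contiguous
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path
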