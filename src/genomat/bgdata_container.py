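"""Aligned genotype/sample/variant container.

A :class:`BGDataSet` binds three components into one analysis-ready unit,
mirroring the structure of a PLINK fileset: ``geno`` (any matrix-like
genotype object — a BedMatrix, a LinkedMatrix over per-chromosome
filesets, or a plain array), ``pheno`` (one row per sample: IDs, sex,
covariates, phenotypes), and ``map`` (one row per variant: chromosome, id,
position, alleles).  The contract is positional: pheno rows align with
geno rows, and map rows align with geno columns, in order.  Constructors
and subsetting enforce this alignment so downstream statistics can index
the three components interchangeably.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linked_arrays import LinkedMatrix, MatrixView, node_shape
from .bed_io import open_bed

__all__ = ["BGDataSet", "load_bgdata", "subset_bgdata", "read_phenotype_table"]

logger = logging.getLogger(__name__)


@dataclass
class BGDataSet:
    """Genotypes plus aligned sample and variant tables.

    Invariants (checked at construction): ``len(pheno) == geno.shape[0]``
    and ``len(map) == geno.shape[1]``, with rows in the same order as the
    corresponding geno axis.
    """

    geno: object
    pheno: pd.DataFrame
    map: pd.DataFrame = field(default=None)

    def __post_init__(self):
        n, p = node_shape(self.geno)
        if self.map is None:
            self.map = pd.DataFrame(index=pd.RangeIndex(p))
        if len(self.pheno) != n:
            raise ValueError(
                f"pheno has {len(self.pheno)} rows but geno has {n} samples; "
                "rows of pheno must align with rows of geno"
            )
        if len(self.map) != p:
            raise ValueError(
                f"map has {len(self.map)} rows but geno has {p} variants; "
                "rows of map must align with columns of geno"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return node_shape(self.geno)

    def __repr__(self) -> str:
        n, p = self.shape
        return (f"BGDataSet({n} samples x {p} variants, "
                f"pheno columns: {list(self.pheno.columns)})")


def read_phenotype_table(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited phenotype table with a header row.

    The delimiter is auto-detected among tab, comma and whitespace unless
    given explicitly.
    """
    if delimiter is not None:
        return pd.read_csv(path, sep=delimiter)
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    return pd.read_csv(path, sep=sep)


def load_bgdata(
    fileset_roots,
    phenotype_file: str | os.PathLike | None = None,
    id_column: str | None = None,
    delimiter: str | None = None,
) -> BGDataSet:
    """Assemble a BGDataSet from one or more PLINK filesets plus an optional
    phenotype table.

    With several roots, ``geno`` is a column-linked matrix over per-fileset
    BedMatrix nodes in the given order, ``map`` is the concatenation of the
    .bim tables, and ``pheno`` starts from the first fileset's .fam table.
    A phenotype file is left-joined onto the .fam samples by ``id_column``
    (default: the .fam within-family ID) and reordered to .fam order;
    phenotype rows without a matching sample are dropped with a logged
    count, and samples without a phenotype row raise an alignment error.
    """
    if isinstance(fileset_roots, (str, os.PathLike)):
        fileset_roots = [fileset_roots]
    beds = [open_bed(root) for root in fileset_roots]
    if len(beds) == 1:
        geno = beds[0]
    else:
        geno = LinkedMatrix(beds, axis="columns")
    vmap = pd.concat([b.bim for b in beds], ignore_index=True)
    pheno = beds[0].fam.copy()
    pheno["sample_id"] = beds[0].sample_ids

    if phenotype_file is not None:
        table = read_phenotype_table(phenotype_file, delimiter=delimiter)
        key = id_column if id_column is not None else table.columns[0]
        if key not in table.columns:
            raise ValueError(f"id column {key!r} not found in {phenotype_file}")
        if table[key].duplicated().any():
            dupes = table.loc[table[key].duplicated(), key].head(5).tolist()
            raise ValueError(f"duplicate sample IDs in phenotype file: {dupes}")
        fam_ids = pheno["within_family_id"].astype(str)
        table = table.copy()
        table[key] = table[key].astype(str)
        known = table[key].isin(set(fam_ids))
        if (~known).any():
            logger.info("dropping %d phenotype rows with no matching sample",
                        int((~known).sum()))
            table = table[known]
        missing = ~fam_ids.isin(set(table[key]))
        if missing.any():
            first = fam_ids[missing].head(5).tolist()
            raise ValueError(
                f"{int(missing.sum())} samples have no phenotype row; first few: {first}"
            )
        merged = pheno.merge(table, left_on="within_family_id", right_on=key,
                             how="left", suffixes=("", "_pheno"))
        merged.index = pheno.index
        pheno = merged
    return BGDataSet(geno=geno, pheno=pheno, map=vmap)


def subset_bgdata(bgd: BGDataSet, rows=None, cols=None) -> BGDataSet:
    """Subset all three components consistently, lazily for genotypes.

    ``rows`` and ``cols`` are 0-based index sets (order and duplicates
    preserved).  The genotype component becomes a :class:`MatrixView` that
    retains the index sets without copying payload data.
    """
    n, p = node_shape(bgd.geno)
    rows = np.arange(n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
    cols = np.arange(p, dtype=np.intp) if cols is None else np.asarray(cols, dtype=np.intp)
    view = MatrixView(bgd.geno, rows, cols)
    return BGDataSet(
        geno=view,
        pheno=bgd.pheno.iloc[rows].reset_index(drop=True),
        map=bgd.map.iloc[cols].reset_index(drop=True),
    )
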