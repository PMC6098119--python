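"""Low-expression filtering and astrocyte-specificity annotation.

Both steps sit upstream of network construction: the FPKM filter removes
genes with essentially no signal (FPKM < 10 in >= 90% of samples), and the
astrocyte fraction annotates each gene with the share of its total
expression derived from astrocytes in an external cell-type reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from endfootnet.data_io import CellTypeFractionTable, ExpressionMatrix, UnitError

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input_genes: int
    n_retained: int
    removed_gene_ids: list[str]
    threshold_fpkm: float
    max_low_fraction: float

    def __post_init__(self) -> None:
        assert self.n_input_genes == self.n_retained + len(self.removed_gene_ids)


def filter_low_expression(
    expr: ExpressionMatrix,
    threshold_fpkm: float = 10.0,
    max_low_fraction: float = 0.9,
    allow_non_fpkm: bool = False,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes whose FPKM is below ``threshold_fpkm`` in >= ``max_low_fraction``
    of samples.

    The comparison is strict (< threshold) and the fraction inclusive
    (>= max_low_fraction): a gene low in exactly 90% of samples is removed.
    Retained gene order is preserved. Only meaningful for FPKM matrices;
    other units raise :class:`UnitError` unless ``allow_non_fpkm`` is set.
    """
    if expr.unit != "fpkm" and not allow_non_fpkm:
        raise UnitError(
            f"low-expression filter expects FPKM, got {expr.unit!r}; "
            "pass allow_non_fpkm=True to override"
        )
    vals = expr.values.to_numpy(dtype=float)
    low_fraction = (vals < threshold_fpkm).mean(axis=1)
    keep = low_fraction < max_low_fraction
    removed = [g for g, k in zip(expr.gene_ids, keep) if not k]
    filtered = ExpressionMatrix(expr.region, expr.unit, expr.values.loc[keep])
    report = FilterReport(
        n_input_genes=expr.n_genes,
        n_retained=int(keep.sum()),
        removed_gene_ids=removed,
        threshold_fpkm=threshold_fpkm,
        max_low_fraction=max_low_fraction,
    )
    return filtered, report


def annotate_astro_fraction(
    expr: ExpressionMatrix, celltype_table: CellTypeFractionTable
) -> pd.Series:
    """Astrocyte expression fraction per gene of ``expr``; NaN where the gene
    is absent from the cell-type reference (such genes later fail the
    astrocyte-specificity criterion, conservatively)."""
    frac = celltype_table.astro_fraction.reindex(expr.gene_ids)
    n_missing = int(frac.isna().sum())
    if n_missing == len(frac):
        raise ValueError("no overlap between expression genes and cell-type table")
    if n_missing:
        log.warning(
            "%d of %d genes absent from cell-type table; treated as non-astrocytic",
            n_missing,
            len(frac),
        )
    assert ((frac.dropna() >= 0) & (frac.dropna() <= 1)).all()
    frac.name = "astro_fraction"
    return frac
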