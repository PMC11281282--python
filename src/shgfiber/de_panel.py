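"""Gene-panel threshold filtering of differential-expression tables.

Differential-expression results (one row per gene: log2 fold change, p-value,
BH-adjusted p-value) are screened against curated panels of extracellular
matrix (ECM), cancer-associated-fibroblast (CAF), immune-checkpoint, and
T-cell marker genes.  A gene is called significantly altered when
``|log2fc| > 0.5`` (about a 1.4-fold change, strict) and ``padj <= 0.05``
(non-strict).  The "<0.5" side of the fold-change rule is read as
``log2fc < -0.5``, i.e. the filter is symmetric in magnitude — the literal
one-sided reading would retain every down-regulated gene.

A reference table of invasive-vs-noninvasive lung adenocarcinoma results over
the four panels ships with the package for regression testing
(:func:`load_reference_table`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

PANELS = ("ECM", "CAF", "immune_checkpoint", "T_cell")

DE_COLUMNS = ["symbol", "gene_id", "log2fc", "pvalue", "padj"]


@dataclass(frozen=True)
class GenePanel:
    """A named set of marker gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("panel symbols must be unique")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Monotonicity in p-rank order is enforced by the step-up construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2fc_to_fold(log2fc: float) -> float:
    """Linear fold change corresponding to a log2 fold change (2**log2fc)."""
    return float(2.0 ** log2fc)


def filter_significant(
    rows: pd.DataFrame,
    panel: GenePanel | None = None,
    lfc_abs_min: float = 0.5,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Rows passing the panel membership and significance thresholds.

    Keeps rows with ``|log2fc| > lfc_abs_min`` (strict) and
    ``padj <= padj_max`` (non-strict), restricted to ``panel`` when given,
    sorted by log2 fold change descending.  Duplicate gene symbols in the
    input raise, since the filter is defined per gene.
    """
    if lfc_abs_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    missing = {"symbol", "log2fc", "padj"} - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if rows["symbol"].duplicated().any():
        dupes = rows.loc[rows["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate gene symbols: {dupes}")
    keep = (rows["log2fc"].abs() > lfc_abs_min) & (rows["padj"] <= padj_max)
    if panel is not None:
        keep &= rows["symbol"].isin(panel.symbols)
    return rows[keep].sort_values("log2fc", ascending=False).reset_index(drop=True)


def load_reference_table() -> pd.DataFrame:
    """Published invasive-vs-noninvasive DE results over the four panels.

    39 genes with their log2 fold changes, p-values, adjusted p-values, and
    panel membership, transcribed from the published comparison of invasive
    and noninvasive stage IA lung adenocarcinoma (GEO series GSE166720).
    """
    ref = resources.files("shgfiber").joinpath("data/invasive_vs_noninvasive_de.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_panel(name: str) -> GenePanel:
    """One of the shipped marker panels: ECM, CAF, immune_checkpoint, T_cell."""
    if name not in PANELS:
        raise ValueError(f"unknown panel {name!r}; choose from {PANELS}")
    table = load_reference_table()
    return GenePanel(name, tuple(table.loc[table["panel"] == name, "symbol"]))


def read_de_tsv(path) -> pd.DataFrame:
    """Read a DE result TSV with columns symbol, gene_id, log2fc, pvalue, padj."""
    table = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return table


def write_de_tsv(table: pd.DataFrame, path) -> None:
    """Write a DE result table as TSV."""
    table.to_csv(path, sep="\t", index=False)
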