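"""Recompute published-style summaries from supplied supplementary tables.

The full-scale study results (site counts, trend counts, mean efficiencies)
derive from deep-sequencing data that this package does not download.  When
a user supplies the corresponding supplementary tables — a per-organelle
site-information table and a sites x samples editing-allele-proportion
matrix — these helpers re-derive the summaries with the same pipeline
machinery (trend classification, type spectra, codon-position shares).

Expected inputs (XLSX or TSV, column names configurable):

* site-information table: one row per site with at least an editing-type
  column, and optionally codon-position and hydropathy-change columns;
* efficiency matrix: sites x ordered per-condition columns of editing
  allele proportions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .efficiency_analysis import classify_trend
from .errors import FormatError

__all__ = [
    "load_table",
    "trend_counts",
    "mean_efficiency",
    "type_counts",
    "codon_position_share",
    "hydropathy_count",
]


def load_table(path: str | Path) -> pd.DataFrame:
    """Load a supplementary table (.xlsx via openpyxl, otherwise TSV/CSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return pd.read_csv(path, sep="\t")
    raise FormatError(f"unsupported supplementary-table format: {path.suffix}")


def trend_counts(efficiency: pd.DataFrame, condition_columns: list[str]
                 ) -> dict[str, int]:
    """Step-down / step-up counts over a proportion matrix.

    Uses the strict monotonicity classifier on the ordered condition
    columns (depths are not published, so no significance augmentation is
    possible here); rows missing any condition are incomplete.
    """
    labels = [
        classify_trend([row[c] for c in condition_columns])
        for _, row in efficiency.iterrows()
    ]
    return {
        "step_down": sum(l == "step_down" for l in labels),
        "step_up": sum(l == "step_up" for l in labels),
        "total_trend": sum(l in {"step_down", "step_up"} for l in labels),
    }


def mean_efficiency(efficiency: pd.DataFrame, columns: list[str] | None = None
                    ) -> float:
    """Grand mean editing proportion over the selected columns."""
    cols = columns or list(efficiency.select_dtypes("number").columns)
    return float(efficiency[cols].stack().mean())


def type_counts(site_info: pd.DataFrame, type_column: str = "edit_type"
                ) -> pd.Series:
    """Editing-type spectrum (e.g. the C-to-U count) from a site table."""
    return site_info[type_column].value_counts()


def codon_position_share(site_info: pd.DataFrame,
                         position_column: str = "codon_position") -> pd.Series:
    """Proportions at codon positions 1/2/3 over sites with a codon position."""
    pos = pd.to_numeric(site_info[position_column], errors="coerce").dropna()
    pos = pos[pos.isin([1, 2, 3])]
    return pos.value_counts(normalize=True).sort_index()


def hydropathy_count(site_info: pd.DataFrame, category: str,
                     column: str = "hydropathy_change") -> int:
    return int((site_info[column] == category).sum())
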