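"""FPKM expression quantification and editing-factor (PPR) screening.

Gene expression is measured in FPKM (fragments per kilobase of transcript
per million mapped reads) computed from a gene x sample count table with
gene lengths.  Differential expression between two temperature conditions
is screened with a Welch two-sample test on log2(FPKM + 1) replicate values
and a linear-scale fold change with a +1 pseudo-count; a gene is called DE
when p < 0.01 and the fold change exceeds 2 in either direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .efficiency_analysis import classify_trend
from .errors import DataError, PreconditionError

__all__ = [
    "ExpressionTable",
    "design_from_sample_names",
    "compute_fpkm",
    "differential_expression",
    "factor_trend_report",
]


class ExpressionTable:
    """Gene-level counts with lengths and a sample design.

    ``counts``: genes x samples integer DataFrame; ``gene_lengths``: Series
    (bp) aligned to the count index; ``design``: DataFrame with columns
    sample / condition / replicate covering every count column.
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series,
                 design: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        if not counts.index.equals(gene_lengths.index):
            gene_lengths = gene_lengths.reindex(counts.index)
            if gene_lengths.isna().any():
                raise DataError("gene_lengths missing for some genes")
        if (gene_lengths <= 0).any():
            raise DataError("gene lengths must be positive")
        missing = set(counts.columns) - set(design["sample"])
        if missing:
            raise DataError(f"design missing samples: {sorted(missing)}")
        self.counts = counts
        self.gene_lengths = gene_lengths
        self.design = design.reset_index(drop=True)

    @property
    def fpkm(self) -> pd.DataFrame:
        return compute_fpkm(self.counts, self.gene_lengths)

    def samples_for(self, condition: str) -> list[str]:
        rows = self.design[self.design["condition"] == condition]
        return [s for s in rows["sample"] if s in self.counts.columns]


def design_from_sample_names(sample_names) -> pd.DataFrame:
    """Build a design table from "<condition>_<replicate>" sample names."""
    rows = []
    for name in sample_names:
        cond, _, rep = str(name).rpartition("_")
        if not cond:
            raise DataError(f"sample name {name!r} is not <condition>_<replicate>")
        rows.append({"sample": name, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows)


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM = count * 1e9 / (library size * gene length), with the library
    size the per-sample column sum."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise DataError("every gene needs a positive length")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        zero = libsize[libsize == 0].index[0]
        raise DataError(f"sample {zero!r} has zero library size")
    return counts.mul(1e9).div(libsize, axis=1).div(lengths, axis=0)


def differential_expression(
    table: ExpressionTable,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Screen every gene for differential expression between two conditions.

    Per gene: Welch two-sample test on log2(FPKM + 1) replicate values and
    linear fold change (mean_b + 1)/(mean_a + 1).  ``is_de`` requires
    p < ``alpha`` and fold change > ``fc_threshold`` in either direction;
    ``direction`` is "down"/"up" with increasing condition order a -> b.
    """
    samples_a = table.samples_for(condition_a)
    samples_b = table.samples_for(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise PreconditionError("need at least two replicates per condition")
    fpkm = table.fpkm
    fa = fpkm[samples_a].to_numpy()
    fb = fpkm[samples_b].to_numpy()
    la = np.log2(fa + 1.0)
    lb = np.log2(fb + 1.0)
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant replicate vectors trigger a scipy precision warning;
        # those genes are handled by the explicit degenerate guard below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero-variance guard: identical replicate vectors carry no evidence,
    # perfectly separated constant groups are maximally significant
    degenerate = np.isnan(pvals)
    same_mean = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    pvals[degenerate & same_mean] = 1.0
    pvals[degenerate & ~same_mean] = 0.0

    mean_a = fa.mean(axis=1)
    mean_b = fb.mean(axis=1)
    fc = (mean_b + 1.0) / (mean_a + 1.0)
    magnitude = np.maximum(fc, 1.0 / fc)
    is_de = (pvals < alpha) & (magnitude > fc_threshold)
    return pd.DataFrame({
        "gene_id": fpkm.index,
        f"mean_fpkm_{condition_a}": mean_a,
        f"mean_fpkm_{condition_b}": mean_b,
        "fold_change": fc,
        "log2_fold_change": np.log2(fc),
        "p": pvals,
        "is_de": is_de,
        "direction": np.where(fc < 1.0, "down", np.where(fc > 1.0, "up", "flat")),
    }).set_index("gene_id")


def factor_trend_report(
    table: ExpressionTable,
    factor_gene_ids,
    condition_order: list[str],
) -> tuple[pd.DataFrame, float]:
    """Per-factor condition means and monotone trend of mean FPKM.

    Returns the per-gene table and the fraction of factor genes whose mean
    expression strictly decreases along the condition order (the same strict
    rule as editing-efficiency trend classification, applied to means).
    """
    if len(condition_order) < 2:
        raise PreconditionError("need at least two conditions")
    fpkm = table.fpkm
    unknown = [g for g in factor_gene_ids if g not in fpkm.index]
    if unknown:
        raise DataError(f"unknown factor gene id {unknown[0]!r}")
    rows = []
    for gene in factor_gene_ids:
        means = []
        for cond in condition_order:
            samples = table.samples_for(cond)
            if not samples:
                raise PreconditionError(f"condition {cond!r} has no samples")
            means.append(float(fpkm.loc[gene, samples].mean()))
        trend = classify_trend(means)
        rows.append({"gene_id": gene, "trend": trend,
                     **{f"mean_fpkm_{c}": m for c, m in zip(condition_order, means)}})
    report = pd.DataFrame(rows).set_index("gene_id")
    frac_down = float((report["trend"] == "step_down").mean()) if len(report) else 0.0
    return report, frac_down
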