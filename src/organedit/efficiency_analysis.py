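"""Editing-efficiency matrix, per-site tests, trend calling and clustering.

The central object is :class:`EfficiencyMatrix` — sites x ordered temperature
conditions, carrying edited and total allele depths alongside the derived
efficiency (edited/total) fractions.  Efficiency here is a true allele
fraction: the denominator is ref + edited allele depth, not the raw DP.

Trend vocabulary: a *step-down* site's efficiency strictly decreases over
every consecutive pair of the ordered conditions, a *step-up* site's strictly
increases; sites missing any condition are *incomplete*.  The default trend
rule additionally requires the first-vs-last condition Fisher's exact
comparison to be significant, which keeps chance monotone orderings of flat
sites (probability 1/4! over four conditions) out of the trend sets; pass
``significance_alpha=None`` for the monotonicity-only reading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .editing_caller import EditingSite
from .errors import DataError, PreconditionError
from .stats import fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "EfficiencyMatrix",
    "TrendRule",
    "TrendCall",
    "editing_efficiency",
    "build_efficiency_matrix",
    "site_condition_test",
    "classify_trend",
    "call_trends",
    "wilcoxon_rank_sum",
    "neighbor_condition_comparisons",
    "normalize_rows",
    "hierarchical_cluster",
]

_TOL = 1e-9


def editing_efficiency(edited_depth: int, total_depth: int) -> float:
    """Editing efficiency = depth of edited bases / total read depth.

    Returns NaN (the missing marker) when the site was not covered.
    """
    if total_depth < 0 or edited_depth < 0:
        raise DataError("depths must be non-negative")
    if edited_depth > total_depth:
        raise DataError(
            f"edited depth {edited_depth} exceeds total depth {total_depth}"
        )
    if total_depth == 0:
        return float("nan")
    return edited_depth / total_depth


@dataclass
class EfficiencyMatrix:
    """Sites x ordered conditions with edited/total depths and fractions.

    ``edited`` and ``total`` are DataFrames indexed by site_id with the
    condition columns in declared (temperature-ascending) order; cells are
    NaN where a site was not observed in a condition.
    """

    edited: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.edited.index.equals(self.total.index) or \
                not self.edited.columns.equals(self.total.columns):
            raise DataError("edited and total tables must be aligned")

    @property
    def site_ids(self) -> list[str]:
        return list(self.edited.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.edited.columns)

    @property
    def efficiency(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = self.edited / self.total
        return eff.where(self.total > 0)

    def depths_at(self, site_id: str, condition: str) -> tuple[int, int]:
        e = self.edited.at[site_id, condition]
        t = self.total.at[site_id, condition]
        if pd.isna(t):
            return 0, 0
        return int(e), int(t)

    # -- flat-file round trip -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per site: edited_<cond>, total_<cond>, eff_<cond> columns."""
        out = pd.DataFrame(index=self.edited.index)
        eff = self.efficiency
        for cond in self.condition_ids:
            out[f"edited_{cond}"] = self.edited[cond]
            out[f"total_{cond}"] = self.total[cond]
            out[f"eff_{cond}"] = eff[cond]
        out.index.name = "site_id"
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EfficiencyMatrix":
        conds = [c[len("edited_"):] for c in frame.columns if c.startswith("edited_")]
        edited = frame[[f"edited_{c}" for c in conds]].copy()
        total = frame[[f"total_{c}" for c in conds]].copy()
        edited.columns = conds
        total.columns = conds
        return cls(edited=edited, total=total)


def build_efficiency_matrix(
    sites_by_condition: dict[str, list[EditingSite]],
    condition_order: list[str],
) -> EfficiencyMatrix:
    """Assemble the union of sites across conditions into one matrix.

    A site absent from a condition gets a missing (NaN) cell; depths are
    carried for the exact tests.  Duplicate site_ids within one condition are
    a data error, an empty condition only a warning.
    """
    site_ids: list[str] = []
    seen: set[str] = set()
    for cond in condition_order:
        if not sites_by_condition.get(cond):
            warnings.warn(f"condition {cond!r} contributed no sites", stacklevel=2)
            continue
        ids = [s.site_id for s in sites_by_condition[cond]]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate site_id {dup!r} in condition {cond!r}")
        for sid in ids:
            if sid not in seen:
                seen.add(sid)
                site_ids.append(sid)

    edited = pd.DataFrame(np.nan, index=site_ids, columns=condition_order)
    total = pd.DataFrame(np.nan, index=site_ids, columns=condition_order)
    for cond in condition_order:
        for site in sites_by_condition.get(cond, []):
            edited.at[site.site_id, cond] = site.edited_depth
            total.at[site.site_id, cond] = site.total_depth
    edited.index.name = total.index.name = "site_id"
    return EfficiencyMatrix(edited=edited, total=total)


def site_condition_test(
    edited_a: int, total_a: int, edited_b: int, total_b: int
) -> float:
    """Two-sided Fisher's exact p comparing one site's editing fraction
    between two conditions ([[edited, unedited] x 2])."""
    if total_a <= 0 or total_b <= 0:
        raise PreconditionError("both totals must be positive")
    if edited_a > total_a or edited_b > total_b:
        raise DataError("edited depth exceeds total depth")
    return fisher_exact_2x2(edited_a, total_a - edited_a, edited_b, total_b - edited_b)


def classify_trend(efficiencies, tol: float = _TOL) -> str:
    """Label an ordered efficiency vector.

    ``incomplete`` if any value is missing, ``step_down``/``step_up`` when
    every consecutive pair strictly decreases/increases (strictness beyond
    ``tol``), ``none`` otherwise.
    """
    effs = [float(e) for e in efficiencies]
    if len(effs) < 2:
        raise PreconditionError("need at least two conditions to classify a trend")
    if any(math.isnan(e) for e in effs):
        return "incomplete"
    diffs = [b - a for a, b in zip(effs, effs[1:])]
    if all(d < -tol for d in diffs):
        return "step_down"
    if all(d > tol for d in diffs):
        return "step_up"
    return "none"


@dataclass
class TrendRule:
    """How a trend call is made from an efficiency profile.

    ``monotone``: "strict" requires strict per-step change; "nonstrict"
    allows per-step ties but requires a total change of at least
    ``min_total_change``.  ``significance_alpha``: when set, a monotone
    profile is only called a trend if the Fisher comparison between the
    first and last conditions is significant at that level (the screening
    used before separating step-up/step-down sites); None disables it.
    """

    monotone: str = "strict"
    min_total_change: float = 0.0
    significance_alpha: float | None = 0.01

    def __post_init__(self) -> None:
        if self.monotone not in {"strict", "nonstrict"}:
            raise DataError("monotone must be 'strict' or 'nonstrict'")


@dataclass
class TrendCall:
    site_id: str
    trend: str
    efficiencies: list[float]
    neighbor_p: list[float] = field(default_factory=list)
    endpoint_p: float | None = None


def _monotone_label(effs: list[float], rule: TrendRule) -> str:
    if any(math.isnan(e) for e in effs):
        return "incomplete"
    if rule.monotone == "strict":
        return classify_trend(effs)
    diffs = [b - a for a, b in zip(effs, effs[1:])]
    span = effs[0] - effs[-1]
    if all(d <= _TOL for d in diffs) and span >= rule.min_total_change:
        return "step_down"
    if all(d >= -_TOL for d in diffs) and -span >= rule.min_total_change:
        return "step_up"
    return "none"


def call_trends(matrix: EfficiencyMatrix, rule: TrendRule | None = None) -> list[TrendCall]:
    """Classify every site of the matrix under ``rule`` (default
    :class:`TrendRule`)."""
    rule = rule or TrendRule()
    eff = matrix.efficiency
    conds = matrix.condition_ids
    calls: list[TrendCall] = []
    for sid in matrix.site_ids:
        effs = [float(eff.at[sid, c]) for c in conds]
        trend = _monotone_label(effs, rule)
        neighbor_p: list[float] = []
        for a, b in zip(conds, conds[1:]):
            ea, ta = matrix.depths_at(sid, a)
            eb, tb = matrix.depths_at(sid, b)
            neighbor_p.append(
                site_condition_test(ea, ta, eb, tb) if ta > 0 and tb > 0 else float("nan")
            )
        endpoint_p = None
        if trend in {"step_down", "step_up"} and rule.significance_alpha is not None:
            ea, ta = matrix.depths_at(sid, conds[0])
            eb, tb = matrix.depths_at(sid, conds[-1])
            endpoint_p = site_condition_test(ea, ta, eb, tb)
            if endpoint_p >= rule.significance_alpha:
                trend = "none"
        calls.append(TrendCall(site_id=sid, trend=trend, efficiencies=effs,
                               neighbor_p=neighbor_p, endpoint_p=endpoint_p))
    return calls


def neighbor_condition_comparisons(
    matrix: EfficiencyMatrix,
    subset: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-wise Wilcoxon rank-sum between each two neighboring conditions.

    Runs on the efficiency columns of ``subset`` (default: all sites),
    dropping missing cells per column; returns one row per neighboring pair
    with the U statistic, two-sided p and significance at ``alpha``.
    """
    eff = matrix.efficiency
    if subset is not None:
        if not subset:
            raise PreconditionError("subset must be non-empty")
        eff = eff.loc[subset]
    rows = []
    conds = matrix.condition_ids
    for a, b in zip(conds, conds[1:]):
        ga = eff[a].dropna().to_numpy()
        gb = eff[b].dropna().to_numpy()
        stat, p = wilcoxon_rank_sum(ga, gb)
        rows.append({
            "pair": f"{a}-{b}", "n_a": ga.size, "n_b": gb.size,
            "statistic": stat, "p": p, "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


def normalize_rows(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Row-standardize for clustering/heatmaps: impute missing cells with the
    row mean, centre each row to mean 0 and divide by its sample (n-1)
    standard deviation; constant rows map to all zeros."""
    frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=float, copy=True) if frame else \
        np.array(values, dtype=float, copy=True)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise PreconditionError("normalize_rows expects a 2-D matrix")
    row_means = np.nanmean(arr, axis=1, keepdims=True)
    inds = np.where(np.isnan(arr))
    arr[inds] = np.take(row_means.ravel(), inds[0])
    centred = arr - arr.mean(axis=1, keepdims=True)
    if arr.shape[1] > 1:
        sd = arr.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros((arr.shape[0], 1))
    out = np.divide(centred, sd, out=np.zeros_like(centred), where=sd > 0)
    if frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def hierarchical_cluster(
    values: pd.DataFrame | np.ndarray, axis: str = "rows"
) -> tuple[list[int], np.ndarray]:
    """Agglomerative clustering with Euclidean distance and complete linkage.

    ``axis`` is "rows" (sites) or "cols" (samples).  Returns the leaf order
    (indices into the clustered axis) and the SciPy-format merge tree; a
    single item yields the identity ordering and an empty tree.
    """
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if axis == "cols":
        arr = arr.T
    elif axis != "rows":
        raise PreconditionError("axis must be 'rows' or 'cols'")
    n = arr.shape[0]
    if n == 1:
        return [0], np.empty((0, 4))
    tree = linkage(arr, method="complete", metric="euclidean")
    return [int(i) for i in leaves_list(tree)], tree
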