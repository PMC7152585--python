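"""Descriptive summaries of annotated editing sites.

All summaries are pure functions of their input site lists: permuting the
input never changes a count, and category vocabularies are closed.
"""

from __future__ import annotations

import pandas as pd

from .editing_caller import EditingSite
from .efficiency_analysis import TrendCall
from .errors import DataError

__all__ = [
    "HYDROPATHY_CATEGORIES",
    "sites_to_frame",
    "type_spectrum",
    "codon_position_distribution",
    "hydropathy_summary",
    "per_gene_trend_summary",
]

#: fixed reporting order of hydropathy-change categories
HYDROPATHY_CATEGORIES = (
    "hydrophobic2hydrophobic",
    "hydrophilic2hydrophilic",
    "hydrophobic2hydrophilic",
    "hydrophilic2hydrophobic",
)


def sites_to_frame(sites: list[EditingSite]) -> pd.DataFrame:
    """Flatten :class:`EditingSite` objects into a tidy DataFrame."""
    rows = [{
        "site_id": s.site_id, "seq_id": s.seq_id, "pos": s.pos,
        "ref_allele": s.ref_allele, "alt_allele": s.alt_allele,
        "gene_id": s.gene_id if s.gene_id is not None else "",
        "region": s.region, "edit_type": s.edit_type,
        "codon_position": s.codon_position if s.codon_position is not None else "",
        "codon_before": s.codon_before or "", "codon_after": s.codon_after or "",
        "aa_before": s.aa_before or "", "aa_after": s.aa_after or "",
        "silent": "" if s.silent is None else s.silent,
        "hydropathy_change": s.hydropathy_change,
        "edited_depth": s.edited_depth, "total_depth": s.total_depth,
        "efficiency": s.efficiency if s.efficiency is not None else float("nan"),
        "condition_id": s.condition_id,
    } for s in sites]
    return pd.DataFrame(rows)


def _frame_to_sites(df: pd.DataFrame) -> list[EditingSite]:
    """Inverse of :func:`sites_to_frame` (round-trips through TSV)."""
    def _opt(v, cast=str):
        if pd.isna(v) or v == "":
            return None
        return cast(v)

    sites = []
    for _, r in df.iterrows():
        silent = r.get("silent")
        sites.append(EditingSite(
            site_id=r["site_id"], seq_id=r["seq_id"], pos=int(r["pos"]),
            ref_allele=r["ref_allele"], alt_allele=r["alt_allele"],
            gene_id=_opt(r.get("gene_id")), region=r["region"],
            edit_type=r["edit_type"],
            codon_position=_opt(r.get("codon_position"), lambda v: int(float(v))),
            codon_before=_opt(r.get("codon_before")),
            codon_after=_opt(r.get("codon_after")),
            aa_before=_opt(r.get("aa_before")), aa_after=_opt(r.get("aa_after")),
            silent=None if pd.isna(silent) or silent == "" else bool(silent),
            hydropathy_change=r.get("hydropathy_change", "not-applicable"),
            edited_depth=int(r.get("edited_depth", 0)),
            total_depth=int(r.get("total_depth", 0)),
            condition_id=str(r.get("condition_id", "")),
        ))
    return sites


def type_spectrum(sites: list[EditingSite]) -> pd.DataFrame:
    """Counts and within-group proportions per edit type, grouped by
    condition and organelle (seq_id)."""
    if not sites:
        return pd.DataFrame(
            columns=["condition_id", "seq_id", "edit_type", "count", "proportion"]
        )
    df = sites_to_frame(sites)
    counts = (
        df.groupby(["condition_id", "seq_id", "edit_type"], sort=True)
        .size().rename("count").reset_index()
    )
    totals = counts.groupby(["condition_id", "seq_id"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def codon_position_distribution(sites: list[EditingSite]) -> pd.DataFrame:
    """Counts at codon positions 1/2/3 plus a "non-coding" bucket.

    Proportions are taken over CDS sites only, so positions 1+2+3 sum to 1.
    """
    if not sites:
        return pd.DataFrame(
            columns=["condition_id", "seq_id", "codon_position", "count", "proportion"]
        )
    df = sites_to_frame(sites)
    df["bucket"] = df["codon_position"].map(
        lambda p: str(int(p)) if p != "" else "non-coding"
    )
    counts = (
        df.groupby(["condition_id", "seq_id", "bucket"], sort=True)
        .size().rename("count").reset_index()
        .rename(columns={"bucket": "codon_position"})
    )
    cds = counts[counts["codon_position"] != "non-coding"]
    cds_totals = cds.groupby(["condition_id", "seq_id"])["count"].transform("sum")
    counts["proportion"] = float("nan")
    counts.loc[cds.index, "proportion"] = cds["count"] / cds_totals
    return counts


def hydropathy_summary(sites: list[EditingSite]) -> pd.DataFrame:
    """Counts of hydropathy-change categories over non-silent CDS sites.

    Silent sites and changes involving a stop codon do not contribute; the
    four categories are reported in the fixed canonical order even when zero.
    """
    df = sites_to_frame(sites) if sites else pd.DataFrame(
        columns=["condition_id", "seq_id", "region", "silent", "hydropathy_change"]
    )
    keep = df[
        (df.get("region") == "CDS")
        & (df.get("silent") == False)  # noqa: E712 -- silent may be "" for non-CDS
        & (df.get("hydropathy_change").isin(HYDROPATHY_CATEGORIES))
    ] if len(df) else df
    groups = sorted(
        set(zip(keep["condition_id"], keep["seq_id"]))
    ) if len(keep) else []
    rows = []
    for cond, seq in groups:
        sub = keep[(keep["condition_id"] == cond) & (keep["seq_id"] == seq)]
        for cat in HYDROPATHY_CATEGORIES:
            rows.append({
                "condition_id": cond, "seq_id": seq, "category": cat,
                "count": int((sub["hydropathy_change"] == cat).sum()),
            })
    out = pd.DataFrame(rows, columns=["condition_id", "seq_id", "category", "count"])
    if len(out):
        totals = out.groupby(["condition_id", "seq_id"])["count"].transform("sum")
        out["proportion"] = out["count"] / totals.where(totals > 0)
    return out


def per_gene_trend_summary(
    trend_calls: list[TrendCall], sites: list[EditingSite]
) -> pd.DataFrame:
    """Per-gene counts of step-down/step-up sites with their identities.

    ``sites`` supplies the annotation joined by site_id (any condition's
    annotation serves; the genomic annotation is condition-invariant).
    """
    by_id: dict[str, EditingSite] = {}
    for s in sites:
        by_id.setdefault(s.site_id, s)
    genes: dict[str, dict] = {}
    for call in trend_calls:
        if call.trend not in {"step_down", "step_up"}:
            continue
        if call.site_id not in by_id:
            raise DataError(f"trend call {call.site_id!r} missing from annotation")
        site = by_id[call.site_id]
        gene = site.gene_id if site.gene_id is not None else "(intergenic)"
        entry = genes.setdefault(gene, {
            "gene_id": gene, "n_step_down": 0, "n_step_up": 0,
            "site_ids": [], "aa_changes": [],
        })
        entry[f"n_{call.trend}"] += 1
        entry["site_ids"].append(site.site_id)
        if site.aa_before and site.aa_after:
            entry["aa_changes"].append(f"{site.aa_before}-to-{site.aa_after}")
    rows = sorted(
        genes.values(),
        key=lambda e: (-(e["n_step_down"] + e["n_step_up"]), e["gene_id"]),
    )
    for e in rows:
        e["site_ids"] = ",".join(e["site_ids"])
        e["aa_changes"] = ",".join(e["aa_changes"])
    return pd.DataFrame(
        rows, columns=["gene_id", "n_step_down", "n_step_up", "site_ids", "aa_changes"]
    )
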