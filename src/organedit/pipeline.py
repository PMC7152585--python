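"""End-to-end orchestration: VCFs -> merged variants -> filter cascade ->
annotated sites -> efficiency matrix -> trend calls and group tests.

This is the programmatic equivalent of running the CLI subcommands in
sequence, returning every intermediate product for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .editing_caller import (
    EditingSite,
    FilterConfig,
    FilterOutcome,
    annotate_site,
    apply_filter_cascade,
    merge_replicates,
)
from .efficiency_analysis import (
    EfficiencyMatrix,
    TrendCall,
    TrendRule,
    build_efficiency_matrix,
    call_trends,
    neighbor_condition_comparisons,
)
from .io_formats import GeneFeature, GenomeSequence, VariantRecord, read_vcf

__all__ = ["PipelineResult", "call_condition_sites", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, condition-resolved."""

    sites_by_condition: dict[str, list[EditingSite]]
    outcomes_by_condition: dict[str, list[FilterOutcome]]
    matrix: EfficiencyMatrix
    trend_calls: list[TrendCall]
    neighbor_tests: pd.DataFrame

    @property
    def all_sites(self) -> list[EditingSite]:
        return [s for sites in self.sites_by_condition.values() for s in sites]

    def trend_subset(self, trend: str) -> list[str]:
        return [c.site_id for c in self.trend_calls if c.trend == trend]

    def filter_report(self) -> pd.DataFrame:
        """One row per rejected variant with the rules it violated."""
        rows = []
        for cond, outcomes in self.outcomes_by_condition.items():
            for out in outcomes:
                if not out.passed:
                    rows.append({
                        "condition_id": cond,
                        "seq_id": out.variant.seq_id,
                        "pos": out.variant.pos,
                        "failed_rules": ",".join(out.failed_rules),
                    })
        return pd.DataFrame(
            rows, columns=["condition_id", "seq_id", "pos", "failed_rules"]
        )


def call_condition_sites(
    replicate_records: list[list[VariantRecord]],
    genome: GenomeSequence,
    features: list[GeneFeature],
    cfg: FilterConfig | None = None,
) -> tuple[list[EditingSite], list[FilterOutcome]]:
    """Merge one condition's replicates, run the cascade, annotate survivors."""
    cfg = cfg or FilterConfig()
    merged = merge_replicates([r for rep in replicate_records for r in rep])
    outcomes = apply_filter_cascade(merged, cfg, features)
    sites = [
        annotate_site(out.variant, genome, features)
        for out in outcomes if out.passed
    ]
    return sites, outcomes


def run_pipeline(
    genome: GenomeSequence,
    features: list[GeneFeature],
    vcf_by_condition: dict[str, list[object]],
    condition_order: list[str] | None = None,
    filter_config: FilterConfig | None = None,
    trend_rule: TrendRule | None = None,
) -> PipelineResult:
    """Run calling, efficiency and trend analysis over all conditions.

    ``vcf_by_condition`` maps each condition to its replicate inputs — VCF
    paths or pre-parsed :class:`VariantRecord` lists.
    """
    condition_order = condition_order or list(vcf_by_condition)
    sites_by_condition: dict[str, list[EditingSite]] = {}
    outcomes_by_condition: dict[str, list[FilterOutcome]] = {}
    for cond in condition_order:
        replicate_records = []
        for item in vcf_by_condition[cond]:
            if isinstance(item, (str, Path)):
                replicate_records.append(read_vcf(item, condition_id=cond))
            else:
                replicate_records.append(list(item))
        sites, outcomes = call_condition_sites(
            replicate_records, genome, features, filter_config
        )
        sites_by_condition[cond] = sites
        outcomes_by_condition[cond] = outcomes

    matrix = build_efficiency_matrix(sites_by_condition, condition_order)
    trends = call_trends(matrix, trend_rule)
    step_down = [c.site_id for c in trends if c.trend == "step_down"]
    neighbor = neighbor_condition_comparisons(
        matrix, subset=step_down or None, alpha=0.05
    )
    return PipelineResult(
        sites_by_condition=sites_by_condition,
        outcomes_by_condition=outcomes_by_condition,
        matrix=matrix,
        trend_calls=trends,
        neighbor_tests=neighbor,
    )
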