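"""Editing-site calling: replicate merging, the ten-rule filter cascade, and
codon-level annotation of the surviving variants.

The cascade mirrors standard practice for calling C-to-U editing from
organelle RNA-seq variant files.  Every rule is evaluated for every record
(no short-circuiting) so the diagnostic output lists *all* violated rules,
which also makes each rule independently testable.  A variant survives only
when ``failed_rules`` is empty.

Rules, in reporting order:

``quality``
    variant quality >= ``min_qual`` and allele-depth fields present.
``depth``
    total read depth strictly greater than ``min_depth - 1`` (the classic
    "DP > 4" screen at the defaults).
``alt_proportion``
    edited-allele fraction alt/(ref+alt) >= ``min_alt_proportion``.
``multiple_alt``
    exactly one ALT allele.
``distance``
    no other variant closer than ``min_neighbor_distance`` bp.
``spliced_junction``
    not within ``junction_exclusion`` bp of an internal segment boundary of
    a multi-segment feature (splice-edge misalignment artifacts).
``indel``
    REF and every ALT are single nucleotides.
``llr``
    binomial log-likelihood ratio of an editing model against a
    sequencing-error-only model >= ``llr_threshold``.
``strand_bias``
    two-sided Fisher's exact p on the DP4 strand table >= ``strand_bias_alpha``
    (records without strand counts pass).
``cluster``
    fewer than ``cluster_max`` variants inside any window of
    ``cluster_window`` bp containing the position (dense clusters of
    apparent variants are the canonical residual false-positive class).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import DataError, PreconditionError
from .io_formats import GeneFeature, GenomeSequence, VariantRecord
from .stats import fisher_exact_2x2

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "EditingSite",
    "FILTER_RULES",
    "HYDROPHOBIC_RESIDUES",
    "merge_replicates",
    "apply_filter_cascade",
    "llr_statistic",
    "strand_bias_fisher",
    "annotate_site",
    "hydropathy_change",
]

FILTER_RULES = (
    "quality",
    "depth",
    "alt_proportion",
    "multiple_alt",
    "distance",
    "spliced_junction",
    "indel",
    "llr",
    "strand_bias",
    "cluster",
)

#: Residues counted as hydrophobic (Kyte-Doolittle-positive plus G and C).
HYDROPHOBIC_RESIDUES = frozenset("AVLIPFMWCG")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class FilterConfig:
    """Thresholds of the ten-rule cascade (defaults follow the classic
    organelle editing-caller settings)."""

    min_qual: float = 20.0
    min_depth: int = 5  # pass requires DP > min_depth - 1, i.e. DP > 4
    min_alt_proportion: float = 0.1
    min_neighbor_distance: int = 5
    junction_exclusion: int = 3
    error_rate: float = 0.01
    llr_threshold: float = 10.0
    strand_bias_alpha: float = 0.01
    cluster_window: int = 100
    cluster_max: int = 3

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_depth", "min_neighbor_distance",
                     "junction_exclusion", "llr_threshold", "cluster_window",
                     "cluster_max"):
            if getattr(self, name) <= 0:
                raise DataError(f"FilterConfig.{name} must be strictly positive")
        for name in ("min_alt_proportion", "error_rate", "strand_bias_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"FilterConfig.{name} must lie in (0, 1)")


@dataclass
class FilterOutcome:
    """Per-variant cascade verdict; ``passed`` iff no rule failed."""

    variant: VariantRecord
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


@dataclass
class EditingSite:
    """A filter-surviving variant annotated as an RNA editing site.

    ``edit_type`` is transcript-oriented for genic sites (a genomic C>T in a
    plus-strand gene and a genomic G>A in a minus-strand gene both read
    "C-to-U"); intergenic sites are labelled in genome orientation.
    """

    site_id: str
    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: str | None
    region: str  # CDS | intron | intergenic | non-coding-gene
    edit_type: str
    codon_position: int | None = None
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None
    silent: bool | None = None
    hydropathy_change: str = "not-applicable"
    edited_depth: int = 0
    total_depth: int = 0
    condition_id: str = ""

    @property
    def efficiency(self) -> float | None:
        if self.total_depth == 0:
            return None
        return self.edited_depth / self.total_depth


# ---------------------------------------------------------------------------
# replicate merging
# ---------------------------------------------------------------------------

def merge_replicates(records: list[VariantRecord]) -> list[VariantRecord]:
    """Merge replicate observations of one condition position-wise.

    Depths and strand counts are summed, quality takes the maximum.
    Replicates reporting different ALT alleles at one position merge into a
    multi-allelic record (left for the multiple-alt filter to reject);
    conflicting REF alleles are a data error.
    """
    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    for rec in records:
        by_pos.setdefault((rec.seq_id, rec.pos), []).append(rec)

    merged: list[VariantRecord] = []
    for (seq_id, pos), group in sorted(by_pos.items(), key=lambda kv: kv[0]):
        refs = {g.ref_allele for g in group}
        if len(refs) > 1:
            raise DataError(
                f"conflicting ref alleles {sorted(refs)} at {seq_id}:{pos}"
            )
        alts: list[str] = []
        for g in group:
            for a in g.alt_alleles:
                if a not in alts:
                    alts.append(a)
        quals = [g.qual for g in group if g.qual is not None]
        depths_ok = all(g.has_depth for g in group)
        strand_ok = all(g.strand_counts is not None for g in group)
        merged.append(
            VariantRecord(
                seq_id=seq_id,
                pos=pos,
                ref_allele=group[0].ref_allele,
                alt_alleles=alts,
                qual=max(quals) if quals else None,
                total_depth=sum(g.total_depth for g in group) if depths_ok else None,
                ref_depth=sum(g.ref_depth for g in group) if depths_ok else None,
                alt_depth=sum(g.alt_depth for g in group) if depths_ok else None,
                strand_counts=tuple(
                    sum(g.strand_counts[i] for g in group) for i in range(4)
                ) if strand_ok else None,
                condition_id=group[0].condition_id,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# filter statistics
# ---------------------------------------------------------------------------

def llr_statistic(ref_depth: int, alt_depth: int, error_rate: float = 0.01) -> float:
    """Binomial log-likelihood ratio of editing vs sequencing error.

    Compares the maximum-likelihood editing fraction (clamped from below at
    the error rate) against the error-only model for ``alt_depth`` successes
    in ``ref_depth + alt_depth`` trials; natural logarithms.  Always >= 0.
    """
    n = ref_depth + alt_depth
    if n <= 0:
        raise PreconditionError("llr_statistic requires ref_depth + alt_depth > 0")
    if not 0.0 < error_rate < 1.0:
        raise PreconditionError("error_rate must lie in (0, 1)")

    p_hat = max(alt_depth / n, error_rate)

    def loglik(p: float) -> float:
        ll = 0.0
        if alt_depth:
            ll += alt_depth * math.log(p)
        if ref_depth:
            ll += ref_depth * math.log1p(-p)
        return ll

    return loglik(p_hat) - loglik(error_rate)


def strand_bias_fisher(strand_counts: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact p for strand bias on a DP4-style table
    [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]."""
    rf, rr, af, ar = strand_counts
    return fisher_exact_2x2(rf, rr, af, ar)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def apply_filter_cascade(
    records: list[VariantRecord],
    cfg: FilterConfig,
    annotation: list[GeneFeature] | None = None,
) -> list[FilterOutcome]:
    """Evaluate all ten rules for every record of one sequence.

    Records must be position-sorted and share one ``seq_id``; every record
    receives exactly one :class:`FilterOutcome` whose ``failed_rules`` lists
    every violated rule in cascade order.
    """
    if not records:
        return []
    positions = [r.pos for r in records]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise PreconditionError("records must be sorted by position")
    if len({r.seq_id for r in records}) > 1:
        raise PreconditionError("records must all come from one sequence")

    junctions: list[int] = []
    for feat in annotation or []:
        if len(feat.segments) > 1:
            junctions.extend(feat.internal_boundaries())
    junctions.sort()

    clustered = _cluster_flags(positions, cfg.cluster_window, cfg.cluster_max)

    outcomes: list[FilterOutcome] = []
    for i, rec in enumerate(records):
        failed: list[str] = []

        if rec.qual is None or rec.qual < cfg.min_qual or not rec.has_depth:
            failed.append("quality")

        if rec.total_depth is not None and rec.total_depth < cfg.min_depth:
            failed.append("depth")

        frac = rec.alt_fraction
        if frac is not None and frac < cfg.min_alt_proportion:
            failed.append("alt_proportion")

        if len(rec.alt_alleles) != 1:
            failed.append("multiple_alt")

        gap_ok = True
        if i > 0 and rec.pos - positions[i - 1] < cfg.min_neighbor_distance:
            gap_ok = False
        if i + 1 < len(positions) and positions[i + 1] - rec.pos < cfg.min_neighbor_distance:
            gap_ok = False
        if not gap_ok:
            failed.append("distance")

        if any(abs(rec.pos - j) <= cfg.junction_exclusion for j in junctions):
            failed.append("spliced_junction")

        if rec.is_indel:
            failed.append("indel")

        if rec.has_depth and (rec.ref_depth + rec.alt_depth) > 0:
            if llr_statistic(rec.ref_depth, rec.alt_depth, cfg.error_rate) < cfg.llr_threshold:
                failed.append("llr")

        if rec.strand_counts is not None:
            if strand_bias_fisher(rec.strand_counts) < cfg.strand_bias_alpha:
                failed.append("strand_bias")

        if clustered[i]:
            failed.append("cluster")

        outcomes.append(FilterOutcome(variant=rec, failed_rules=failed))
    return outcomes


def _cluster_flags(positions: list[int], window: int, cluster_max: int) -> list[bool]:
    """Mark positions lying in any span <= ``window`` bp holding >= ``cluster_max``
    variants (two-pointer sweep over the sorted positions)."""
    n = len(positions)
    flags = [False] * n
    k = 0
    for j in range(n):
        while k + 1 < n and positions[k + 1] - positions[j] <= window:
            k += 1
        if k - j + 1 >= cluster_max:
            for idx in range(j, k + 1):
                flags[idx] = True
    return flags


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def hydropathy_change(aa_before: str, aa_after: str) -> str:
    """Classify an amino-acid substitution by hydropathy shift.

    Uses the hydrophobic set {A, V, L, I, P, F, M, W, C, G}; any change
    involving a stop codon is ``not-applicable``.
    """
    if aa_before == "*" or aa_after == "*":
        return "not-applicable"
    for aa in (aa_before, aa_after):
        if len(aa) != 1 or not (aa.isalpha() and aa.upper() in "ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"unknown amino-acid letter {aa!r}")
    before = "hydrophobic" if aa_before.upper() in HYDROPHOBIC_RESIDUES else "hydrophilic"
    after = "hydrophobic" if aa_after.upper() in HYDROPHOBIC_RESIDUES else "hydrophilic"
    return f"{before}2{after}"


def _rna_label(base: str) -> str:
    return "U" if base == "T" else base


def _edit_type(ref: str, alt: str) -> str:
    return f"{_rna_label(ref)}-to-{_rna_label(alt)}"


def annotate_site(
    record: VariantRecord,
    genome: GenomeSequence,
    features: list[GeneFeature],
    organelle_label: str | None = None,
) -> EditingSite:
    """Annotate a cascade-surviving single-nucleotide variant.

    Locates the containing feature (ties broken by smallest spliced span),
    computes the transcript-strand codon before and after editing for CDS
    hits, translates both, and classifies silence and hydropathy change.
    Minus-strand features complement the alleles, so ``edit_type`` is always
    transcript-oriented for genic sites.
    """
    if len(record.ref_allele) != 1 or len(record.alt_alleles) != 1 \
            or len(record.alt_alleles[0]) != 1:
        raise PreconditionError(
            f"annotate_site requires a biallelic SNV at {record.seq_id}:{record.pos}"
        )
    ref, alt = record.ref_allele, record.alt_alleles[0]
    pos = record.pos
    label = organelle_label or record.seq_id
    site_id = f"{label}-{pos}"
    edited = record.alt_depth or 0
    total = (record.ref_depth or 0) + (record.alt_depth or 0)

    containing = [f for f in features if f.contains(pos)]
    containing.sort(key=lambda f: (f.spliced_length, f.span[0]))
    feat = containing[0] if containing else None

    if feat is None:
        # inside a gene's hull but outside its segments -> intron
        hulls = [f for f in features if f.in_span(pos)]
        hulls.sort(key=lambda f: (f.span[1] - f.span[0], f.span[0]))
        if hulls:
            g = hulls[0]
            t_ref, t_alt = _orient(ref, alt, g.strand)
            return EditingSite(
                site_id=site_id, seq_id=record.seq_id, pos=pos,
                ref_allele=ref, alt_allele=alt, gene_id=g.gene_id,
                region="intron", edit_type=_edit_type(t_ref, t_alt),
                edited_depth=edited, total_depth=total,
                condition_id=record.condition_id,
            )
        return EditingSite(
            site_id=site_id, seq_id=record.seq_id, pos=pos,
            ref_allele=ref, alt_allele=alt, gene_id=None,
            region="intergenic", edit_type=_edit_type(ref, alt),
            edited_depth=edited, total_depth=total,
            condition_id=record.condition_id,
        )

    t_ref, t_alt = _orient(ref, alt, feat.strand)
    site = EditingSite(
        site_id=site_id, seq_id=record.seq_id, pos=pos,
        ref_allele=ref, alt_allele=alt, gene_id=feat.gene_id,
        region="CDS" if feat.feature_kind == "CDS" else "non-coding-gene",
        edit_type=_edit_type(t_ref, t_alt),
        edited_depth=edited, total_depth=total,
        condition_id=record.condition_id,
    )
    if feat.feature_kind != "CDS":
        return site
    if not feat.frame_ok:
        warnings.warn(
            f"CDS {feat.gene_id} is out of frame; site {site_id} left without "
            "codon annotation",
            stacklevel=2,
        )
        return site

    # spliced transcript coordinate (0-based)
    offset = 0
    for start, end in feat.segments:
        if start <= pos <= end:
            plus_index = offset + (pos - start)
            break
        offset += end - start + 1
    length = feat.spliced_length
    t_index = plus_index if feat.strand == "+" else length - 1 - plus_index

    codon_idx = t_index // 3
    within = t_index % 3

    spliced = "".join(
        genome.residues[start - 1:end] for start, end in feat.segments
    )
    transcript = spliced if feat.strand == "+" else _revcomp(spliced)
    codon_before = transcript[codon_idx * 3: codon_idx * 3 + 3]
    codon_after = codon_before[:within] + t_alt + codon_before[within + 1:]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())

    site.codon_position = within + 1
    site.codon_before = codon_before
    site.codon_after = codon_after
    site.aa_before = aa_before
    site.aa_after = aa_after
    site.silent = aa_before == aa_after
    site.hydropathy_change = hydropathy_change(aa_before, aa_after) \
        if "*" not in (aa_before, aa_after) else "not-applicable"
    return site


def _orient(ref: str, alt: str, strand: str) -> tuple[str, str]:
    if strand == "+":
        return ref, alt
    return _COMPLEMENT[ref], _COMPLEMENT[alt]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))
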