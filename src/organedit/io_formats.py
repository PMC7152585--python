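"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere, matching both the VCF
and the NCBI feature-table (tbl) dialects.  No half-open conversion is ever
exposed.

Formats handled:

* FASTA genome sequences (via Biopython),
* NCBI feature tables (``.tbl``, the Sequin submission dialect; parsed here
  because no installed library reads it),
* VCF v4.x variant files (via pysam),
* tab-separated output tables with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .errors import DataError, FormatError, RangeError

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "GenomeSequence",
    "GeneFeature",
    "VariantRecord",
    "read_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_vcf",
    "write_vcf",
]


@dataclass(frozen=True)
class GenomeSequence:
    """An organelle genome: identifier plus upper-case A/C/G/T/N residues."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - NUCLEOTIDES
        if bad:
            raise FormatError(
                f"non-nucleotide character {sorted(bad)[0]!r} in sequence {self.seq_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise RangeError(f"position {pos} outside genome of length {self.length}")
        return self.residues[pos - 1]


@dataclass
class GeneFeature:
    """A stranded, possibly multi-segment annotated feature.

    ``segments`` are (start, end) pairs, 1-based inclusive, stored ascending
    on the plus strand regardless of the feature's own strand.  For minus
    strand features the transcript runs from the highest coordinate down.
    """

    gene_id: str
    symbol: str
    strand: str  # "+" or "-"
    segments: list[tuple[int, int]]
    feature_kind: str = "CDS"
    product: str = ""
    #: False when a CDS spliced length is not a multiple of 3 (flagged, not fatal).
    frame_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.segments:
            if not 1 <= start <= end:
                raise RangeError(f"bad segment ({start}, {end}) in {self.gene_id}")
        ordered = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise DataError(f"overlapping segments in feature {self.gene_id}")
        self.segments = ordered
        if self.feature_kind == "CDS" and self.spliced_length % 3 != 0:
            self.frame_ok = False
            warnings.warn(
                f"CDS {self.gene_id}: spliced length {self.spliced_length} "
                "is not a multiple of 3",
                stacklevel=2,
            )

    @property
    def spliced_length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic hull (first start, last end)."""
        return self.segments[0][0], self.segments[-1][1]

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.segments)

    def in_span(self, pos: int) -> bool:
        start, end = self.span
        return start <= pos <= end

    def internal_boundaries(self) -> list[int]:
        """Genomic coordinates flanking introns (for the junction filter)."""
        bounds: list[int] = []
        for (s1, e1), (s2, e2) in zip(self.segments, self.segments[1:]):
            bounds.extend((e1, s2))
        return bounds


@dataclass
class VariantRecord:
    """One genomic variant observation from a per-condition VCF.

    ``strand_counts`` is (ref_forward, ref_reverse, alt_forward, alt_reverse)
    as in a DP4 field, or None when strand information is absent.  Depth
    fields are None when the VCF record carried none; such records are
    removed later by the quality filter.
    """

    seq_id: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    qual: float | None
    total_depth: int | None
    ref_depth: int | None
    alt_depth: int | None
    strand_counts: tuple[int, int, int, int] | None = None
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RangeError(f"variant position {self.pos} must be >= 1")
        if (
            self.total_depth is not None
            and self.ref_depth is not None
            and self.alt_depth is not None
            and self.ref_depth + self.alt_depth > self.total_depth
        ):
            raise DataError(
                f"ref+alt depth exceeds total depth at {self.seq_id}:{self.pos}"
            )
        if self.strand_counts is not None:
            if any(c < 0 for c in self.strand_counts):
                raise DataError(f"negative strand count at {self.seq_id}:{self.pos}")

    @property
    def has_depth(self) -> bool:
        return (
            self.total_depth is not None
            and self.ref_depth is not None
            and self.alt_depth is not None
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or any(len(a) != 1 for a in self.alt_alleles)

    @property
    def alt_fraction(self) -> float | None:
        if not self.has_depth or (self.ref_depth + self.alt_depth) == 0:
            return None
        return self.alt_depth / (self.ref_depth + self.alt_depth)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read the first record of a FASTA file as a :class:`GenomeSequence`.

    Multi-record files yield the first record with a warning.  An empty file
    or a non-nucleotide alphabet raises :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records, using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return GenomeSequence(seq_id=rec.id, residues=str(rec.seq).upper())


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# NCBI feature table (.tbl)
# ---------------------------------------------------------------------------

_KNOWN_KINDS = {"CDS", "tRNA", "rRNA"}


def read_feature_table(
    path: str | Path, genome_length: int | None = None
) -> list[GeneFeature]:
    """Parse an NCBI feature table into :class:`GeneFeature` objects.

    Dialect: ``>Feature <seqid>`` header, then per feature a
    ``start<TAB>end<TAB>kind`` line, continuation ``start<TAB>end`` lines for
    further segments, and qualifier lines (three leading tabs) of which
    ``gene``, ``locus_tag`` and ``product`` are kept.  ``start > end`` on the
    first line signals the minus strand; coordinates are stored ascending.
    """
    raw: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                continue
            parts = line.split("\t")
            if parts[0] and len(parts) >= 3 and parts[2]:
                # new feature header line
                current = {
                    "kind": parts[2],
                    "coords": [(_coord(parts[0], lineno), _coord(parts[1], lineno))],
                    "gene": "",
                    "locus_tag": "",
                    "product": "",
                }
                raw.append(current)
            elif parts[0] and len(parts) >= 2:
                # continuation segment
                if current is None:
                    raise FormatError(f"{path}:{lineno}: segment before any feature")
                current["coords"].append(
                    (_coord(parts[0], lineno), _coord(parts[1], lineno))
                )
            elif len(parts) >= 5 and not parts[0]:
                # qualifier line: \t\t\tkey\tvalue
                if current is None:
                    raise FormatError(f"{path}:{lineno}: qualifier before any feature")
                key, value = parts[3], parts[4]
                if key in {"gene", "locus_tag", "product"}:
                    current[key] = value
            else:
                raise FormatError(f"{path}:{lineno}: unparseable feature-table line")

    features: list[GeneFeature] = []
    for idx, entry in enumerate(raw):
        coords = entry["coords"]
        minus = coords[0][0] > coords[0][1]
        segments = [(min(a, b), max(a, b)) for a, b in coords]
        if genome_length is not None:
            for start, end in segments:
                if end > genome_length:
                    raise RangeError(
                        f"feature coordinate {end} outside genome length {genome_length}"
                    )
        symbol = entry["gene"] or entry["locus_tag"] or f"feature{idx + 1}"
        gene_id = entry["locus_tag"] or entry["gene"] or f"feature{idx + 1}"
        features.append(
            GeneFeature(
                gene_id=gene_id,
                symbol=symbol,
                strand="-" if minus else "+",
                segments=segments,
                feature_kind=entry["kind"],
                product=entry["product"],
            )
        )
    return features


def _coord(token: str, lineno: int) -> int:
    try:
        return int(token.lstrip("<>"))
    except ValueError as exc:
        raise FormatError(f"line {lineno}: bad coordinate {token!r}") from exc


def write_feature_table(
    features: Sequence[GeneFeature], path: str | Path, seq_id: str = "genome"
) -> None:
    """Write features back out in the tbl dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write(f">Feature {seq_id}\n")
        for feat in features:
            segs = feat.segments if feat.strand == "+" else [
                (e, s) for s, e in reversed(feat.segments)
            ]
            first = True
            for a, b in segs:
                if first:
                    fh.write(f"{a}\t{b}\t{feat.feature_kind}\n")
                    first = False
                else:
                    fh.write(f"{a}\t{b}\n")
            if feat.symbol:
                fh.write(f"\t\t\tgene\t{feat.symbol}\n")
            if feat.gene_id:
                fh.write(f"\t\t\tlocus_tag\t{feat.gene_id}\n")
            if feat.product:
                fh.write(f"\t\t\tproduct\t{feat.product}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, condition_id: str = "") -> list[VariantRecord]:
    """Read a VCF v4.x file into :class:`VariantRecord` objects.

    Allele depths are taken from an INFO ``DP4`` field when present (it also
    carries the strand counts needed by the strand-bias filter); otherwise
    from a per-sample ``AD`` field.  Records lacking both carry missing depth
    markers and are removed later by the quality filter.  Only the first ALT
    allele's depth populates ``alt_depth``; multi-allelic records are kept
    intact for the multiple-alt filter to reject.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    records: list[VariantRecord] = []
    with vf:
        for idx, rec in enumerate(vf, start=1):
            try:
                records.append(_convert_vcf_record(rec, condition_id))
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: record {idx}: {exc}") from exc
    return records


def _convert_vcf_record(rec, condition_id: str) -> VariantRecord:
    alts = [str(a) for a in (rec.alts or ())]
    info = rec.info
    strand_counts = None
    ref_depth = alt_depth = None
    if "DP4" in info:
        dp4 = tuple(int(x) for x in info["DP4"])
        if len(dp4) != 4:
            raise ValueError(f"DP4 has {len(dp4)} values")
        strand_counts = dp4
        ref_depth = dp4[0] + dp4[1]
        alt_depth = dp4[2] + dp4[3]
    else:
        for sample in rec.samples.values():
            ad = sample.get("AD")
            if ad is not None and len(ad) >= 2 and ad[0] is not None:
                ref_depth = int(ad[0])
                alt_depth = int(ad[1])
                break
    total_depth = None
    if "DP" in info:
        total_depth = int(info["DP"])
    elif ref_depth is not None:
        total_depth = ref_depth + alt_depth
    return VariantRecord(
        seq_id=rec.chrom,
        pos=rec.pos,
        ref_allele=str(rec.ref),
        alt_alleles=alts,
        qual=float(rec.qual) if rec.qual is not None else None,
        total_depth=total_depth,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        strand_counts=strand_counts,
        condition_id=condition_id,
    )


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    seq_id: str,
    genome_length: int,
) -> None:
    """Write records as a minimal uncompressed VCF v4.2 with DP/DP4 INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={seq_id},length={genome_length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write(
            '##INFO=<ID=DP4,Number=4,Type=Integer,Description='
            '"Ref-forward, ref-reverse, alt-forward and alt-reverse bases">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: r.pos):
            info_parts = []
            if rec.total_depth is not None:
                info_parts.append(f"DP={rec.total_depth}")
            if rec.strand_counts is not None:
                info_parts.append("DP4=" + ",".join(str(c) for c in rec.strand_counts))
            info = ";".join(info_parts) or "."
            qual = "." if rec.qual is None else f"{rec.qual:g}"
            fh.write(
                f"{rec.seq_id}\t{rec.pos}\t.\t{rec.ref_allele}\t"
                f"{','.join(rec.alt_alleles)}\t{qual}\t.\t{info}\n"
            )
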