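"""Seed-reproducible synthetic organelle editing datasets.

The generator emulates the study design the pipeline targets: a small
circular organelle genome carrying strand-mixed CDS genes (a fraction with
two spliced segments), planted C-to-U editing sites — genomic G>A on
minus-strand genes, so transcript-orientation logic is always exercised —
whose true editing fraction is constant, strictly decreasing or strictly
increasing across four ordered temperature conditions, with read depths
drawn per replicate from a negative binomial and edited depths binomially.
Alongside the genuine sites it plants, per filter rule, artifact variants
constructed to violate exactly that rule.  It also emits a replicate
gene-level count matrix in which a planted subset of editing-factor genes
is down-regulated with temperature.

No generated VCF field encodes a truth label; recovery must come from the
pipeline.  Identical seeds yield byte-identical output files.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError
from .io_formats import (
    GeneFeature,
    GenomeSequence,
    VariantRecord,
    write_fasta,
    write_feature_table,
    write_vcf,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "plant_trend_profiles",
           "generate_dataset"]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: minimum spacing (bp) between independent planted variants: any three
#: variants then span >100 bp, clearing both the distance and cluster rules
_SITE_SPACING = 52
#: artifacts keep this distance from every unrelated variant
_ARTIFACT_SPACING = 150
#: genuine sites stay this far from spliced junctions: junction artifacts can
#: then be planted at a boundary without tripping the distance rule or
#: sharing a 100 bp cluster window with any genuine site
_JUNCTION_CLEARANCE = 104

ARTIFACT_RULES = (
    "quality", "depth", "alt_proportion", "multiple_alt", "distance",
    "spliced_junction", "indel", "llr", "strand_bias", "cluster",
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the four-temperature, three-replicate design the
    pipeline analyses, with trend fractions and depths at which the planted
    effects are resolvable (see the methods note).
    """

    seed: int = 0
    genome_length: int = 50_000
    n_genes: int = 30
    minus_strand_fraction: float = 0.4
    multi_segment_fraction: float = 0.2
    conditions: tuple[str, ...] = ("T25", "T35", "T40", "T45")
    replicates: int = 3
    n_edit_sites: int = 250
    fraction_step_down: float = 0.25
    fraction_step_up: float = 0.10
    fraction_flat: float = 0.65
    base_efficiency: tuple[float, float] = (0.80, 0.95)
    per_step_drop: tuple[float, float] = (0.12, 0.18)
    flat_efficiency: tuple[float, float] = (0.20, 0.90)
    mean_depth: float = 40.0
    depth_dispersion: float = 8.0
    artifact_per_rule: int = 5
    n_expression_genes: int = 500
    n_factor_genes: int = 60
    fraction_factors_down: float = 0.8
    fold_range: tuple[float, float] = (8.0, 8.0)
    noise_sigma: float = 0.2
    seq_id: str = "synorg"

    def __post_init__(self) -> None:
        fracs = (self.fraction_step_down, self.fraction_step_up, self.fraction_flat)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("trend fractions must lie in [0,1] and sum to 1")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth parameters must be positive")
        if len(self.conditions) < 2:
            raise ConfigError("need at least two conditions")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus truth tables; ``write`` emits the flat files."""

    config: SimulationConfig
    genome: GenomeSequence
    features: list[GeneFeature]
    #: (condition, replicate-name) -> VCF records
    vcf_records: dict[tuple[str, str], list[VariantRecord]]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: pd.DataFrame
    factor_ids: list[str]
    truth_sites: pd.DataFrame
    truth_artifacts: pd.DataFrame
    truth_expression: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_feature_table(self.features, outdir / "genes.tbl", self.genome.seq_id)
        for (cond, rep), records in sorted(self.vcf_records.items()):
            write_vcf(records, outdir / f"{cond}_{rep}.vcf",
                      self.genome.seq_id, self.genome.length)
        counts = self.counts.copy()
        counts.insert(0, "length", self.gene_lengths)
        counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        self.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        pd.Series(self.factor_ids, name="gene_id").to_csv(
            outdir / "factors.tsv", sep="\t", index=False
        )
        self.truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.truth_artifacts.to_csv(
            outdir / "truth_artifacts.tsv", sep="\t", index=False
        )
        self.truth_expression.to_csv(
            outdir / "truth_expression.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# trend profiles
# ---------------------------------------------------------------------------

def plant_trend_profiles(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], np.ndarray]:
    """Draw per-site true-efficiency vectors across the ordered conditions.

    Step-down sites start within ``base_efficiency`` and drop by a fresh
    ``per_step_drop`` draw at each step; step-up sites are mirrored
    (start = 1 - base draw, rising steps); flat sites are constant within
    ``flat_efficiency``.  Values are clamped to [0.02, 0.98]; a draw whose
    clamped vector no longer satisfies its label is redrawn.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_edit_sites
    n_down = round(n * cfg.fraction_step_down)
    n_up = round(n * cfg.fraction_step_up)
    labels = (["step_down"] * n_down + ["step_up"] * n_up
              + ["flat"] * (n - n_down - n_up))
    ncond = len(cfg.conditions)
    profiles = np.empty((n, ncond))
    for i, label in enumerate(labels):
        for attempt in range(100):
            if label == "flat":
                vec = np.full(ncond, rng.uniform(*cfg.flat_efficiency))
            else:
                steps = rng.uniform(*cfg.per_step_drop, size=ncond - 1)
                if label == "step_down":
                    start = rng.uniform(*cfg.base_efficiency)
                    vec = np.concatenate([[start], start - np.cumsum(steps)])
                else:
                    start = 1.0 - rng.uniform(*cfg.base_efficiency)
                    vec = np.concatenate([[start], start + np.cumsum(steps)])
            vec = np.clip(vec, 0.02, 0.98)
            if _label_holds(vec, label):
                profiles[i] = vec
                break
        else:
            raise ConfigError(
                f"cannot draw a {label} profile inside [0.02, 0.98]; "
                "narrow base_efficiency/per_step_drop"
            )
    return labels, profiles


def _label_holds(vec: np.ndarray, label: str) -> bool:
    diffs = np.diff(vec)
    if label == "step_down":
        return bool(np.all(diffs < -1e-9))
    if label == "step_up":
        return bool(np.all(diffs > 1e-9))
    return bool(np.all(diffs == 0.0))


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    cursor = int(rng.integers(300, 601))
    n_multi = round(cfg.multi_segment_fraction * cfg.n_genes)
    multi_idx = set(rng.choice(cfg.n_genes, size=n_multi, replace=False).tolist())
    for i in range(cfg.n_genes):
        spliced = 3 * int(rng.integers(150, 401))  # 450-1200 bp CDS
        minus = rng.random() < cfg.minus_strand_fraction
        multi = i in multi_idx
        if multi:
            part1 = 3 * int(rng.integers(30, spliced // 3 - 29))
            intron = int(rng.integers(80, 201))
            segments = [
                (cursor, cursor + part1 - 1),
                (cursor + part1 + intron, cursor + spliced + intron - 1),
            ]
        else:
            segments = [(cursor, cursor + spliced - 1)]
        cursor = segments[-1][1] + int(rng.integers(200, 501))
        features.append(GeneFeature(
            gene_id=f"GENE{i + 1:03d}",
            symbol=f"g{i + 1:03d}",
            strand="-" if minus else "+",
            segments=segments,
            feature_kind="CDS",
            product="synthetic organelle protein",
        ))
    if cursor > cfg.genome_length - 200:
        raise ConfigError(
            f"{cfg.n_genes} genes need ~{cursor} bp but genome_length is "
            f"{cfg.genome_length}"
        )
    return features


def _spliced_pos(feat: GeneFeature, plus_index: int) -> int:
    """Genomic position of 0-based plus-orientation spliced index."""
    remaining = plus_index
    for start, end in feat.segments:
        seg_len = end - start + 1
        if remaining < seg_len:
            return start + remaining
        remaining -= seg_len
    raise IndexError(plus_index)


def _truth_codon(feat: GeneFeature, plus_index: int, genome: str,
                 alt_genomic: str) -> tuple[int, str, str, str, str]:
    """Codon position (1-3), codons and amino acids before/after editing,
    computed directly from the planted geometry."""
    length = feat.spliced_length
    t_index = plus_index if feat.strand == "+" else length - 1 - plus_index
    spliced = "".join(genome[s - 1:e] for s, e in feat.segments)
    transcript = spliced if feat.strand == "+" else \
        "".join(_COMPLEMENT[b] for b in reversed(spliced))
    codon_idx, within = divmod(t_index, 3)
    codon_before = transcript[codon_idx * 3: codon_idx * 3 + 3]
    t_alt = alt_genomic if feat.strand == "+" else _COMPLEMENT[alt_genomic]
    codon_after = codon_before[:within] + t_alt + codon_before[within + 1:]
    return (within + 1, codon_before, codon_after,
            str(Seq(codon_before).translate()), str(Seq(codon_after).translate()))


# ---------------------------------------------------------------------------
# placement bookkeeping
# ---------------------------------------------------------------------------

class _Occupancy:
    """Sorted positions of every planted variant, with spacing queries."""

    def __init__(self) -> None:
        self._positions: list[int] = []

    def clear_of(self, pos: int, spacing: int) -> bool:
        i = bisect.bisect_left(self._positions, pos)
        for j in (i - 1, i):
            if 0 <= j < len(self._positions) and abs(self._positions[j] - pos) < spacing:
                return False
        return True

    def add(self, pos: int) -> None:
        bisect.insort(self._positions, pos)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full synthetic dataset (and write it when ``outdir`` is
    given).  Identical configs produce byte-identical files."""
    rng = np.random.default_rng(cfg.seed)

    features = _build_annotation(cfg, rng)
    genome_arr = _BASES[rng.integers(0, 4, size=cfg.genome_length)]

    labels, profiles = plant_trend_profiles(cfg, rng)
    occupancy = _Occupancy()
    junctions = [b for f in features if len(f.segments) > 1
                 for b in f.internal_boundaries()]

    # --- genuine editing sites ------------------------------------------
    site_rows = []
    for i, label in enumerate(labels):
        for attempt in range(500):
            feat = features[int(rng.integers(0, len(features)))]
            plus_index = int(rng.integers(0, feat.spliced_length))
            pos = _spliced_pos(feat, plus_index)
            if not occupancy.clear_of(pos, _SITE_SPACING):
                continue
            if any(abs(pos - j) < _JUNCTION_CLEARANCE for j in junctions):
                continue
            break
        else:
            raise ConfigError(
                "cannot place all editing sites; enlarge the genome or plant fewer"
            )
        occupancy.add(pos)
        ref = "C" if feat.strand == "+" else "G"
        genome_arr[pos - 1] = ref
        site_rows.append({
            "pos": pos, "feature": feat, "plus_index": plus_index,
            "label": label, "profile": profiles[i], "ref": ref,
            "alt": _TRANSITION[ref],
        })

    # --- artifact variants ----------------------------------------------
    artifact_groups = _plan_artifacts(cfg, rng, features, junctions, occupancy)

    genome = GenomeSequence(seq_id=cfg.seq_id, residues="".join(genome_arr))

    # truth codons need the final genome string
    truth_site_rows = []
    for row in site_rows:
        cp, cb, ca, aab, aaa = _truth_codon(
            row["feature"], row["plus_index"], genome.residues, row["alt"]
        )
        entry = {
            "site_id": f"{cfg.seq_id}-{row['pos']}",
            "pos": row["pos"],
            "gene_id": row["feature"].gene_id,
            "strand": row["feature"].strand,
            "trend": row["label"],
            "codon_position": cp, "codon_before": cb, "codon_after": ca,
            "aa_before": aab, "aa_after": aaa,
        }
        for cond, eff in zip(cfg.conditions, row["profile"]):
            entry[f"eff_{cond}"] = eff
        truth_site_rows.append(entry)
    truth_columns = (["site_id", "pos", "gene_id", "strand", "trend",
                      "codon_position", "codon_before", "codon_after",
                      "aa_before", "aa_after"]
                     + [f"eff_{c}" for c in cfg.conditions])
    truth_sites = pd.DataFrame(truth_site_rows, columns=truth_columns) \
        .sort_values("pos").reset_index(drop=True)

    # --- per-replicate VCFs ----------------------------------------------
    rep_names = [f"rep{r + 1}" for r in range(cfg.replicates)]
    vcf_records: dict[tuple[str, str], list[VariantRecord]] = {
        (cond, rep): [] for cond in cfg.conditions for rep in rep_names
    }
    nb_n = cfg.depth_dispersion
    nb_p = nb_n / (nb_n + cfg.mean_depth)
    for row in site_rows:
        for ci, cond in enumerate(cfg.conditions):
            eff = row["profile"][ci]
            for rep in rep_names:
                total = int(rng.negative_binomial(nb_n, nb_p))
                if total == 0:
                    continue
                alt = int(rng.binomial(total, eff))
                if alt == 0:
                    continue
                ref_d = total - alt
                rf = int(rng.binomial(ref_d, 0.5))
                af = int(rng.binomial(alt, 0.5))
                vcf_records[(cond, rep)].append(VariantRecord(
                    seq_id=cfg.seq_id, pos=row["pos"], ref_allele=row["ref"],
                    alt_alleles=[row["alt"]],
                    qual=float(rng.integers(40, 100)),
                    total_depth=total, ref_depth=ref_d, alt_depth=alt,
                    strand_counts=(rf, ref_d - rf, af, alt - af),
                    condition_id=cond,
                ))

    truth_artifact_rows = []
    for group in artifact_groups:
        cond = cfg.conditions[int(rng.integers(0, len(cfg.conditions)))]
        rep = rep_names[int(rng.integers(0, cfg.replicates))]
        for rec in group["records"]:
            rec = replace(rec, seq_id=cfg.seq_id, condition_id=cond)
            rec = _fill_artifact_ref(rec, genome)
            vcf_records[(cond, rep)].append(rec)
            truth_artifact_rows.append({
                "pos": rec.pos, "rule": group["rule"],
                "condition": cond, "replicate": rep,
            })
    truth_artifacts = pd.DataFrame(
        truth_artifact_rows, columns=["pos", "rule", "condition", "replicate"]
    ).sort_values(["rule", "pos"]).reset_index(drop=True)

    for key in vcf_records:
        vcf_records[key].sort(key=lambda r: r.pos)

    # --- expression matrix ----------------------------------------------
    counts, gene_lengths, design, factor_ids, truth_expression = \
        _generate_expression(cfg, rng, rep_names)

    dataset = SyntheticDataset(
        config=cfg, genome=genome, features=features, vcf_records=vcf_records,
        counts=counts, gene_lengths=gene_lengths, design=design,
        factor_ids=factor_ids, truth_sites=truth_sites,
        truth_artifacts=truth_artifacts, truth_expression=truth_expression,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset


def _fill_artifact_ref(rec: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Substitute the genome base into placeholder REF/ALT alleles."""
    base = genome.base(rec.pos)
    ref = rec.ref_allele.replace("N", base)
    alts = [a.replace("N", base).replace("n", _TRANSITION[base])
            for a in rec.alt_alleles]
    # any extra allele must differ from both the ref and the first alt
    for i in range(1, len(alts)):
        if alts[i] in (ref, alts[0]):
            alts[i] = next(b for b in "ACGT" if b not in (ref, alts[0]))
    return replace(rec, ref_allele=ref, alt_alleles=alts)


def _clean_record(pos: int, qual: float = 99.0, total: int = 60, alt: int = 30,
                  ) -> VariantRecord:
    """A record that passes every per-record rule; REF/ALT are placeholders
    ('N' = genome base, 'n' = its transition partner) filled in later."""
    ref_d = total - alt
    return VariantRecord(
        seq_id="", pos=pos, ref_allele="N", alt_alleles=["n"], qual=qual,
        total_depth=total, ref_depth=ref_d, alt_depth=alt,
        strand_counts=(ref_d // 2, ref_d - ref_d // 2, alt // 2, alt - alt // 2),
    )


def _plan_artifacts(cfg, rng, features, junctions, occupancy) -> list[dict]:
    """Build artifact record groups, each violating exactly one rule.

    Depth recipes are chosen so no other rule trips: e.g. the low-depth
    artifact keeps a high alt fraction (so the LLR still clears 10) and the
    low-alt-fraction artifact sits at depth 100 with 9 edited reads (LLR
    ~12, above threshold).  Strand counts are split evenly except for the
    strand-bias class.
    """
    k = cfg.artifact_per_rule
    groups: list[dict] = []

    def place_free(spacing: int = _ARTIFACT_SPACING, width: int = 0) -> int:
        for attempt in range(2000):
            pos = int(rng.integers(100, cfg.genome_length - 100 - width))
            ends = [pos, pos + width] if width else [pos]
            # stay out of every junction's cluster window too: a junction
            # artifact planted later must not share a 100 bp span with us
            if all(occupancy.clear_of(p, spacing) for p in ends) and \
                    all(abs(p - j) > 110 for j in junctions for p in ends):
                return pos
        raise ConfigError("cannot place artifact variants; genome too crowded")

    def single(rule: str, rec: VariantRecord) -> None:
        groups.append({"rule": rule, "records": [rec]})
        occupancy.add(rec.pos)

    for _ in range(k):
        single("quality", replace(_clean_record(place_free()), qual=5.0))
    for _ in range(k):
        p = place_free()
        rec = VariantRecord(seq_id="", pos=p, ref_allele="N", alt_alleles=["n"],
                            qual=80.0, total_depth=4, ref_depth=1, alt_depth=3,
                            strand_counts=(0, 1, 1, 2))
        single("depth", rec)
    for _ in range(k):
        p = place_free()
        rec = VariantRecord(seq_id="", pos=p, ref_allele="N", alt_alleles=["n"],
                            qual=80.0, total_depth=100, ref_depth=91, alt_depth=9,
                            strand_counts=(45, 46, 4, 5))
        single("alt_proportion", rec)
    for _ in range(k):
        rec = _clean_record(place_free())
        rec = replace(rec, alt_alleles=["n", "A"])  # second allele deduped later
        single("multiple_alt", rec)
    for _ in range(k):
        p = place_free(width=2)
        pair = [_clean_record(p), _clean_record(p + 2)]
        groups.append({"rule": "distance", "records": pair})
        occupancy.add(p)
        occupancy.add(p + 2)
    junction_sites = _junction_artifact_positions(cfg, rng, junctions, occupancy, k)
    for p in junction_sites:
        single("spliced_junction", _clean_record(p))
    for _ in range(k):
        rec = _clean_record(place_free())
        rec = replace(rec, alt_alleles=["NA"])  # insertion: genome base + A
        single("indel", rec)
    for _ in range(k):
        p = place_free()
        rec = VariantRecord(seq_id="", pos=p, ref_allele="N", alt_alleles=["n"],
                            qual=80.0, total_depth=10, ref_depth=8, alt_depth=2,
                            strand_counts=(4, 4, 1, 1))
        single("llr", rec)
    for _ in range(k):
        p = place_free()
        rec = VariantRecord(seq_id="", pos=p, ref_allele="N", alt_alleles=["n"],
                            qual=99.0, total_depth=60, ref_depth=30, alt_depth=30,
                            strand_counts=(15, 15, 30, 0))
        single("strand_bias", rec)
    for _ in range(k):
        p = place_free(width=80)
        triple = [_clean_record(p), _clean_record(p + 40), _clean_record(p + 80)]
        groups.append({"rule": "cluster", "records": triple})
        for rec in triple:
            occupancy.add(rec.pos)
    return groups


def _junction_artifact_positions(cfg, rng, junctions, occupancy, k) -> list[int]:
    positions: list[int] = []
    candidates = list(junctions)
    rng.shuffle(candidates)
    for boundary in candidates:
        if len(positions) == k:
            break
        pos = boundary + int(rng.integers(-2, 3))  # inside the exclusion zone
        if occupancy.clear_of(pos, 101):  # clear of every cluster window
            positions.append(pos)
            occupancy.add(pos)
    if len(positions) < k:
        raise ConfigError(
            "not enough spliced junctions for the junction-artifact class; "
            "raise multi_segment_fraction or n_genes"
        )
    return positions


def _generate_expression(cfg, rng, rep_names):
    n = cfg.n_expression_genes
    gene_ids = [f"EXPR{i + 1:04d}" for i in range(n)]
    lengths = pd.Series(rng.integers(500, 3001, size=n), index=gene_ids,
                        name="length")
    base_level = 10.0 ** rng.uniform(1.0, 3.0, size=n)

    if cfg.n_factor_genes > n:
        raise ConfigError("n_factor_genes exceeds n_expression_genes")
    factor_idx = rng.choice(n, size=cfg.n_factor_genes, replace=False)
    factor_idx.sort()
    n_down = round(cfg.n_factor_genes * cfg.fraction_factors_down)
    down_idx = set(factor_idx[:n_down].tolist())
    folds = {i: float(rng.uniform(*cfg.fold_range)) for i in sorted(down_idx)}

    ncond = len(cfg.conditions)
    sample_names = [f"{cond}_{rep}" for cond in cfg.conditions for rep in rep_names]
    scale = {s: float(rng.uniform(0.7, 1.3)) for s in sample_names}

    counts = np.zeros((n, len(sample_names)), dtype=int)
    true_means = np.zeros((n, ncond))
    for gi in range(n):
        for ci, cond in enumerate(cfg.conditions):
            mult = folds[gi] ** (-(ci / (ncond - 1))) if gi in down_idx else 1.0
            true_means[gi, ci] = base_level[gi] * mult
            for ri, rep in enumerate(rep_names):
                s = f"{cond}_{rep}"
                mean_count = (base_level[gi] * mult * lengths.iloc[gi] / 1000.0
                              * scale[s])
                noise = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
                counts[gi, ci * len(rep_names) + ri] = int(round(mean_count * noise))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_names)
    design = pd.DataFrame({
        "sample": sample_names,
        "condition": [s.rsplit("_", 1)[0] for s in sample_names],
        "replicate": [s.rsplit("_", 1)[1] for s in sample_names],
    })
    factor_ids = [gene_ids[i] for i in factor_idx]
    truth_rows = []
    for gi in range(n):
        truth_rows.append({
            "gene_id": gene_ids[gi],
            "is_factor": gi in set(factor_idx.tolist()),
            "trend": "step_down" if gi in down_idx else "flat",
            "fold": folds.get(gi, 1.0),
            **{f"mean_{c}": true_means[gi, ci]
               for ci, c in enumerate(cfg.conditions)},
        })
    truth_expression = pd.DataFrame(truth_rows)
    return counts_df, lengths, design, factor_ids, truth_expression
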