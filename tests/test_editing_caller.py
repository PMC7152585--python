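import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organedit.editing_caller import (
    FILTER_RULES,
    FilterConfig,
    annotate_site,
    apply_filter_cascade,
    hydropathy_change,
    llr_statistic,
    merge_replicates,
    strand_bias_fisher,
)
from organedit.errors import DataError, PreconditionError
from organedit.io_formats import GeneFeature, GenomeSequence, VariantRecord

from .oracles import fisher_two_sided_oracle


def _rec(pos, ref="C", alts=("T",), qual=99.0, total=60, ref_d=30, alt_d=30,
         strands=None, seq="m", cond="T25"):
    return VariantRecord(seq, pos, ref, list(alts), qual, total, ref_d, alt_d,
                         strand_counts=strands, condition_id=cond)


class TestMergeReplicates:
    def test_depths_sum_and_qual_takes_max(self):
        reps = [_rec(100, total=20, ref_d=16, alt_d=4, qual=q,
                     strands=(8, 8, 2, 2)) for q in (50.0, 80.0, 60.0)]
        reps[1].alt_depth = 5
        reps[1].ref_depth = 15
        reps[2].alt_depth = 3
        reps[2].ref_depth = 17
        (merged,) = merge_replicates(reps)
        assert merged.total_depth == 60
        assert merged.alt_depth == 12
        assert merged.ref_depth == 48
        assert merged.qual == 80.0
        assert merged.strand_counts == (24, 24, 6, 6)

    def test_single_replicate_is_identity(self):
        (merged,) = merge_replicates([_rec(100)])
        assert (merged.pos, merged.total_depth, merged.alt_depth) == (100, 60, 30)

    def test_conflicting_alts_become_multi_allelic(self):
        merged = merge_replicates([_rec(100, alts=("T",)), _rec(100, alts=("G",))])
        assert merged[0].alt_alleles == ["T", "G"]

    def test_conflicting_refs_raise(self):
        with pytest.raises(DataError, match="ref alleles"):
            merge_replicates([_rec(100, ref="C"), _rec(100, ref="G")])


class TestLlrStatistic:
    def test_clamped_when_alt_fraction_below_error_rate(self):
        assert llr_statistic(20, 0, 0.01) == 0.0

    def test_pure_alt_closed_form(self):
        # 20 edited reads, none unedited: LLR = -20 ln(0.01)
        assert llr_statistic(0, 20, 0.01) == pytest.approx(20 * math.log(100),
                                                           rel=1e-12)

    def test_low_fraction_value(self):
        expected = (5 * math.log(0.05) + 95 * math.log(0.95)) - \
            (5 * math.log(0.01) + 95 * math.log(0.99))
        assert llr_statistic(95, 5, 0.01) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.1291, abs=1e-4)

    def test_zero_total_depth_rejected(self):
        with pytest.raises(PreconditionError):
            llr_statistic(0, 0, 0.01)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(total=st.integers(1, 300), alt=st.integers(0, 299))
    def test_monotone_in_alt_depth_at_fixed_total(self, total, alt):
        alt = min(alt, total - 1)
        lo = llr_statistic(total - alt, alt)
        hi = llr_statistic(total - alt - 1, alt + 1)
        assert hi >= lo - 1e-9


class TestStrandBiasFisher:
    def test_proportional_rows_give_one(self):
        assert strand_bias_fisher((10, 10, 5, 5)) == pytest.approx(1.0)

    def test_fully_separated_table(self):
        # margins 10/10/10/10: only the two extreme tables are as unlikely
        assert strand_bias_fisher((10, 0, 0, 10)) == pytest.approx(
            2 / 184756, rel=1e-9
        )

    def test_agrees_with_enumeration_oracle(self):
        assert strand_bias_fisher((7, 3, 4, 6)) == pytest.approx(
            fisher_two_sided_oracle(7, 3, 4, 6), rel=1e-9
        )

    def test_all_zero_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert strand_bias_fisher((0, 0, 0, 0)) == 1.0


class TestFilterCascade:
    def test_depth_boundary_dp4_fails(self):
        (out,) = apply_filter_cascade(
            [_rec(100, total=4, ref_d=1, alt_d=3)], FilterConfig(), []
        )
        assert out.failed_rules == ["depth"]

    def test_low_alt_proportion_fails(self):
        (out,) = apply_filter_cascade(
            [_rec(100, total=20, ref_d=19, alt_d=1)], FilterConfig(), []
        )
        assert "alt_proportion" in out.failed_rules

    def test_clean_record_passes_all_rules(self):
        (out,) = apply_filter_cascade([_rec(100)], FilterConfig(), [])
        assert out.passed and out.failed_rules == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(PreconditionError, match="sorted"):
            apply_filter_cascade([_rec(200), _rec(100)], FilterConfig(), [])

    def test_every_record_gets_exactly_one_outcome(self, small_dataset,
                                                   small_pipeline):
        for cond, outcomes in small_pipeline.outcomes_by_condition.items():
            merged_positions = sorted(
                {r.pos for rep in range(small_dataset.config.replicates)
                 for r in small_dataset.vcf_records[(cond, f"rep{rep + 1}")]}
            )
            assert sorted(o.variant.pos for o in outcomes) == merged_positions
            survivors = sum(o.passed for o in outcomes)
            failures = sum(not o.passed for o in outcomes)
            assert survivors + failures == len(outcomes)

    def test_each_rule_rejects_exactly_its_artifact(self, small_dataset,
                                                    small_pipeline):
        """Every planted artifact class trips precisely its intended rule."""
        art = small_dataset.truth_artifacts
        seen_rules = set()
        for cond, outcomes in small_pipeline.outcomes_by_condition.items():
            by_pos = {o.variant.pos: o for o in outcomes}
            for _, row in art[art.condition == cond].iterrows():
                assert by_pos[row.pos].failed_rules == [row.rule], \
                    f"{row.rule} artifact at {row.pos}: {by_pos[row.pos].failed_rules}"
                seen_rules.add(row.rule)
        assert seen_rules == set(FILTER_RULES)


class TestAnnotation:
    @pytest.fixture()
    def toy(self):
        #            1        10        20
        # plus CDS 4..12: ATG TCA TAC ; minus CDS 14..22 (transcript ATG CCA TAA)
        residues = "AAA" + "ATGTCATAC" + "G" + "TTATGGCAT" + "AAAAAAAAAA"
        genome = GenomeSequence("m", residues)
        plus = GeneFeature("gplus", "gplus", "+", [(4, 12)], "CDS")
        minus = GeneFeature("gminus", "gminus", "-", [(14, 22)], "CDS")
        return genome, [plus, minus]

    def test_serine_to_leucine_on_plus_strand(self, toy):
        genome, feats = toy
        # TCA codon, position 2 (genomic pos 8, C>T) -> TTA, Ser -> Leu
        site = annotate_site(_rec(8, "C", ("T",)), genome, feats)
        assert site.region == "CDS" and site.gene_id == "gplus"
        assert site.edit_type == "C-to-U"
        assert (site.codon_before, site.codon_after) == ("TCA", "TTA")
        assert (site.aa_before, site.aa_after) == ("S", "L")
        assert site.codon_position == 2
        assert site.silent is False
        assert site.hydropathy_change == "hydrophilic2hydrophobic"

    def test_minus_strand_g_to_a_is_transcript_c_to_u(self, toy):
        genome, feats = toy
        # transcript codon CCA (pos 2): genomic G>A at pos 18 -> CTA, Pro -> Leu
        site = annotate_site(_rec(18, "G", ("A",)), genome, feats)
        assert site.gene_id == "gminus"
        assert site.edit_type == "C-to-U"
        assert (site.codon_before, site.codon_after) == ("CCA", "CTA")
        assert (site.aa_before, site.aa_after) == ("P", "L")
        assert site.hydropathy_change == "hydrophobic2hydrophobic"

    def test_third_position_synonymous(self, toy):
        genome, feats = toy
        # TAC codon position 3 (genomic pos 12, C>T) -> TAT, Tyr -> Tyr
        site = annotate_site(_rec(12, "C", ("T",)), genome, feats)
        assert (site.codon_before, site.codon_after) == ("TAC", "TAT")
        assert site.silent is True
        assert site.codon_position == 3

    def test_intergenic_site_keeps_genome_orientation(self, toy):
        genome, feats = toy
        site = annotate_site(_rec(25, "A", ("G",)), genome, feats)
        assert site.region == "intergenic"
        assert site.gene_id is None
        assert site.edit_type == "A-to-G"


class TestHydropathy:
    @pytest.mark.parametrize("pair,expected", [
        (("S", "L"), "hydrophilic2hydrophobic"),
        (("P", "L"), "hydrophobic2hydrophobic"),
        (("S", "S"), "hydrophilic2hydrophilic"),
        (("L", "S"), "hydrophobic2hydrophilic"),
        (("Q", "*"), "not-applicable"),
    ])
    def test_classification(self, pair, expected):
        assert hydropathy_change(*pair) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_change("S", "B")


class TestStrandSymmetry:
    def test_mirrored_genome_gives_identical_annotation(self, study):
        """Reverse-complementing the genome, mirroring features and alleles,
        leaves edit type, amino acids and silence calls unchanged."""
        ds, result = study
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
        L = ds.genome.length
        rc_genome = GenomeSequence(
            ds.genome.seq_id,
            "".join(comp[b] for b in reversed(ds.genome.residues)),
        )
        rc_feats = [
            GeneFeature(
                f.gene_id, f.symbol,
                "-" if f.strand == "+" else "+",
                [(L + 1 - e, L + 1 - s) for s, e in f.segments],
                f.feature_kind, f.product,
            )
            for f in ds.features
        ]
        checked = 0
        for cond, outcomes in result.outcomes_by_condition.items():
            for out in outcomes:
                if not out.passed:
                    continue
                rec = out.variant
                mirrored = VariantRecord(
                    rec.seq_id, L + 1 - rec.pos,
                    comp[rec.ref_allele],
                    [comp[a] for a in rec.alt_alleles],
                    rec.qual, rec.total_depth, rec.ref_depth, rec.alt_depth,
                    condition_id=rec.condition_id,
                )
                orig = annotate_site(rec, ds.genome, ds.features)
                mirr = annotate_site(mirrored, rc_genome, rc_feats)
                assert mirr.edit_type == orig.edit_type
                assert mirr.aa_before == orig.aa_before
                assert mirr.aa_after == orig.aa_after
                assert mirr.silent == orig.silent
                assert mirr.codon_position == orig.codon_position
                checked += 1
        assert checked > 500
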