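# Methods

## Scope and model

`organedit` treats organelle RNA editing as an allele-frequency problem on
RNA-seq variant calls. The genome is the unedited reference; an editing
site appears as a genomic C>T (plus-strand gene) or G>A (minus-strand gene)
variant whose alternate-allele fraction estimates the per-site editing
efficiency. The pipeline's stages are: replicate merging, a filter cascade
that removes technical artifacts, codon-level annotation of the survivors,
per-site efficiency across an ordered condition series, monotone-trend
classification with exact tests, and an expression screen of the
editing-factor (PPR) gene panel.

Assumptions: variants are called against a single circular organelle
reference per run; allele depths (DP4 or AD) are trustworthy conditional on
the upstream caller; reads are strand-balanced at genuine sites; editing at
one site is independent of editing at others (no haplotype modelling); and
replicate libraries within a condition are exchangeable, so their depths
may be summed before calling (maximizing depth at the cost of replicate-
level variance estimates for efficiency).

## Replicate merging

Within a condition, depths, DP4 strand counts and (by summation) total
depth are pooled across replicates; variant quality takes the maximum.
Replicates disagreeing on the ALT allele merge into a multi-allelic record
that the cascade later rejects; disagreeing REF alleles are a hard data
error since all replicates were called against one reference.

## The filter cascade

All ten rules are evaluated for every record — no short-circuiting — so the
report lists every violated rule, and each rule is independently testable.
A record survives only with zero violations.

| rule | pass condition | default |
|---|---|---|
| quality | QUAL ≥ `min_qual` and depth fields present | 20 |
| depth | total depth > `min_depth`−1 (i.e. DP > 4) | 5 |
| alt_proportion | alt/(ref+alt) ≥ `min_alt_proportion` | 0.1 |
| multiple_alt | exactly one ALT allele | — |
| distance | no other variant within `min_neighbor_distance` bp | 5 |
| spliced_junction | > `junction_exclusion` bp from internal segment boundaries of multi-segment features | 3 |
| indel | REF and ALT single nucleotides | — |
| llr | binomial LLR ≥ `llr_threshold` | 10 |
| strand_bias | two-sided Fisher p ≥ `strand_bias_alpha` on DP4 | 0.01 |
| cluster | < `cluster_max` variants in any `cluster_window` bp span containing the site | 3 in 100 |

The LLR compares an editing model with MLE fraction p̂ = max(alt/n, e)
against an error-only model with per-base error rate e (default 0.01),
using natural logs: LLR = ℓ(p̂) − ℓ(e) ≥ 0. At e = 0.01 an isolated
requirement of LLR ≥ 10 roughly demands ≥ 3 high-confidence edited reads.
The strand-bias test is Fisher's exact on [[ref_fwd, ref_rev],
[alt_fwd, alt_rev]]; records without strand information pass (nothing to
test). The cluster rule targets dense runs of apparent variants, the
classic residual false-positive class from misalignment; it is evaluated
with a two-pointer sweep over the sorted positions.

Design choices made where the procedure admits alternatives: DP4 is
preferred over AD when both are present (it carries the strand counts);
only the first ALT allele's depth populates `alt_depth`, leaving
multi-allelic records intact for their dedicated rule; the depth inequality
is read strictly (DP = 4 fails).

## Annotation

The containing feature is found by segment containment, ties broken by the
smallest spliced span (so a tRNA nested in a CDS wins). CDS hits get a
transcript coordinate through the spliced, strand-oriented sequence; the
codon before editing is read from the genome and the codon after by
substituting the strand-corrected alternate base; both translate under the
standard genetic code. Edit types are transcript-oriented for genic sites —
a genomic G>A in a minus-strand gene is reported "C-to-U" — and
genome-oriented for intergenic sites, which have no defining strand.
Hydropathy classes use the hydrophobic set {A, V, L, I, P, F, M, W, C, G}
(Kyte–Doolittle-positive plus glycine and cysteine); substitutions
involving a stop codon are `not-applicable`. A CDS whose spliced length is
not a multiple of 3 is flagged at parse time and annotated without codon
fields rather than guessing a frame.

## Efficiency, trends and group tests

Efficiency is edited/(edited+unedited) allele depth — deliberately not the
raw DP, which can include bases belonging to neither allele. The matrix
holds the union of sites over conditions with missing cells where a site
was not observed.

Trend vocabulary over the ordered conditions: *step-down* = strictly
decreasing at every consecutive pair (tolerance 1e−9), *step-up* strictly
increasing, *incomplete* when any condition is missing. Because four iid
noisy values are strictly monotone by chance with probability 1/4! ≈ 4.2 %,
monotonicity alone mislabels a non-negligible share of genuinely flat
sites. The default trend rule therefore also requires the Fisher's exact
comparison between the first and last conditions to be significant at
p < 0.01 — the same per-site significance screening applied before trend
separation in this analysis tradition. Monotonicity-only
(`significance_alpha=None`) and a non-strict variant with a minimum total
drop (`monotone="nonstrict"`, `min_total_change`) are available; sites
absent from any condition are excluded as incomplete rather than
classified on partial profiles.

Per-site condition comparisons are two-sided Fisher's exact tests on
[[edited, unedited] × 2]; the group-level comparison between neighboring
conditions is the two-tailed Wilcoxon rank-sum over the (sub)set's
efficiency columns. The rank-sum test uses the exact null distribution
when both groups have ≤ 8 tie-free observations and otherwise the normal
approximation with tie and continuity corrections; a pooled sample that is
one repeated value returns p = 1 (zero-variance guard). Both Fisher uses
share a single exact-test core (scipy's, two-sided by summing
hypergeometric probabilities not exceeding the observed table's within
relative tolerance 1e−7).

For heatmap-style ordering, rows are standardized — missing cells imputed
with the row mean (neutral after centring), centred, divided by the sample
(n−1) standard deviation, constant rows mapped to zero — and clustered
agglomeratively with Euclidean distance and complete linkage;
ties break deterministically on the smallest item index. The published
description of row scaling says values were *multiplied* by the standard
deviation; multiplication does not standardize, and the referenced heatmap
tooling divides, so division is implemented.

## Expression screen

FPKM = count × 10⁹ / (library size × gene length), library size being the
per-sample column sum. Differential expression between two conditions is a
per-gene Welch two-sample test on log2(FPKM + 1) replicate values with a
linear-scale fold change (mean_b + 1)/(mean_a + 1); a gene is DE at
p < 0.01 and fold change > 2 in either direction. This is a transparent
stand-in for assembly-based DE machinery: the thresholds, not the test
statistic, define the screen here, and the +1 pseudo-count stabilizes
zero-count genes (a constant-zero gene has FC exactly 1). Identical
replicate vectors make the Welch statistic undefined; the degenerate guard
returns p = 1 for equal means and p = 0 for separated constant groups.
The factor-panel report applies the same strict monotone rule to
per-condition mean FPKM and reports the fraction of factor genes
decreasing.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design the pipeline targets: four
ordered temperature conditions × three replicates; a 50 kb circular-style
genome with 30 single- and two-segment CDS genes, 40 % minus-strand;
250 editing sites of which 25 % step-down, 10 % step-up and 65 % flat
(mirroring the published proportion of trend sites at desk scale);
per-replicate depths negative-binomial around 40 (dispersion 8, so merged
depth ≈ 120 — comfortably above the ≥ 60 regime in which a 0.12–0.18
per-step drop is statistically resolvable); step-down profiles start at
0.80–0.95 and drop 0.12–0.18 per step (the lower bound keeps three
consecutive observed decreases detectable at the planted depth with ≥ 90 %
probability; smaller steps are valid biology but unresolvable at this
depth), step-up mirrored, flat sites uniform on 0.20–0.90, all clamped to
[0.02, 0.98]; edited depths binomial; strand counts symmetric-binomial.
Minus-strand sites are planted as genomic G>A so orientation logic is
always exercised. Per filter rule it plants five artifact variants
engineered to violate exactly that rule (e.g. the low-depth artifact keeps
a high alt fraction so the LLR still passes; the low-alt-fraction artifact
sits at depth 100 with 9 edited reads so its LLR ≈ 12 clears the
threshold), with deterministic balanced strand splits outside the
strand-bias class. Placement keeps independent variants ≥ 52 bp apart
(any three then span > 100 bp, clear of the cluster window), grouped
artifacts ≥ 150 bp from everything else, and genuine sites ≥ 104 bp from
spliced junctions so junction artifacts own their neighborhoods.
The expression matrix plants 60 factor genes among 500, 80 % of them
down-regulated 8-fold from first to last condition along a geometric
ladder, with log-normal σ = 0.2 count noise and per-sample library-size
factors.

Not emulated: read-level errors and alignment (artifacts are planted at
the variant level, not generated by a misaligner), positional sequence
context of editing sites (no PPR binding-site model), overlapping genes,
partial editing linkage across sites, batch effects in expression, and
U-to-C editing. Passing tests therefore demonstrate that the pipeline's
inference is correct for data matching its variant-level model — not that
the upstream caller's artifact spectrum is fully represented.

## Numerical choices and problem sizes

Strict-monotonicity tolerance 1e−9; Fisher two-sided comparison tolerance
1e−7 (relative); exact rank-sum branch bounded at n ≤ 8 per group;
clustering tie-break by smallest index; all coordinates 1-based inclusive
end to end. The test suite and the acceptance script run the default
design (250 sites, 65 artifact records, 500 expression genes, 12 VCFs) in
a few seconds; the exact-test oracle sweep covers every 2×2 table with all
margins ≤ 12.

## Known limitations

Efficiency confidence intervals are not reported (depths are carried, so a
binomial interval is a small extension); no multiple-testing correction is
applied across sites, matching the analysis tradition this follows — a
Benjamini–Hochberg pass over the per-site tests would be the first thing
to add for genome-scale organelles; merged replicates preclude
between-replicate variance in efficiency; and the DE screen's Welch test
is a deliberate simplification of assembly-based pipelines.
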