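# Methods

## Coverage model and gene-state classification

Alignments are consumed as SAM text; only primary mapped records count
(unmapped 0x4, secondary 0x100 and supplementary 0x800 flags are dropped,
with counted log lines). No MAPQ filter is applied by default (`mapq_min`
is configurable) — depth-tool defaults vary here and the analysis this
mirrors stated none. All coordinates are 0-based half-open internally;
SAM's 1-based positions are converted exactly once at parse time.

Per-base depth follows standard CIGAR semantics: M/=/X add one to every
consumed position, D/N consume reference without adding depth, I/S/H touch
nothing. "Covered" means depth ≥ 1 — the standard breadth definition. Two
identities hold by construction and are asserted in tests: total depth
equals the sum of reference-consuming M/=/X lengths over kept alignments
(conservation), and breadth = 0 exactly when mean depth = 0.

Normalized depth (gene mean depth / genome-wide mean depth) is computed and
reported for cross-sample comparison, but **classification thresholds apply
to raw mean depth** by default: the presence thresholds are stated in
absolute fold coverage (≥ 20x for luna-dominant samples, ≥ 2x for
lotti-dominant ones), which only makes sense on the raw scale. A config
switch (`threshold_on_normalized_depth`) flips this for users who prefer the
normalized scale. A sample whose genome-wide mean depth is zero gets missing
normalized values and is flagged unusable rather than erroring.

Classification cutoffs:

| parameter          | default | meaning                                     |
|--------------------|---------|---------------------------------------------|
| breadth_present    | 0.65    | minimum covered fraction for *present*      |
| depth_present luna | 20x     | depth floor in luna-dominant samples        |
| depth_present lotti| 2x      | depth floor in lotti-dominant samples       |
| breadth_absent     | 0.10    | breadth ceiling for *absent*                |
| depth_absent       | 1.0x    | depth ceiling for *absent*                  |

The absence cutoffs are a design choice (the source analysis said only
"below predefined cutoffs"): the wide gap between absence and presence
regions creates a deliberate *unknown* buffer, keeping the downstream test
conservative. The constructor enforces breadth_absent < breadth_present and
depth_absent < min(presence depths), which makes the three states a
partition of the (breadth, depth) domain.

## Differential presence

Unknown cells contribute to no margin. A gene with an empty present+absent
margin in either group is *untestable*: it is excluded before FDR
correction (so it does not inflate m) and reported with q = NaN; the count
of untestable genes is written to the run metadata.

The two-sided Fisher exact p-value uses the point-probability ordering: the
sum over all 2×2 tables with the observed margins whose hypergeometric
point probability does not exceed the observed one. It is computed with
exact integer arithmetic — binomial-coefficient numerators over the common
denominator C(n, k) — so the ordering comparison is exact and needs no
floating-point tie tolerance; at cohort scale (n ≈ 86) the integers are
tiny by bignum standards. The test suite checks this against exhaustive
rational enumeration (all tables with total ≤ 30) and against
scipy.stats.fisher_exact.

BH FDR is statsmodels' `multipletests(method="fdr_bh")` behind the
`bh_fdr` surface, verified against a hand-written step-up oracle. The
direction of a significant call comes from the present-fractions
(a/(a+b) vs c/(c+d)), not from the odds ratio, so infinite odds ratios
(b·c = 0) need no special-casing; α defaults to 0.05.

## Community analysis

Pipeline order is fixed: organelle/eukaryote taxon removal (lineage string
containing mitochondria / chloroplast / eukaryota, case-insensitive), then
the library-size filter (strict < 1000 total reads), then CSS. "Unclassified"
lineages are kept — absence of taxonomy is not organelle evidence.

CSS uses the nearest-rank quantile over a sample's **positive** counts: with
k positive counts sorted ascending, the quantile value is the element at
1-based index ⌈l·k⌉ (l = 0.5 by default; the adaptive quantile selection of
the original CSS method is out of scope), and the scaling factor s_j is the
sum of all counts ≤ that value. Normalized counts are raw · scale / s_j
(scale 1000). The dialect is stated this precisely because quantile
conventions differ between implementations; the worked example
[0, 2, 4, 6, 8] → quantile 4, s = 6 pins it down. Per-sample scale
invariance (multiplying a sample by c > 0 changes nothing after
normalization) is the property that matters and is tested.

Dominance: among focal ASVs detected at raw count ≥ `detection_min_count`
(default 1 — observed abundances reach down to ~0.006%, implying no floor),
the one with the largest relative abundance; exact ties break to the
lexicographically smallest ASV id, a measure-zero deterministic rule.
Detection uses raw counts, not CSS values, so dominance and categories are
invariant under per-sample rescaling.

Co-occurrence: the six categories (lotti alone; lotti + one variant; all
three; both variants without lotti; a single variant alone; none) partition
the 8 detection patterns of the focal trio. Richness is the observed ASV
count at the detection threshold, optionally restricted by a taxonomy
substring (e.g. the focal genus). Shared-ASV detection requires a common id
space between gill and environment tables (identical sequences ⇒ identical
ids, as in a joint ASV inference run) and reports per-compartment prevalence
and mean relative abundance, sorted by environment prevalence.

## The synthetic-data generator

**Metagenome side.** Genes are laid head-to-tail between fixed spacers, so
expected per-gene depth is exact. Reads are error-free truth placements
(all-M CIGARs), uniform within their gene and never straddling boundaries;
per-gene read counts are Poisson(depth · gene_length / read_length). The
default regimes — 50x core and specific in group A; 5x core, 0x specific in
group B — reproduce the depth structure the classification thresholds were
designed for. What this does **not** emulate: sequencing errors, mapping
ambiguity, paired ends, GC bias, shared-gene depth differences caused by
strain mixtures within a sample. Passing recovery tests therefore shows the
classification + testing machinery is correct given faithful alignments,
not that any mapper would produce such alignments.

**Amplicon side.** Each of `n_hosts` gill samples draws a co-occurrence
category at the observed frequencies (23.8 / 14.6 / 25 / 36.9 %,
renormalized since the printed values sum to 1.003), then focal relative
abundances from the observed dominance ranges (lotti 68.3–98.7%, luna
variants 48.4–98.1%); both luna variants are always co-planted in
variants-only hosts, since neither variant was ever observed without the
other. Subordinate fractions are drawn as proportions of the non-dominant
remainder so totals stay below 1 with headroom for background. The minor
variant in the lotti + one-variant category is drawn from 0.05–1.9%
relative abundance: the floor is raised above the lowest observed value
(0.006%) so every planted pattern has an expected count ≈ 10 at the default
library size and observed categories match planted ones by construction —
with a 6e-5 floor, ~30% of such plantings would be invisible and the
category split unrecoverable at any cohort size. Background diversity is a
symmetric Dirichlet over 60 ASVs (concentration 0.3); a host-mitochondrial
ASV (gill) and a chloroplast ASV at 10–40% (seagrass blades) exercise the
organelle filter. Library sizes are lognormal around a median of 20,000
(σ = 0.35); an optional `low_quality_fraction` plants sub-1000-read samples
to exercise the quality filter.

The environment tables plant luna variant 1 in all four compartments
(mean relative abundance 2×10⁻⁴ on the root/rhizome, lower elsewhere) and
ASV_1n2_n6n only on blades and root/rhizome at twice variant 1's rhizome
abundance (~0.04% vs ~0.02%); ASV_1n2_n6n also appears in ~60% of gill
samples below 1%. The planted shared set is therefore exactly
{luna variant 1, ASV_1n2_n6n}. Gill and environment background ASVs use
disjoint id spaces so no accidental third shared ASV can arise.

Everything is deterministic given (params, seed) — byte-identical files on
rerun — with all randomness drawn from one numpy Generator per dataset.

## Problem sizes and numerical choices

Default driver/CLI scale is 8+8 samples × 200 genes (12 planted specific)
and 130 hosts, which runs the full pipeline in seconds; recovery and null
false-discovery behaviour are measured at 20+20 samples × 500 genes with 25
planted genes, and category-proportion recovery at 10,000 hosts — sizes at
which binomial/Poisson noise is far smaller than the effects being checked.
Depth vectors are integer; breadth and depth means are exact ratios of
integers and only rounded at output (6 decimals). Fisher p-values and BH
q-values are exact up to one float division. Degenerate inputs have defined
behaviour rather than crashes: empty FASTA → empty list with a warning,
zero-depth samples → flagged with missing normalized depth, one-sided
cohorts → explicit refusal in differential testing, all-unknown genes →
untestable.

## Known limitations

- SAM text only (no BAM/CRAM); cohorts at real scale should pre-sort reads.
- The Fisher test conditions on both margins; like the original analysis it
  ignores uncertainty in the present/absent classification itself.
- CSS uses a fixed quantile; no adaptive quantile search.
- Ordination, PERMANOVA, diversity beyond observed richness, and
  phylogenetic analyses are out of scope — the module chain ends at the
  derived tables those methods would consume.
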