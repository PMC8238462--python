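# Methods

This note records the models implemented in `mslsites`, the conventions
and defaults chosen where the procedures admit more than one reading, and
what the synthetic-data tests do and do not establish.

## Coordinates and overlap criteria

All in-memory intervals are 0-based half-open (BED convention); readers
convert on ingest (GFF3's 1-based inclusive coordinates included) and
writers convert back. Three half-overlap criteria recur and are kept
distinct because their wordings differ:

| rule | test | used for |
|---|---|---|
| reciprocal_half | overlap **>** len/2 of *each* interval | DC vs non-DC, three-way site partition |
| either_half | overlap **>** len/2 of *either* interval | merging adjacent peaks |
| one_sided_half | overlap **≥** len/2 of the *focal* interval | cross-species conservation |
| center_within | partner's center/summit inside the interval | cis-element assignment |

"Larger than half" is implemented strictly (>), "at least half"
non-strictly (≥). For odd lengths the half-length is the exact rational
len/2 compared against the integer overlap, so the two members of a pair
are treated symmetrically; both thresholds are configurable at the
function level. Peak merging is a single left-to-right pass over peaks
sorted by (chrom, start, end), transitive within the pass, with input
indices recorded as provenance.

Whether a single criterion was intended for merging versus conservation
is not determinable from the procedure descriptions; both are implemented
as worded, and reports always state the rule used.

## Ortholog projection

The ortholog map is a set of equal-length interval block pairs,
non-overlapping on both sides (one-to-one). Projection intersects the
query with the blocks, maps each piece linearly (minus-strand blocks
reverse within-block offsets), and returns the minimal destination
interval spanning the pieces. Pieces on several destination chromosomes
are resolved by largest projected length, ties by lexicographically first
chromosome — a documented determinism choice; how split projections were
resolved originally is not specified. Full chain-gap arithmetic is out of
proportion for interval-level orthology: a UCSC-chain ingest collapses
aligned runs to blocks, and block semantics are the contract.

## Turnover and conservation

Presence/absence compares the highest linear fold-enrichment (FE) over
the peak to the highest FE over the orthologous region extended by half
its length on each side. "Reduced 10-fold or more" is read literally on
linear FE: absent iff other ≤ own/10, boundary inclusive. A peak with
zero own-signal cannot meaningfully be tested (own/10 = 0) and is called
present with a warning. The half-length extension applies only to the
presence/absence search, not to the conservation test, which follows the
procedure as written.

Conservation projects the focal peak into the partner's coordinates
(direction configurable; the default matches the "mapped onto the
orthologous regions of the other" phrasing) and requires ≥ half of the
projected region to be covered by the union of same-protein partner
peaks. Unmappable peaks are counted unconserved but carry a separate
`mappable` flag so the two causes are not conflated.

## DC classification and the three-way partition

DC status is a boolean reciprocal-half overlap with any MSL2 region on
pre-merged (within-protein) peak lists; many-to-one overlaps count once.
The seven-class MOF/MSL1/MSL2 membership partition links regions across
proteins by reciprocal-half overlap and counts each connected group once
under the set of proteins it contains (Venn semantics: three identical
intervals contribute one triple region). Merge scope — within protein
first, then cross-protein membership — is a documented choice where the
original bookkeeping is ambiguous. Chromosome classes are X = {X, chrX},
autosome = {2L, 2R, 3L, 3R} (chr-prefixed accepted); chromosome 4 and
unplaced scaffolds are "other" and excluded from autosomes, matching the
published table's convention. Both name lists are parameters.

## Extended McDonald–Kreitman test

Per site class with length L: D counts sites fixed in the ingroup and
differing from the outgroup; P counts segregating sites;
P(−singleton) excludes sites whose minor allele count is exactly 1
(computed after dropping samples with missing calls — the standard
definition; missing-data handling is not otherwise specified). A site
polymorphic in the ingroup is never D, keeping D and P disjoint. Sites
without outgroup information are unusable. The estimator is

    alpha = 1 − (D_neut · P_sel) / (D_sel · P_neut)

on singleton-excluded P for both classes. This is the classical
divergence/polymorphism contrast estimator; it was verified by exact
recomputation of all eighteen published class estimates from the printed
count columns before being frozen into the implementation
(`tests/test_acceptance.py` re-runs that check to 3 decimal places).
alpha is NaN when any of the four counts is zero. Fisher's exact test is
two-sided on [[D_sel, P_sel], [D_neut, P_neut]] (scipy); a flag switches
to singleton-inclusive P, but singleton-excluded is the default per the
published table's own convention. X-linked selected classes must be
paired with X-linked four-fold controls and autosomal with autosomal,
because the two chromosome classes differ in effective population size
and selective regime.

Four-fold degenerate sites are third positions of codons whose amino
acid is invariant to any third-base change under the standard nuclear
code; the prefix set is cross-checked against Biopython's codon table in
the tests. CDS segments are concatenated in transcript order and
reverse-complemented on minus-strand genes; genes with CDS length not
divisible by 3 are skipped with a warning, codons containing ambiguity
codes are skipped. Per-gene MK uses Fisher on [[Dn, Pn], [Ds, Ps]] with
Benjamini–Hochberg correction across genes (statsmodels) and flags an
excess when Dn/Ds > Pn/Ps at q < 0.05 (threshold configurable).

## TE pipeline

Cleaning order: (1) drop hits overlapping microsatellite intervals;
(2) union-merge overlapping same-family hits; (3) sort by length
descending and truncate each insertion by the regions already accepted —
when truncation splits an insertion the longest surviving fragment is
kept (preserves the longest-first priority; the original is silent on
splits); (4) drop anything under 100 bp. After cleaning, insertions of
different families never overlap (asserted in tests).

TE-derived site calling offers both rules in circulation: half_overlap
(≥ half the peak inside a *single* insertion — overlaps are not summed
across insertions) is the default; center_in_te (summit inside an
insertion) is selectable, and reports name the rule used. Family
enrichment is LOR = log₂((n_f/L_f)/(N/G)) with families at LOR ≥ 1.5
called enriched; family lengths and the genome size are computed from
the provided annotation rather than hard-coded. Motif counting is exact
overlapping string matching on forward plus reverse-complement strands,
deduplicated by forward position — a deliberately simple occurrence
counter with no p-value model; it is suitable for short unambiguous
motifs (GAGA, CACA, GCA) and nothing more.

## Cis-regulatory overlap

Default rule: an element is assigned to a site when the element's
center/summit lies inside the site (half-open, so a center at the end
coordinate misses). The half-length variant (shared region ≥ half of
either the site or the element) is a flag. A site may hit several
categories; category counts are deliberately redundant while the total
row counts distinct sites. Inputs must share one coordinate system;
chromosome-name intersection is validated and coordinate lift-over is
out of scope.

## Expression divergence

TPM values are averaged across biological replicates per gene × species
× sex; genes absent from one species leave the orthologous set with a
warning. Expression changes use (x − mean)/sd per species with the
sample (n−1) standard deviation — a documented choice, configurable, as
the convention is not stated. Gene groups: a gene is unconserved-BS+ if
any unconserved non-DC site overlaps its strand-aware window (2 kb
upstream of the 5′ end plus the whole annotated gene body, introns and
UTRs included) by ≥ 1 bp; else conserved-BS+ if a conserved site does;
else BS−. TE+ marks any cleaned insertion in the same window. Window
intersection is any-overlap, not a half rule — the grouping criterion is
the presence of a site, not an overlap fraction.

Group divergence is the group-level statistic 1 − ρ (Spearman, average
ranks on ties) between the two species' mean-TPM vectors over the
group's genes — the group-level reading is the one consistent with a
per-group bootstrap. Uncertainty comes from resampling genes (not
replicates) with replacement, 1,000 draws by default, fully seeded.
Groups of fewer than 3 genes return no estimate. Group comparisons use
two-sided Mann-Whitney U on the bootstrap distributions; bootstrap draws
are not independent observations, so these p-values describe separation
of resampling distributions rather than a calibrated test — the
procedure mirrors common practice for this statistic and is reported
with that caveat.

## Synthetic data: what it emulates and what it does not

The generator produces two collinear coordinate systems joined by
alternating equal-length ortholog blocks (default 5 chromosomes × 1 Mb,
90% block coverage), peaks on a collision-free grid inside blocks with
linear FE in [5, 50], a 10% species-specific gain fraction (partner
signal strictly below own/10; shared peaks strictly above), MSL2
concentrated 97% on the X, and a configurable fraction of MOF/MSL1
peaks planted on MSL2 regions. Variant classes use fly-like densities
(divergence 0.161/bp, singleton-excluded polymorphism 0.087/bp,
singletons 0.022/bp, a 197-chromosome sample); a chosen true α is
realised through D_sel = (D_neut/P_neut)·P_sel/(1 − α). Expression
tables share a log-normal baseline between species with group-scaled
between-species noise (sd 0.8 / 0.4 / 0.15 for unconserved-BS+ / BS− /
conserved-BS+) and replicate noise sd 0.1 on the log scale.

One integer seed drives named substreams (SeedSequence keyed by
generator name), so adding a generator never perturbs another's draws
and regeneration is byte-identical.

None of this is sequence-realistic: there is no coalescent, no linkage,
no indels, no motif content, no read-level noise, and block orthology has
no within-block gaps. Passing recovery tests therefore demonstrates that
the estimators are correct under their own assumptions — unbiased α
recovery at realistic class lengths, exact turnover-label recovery for
signals off the 10-fold boundary, LOR recovery of a planted 8× family —
not that the pipeline is robust to alignment error, mapping bias or
annotation noise in real data.

## Problem sizes and numerical choices

Replicated studies in the test suite run at sizes chosen to make
sampling error negligible relative to the tolerances they assert:
α recovery uses Poisson per-class counts at class lengths of 2.0/3.5 Mb
(100 replicates per α value) rather than explicit per-site streams,
which the generator also provides and which the end-to-end tests use at
smaller lengths; expression ordering uses 100 replicates at 500 genes
per group with 1,000 bootstrap draws; TE enrichment uses 20 replicates
with ~800 expected sites in the planted family. Fisher p-values come
from scipy's exact implementation even at genome-scale counts.
Degenerate inputs are defined rather than left to float arithmetic:
D/P is NaN at 0/0 and +inf at D>0/P=0; α is NaN when any count is 0;
LOR is −inf for zero observed sites and NaN for zero family length.

## Known limitations

* Motif occurrence counting replaces p-value-based motif scanning; counts
  for degenerate or long motifs would not be comparable.
* The ortholog map carries no within-block indels; projections through
  real reciprocal-best chains are approximated at block resolution.
* Genome-scale site counts from the original ChIP experiments cannot be
  regenerated from synthetic data; only the printed count arithmetic and
  the estimator behaviour are verifiable at desk scale.
* Mann-Whitney on bootstrap distributions overstates certainty (see
  above); effect direction and magnitude are the meaningful outputs.
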