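# Methods

`polymaps` reconstructs the subgenome structure of an allo-octoploid F1
cross from targeted-capture sequencing: it calls single-homeolog markers
from pileups, builds per-parent linkage maps, attaches phylogenetic markers
to linkage groups through shared reads, labels the four subgenomes against
diploid reference taxa, and scans the labelled maps for interhomeolog
introgression and interchromosomal rearrangements.  This note records the
models, rules and numerical choices, and what the synthetic test bed does
and does not establish.

## Genotype model

Sequencing of an octoploid samples eight homeologous haplotypes, so a
variant heterozygous at a single homeolog appears at roughly 1/8 read
frequency.  Calling is threshold-based rather than likelihood-based,
because no polyploid genotype-likelihood model distinguishes allele dosage
reliably at these depths:

* **HET** — rare variant seen ≥ 2 times at ≥ 2.5 % frequency;
* **HOM** — no rare variant, or one copy at < 1.25 % (treated as a
  sequencing error);
* **MISSING** — depth < 32×, or anything between the rules (including a
  single rare read at ≥ 1.25 %, and a tie between two rare bases — the
  rules presume a biallelic rare variant).

Frequency comparisons use integer cross-multiplication, so the 2.5 %/1.25 %
boundaries are exact at every depth (2 of 80 reads is heterozygous; 1 of 80
is missing, not homozygous).  Depth counts A/C/G/T calls only; ambiguity
codes and indel events are consumed without contributing, because the
frequency thresholds are defined on called bases.

A site becomes a linkage-map marker (LG SNP) when exactly one parent is
HET, both genotype classes appear in ≥ 8 progeny (the Mendelian 1:1
screen), and at most one progeny is missing.  Sites HET in both parents are
held out as the *biparental* set used only to pair maternal with paternal
linkage groups.  Adjacent SNPs < 1 kb apart share a *region*; regions are
the unit of the downstream homoplasy tallies.

The diploid-cross filter is separate and likelihood-based: a genotype is
valid at depth ≥ 20 with best Phred-scaled likelihood 0 and all others
≥ 40; a site is kept with < 8 missing offspring, no genotype class above
85 % of offspring, and offspring producible from the parental pair under
Mendelian inheritance.

## Linkage maps

Each LG SNP's progeny vector is binary (testcross configuration).  For a
pair with n complete progeny and k matches under the better phase,
r̂ = (n−k)/n (clamped to [10⁻⁶, 0.5]) and
LOD = k·log₁₀ 2(1−r̂) + (n−k)·log₁₀ 2r̂.  Groups are single-linkage
closures over pairs with LOD ≥ 5; the full pairwise matrix is never
materialised (blocked edge discovery, identical output).  Within a group,
markers are ordered by greedy nearest-neighbour seriation on r̂ (ties by
reference position), distances use the Kosambi function
d = 25·ln((1+2r)/(1−2r)) (Haldane available), and groups split at gaps
> 33 cM.  Split pieces from the same LOD cluster that share a modal
reference chromosome are re-joined automatically and logged — a
deterministic stand-in for the visual-inspection joins used on real maps.
Pieces from *different* clusters are never merged on reference position
alone, because homeologous groups share reference chromosomes by
construction; a label-aware join is available after subgenome labelling.
Groups with < 5 LG SNPs are "minor" and excluded from analysis.  Each
group's primary chromosome is the modal chromosome of its markers (ties to
the smaller identifier, logged).

Maternal/paternal group pairing uses the biparental SNPs' segregation
rather than shared positions: a biparental SNP's homozygous progeny
inherited neither parent's minor haplotype, so its HOM indicator
co-segregates, in one phase or the other, with the true linkage group of
each parent.  Each biparental SNP votes for the (maternal, paternal) pair
with the strongest phase-maximised agreement (threshold 0.65, roughly
midway between the 0.75 expected for the true group and the 0.5 null), and
votes feed a maximum-weight bipartite matching.  A purely positional weight
is degenerate whenever several groups cover the same capture targets.

## Anchored phylogenetic markers and subgenome labels

Reads carrying an LG SNP's minor allele sample one haplotype of one
subgenome.  Within a read length (default 100 bp, the capture-probe
length) of the anchor, any site that differentiates other linkage groups
and/or the diploid taxa becomes a phylogenetic marker for the anchor's
group: qualifying reads are pooled per group and a strict-majority
consensus is taken per site (ties yield missing data; minimum qualifying
reads defaults to 1, configurable for noisy data).  LG SNP positions
themselves are excluded — they were ascertained to be subgenome-private
and carry no phylogenetic signal.

Per haploid chromosome, the site × taxon matrix holds that chromosome's
linkage groups (both parents), the vesca-like and iinumae-like diploid
taxa, and an outgroup; most octoploid cells are missing because a group is
only observed where it has a nearby anchor.  Trees are neighbour joining on
p-distances with pairwise deletion; taxon pairs sharing no sites get the
maximum observed distance and are logged.  The matrix exports to relaxed
PHYLIP for external maximum-likelihood analysis; the internal NJ tree
exists for labelling and testing, not as a substitute for ML.

Labels: Av is the group set in the minimal clade containing the vesca-like
taxon but not the iinumae-like taxon; among the rest, Bi sits in the
minimal clade containing the iinumae-like taxon; of each parent's final
two, B1 is the more divergent from the iinumae-like taxon.  Because
ascertained-site matrices with heavy, structured missingness can distort
NJ (distances are inflated ~6× relative to true divergence, and group rows
share only about half their sites), a parent whose clade assignment is
inconsistent but has all four groups falls back to a deterministic
divergence ranking (Av = closest to vesca; then Bi = closest, B1 =
farthest from iinumae) — the same criterion the tree rule already uses for
B1/B2.  Anything else is reported `unresolved`, never guessed.

## Introgression scan

For a site with non-missing bases for a subgenome, both ingroup diploid
taxa and an outgroup, only 2:2 patterns are informative: *supportive*
(subgenome with its sister; other two together), *introgression-like*
(subgenome with the wrong ingroup taxon; sister with the outgroup), or
*outgroup homoplasy* (subgenome with the outgroup; the two ingroup taxa
together).  Without introgression the last two arise from the same
processes (independent mutation, lineage sorting, error) and are equally
frequent; the excess test is an exact two-sided binomial against 0.5 on
the region counts, with a Fisher variant against an exact 50:50 row
reported alongside.

Regions mix site classes: a region with both supportive and
introgression-like sites *for the same parental sample* is
support/homoplasy and counts against introgression.  A cluster is any
maximal run of regions starting and ending at introgression-like regions,
containing ≥ 2 of them, with introgression:supportive-side ratio ≥ 4
(support/homoplasy counts on the supportive side; outgroup regions are
neutral; an all-introgression window qualifies at any length ≥ 2).  The
window rule is not uniquely determined by a verbal description, so the
implementation is defined as "all qualifying windows, overlapping windows
merged", and the test suite pins it to an independent brute-force
enumerator over every track up to length 12.  Cluster intervals span first
to last member marker site; geometry (span quantiles, genomic union,
cross-subgenome overlap extent) is computed on those intervals.
Directionality is a Fisher exact test of observed cluster directions
against a 3:1 expectation (three iinumae-like subgenomes versus one Av).
Corroboration uses vesca-like:iinumae-like allele-depth ratios (combined
depth 45–200×, ratio within [1/8, 8], 1-Mb bins, Welch t in- versus
out-of-cluster).

## Rearrangement scan

A rearrangement is an LG SNP whose group's primary chromosome differs from
the SNP's own mapping position; the restricted set keeps events within
1 kb of a capture target.  The clustering null redistributes the events
independently and uniformly over all targeted regions that carry LG SNPs
("randomly distributed" read as independent placement; a
without-replacement variant is provided for sensitivity).  Each of the
10,000 replicates records the number of regions with ≥ 2 events and the
mean co-occupancy per event; intervals are empirical 2.5/97.5 percentiles.
For 105 events over 2,598 regions the expected co-occupancy is
(105−1)/2598 ≈ 0.040 and the expected multi-occupied regions
2598·P(Bin(105, 1/2598) ≥ 2) ≈ 2.1; the replicate distribution of the
latter is near-Poisson, so its honest 95 % percentile interval is (0, 5).
Copy-number corroboration normalises each sample's central-site depths to
sum to one and Welch-compares octoploid:diploid ratios at rearranged
versus other targeted regions.  In-silico PCR places SSR primer pairs by
exact matching (forward primer plus-strand, reverse primer's reverse
complement downstream, 3′ ends ≤ 2 kb apart); an allowed-mismatch
parameter exists but defaults to 0.

## Scaffold ordering

Anchored scaffolds are ordered by the median map position of their
anchors (ties by prior-assembly rank), flipped when within-scaffold anchor
order anticorrelates with map position (single-anchor scaffolds keep the
prior orientation), split at the midpoint between anchors mapping to
different groups, and concatenated with fixed 10-kb N gaps.  Synteny
stretches are maximal runs of identical partner-genome chromosome labels
in a positionally ordered ortholog list.

## The synthetic cross

The generator encodes the inferred history directly: an ancestor splits
into a vesca-like lineage (vesca-like diploid + subgenome Av) and an
iinumae-like lineage whose radiation yields B1, B2 and the
(iinumae-like diploid, Bi) clade, with a distant outgroup.  Substitutions
are equal-rate and independent per branch (Jukes–Cantor-like; downstream
logic only consumes base-identity partitions).  Default branch rates
(substitutions/site) — outgroup 0.06, vesca stem 0.02, iinumae stem 0.015,
B1 0.010, B2 0.006, iinumae/Bi stem 0.004, terminals 0.004–0.006, parental
private variation 5×10⁻⁴ — give B1 the greatest iinumae divergence and
realistic capture-window variant densities (~10–15 % of sites variable
across all taxa).

Introgression is wholesale tract replacement by the vesca-lineage
ancestral sequence (agnostic between homoploid hybridisation and
homeologous exchange); default six 60-kb tracts on B subgenomes, so each
covers several capture targets.  Transpositions are copy-and-paste: a
target window of one subgenome is duplicated onto an acceptor chromosome
of one parental haplotype, inflating donor-window depth by 9/8 in carriers
(a "fixed" variant duplicates every haplotype, doubling octoploid depth);
a marker mutation is planted on the copy at a site chosen to be invariant
across all parental haplotypes, so the only variant there segregates with
the acceptor chromosome.  The cross is disomic: per parent per subgenome
each progeny receives one recombinant haplotype (Poisson crossovers, mean
1 per chromosome, uniform positions), with no exchange between subgenomes.

Capture emulates probes around central targeted sites: every read covers
its target's centre, so `depth` (default 80×) is the per-individual
central coverage, tapering linearly within ±100 bp.  Single-subgenome
heterozygous sites are planted at fixed offsets from each centre (−20 to
−2 bp for the maternal parent, +4 to +22 for the paternal, one offset per
subgenome; a biparental site at −26 on every fourth target), so every
target can yield LG SNPs for all eight parent × subgenome maps — the
deterministic equivalent of a per-parent heterozygosity rate of ~4 sites
per capture window.  Per-base errors (default 0.2 %) flip read bases
independently at the scored variant sites; error-only sites elsewhere are
not emitted, since a singleton error away from a variant site can at most
produce a HOM or MISSING call at an otherwise invariant position.  A
diploid vesca-like reference individual is sequenced alongside for depth
normalisation.  Everything is deterministic given the seed, including
per-target read blocks (re-derivable in any order).

### What the test bed shows — and does not

The noise-free test bed (error 0, 64 targets/chromosome, otherwise the
full cross) establishes mechanics: 99.5 % of truly single-parent-het
planted sites return as LG SNPs; 28 major groups per parent with correct
primary chromosomes; 56/56 subgenome labels; all planted tracts recovered
with no false Av cluster; planted transpositions detected with correct
donor/acceptor chromosomes.  At the full-scale defaults with 0.2 %
per-base error, recovery collapses (≈ 0.24) — not from a software defect
but from the calling rules themselves: a homozygous sample with exactly
one erroneous read at a site has rare-allele frequency 1/d ≥ 1.25 %
whenever d ≤ 80 and is coded MISSING, and the ≤ 1-missing-progeny screen
then rejects most sites (retention ≈ (1+λ)e^{−λ} with λ ≈ 2 ambiguous
progeny per site).  This sensitivity of threshold callers to the
error-rate × depth interaction is a real property of the method and is
reported as such by the full-scale test rather than smoothed over.  The
generator also omits capture-efficiency bias, indels, mapping error,
paralogous collapse and polysomic inheritance, so passing tests bound
correctness of the implementation, not performance on real libraries.

## Problem sizes

The suite's standard cross uses 7 × 1 Mb chromosomes with 64
targets/chromosome (one session-scoped run, ~15 s); the full-scale run
uses the generator defaults, 300 targets/chromosome (~45 s).  The
permutation null runs its full 10,000 replicates everywhere.
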