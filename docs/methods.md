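# Methods

This note documents the statistical model behind `comotif`, its tunable
parameters, the synthetic data used to validate it, and the numerical and
design choices made where the procedure admitted more than one reading.

## Binding-site model

A PWM is a matrix of per-position base frequencies. A window of the genome
is scored as the log-odds (bits) of the window under the PWM versus an
i.i.d. mononucleotide background; a pseudocount of 1e-3 is added to the
frequencies (and renormalized) so the log-odds are finite. Per-column
scores are discretized onto an integer grid (1000 bins per column, a
configurable knob) and convolved column by column under the background to
give the exact null distribution of the discretized score; the p-value of a
score is the null probability of a score at least as large. A window is
reported when its p-value is at or below the scan threshold (default
1e-4), on either strand; the reverse strand is scored with the
reverse-complemented score matrix so the same p-value table applies
exactly. Windows containing N are skipped, and sites overlapping annotated
coding exons by ≥ 1 nt are removed. The background model is the
genome-wide mononucleotide composition; no higher-order model is used.

Column information content is IC = 2 + Σᵢ pᵢ log₂ pᵢ bits (0·log₂0 := 0).
Leading and trailing PWM columns with IC < 0.2 are trimmed before
scanning; interior columns are never removed.

## Conservation: branch length scores and percentiles

For a site on the reference genome, every other species' alignment row is
scanned with the same PWM and threshold; a species is a *conserved
instance* when it has a match (either strand) starting within ±10
alignment columns of the site. Offsets are counted in alignment columns,
which is well defined for every row (for the gapless alignment dialect the
two conventions coincide). The matched set always includes the reference.

BLS is the total branch length of the minimal subtree spanning the matched
leaves divided by the total tree length; it is 0 when only the reference
matched and 1 when all species matched. Internally an edge contributes iff
the matched set is split by it, evaluated with precomputed leaf bitmasks
(O(edges) per site, memoized per matched set).

An isolated match in a distant species can dominate BLS spuriously. All
species are ranked by patristic distance from the reference (ties broken
by name); with m1 and m2 the most and second-most distant matched species,
m1 is discarded *before* BLS when more than four species lie strictly
between their ranks and dist(m1) > 2·dist(m2). The species between m1 and
m2 in rank are necessarily unmatched, so the two published readings of
"gap of more than four species" coincide under this ordering. At most one
species is ever removed.

Per motif, a site's conservation percentile is the fraction of that
motif's sites with strictly smaller BLS (values in [0, 1); ties share the
lower value). Downstream stages use two operating points: the top 20% most
conserved sites (percentile ≥ 0.8) for network-level evaluation, and a
floor of 0.6 for pair analysis, where lower-quality sites are admitted but
down-weighted by the percentile itself.

## Accessibility

A site's accessibility score in a condition is the mean per-base signal
over the site extended by 50 nt on each side (clipped at chromosome
bounds). The window is anchored at the site's edges, not its midpoint, so
long motifs remain fully covered. The per-stage threshold is the
nearest-rank (1 − 0.05) quantile of the pooled per-base scores of that
stage's track (bedGraph runs expanded by length); a site is accessible iff
its score strictly exceeds the threshold, so ties at the threshold are
inaccessible.

Stage dynamics: a motif's normalized degree in a stage is its
accessible-site count divided by the total over all motifs in that stage
(degrees sum to 1 per stage); the variation ratio is max/min over stages
(+inf when the minimum is 0, excluded from histograms); the centered
degree divides by the motif's mean degree across stages. The null permutes
each site's binary per-stage accessibility vector independently and
uniformly across stages and recomputes everything.

## PWM clustering and composition strata

Similarity between two PWMs is the maximum over all end-gapped column
offsets and both orientations of Σ wᵢ·PCC(xᵢ, yᵢ) / Σ wᵢ, where matched
columns weigh wᵢ = √(ICx·ICy) and each unmatched end column adds IC/2 to
the denominator with a zero numerator (a pure penalty). PCC is computed
over the 4 base frequencies; a zero-variance column yields PCC 0. Offsets
with fewer than two matched columns are skipped. Average-linkage
clustering is cut so that every merge inside a flat cluster has similarity
≥ 0.8. The representative of a cluster is its lexicographically smallest
TF name; centroids average members over the anchor columns covered by all
members after best-offset alignment.

Composition clusters — the strata of the shuffling null — are built from
the centroid's column-mean base composition minus the genomic background.
Clusters in the bottom 10% by composition standard deviation (weak base
preference; strict rank, ties by id) go to "others"; the rest are
average-linkage clustered on max(PCC(u,v), PCC(u, revcomp(v))) cut at 0.8,
and groups of fewer than five members are merged into "others", which
itself remains a stratum.

## The co-localization statistic

With one motif fixed as the *pivot*, for every pivot site and every other
motif only the nearest other-motif site on each side within 1000 nt is
paired (distance = gap between nearest interval edges; overlap = 0; side
by midpoint, ties to the right; distance ties broken by start coordinate).
Pair weight = min of the two conservation percentiles. Weighted counts
accumulate in ten 100-nt bins. Homotypic pairs are excluded.

The null permutes motif identity labels uniformly within each
(chromosome × composition cluster) stratum of the analyzed site set
(percentile ≥ 0.6, accessible in the stage), leaving positions, strands
and percentiles attached to the genomic records; all sites of the pivot
motif are frozen — neither relabeled nor used as shuffle targets. The
empirical p of a bin is the fraction of randomizations whose weighted
count is ≥ the real count (no +1 correction; the minimum attainable p is
0). Only bins whose real count reaches 1% of the total percentile mass of
*both* involved motifs are tested; BH correction is applied per
(pivot, stage) family over all eligible (other motif, bin) tests, and
significance for calling is read off the [0, 100) bin. A pair is called
when the first bin passes FDR ≤ 0.05 with either motif as pivot and the
smaller of the two directions' first-bin weighted counts is ≥ 10. The
per-stage enrichment ratio of a pair is the mean over the two pivot
directions of (real first-bin count)/(mean shuffled first-bin count);
centered ratios divide by the mean over stages; a stage with zero null
mean is excluded with a warning.

Each (pivot, stage) work unit draws its RNG stream from the master seed by
stable hashing (CRC32 of "stage:pivot"), so results are independent of
execution order and byte-identical across runs.

## Synthetic studies

The generator emulates the study design end to end: a reference genome
drawn i.i.d. from the genomic base composition (defaults to the
*D. melanogaster* genome composition A 28.87 / C 21.15 / G 21.11 /
T 28.86%); 11 further species' rows evolved along a 12-leaf
Drosophila-shaped phylogeny by Jukes–Cantor substitution per branch
(gapless rows, so alignment columns equal reference coordinates); and
five stage tracks of clipped Gaussian noise plus high plateaus covering
just under 5% of each chromosome.

Planted features carry their own ground truth. Motif instances are copied
intact into the rows of a reference-anchored distance-rank prefix of the
species (chosen to meet a target BLS; the achievable values are exposed,
and an unreachable target raises an error listing them) and scrambled in
all other species, so downstream BLS is controlled exactly. Per motif
there are non-conserved, mid-conservation and conserved-accessible decoy
sites; the latter give every motif analyzed sites in every stage. Planted
pairs are consensus-A, random gap (≤ 80 nt), consensus-B words placed in
dedicated narrow plateaus of the designated stage.

Three generator policies keep the planted truth identifiable, i.e. make
the truth table sufficient to predict the pipeline's output:

- every pair occurrence gets its own plateau, so the shuffling null at
  pair sites measures identity exchange rather than local site crowding;
- the two partner motifs of a planted pair never share a decoy plateau,
  so the planted adjacency is the *only* A–B adjacency and off-stage
  enrichment ratios are exactly 0;
- motif consensi are rejection-sampled so that no two motifs share a
  near-identical (≤ 1 mismatch) aligned subword of ≥ 6 columns in either
  orientation — otherwise one motif's scanner fires inside another's
  planted instances and manufactures spurious co-localization.

What the generator does *not* emulate: indels and alignment error,
rate variation across sites and branches, nucleosome structure or graded
accessibility, motif self-overlap/homotypic clustering, and realistic
PWM degeneracy (planted motifs are sharp). Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
performance on real chromatin data.

Default study conditions: 2 chromosomes × 100 kb, 20 motifs of width 8
from three base-composition archetypes (so composition strata are
non-trivial), 5 stages, one planted pair with 40 occurrences in stage S5;
per motif and chromosome 150 non-conserved and 20 mid-conservation decoys,
plus 5 conserved accessible decoys per stage (2 for pair motifs) at BLS
tiers ≈ 0.78/0.87/1.0. These sizes keep a full pipeline run (including a
1,000-randomization null for every pivot and stage) around 10 s on one
CPU, and were chosen so that per-motif site counts (~300–500) give stable
percentile tiers above the 0.6 analysis floor while chance matches
(~40 per motif, by construction of the p ≤ 1e-4 threshold) stay below it.

## Numerical choices and degenerate inputs

- Score discretization: 1000 bins per column; granularity below 100 is
  refused. The p-value table's total mass is exact to < 1e-9.
- PCC of zero-variance frequency vectors is 0; fully uniform PWMs have
  similarity 0 (with a warning) rather than NaN.
- Nearest-rank quantiles (no interpolation) for accessibility thresholds.
- Percentiles use strictly-smaller counts, so ties never inflate ranks;
  a motif whose sites all tie has every percentile 0.
- Empty categories/denominators yield NaN (reported missing) with a
  warning, never silent zeros: zero-site ChIP percent, zero null-mean
  enrichment ratios, infinite GO ratios (excluded from medians with the
  exclusion count warned).
- Edge-swap randomization performs the requested number of accepted swaps
  but gives up after 100·n + 100 proposals so rigid networks (stars)
  terminate with their degree sequence intact.

## Known limitations

- The BH family choice (per pivot × stage, all eligible bins) is one of
  several defensible readings; a global family would be more conservative.
- The empirical p-value has no +1 correction, so p = 0 occurs; FDR values
  of exactly 0 should be read as p < 1/n_rand.
- Cluster-level site merging keeps the maximum member percentile, which
  slightly favors clusters with many members.
- MAF input is supported but the per-block coordinate maps are exercised
  mainly through the gapless dialect the generator emits.
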