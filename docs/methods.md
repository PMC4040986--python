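# Methods

This note documents the models and procedures implemented in `darkbin`,
the defaults and the reasoning behind them, the numerical conventions, and
what the synthetic fixtures do and do not demonstrate about real data.

## Differential-coverage binning

**Model.** Contigs of one population genome share a coverage profile
across samples up to sequencing-depth scaling and sampling noise.
The binner therefore works on profile *shape*: each contig row of the
coverage matrix is mapped to `log10(coverage + pseudocount)` and scaled to
unit Euclidean norm, projected onto the top three principal axes of the
column-centered matrix (SVD; axes ordered by decreasing variance; the
first nonzero loading of each axis is made positive so the embedding is
sign-deterministic), and clustered by single-linkage agglomeration with a
fixed distance cut. The transform, projection and clustering are all
deterministic — there is no randomized initialization anywhere.

**Parameters.** `pseudocount` = 1 (guards zero coverage; in log10 units a
coverage of 0 maps to 0). `linkage_dist` = 0.05 in embedded units: unit-
norm profiles live on a sphere of radius 1, so 0.05 separates profiles
whose shapes differ by a few per cent while tolerating small noise.
`min_bin_size` = 5 contigs; smaller clusters are reported `unbinned`, as
are contigs with no coverage in any sample (their profile carries no
signal). Unit-normalized *logs* are exactly scale invariant only in the
limit of large coverage; at moderate coverage, proportional profiles are
close but not identical — acceptable because binning compares profiles of
similar depth within one community.

**Caveat.** This is a deliberately minimal, self-contained binner
operating on coverage alone. It does not use tetranucleotide composition,
GC, read linkage, or chimera splitting, and it will merge populations
whose abundance profiles happen to coincide across the available samples
(more samples help). Contigs, not scaffolds, are the unit.

## Marker census and quality gate

Completeness = `100 × (distinct markers found) / marker-set size`;
contamination = `100 × (markers found in more than one copy) / marker-set
size`. The denominator is the **full** marker-set size (105 by default) in
both cases — with found-markers as denominator the reference census values
the implementation is checked against cannot be reproduced. Two hits of
one marker count as multi-copy regardless of whether they fall on the same
or different contigs. Percentages are reported to one decimal, rounded
half away from zero (presentation convention of the census tables this
mirrors). The quality gate is strict: completeness must *exceed* 60% and
contamination must be strictly *below* 10%.

Marker identification itself (profile HMM scanning of translated contigs)
is outside this package; the census consumes a per-contig hit table. The
bundled marker-id list is a synthetic placeholder naming 105 ids
`M001..M105` — any id list of the appropriate size can be supplied.

## Taxonomic-consistency scoring of gene trees

For a taxonomy clade *c* and an edge of the unrooted gene tree splitting
the leaves into sides *R* and *L*: *T*(*c*) is the number of genomes of
*c* present in the tree, *N<sub>x</sub>*(*c*) the number of members of *c*
on side *x*, and *I<sub>x</sub>*(*c*) = |side *x*| − *N<sub>x</sub>*(*c*)
the intruders. The node's consistency for *c* is
`max_x (N_x(c) − I_x(c)) / T(c)`, floored at 0. This form uses exactly
those quantities, equals 1 iff some edge isolates the clade (perfect
monophyly), and is penalized symmetrically by missing members and by
intruders. A clade's consistency is the maximum over all edges (pendant
edges included — harmless, since eligible clades have ≥ 5 members and a
pendant side can score at most 1/T). 

Per rank (domain, phylum, class), clade consistencies are averaged over
clades with at least `min_genomes` = 5 genomes **in the tree**; the tree
score is the unweighted mean of rank averages over ranks that have at
least one eligible clade (a rank with none is dropped from the mean rather
than scored 0 — scoring it 0 would let taxon sampling, not topology,
decide retention). Leaves missing from the taxonomy count as intruders for
every clade. Trees with tree score strictly below `threshold` = 0.86 are
discarded from the concatenation set; a score of exactly 0.86 is retained.

Note one structural property: a clade containing *every* leaf of a tree
can never reach consistency 1 (no proper side holds all leaves), topping
out at (n−1)/n via a pendant edge. Scoring is therefore most meaningful
when trees contain outgroups to each scored clade.

## Masking, concatenation, distances, NJ, bootstrap

**Masking.** A column is removed when its gap fraction strictly exceeds
`max_gap_fraction` = 0.5 (a column gapped in exactly half of the rows is
kept) or when every non-gap character in it is an ambiguity code
(non-ACGT for nucleotides; non-standard letters for amino acids). Column
order is preserved; full dynamic-programming block selection as performed
by dedicated masking tools is not reproduced.

**Concatenation.** Blocks are concatenated in input order over a declared
genome universe; a genome absent from a block receives a gap run across
that block's span. Block coordinates are recorded as 0-based half-open
column spans.

**LogDet distance** (nucleotide): with `F` the 4×4 joint relative-
frequency matrix over columns unambiguous and ungapped in both sequences,
and `f_x`, `f_y` the marginals,
`d = −(1/4)[ln det F − (1/2) Σ_k ln(f_x,k · f_y,k)]`.
LogDet is consistent under general Markov substitution and thus robust to
base-composition drift between lineages. A pair with `det F ≤ 0` or a
missing base in a marginal is *saturated*: building a full distance matrix
then fails with an error listing the offending pairs (a silent NaN would
poison tree building); during bootstrap such replicates are skipped and
counted. Tiny negative values from rounding are clamped to 0. Amino-acid
supermatrices fall back to a gap-excluded normalized mismatch distance,
flagged as `mismatch` in the distance matrix; the distance arm of this
package is exercised on nucleotide data.

**Neighbor joining** is the standard Q-criterion agglomeration with the
usual limb-length formulas. Tie-breaks are deterministic: among pairs
minimizing Q (within a relative tolerance of 1e-12), the lexicographically
smallest pair of cluster keys is joined, a cluster's key being its
smallest leaf label. Negative limb lengths are clamped to 0. The output is
an unrooted tree with a trifurcating seed node. On exactly additive
matrices NJ provably recovers the generating topology and branch lengths,
which the test suite verifies against path-length oracles and an
independent library implementation.

**Bootstrap.** Supermatrix columns are resampled with replacement
(`n_replicates` = 100, seeded); each internal bipartition of the original
tree is assigned the percentage of successful replicate trees containing
it, reported as an integer and attached to the edge's smaller leaf set.
Skipped (saturated) replicates are excluded from the denominator and
reported in a diagnostics field. Monophyly of a named group is true iff
some bipartition side equals the group exactly.

## 16S read-pair recruitment and clustering

A read passes the quality filter iff at least 85% of it aligned
(`aligned_frac ≥ 0.85`, inclusive) and its edit distance is strictly less
than 10% of its length (`edit_distance < 0.10 × read_len` — the strict
form follows the protocol's worked example of "fewer than 10 edits for a
100 bp read"; both thresholds are configurable). A pair survives iff both
reads pass and the patristic distance between the two mates' reference
leaves on the reference phylogeny is at most `radius` = 0.03 — the
mate-to-mate reading of the pair rule; branch-length distance is taken as
path (patristic) distance throughout.

Clustering is greedy: among unprocessed references, seed on the one with
the most assigned pairs (ties → lexicographically smallest id — the
descending-count order is the operative rule, and deterministic
tie-breaking makes runs reproducible), absorb every unprocessed reference
within the radius of the seed, emit, repeat. For cluster membership each
pair is attributed to its first mate's reference; after the concordance
filter both mates' references lie within one radius of each other, so the
choice does not affect which cluster a pair lands in at the separations
the method targets. Clusters partition the surviving pairs; per-cluster
interleaved read sets are emitted for *external* assembly (assembly is out
of scope). Lineage abundance is the fraction of surviving pairs per
lineage, attributing each cluster to its seed reference's lineage.

## Synthetic data

The generator emulates the study conditions the pipeline expects:

* **Communities.** Genome relative abundances per sample are
  lognormal(meanlog 0, sdlog 1) — no abundance model is prescribed by the
  protocol, and only the relative structure matters for binning; contig
  coverage = abundance × depth (default 10×) × lognormal multiplicative
  noise with log-sd `noise_sd` (default 0.05; exactly noise-free at 0).
  Contig lengths are uniform on 5–50 kb and enter only as metadata, since
  binning uses coverage alone.
* **Marker planting** places a requested number of distinct markers on
  random contigs of each genome, duplicating a requested subset onto a
  second contig.
* **Gene trees** nest classes within phyla within domains (uniform branch
  lengths, default 0.1); congruence *g* < 1 applies
  `round((1 − g) × n_leaves)` random leaf relocations, each implemented as
  a label swap between leaves of different classes.
* **Alignments** evolve along a given tree under the one-parameter
  symmetric (Jukes–Cantor) model — the simplest model with a closed-form
  expected mismatch `p = (3/4)(1 − e^{−4d/3})`, which the tests use as an
  oracle; root states are uniform.
* **Read pairs** map both mates to the reference leaf nearest (in
  patristic distance) a half-normal displacement with sd `placement_sd`
  from a designated source leaf, with aligned fractions and edit-distance
  ratios uniform over configurable ranges.

All randomness derives from one integer seed through per-operation child
generators, so identical seeds and arguments give byte-identical outputs.

**What the fixtures do not emulate:** sequencing error profiles, assembly
artifacts and chimerism, strain microdiversity, compositional effects
between samples, gene-specific rate variation, alignment error, or
database incompleteness. Passing tests demonstrate correctness of the
implemented statistics and algorithms under their stated models, not
end-to-end performance on real metagenomes.

## Pipeline and problem sizes

The end-to-end demo plants 12 genomes (2 domains/phyla/classes of 6) in 4
samples with coverage noise 0.02, six marker gene trees of which one is
simulated at congruence 0.3 (so marker selection has something to reject),
a supermatrix of ~10 kb evolved on a congruent species tree with all
branches ≥ 0.1 (signal-saturated, so a 100-replicate bootstrap should
support every true edge at ≥ 90%), and 60 read pairs from two reference
leaves separated by far more than twice the clustering radius. These sizes
keep a full run in the order of seconds while exercising every stage at
its defaults; all of them are configurable. The run directory contains one
subfolder per stage, a JSON config, a JSON report whose canonical
checksum is reproducible for a fixed config and seed, a manifest, and a
log (warnings — dropped references, skipped replicates — are always
logged, never silent).

## Known limitations

* The binner is coverage-only by design; see above.
* Contamination estimation counts multi-copy markers only; it cannot see
  contamination by a genome fragment carrying no markers.
* The consistency measure scores clades independently; it does not
  penalize a tree for nesting errors invisible to any single clade.
* LogDet requires all four bases present in both marginals of a pair;
  very short or extremely biased alignments saturate.
* NJ is used as the distance-arm tree builder; likelihood and parsimony
  inference are out of scope.
* 16S clusters are emitted for external assembly; no assembler is run.
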