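# Methods

This note records the models implemented in `barcodegap`, the default
parameters and why they were chosen, and the known limitations.

## Sequence handling

Sequences are uppercase IUPAC nucleotide strings (`ACGT`, the eleven
ambiguity codes, `-` for gaps, `N` for unknown). FASTA parsing is
delegated to Biopython; a species label may ride in the header after a
`|` separator. Alignment is assumed as input — the package never aligns;
all coordinate arithmetic is 1-based on the plus strand of the standard
658-bp COI barcode region, with closed intervals.

## Distances

The Kimura two-parameter model distinguishes transitions (A↔G, C↔T) from
transversions:

d = −½ ln[(1 − 2P − Q) √(1 − 2Q)]

with P and Q the transition and transversion proportions over
pairwise-complete columns. Columns containing a gap or any ambiguity code
in either sequence are deleted for that pair only (pairwise deletion),
which preserves information in sparsely degraded data at the cost of
per-pair site counts. If either logarithm argument is ≤ 0 the model has
no finite estimate; we raise `SaturationError` instead of substituting an
arbitrary cap, because silent caps distort downstream tree building.

Percentages shown to users are rounded half-up via `decimal.Decimal`, so
3.35 → 3.4 regardless of binary floating-point representation.

## Barcode gap and delimitation

For each ordered pair of species groups we compute within-group maxima
and between-group minima of the K2P percent distance. The gap verdict is

max(within_A, within_B) < t ≤ min(between_AB)

with default t = 2.0%, the conventional COI threshold for Lepidoptera and
the empirical hiatus in this genus. Singleton groups have undefined
within-group statistics (`None`), not zero.

Label-free delimitation is single-linkage: a union–find pass joins any
two specimens with distance strictly below the threshold. Single linkage
is the correct analogue of the gap criterion (a gap exists iff no
between-species link forms); it is deliberately not average or complete
linkage. Clusters are numbered by their lexicographically smallest member
so output is deterministic.

## Tree building

BioNJ (Gascuel 1997) generalises neighbour joining by propagating
first-order variances v(i,j) alongside distances. Pair selection uses the
standard Q criterion

Q(i,j) = (r − 2) d(i,j) − S_i − S_j,  S_i = Σ_k d(i,k)

with ties broken on the lexicographically smallest pair of representative
leaf labels, so the topology is reproducible. Branch lengths are the
usual b_i = ½ d(i,j) + (S_i − S_j)/(2(r − 2)); the reduction weight

λ = ½ + Σ_k (v(j,k) − v(i,k)) / (2(r − 2) v(i,j))

is clamped to [0, 1], and the reduced distances are
d(u,k) = λ(d(i,k) − b_i) + (1 − λ)(d(j,k) − b_j). On additive matrices
this recovers the generating tree exactly for any λ, which the tests
exploit as an oracle. Negative branch lengths are kept (and noted via the
logger) rather than zeroed, to preserve additivity of path lengths.

Bootstrap support resamples alignment columns with replacement
(`numpy.random.default_rng`), rebuilds the tree, and scores each internal
edge by the percentage of replicates containing the same bipartition.
Bipartitions are canonicalised as the side *not* containing the
lexicographically smallest leaf. Replicates whose resampled matrix
saturates are skipped and counted, never silently retried, so reported
support fractions are over successful replicates with the skip count
exposed.

## Diagnostic sites, ID tags and virtual PCR

A site is diagnostic for a set of groups when every group is fixed (one
unambiguous state across all its members) and at least two groups differ.
Primer matching is IUPAC set-intersection: a primer base matches a
template base when their base sets intersect, which correctly handles
degenerate primers (e.g. `R`, `W`) against ambiguous templates. Virtual
PCR requires exactly one binding site for the forward primer and exactly
one for the reverse primer (matched against the reverse-complement
orientation), with the forward site strictly upstream; violations raise
`AmplificationError` naming the failure.

Tag-window selection scores candidate windows by (minimum pairwise
difference count across species, number of diagnostic sites) in
lexicographic descending order, preferring smaller start positions on
ties and collapsing windows with identical site sets to the leftmost.

Species calling from a fragment collects, per covered diagnostic site,
the set of species consistent with the observed base. The verdict is a
species only when the intersection of these sets is a singleton;
conflicting non-empty backings with an empty intersection (or two or more
ambiguity-code observations) yield "contaminated"; a single ambiguity
yields "ambiguous"; no covered sites yields "no-match". This is
deliberately conservative: degraded museum extracts are exactly where
co-amplification happens.

## Morphometrics

Six genitalic measurements (a, b, c, d, h, l) map to

u = a/b + ½ · c/d,  v = h/l

— u summarising uncus/apex proportions, v valva proportions. Exact
linear separability of two labelled clouds is decided by feasibility of
the linear program w·x + b ≥ 1 for one class and ≤ −1 for the other
(scipy `linprog`); the ±1 margins turn strict separation into a closed
feasibility problem. When infeasible, the minimum number of
misclassifications over all linear boundaries is found by a direction
sweep: candidate normals are the perpendiculars and directions of all
point pairs plus the axes; for each, thresholds between consecutive
distinct projections are scanned. This is exact for points in general
position and never undercounts, which the tests verify against an
exhaustive pairwise-boundary oracle.

## Simulator

The simulator emulates the divergence *structure* of a multi-species COI
dataset, not molecular evolution per se:

- an ancestral sequence is drawn i.i.d. from the AT-rich composition
  (A, C, G, T) = (0.31, 0.15, 0.15, 0.39) typical of insect mitochondrial
  COI;
- per-species substitution counts n_i are solved from
  n_i + n_j = L·p(i,j), where p(i,j) inverts the target K2P distance at a
  fixed transition fraction κ/(κ+1) with κ = 4 (bisection); a triangle
  violation among the targets is an error, not a warning;
- species consensuses mutate disjoint positions (infinite sites between
  consensuses), so realised between-species differences hit the targets
  exactly at the consensus level;
- within a species, the first individual carries the consensus and the
  rest add 0–3 private substitutions (`intra_max_diffs = 3`), matching
  the observed sub-1% intraspecific variation;
- all randomness flows from a single `numpy.random.default_rng(seed)`.

Defaults: 3 species, pairwise targets 2.0/3.4/4.5%, 20 individuals per
species, 658 bp — a study-sized dataset that keeps the full pipeline
under a second. The simulator does **not** model rate heterogeneity
across sites, multiple hits within a lineage, indels, or heteroplasmy;
realised K2P distances are recomputed with the package's own distance
code and reported in the truth table, so tests compare against realised
rather than target values.

`degrade_fragments` models museum-specimen degradation as a partition of
each barcode into geometrically distributed fragment lengths (clipped to
a minimum, short tails merged), preserving exact reassembly so truth is
recoverable.

`simulate_morphometrics` draws the six measurements from truncated
Gaussians around per-species mean vectors with relative dispersion,
floored at 10⁻³ to keep ratios defined.

## Numerical choices

- `float64` throughout; no tolerance-based equality in library code
  except documented clamps (λ ∈ [0, 1]).
- Half-up decimal rounding for displayed percentages.
- Bisection for K2P inversion (monotone on the valid domain), 80
  iterations, well below 10⁻¹² residual.
- Deterministic tie-breaking everywhere a choice is otherwise arbitrary
  (pair selection, cluster numbering, tag windows), so identical inputs
  give byte-identical outputs.

## Limitations

- K2P assumes equal base frequencies and a single transition/transversion
  ratio; it is the field-standard choice for COI barcoding but not the
  best-fitting model for deep divergences.
- BioNJ here returns a single tree; no branch-length confidence intervals
  beyond bootstrap bipartition support.
- The morphometric sweep is O(n³ log n) in specimens per comparison —
  fine for tens of specimens, not thousands.
- Virtual PCR models binding as sequence matching only; no melting
  temperature, secondary structure, or mismatch-tolerance model.
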