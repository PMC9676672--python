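# Methods

## Distances

The p-distance between two aligned sequences is the fraction of compared
sites at which they differ, with no correction for multiple substitutions.
Two policies control which sites a pair compares:

- `gap_policy="pairwise-exclude"` (default): a site is dropped from a
  pair's comparison when either sequence has a gap there. This mirrors the
  pairwise-deletion behaviour of the common distance calculators and keeps
  each pair's denominator (`comparable_sites`) explicit.
  `"include-as-mismatch"` instead compares every column, scoring a gap
  opposite a base as a mismatch and two gaps as a match.
- `ambiguity_policy="exclude"` (default): IUPAC ambiguity codes are treated
  like gaps. `"compatible-match"` scores two codes as matching when their
  base sets intersect (R vs A matches, R vs C does not).

A pair with zero comparable sites is reported as NaN with a warning, never
as a silent zero. Distances are kept at full precision; reports round to
four decimals. Within-group statistics are computed both as the mean (the
reporting convention of the published distance tables) and as the maximum
(the delimitation criterion reads "did not exceed" as a bound on every
pair); singleton groups have undefined within-group values, rendered
"n/c".

## Trees and bootstrap

Tree inference here serves only the delimitation step, so neighbor joining
on the p-distance matrix is used; externally inferred support-annotated
Newick trees (e.g. maximum likelihood) are accepted interchangeably via
`SupportTree.from_newick`, with support scale auto-detected (values all
≤ 1 are read as fractions and rescaled to percent).

Neighbor joining follows Saitou–Nei. Determinism and reproducibility:

- Sequences are processed in sorted-id order internally, so results do not
  depend on input row order.
- When several pairs tie on the Q-criterion (exact float equality), the
  pair whose lexicographically sorted cluster keys are smallest is joined,
  a cluster's key being its smallest leaf id. Because Q(i,j) and Q(j,i)
  can differ by one ulp (floating-point subtraction order), tie candidates
  are normalized to unordered pairs before selection.
- Negative branch-length estimates are clamped to zero and the clamped
  total logged at debug level.

The bootstrap resamples alignment columns with replacement (the study
default is 1,000 replicates; the desk-scale tests use 100–200). One
`numpy` generator seeded from the configuration drives all replicate
column draws; replicate trees are not stored — their bipartitions stream
into a counter keyed by a canonical side (the side not containing the
smallest leaf id). A replicate producing an undefined pairwise distance is
skipped with a warning and excluded from the support denominator.

## Delimitation

A candidate clade qualifies as a haplotype group when (1) its bootstrap
support is at least `min_support` (default 99), (2) its within-group
distance (maximum pairwise by default, mean selectable) is at most
`max_within` (default 0.06), and (3) the single-linkage nearest-neighbor
distance — the minimum distance from any member to any non-member —
strictly exceeds the within-group distance. The criteria are applied as a
hard rule; the thresholds are configurable where a user needs to encode a
judgement call.

Candidate enumeration is deliberately wider than the internal edges alone:
both sides of every internal edge, the complement of every pendant edge,
and the full leaf set. The pendant-edge complements matter when all but
one specimen form one coherent group (the complement of a leaf is not an
internal-edge side); being trivial bipartitions they are present in every
bootstrap replicate and carry support 100. The full leaf set has no edge
and no support, so it can only qualify through the zero-divergence bypass:
a clade whose sequences are all identical (within-distance exactly zero)
qualifies regardless of support, because zero-length edges carry no
meaningful bootstrap signal. Among nested qualifying clades the most
inclusive is kept; leaves covered by no qualifying clade are reported
under an explicit `UNASSIGNED` sentinel. Qualifying clades on a single
tree are laminar in practice; a partial overlap would indicate an internal
error and raises an assertion.

`compare_partitions` reports, for each coarse label (an identical-sequence
class of a low-resolution marker, or an OTU), the set of fine groups it
covers, and counts the fine groups that share their label with at least
one other — the resolution collapse. `adjusted_rand` scores a delimited
partition against a known truth, counting each unassigned specimen as its
own singleton so an incomplete partition cannot score 1.0.

## OTU matching

Metabarcode OTUs are amplicon subfragments of the Sanger region, so
`match_otus` uses a global end-free (overlap) alignment, not a local one:
free leading and trailing gaps on both sequences, match +1, mismatch and
gap −1, implemented as a row-vectorized dynamic program (an optional band
restricts the explored diagonals). Identity is matches divided by the
number of alignment columns between the first and last aligned residue
pair. An end-free optimum may trim a terminal mismatch or trade a
mismatch for an indel pair when the flanking context allows; the
difference count (columns − matches) is preserved in such trades. The
best-identity reference is reported when identity reaches `min_identity`
(default 0.99, the OTU clustering threshold), otherwise no match.

## Morphometrics

c′ = tail length / anal body width; the amphid ratio = amphid aperture
width / neck width at the amphid (both measured in µm; the ratio is
reported as a fraction, matching the printed values despite the original
column header's "%"). Classification: c′ below 3.0 is short-tailed, above
5.0 long-tailed, and in between an explicit `intermediate` class — the
published narrative has no rule for that interval (one printed
short-labelled specimen has c′ 3.1), and the package never silently
contradicts a printed label: labels are carried alongside and a
discrepancy report lists every row whose printed ratio differs from the
recomputed one by more than 0.05. On the packaged voucher table the report
contains exactly two rows (N13471, N13491) whose printed c′ is the
truncated rather than rounded quotient of its own inputs.

"As-printed" rounding is half-up at the printed precision (1 decimal for
c′, 2 for the amphid ratio), via `decimal` to avoid binary half-even
surprises. Group summaries report mean, sample (n−1) standard deviation,
range, and the non-missing count per measurement; the printed morphotype
averages (0.14 and 0.26) are computed over all specimens with a defined
ratio, females and juveniles alike, as no stage restriction is stated for
them.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not a coalescent history. A uniform-random ancestral sequence of length L
(default 393) is mutated at ⌈d_between · L⌉ sites per cluster to give one
founder per cluster; the founder site sets are disjoint across clusters,
a deliberate departure from an evolutionary model that makes
between-cluster divergence controllable by construction. Each member then
mutates its founder at Binomial(L, d_within) uniformly chosen sites. All
substitutions pick uniformly among the three other bases; there are no
indels (the COI amplicon is in-frame and indel-free).

Defaults are the study conditions: K = 6 clusters of 5 (the corridor's
six-clade result at desk scale), d_within = 0.015, d_between = 0.15,
L = 393. Companion "18S" sequences (length 600, roughly the Sanger
fragment) are one fixed random sequence per collapse class, copied
verbatim to every member; the default collapse map sends all but the last
cluster to a single class, mirroring the observed pattern in which five
COI clades shared one identical 18S sequence. Morphometric rows draw c′,
anal body width, the amphid ratio, and neck width from per-morphotype
normals truncated at zero (short c′ ~ N(2.4, 0.25²), long c′ ~ N(5.2,
0.4²), the separation of the two voucher morphotypes; scale parameters
from the voucher table's empirical ranges, all editable in
`MORPH_DEFAULTS`); tail length and amphid width are products of the drawn
ratio and width, and stages are female with probability 0.6, the observed
proportion.

For two members of one cluster the expected p-distance is

    E[p] = 2 w (1 − w) + (2/3) w²,   w = d_within,

since a site differs when exactly one member mutated it, or both did and
landed on different bases (probability 1/3 of agreeing). A Binomial site
count spread uniformly over positions is exactly iid Bernoulli per site,
so no finite-L collision correction is needed; the test suite checks this
expectation against a 2,000-pair Monte-Carlo sample.

What the generator does not emulate: substitution-rate heterogeneity,
transition/transversion bias, back-substitution along a genealogy, indels,
sequencing error, and chimeras. Passing the recovery tests therefore shows
that the delimitation machinery is correct under clean cluster structure
at realistic divergences — not that the criteria are robust to alignment
error or within-group paraphyly in field data.

## Problem sizes and numerical choices

The recovery property (and the acceptance script) runs 20 seeded
simulations at K = 6, n = 5 per cluster, with 200 bootstrap replicates
each — enough replicates to resolve the ≥ 99% support criterion (support
must appear in ≥ 198 of 200 replicate trees) while keeping a full run in
seconds. Distance comparisons against printed values use the printed
precision; internal equality checks use exact or 1e-12 tolerances.
Degenerate inputs are defined rather than rejected wherever a sensible
meaning exists: all-equal distance matrices resolve by the documented tie
rule, a single bootstrap replicate yields supports in {0, 100}, and
single-member summary groups report an undefined standard deviation.

## Known limitations

- Neighbor joining stands in for maximum-likelihood inference; for real
  data the intended workflow is to import an externally inferred ML tree
  and delimit on it.
- The delimiter assumes the distance matrix and tree come from the same
  specimens; it does not reconcile conflicting id sets beyond an error.
- Overlap matching reports identity only; it does not attempt taxonomy
  assignment, chimera detection, or the read-processing upstream of OTUs.
- The packaged tables are transcriptions of printed tables and inherit
  their internal inconsistencies, which are surfaced (discrepancy report)
  rather than corrected.
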