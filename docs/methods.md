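# Methods notes

This note records the modeling conventions, defaults and numerical choices
behind `phylobench`, and what the synthetic benchmarks do and do not
demonstrate.

## Tree semantics and the RF distance

Trees are unrooted and leaf-labeled; a rooted Newick string is read as an
unrooted tree by suppressing the artificial degree-2 "root" (branch lengths
on the two root edges are summed). After any construction or restriction no
degree-2 internal node survives, so topology identity is exactly the set of
non-trivial bipartitions and a binary tree on `n` leaves carries `n - 3` of
them. Leaf matching is exact, case-sensitive string equality — silent
normalization hides data errors. The Newick dialect takes labels verbatim
(no quoting, no underscore-to-space), ignores internal labels and support
values for topology identity, and reports parse errors with a character
offset.

`rf_distance(t1, t2)` counts splits of `t1` absent from `t2`. For binary
pairs this is the halved symmetric difference: symmetric, zero iff equal,
at most `n - 3`, so one wrong quartet costs exactly 1. Against a
multifurcating reference (`rf_to_reference`) only *missed reference splits*
count: a polytomy asserts nothing, so extra resolution in the scored tree
is not penalized. This one-sided convention is the one consistent with the
bound that the maximum distance against a partially resolved reference is
its internal-edge count, strictly below `n - 3`. Relative distances divide
by that maximum; against a star reference (no internal edges) the relative
distance is undefined and is returned as a flagged missing value, excluded
from averages.

## The measures

- `Intra(M)`: mean RF distance over all unordered OG pairs, each pair
  restricted to its shared species, pairs with fewer than 4 shared species
  excluded (2 or 3 leaves admit a single unrooted topology). Pairs are
  enumerated exhaustively by default; uniform subsampling is available only
  under an explicit cap *and* seed, and the result is flagged as sampled.
  Pairs are unweighted — a pair sharing 20 species counts like a pair
  sharing 5.
- `Taxon(M)`: per-OG `rf_to_reference` / `relative_rf` /
  `zero_one_distance` against the taxonomy-induced tree on that OG's
  species, averaged over OGs. The relative flavor divides by the
  *reference's* internal-edge count (consistent with the multifurcation
  correction above), not by `n - 3`.
- Method trees are expected binary. A multifurcating method tree is scored
  as-is but warned about and recorded — an unresolved tree makes fewer
  assertions and therefore fewer mistakes (a star tree is never wrong), so
  such methods score with an advantage; `strict=True` rejects them instead.
- Summary tables sort ascending by absolute Taxon, ties broken by method id
  for stable output.

## Paired comparisons

Per-OG distance vectors are retained precisely so methods can be compared
by the *difference* of their distances on each OG. The mean difference
equals the difference of means, but positively correlated per-OG distances
make its variance far smaller. The test is a two-sided normal z-test on
the mean difference with a 95% half-width of exactly `1.96 s / sqrt(n)`;
significance tiers are `≫` (p < 1e-6), `>` (p < 0.05), `≥` (otherwise).
The normal approximation targets the large samples this machinery is meant
for; below n = 30 a small-sample warning is attached rather than switching
to a t-test, keeping the tier arithmetic uniform. Degenerate inputs: zero
variance with a nonzero mean reports p = 0 (`≫`); zero variance with zero
mean reports p = 1.

Component comparisons treat a method id as an ordered underscore-joined
token tuple; method A matches method B for tokens (a, b) iff substituting
a by b in A's tuple yields B, which guarantees identical companion
components. The per-OG differences of all matched pairs are pooled (an OG
counts once per matched pair), and the pooled delta equals the n-weighted
mean of per-pair deltas. No multiple-testing correction is applied across
chains.

## Group cleanup

Sequences with more than 5% unknown symbols are dropped (strict `>`;
exactly 5% is kept). Unknown means `X` for amino acids; for codons, any
triplet containing a base outside A/C/G/T (N, X, IUPAC ambiguity codes).
Of identical sequences (exact string equality on the stored alphabet) only
the first in input order is kept, since a method has no information to
place identical sequences relative to each other. The unknown filter runs
before deduplication, which can only matter in the edge case where a
removed copy would otherwise have been the kept one. A group is accepted
only if at least 4 sequences survive; rejection is a flagged outcome, not
an error, and every removal is logged with its reason. The filter is
idempotent.

## The LBA quartet study

The Felsenstein quartet is `((A,C),(B,D))` with pendant branches to A and B
and the internal branch of length `alpha` (substitutions/site) and pendant
branches to C and D of length `f * alpha`. Placing `alpha` on the internal
branch is a choice the study depends on — it is what keeps the informative
signal small relative to the long-branch noise. Defaults: `f` grid
{5, 7.5, 10, 12.5, 15} with 100 replicates each (500 total), `alpha`
uniform on [0.05, 0.2], DNA of length 1000 under JC69 (K2P with a
configurable transition/transversion ratio is also available). Sequences
evolve site-independently from a uniform root state using the closed-form
substitution probabilities; the simulator is checked in the tests against
the JC69 expected mismatch fraction `(3/4)(1 - exp(-4d/3))`.

Builders: Fitch parsimony scores each of the 3 quartet topologies per site
with equal character costs; the four-point builder picks the pairing
minimizing the within-pair distance sum on JC-corrected distances
`-(3/4) ln(1 - 4p/3)`; the k-mer builder uses pairwise Pearson chi-squared
statistics on k-mer count vectors as distances. Ties (score difference
within 1e-12, e.g. identical sequences) are broken uniformly at random
under the run seed and logged. A mismatch fraction `p >= 3/4` is a
saturated distance; replicates with any saturated entry are discarded and
counted, never imputed. On quartets every error costs RF 1, so the Taxon
measure is the fraction of incorrect reconstructions (over scored
replicates), and the Intra measure is the mean pairwise RF among all
inferred quartets, computed exactly from the per-topology counts.

A caveat worth making explicit: at the default conditions the C-D path
reaches `alpha(2f + 1)` — up to 6.2 substitutions/site — where the expected
mismatch fraction is within a fraction of a percent of 3/4. At 1000 sites
such distances are at the edge of estimability: a substantial share of
replicates saturate outright (and are discarded), and surviving estimates
of near-saturated distances are truncated downward, which biases the
four-point sum toward the short-pair topology. The distance builder is
consistent — its error rate falls as sequences lengthen — but its
finite-length error rate under these defaults is dominated by this
saturation regime rather than by long-branch attraction proper (its errors
group the two *short* branches, the opposite of parsimony's failure mode).

## The synthetic generator

What it emulates: one species tree (uniform random binary topology via
uniform edge attachment, covering all `(2n-5)!!` labeled topologies),
OGs as uniform species subsets whose true trees are the induced subtrees
(so true trees of any two OGs always agree on shared species — the premise
that makes Intra a quality measure), a taxonomy whose induced trees equal
the species-tree restrictions (optionally degraded with random polytomies,
which lose resolution but never contradict the truth), and methods as
Poisson(`lambda`) random NNI perturbations of the true tree. NNI was chosen
as the error model because it is interpretable and RF-bounded: each move
changes at most one split, so RF(truth, output) <= number of moves, and
both measures increase stochastically in `lambda`. Defaults: 30 species,
100 OGs of size 4-12, all seeds explicit.

What it does not emulate: sequence-level noise (alignment error,
rate heterogeneity, compositional bias), lateral gene transfer or
paralogy (OGs violating the shared-history premise), taxonomy errors
correlated with particular methods, and any dependence of error on OG size
or sequence length. Passing the parameter-recovery tests therefore shows
the *measures and statistics* behave correctly when their assumptions
hold; it says nothing about which real tree-building method is best — the
sequence-level behavior is probed only at quartet scale by the LBA study.

## Problem sizes

The test suite exercises the RF oracle exhaustively on all 945 topologies
with 7 leaves (about 450k pairs) plus 1000 random pairs up to 20 leaves
cross-checked against dendropy; parameter recovery uses 8 simulated
methods over 200 OGs of size 10 on 20 species; the LBA acceptance study
uses the full 500 replicates at length 1000. These sizes keep the entire
suite within a couple of minutes on one CPU while leaving the statistical
assertions comfortably powered.

## Known limitations

- RF is the only tree distance implemented; weighted branch-score or
  quartet distances are out of scope.
- Rooted-tree semantics are not supported; taxonomies are used only for
  their induced unrooted topologies.
- The z-test tiers are calibrated for large n; small-n comparisons warn
  but still use the normal approximation.
- Species-to-taxonomy mapping is exact by design; no fuzzy name matching.
- The strain-vs-species pruning rank of a real NCBI dump is a data-side
  decision: the mapping TSV determines at which node each genome attaches.
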