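# Methods

## Colinearity of circular gene orders

Both genomes are reduced to ordinal CDS ranks: each CDS gets rank 1..O
by start coordinate (ties by end, then gene id), strand ignored, and
origin-spanning features ranked by their start like any other. Working
in ranks rather than bp makes C comparable across genomes of different
size and gene density; the normalizer O is always the *target* genome's
CDS count, so C is not symmetric in the two genomes — the query genome
contributes the neighbour order, the target the positions.

Ortholog pairing is reciprocal best hit: for each query protein the
subject with smallest e-value (ties: larger bit score, then
lexicographically smaller id, making output deterministic), kept only
if the relationship holds in both directions and both e-values are
below the cutoff (default 1e-15). RBH is injective, so target ranks in
a pair set are automatically distinct. One-to-many relations are thereby
excluded by construction.

`colinearity_factor` walks neighbours in query-rank order. By default
the walk does not close the circle (n−1 distances for n pairs); with
`wrap=True` the (last, first) neighbour pair is added. For realistic
pair counts (~10^3) the choice moves C by at most one D term, i.e.
at most floor(O/2)/O < 1.

The randomization null draws target ranks uniformly without
replacement. Its exact mean uses the fact that each neighbour pair of a
uniform distinct sample is a uniform ordered pair of distinct ranks, so
E[D] = Σ_k P(|Δ|=k)·min(k, O−k) with P(|Δ|=k) = 2(O−k)/(O(O−1)), and
E[C] = n_used·E[D]/O (≈ n/4 for large O). The Monte-Carlo summary
carries this exact value alongside, so calibration never depends on the
sampler it is checking.

## Rearrangement simulator

Genome A is the identity circular order on n gene labels; genome B is
derived by a stated number of inversions and transpositions applied in
seeded random interleaved order with uniform breakpoints. Events are
unsigned because the statistic ignores orientation. Random inversions
act on an arc of length 2..n/2 (the minor arc), so no draw is a
degenerate full-circle flip, which would be a relabelling of the same
circular genome. Transpositions excise an arc of length 1..n/2 and
reinsert it at a uniform position strictly outside itself. Each gene
survives as an ortholog pair independently with probability
`ortholog_retention`; simulated pairs carry a pseudo e-value of 1e-50
so they pass any sensible cutoff. All simulators are pure functions of
(recipe, seed) via `numpy.random.default_rng`.

Defaults emulate the regime the colinearity statistic is meant for:
genomes of ~1,000–2,000 CDSs with partial ortholog retention, where the
interesting range runs from near-perfect colinearity (C ≈ 1) to
null-level shuffling (C ≈ n/4).

## Sequence simulator and GC landscape

`simulate_sequence` draws bases i.i.d. per position: P(G or C) is the
requested GC level (or an island's own level inside its span), and
among G/C the G probability is (1 ± amplitude)/2 — plus on the
replichore clockwise from the chosen origin (half the circle), minus on
the other. This plants a sign switch of the windowed skew at the origin
and terminus, the canonical signature used to orient prokaryotic
chromosomes. It deliberately omits codon structure, oligomer bias and
strand-specific gene density; passing tests show the estimator
localizes a skew sign switch, not that real origins are always this
clean.

`gc_skew_profile` computes (G−C)/(G+C) per circular window (default
window = step = 1,000 bp; windows wrap past the end) and its running
sum in coordinate order. A window with no G or C has skew 0 by
convention; N bases count toward neither numerator nor denominator.
The reported extremum positions are window *centers*, first occurrence
on ties, so the cumulative minimum sits within about half a window of
the true switch point; the origin-recovery tests use a ±2-window
tolerance accordingly, and rotation to the minimum is a fixed point to
within the same tolerance rather than exactly (both ends of a rotated
profile hover near zero).

`low_gc_regions` chains windows (default 2,000 bp every 500 bp) whose
GC fraction over non-N bases is below the threshold (default 0.47,
chosen against a ~0.55 background), merges chains separated by at most
`merge_gap` (1,000 bp), drops merged spans shorter than `min_length`
(5,000 bp), and recomputes each region's mean GC from the sequence.
The scan is circular: qualifying windows at the end of the
linearization merge with those at the start, and such a region is
reported with start > end plus a wrap flag (split into two lines in BED
output, which is 0-based half-open). With these defaults a 2 kb window
at a 55% background has a GC standard deviation of ~1.1 points, so the
47% threshold sits ~7 SD from both a 55% background and a 40% island —
false windows are negligible and planted islands are recovered
essentially always. Window/step/threshold are all exposed because
region counts on real genomes are parameter-dependent.

## Birth–death gene content model

Families are binary characters on a rooted guide tree (newick via
dendropy; missing branch lengths become 1.0 with a warning; polytomies
are handled natively by the recursions rather than resolved into
zero-length binary splits). The two-state chain with gain g and loss l
per unit branch length has

    P01(t) = g/(g+l) · (1 − e^{−(g+l)t}),  P10(t) = l/(g+l) · (1 − e^{−(g+l)t}).

The root prior defaults to the stationary presence probability
g/(g+l). Likelihoods use Felsenstein pruning with per-node rescaling;
posteriors use the up-down (inside-outside) recursion, whose root
marginal reduces to the likelihood-ratio closed form on two-leaf trees
(tested). Presence is called at posterior > 0.5; a gain on a branch is
a family called absent at the parent and present at the child, a loss
the reverse, so branch events are consistent with node calls by
construction.

Rate fitting aggregates unique phyletic patterns with multiplicities
(cost independent of family count), optimizes log-rates with L-BFGS-B
bounded to [1e-6, 50] from five fixed starting points, and is therefore
deterministic. With `correction_for_unobservable` each family's
likelihood is divided by 1 − P(all-absent), the ascertainment term for
ortholog-cluster matrices that can never contain all-absent families.
Simulation draws the root state from the prior and evolves states
preorder; rate recovery on 8-leaf unit-branch trees with 10,000
families reproduces g = 0.05, l = 0.2 to ~1% (median across seeds).

This is deliberately a presence/absence simplification: the full
gene-content machinery in the literature also models duplications and
family sizes. Copy counts are accepted in the matrix but binarized for
inference; conclusions about expansions are out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use genomes of 100 kb (skew, segmentation),
gene orders of n = 1,000 (rearrangements), and 10,000 families on
8-leaf trees (rate recovery) — sizes at which every Monte-Carlo check
is stable across seeds while the whole suite runs in well under a
minute. Monte-Carlo agreement tests use 3-standard-error bands;
exact formula checks use float tolerance (`pytest.approx` defaults);
the pruning-vs-enumeration oracle agrees to ~1e-15.

## Known limitations

- C depends on the query/target role assignment and on the wrap and
  RBH-vs-best-hit choices; reproducing any published value requires
  matching those choices, and they are all exposed as flags.
- The skew simulator's i.i.d. base model understates the positional
  autocorrelation of real genomes; origin-localization accuracy on real
  data will be worse than on simulations at equal amplitude.
- The segmentation defaults (window/step/min-length/merge-gap) are
  package choices; region counts on real genomes move with them.
- Gain/loss rates are global across branches; per-branch heterogeneity
  is not modelled, and neither are duplications.
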