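# Methods

## Model and representation

A secondary structure over a sequence of n bases (A, C, G, U; T is
normalized to U on input) is a set of basepairs {i, j}, 1 ≤ i < j ≤ n,
restricted to Watson-Crick (A-U, G-C) and wobble (G-U) pairings, with no
base in more than one pair (no triples) and no two pairs interleaved as
i < k < j < l (no pseudoknots).  Two pairs *conflict* when they share an
endpoint or cross; conflicting pairs can never coexist in one valid
structure, which is exactly what makes a Boltzmann ensemble multimodal.
Coordinates are 1-based everywhere, matching CT-format conventions.

The ensemble is represented empirically: an n_samples x n_candidates
binary indicator matrix over the pairs observed in at least one sample,
with per-sample weights summing to one.  Weights are uniform for
sampler output; feeding an exhaustively enumerated distribution with
weights equal to exact Boltzmann probabilities turns every downstream
statistic into an exact computation, which is how the oracle tests and
the exact analyses in the examples work.

## Information measures

Per-pair entropy is the binary entropy of the marginal, in bits, with
0·log 0 = 0 (implemented via `scipy.special.xlogy`).  Mutual information
between two pairs is computed from the weighted empirical 2x2 joint as
I = H[X_a] − H[X_a | X_b]; it is symmetric and clamped to zero below
1e−12 bits to absorb floating-point noise.  Joints are plug-in
estimates with no pseudocounts.  The all-pairs MI matrix used by the
tree search is computed vectorized as I = H(a) + H(b) − H(joint) from
weighted column co-occurrence counts.

For conflicting pairs, P(X_a = 1, X_b = 1) = 0 collapses the MI to a
closed form in the marginals,

    I = (1−p−q) log2(1−p−q) − (1−p) log2(1−p) − (1−q) log2(1−q),

whose derivative in q is log2((1−q)/(1−p−q)) > 0 for p > 0: the MI is
monotone increasing in the competing pair's probability, so the most
probable conflicting pair is also the one sharing the most pairwise MI
with a given pair.  (Note the derivative carries no leading factor of
two; the numerical-derivative test pins this down to 1e−6.)

## MIBP search and cluster tree

Candidates are frequency-filtered before the search: pairs with sampled
frequency below 1% or above 99% carry almost no entropy and are dropped
(at the 1000-sample default this is the familiar fewer-than-10 /
more-than-990 cut, generalized to fractions so behavior is stable for
any sample size).  The MIBP maximizes the MI sum over the filtered
candidates; the sum includes the focal pair's self-term H[X_kl], since
the defining double index is unrestricted — `include_self=False`
removes it, shifting every sum by a constant without changing the
argmax.  Ties (within 1e−9 bits, so symmetric sequences resolve
identically regardless of float summation order) break to the smallest
(i, j).

The tree grows greedily: a node splits on its MIBP when
node_probability x MI_sum ≥ cutoff (default 2 bits, with a 1e−9
comparison tolerance so an exactly-2.0 sum splits), where probability is
absolute mass relative to the root and the MI sum is node-conditional.
Nodes with fewer than `min_node_samples` members (default 10) become
leaves regardless — MI estimated from a handful of samples is noise.
Split order is best-score-first; without a split cap this leaves the
tree unchanged, and with `max_splits` set it retains the most
informative splits, which is how entropy-vs-cluster-count scans are
produced.  Per-node conditional marginals come from subsetting the
samples.  Each node records up to five conflicting pairs, chosen
greedily: the most probable candidate conflicting with the MIBP and
with all previously chosen pairs, probability ties again breaking to
smallest (i, j).

The conditional entropy of a tree is the leaf-probability-weighted sum
of within-leaf summed pair entropies; on exact ensembles it never
exceeds the root ensemble entropy (averaged conditioning cannot
increase entropy), though individual sampled splits can fluctuate.

## Counting and entropy constraints

Structure counts are exact integers from the interval recursion
N(i,j) = [i unpaired] N(i+1,j) + Σ_k [i~k] N(i+1,k−1) N(k+1,j) with
Python's arbitrary-precision arithmetic (log10 reported alongside, via
digit count beyond float range).  Constraints enter as admissibility
masks: forbidden pairs and forced-unpaired positions are removed from
the recursion; a forced pair removes the option of leaving either
endpoint unpaired or pairing it elsewhere, so any decomposition that
cannot realize it contributes zero — which is precisely the set of
structures that would cross it.  Counted objects are distinct basepair
sets only; engines that enumerate coaxial-stacking states count the
same basepair set several times, so our absolute counts are **not
comparable** with such engines' partition-function counts.

Entropy constraints are decided over the full candidate universe — all
pairable (i, j) at the minimum separation, with never-observed pairs at
p = 0 — not just observed candidates; this is an interpretation choice,
flagged here because the alternative (observed pairs only) would never
forbid anything.  Pairs with H < 0.002 bits are forced present when
p > 0.5 and forbidden when p < 0.5; at that threshold the two cases are
separated by p < 1.2e−4 versus p > 1 − 1.2e−4, so the cut is
unambiguous, and mutually conflicting forced pairs are impossible
(both would need p > 0.5).

## Toy generator: what it emulates and what it does not

The generator exhaustively enumerates all valid structures of a short
sequence (default cap 30 nt; enumeration is exponential), assigns each
the sum of its pair energies (defaults G-C −3, A-U −2, G-U −1,
arbitrary units, kT = 1, minimum hairpin loop 3), normalizes Boltzmann
weights, and samples by seeded inverse CDF.  It emulates the one
property the method needs — a multimodal distribution over valid
structures with exactly known marginals, joints and conflicts — and
deliberately omits what real folding thermodynamics has: stacking
cooperativity, loop penalties, dangles, temperature dependence.  Two
consequences matter for interpreting tests.  First, without stacking,
helices are not cooperative units: pairs of a "helix" fluctuate
semi-independently, and block-complementary sequences (the classic
bistable textbook picture) decompose into equal-energy mixed states
rather than two clean modes.  The shipped bistable fixture
`CAGAAUGAAAC` therefore uses a crossing topology — left conformation
{(1,7),(2,6)}, right {(3,11),(6,10)}, every left pair conflicting with
every right pair through the shared switch position 6 or by crossing —
which is bimodal by construction with equal mode energies.  Second,
passing tests demonstrate correctness of the ensemble *summarization*
(entropies, MI, clustering, counting) on exactly known distributions;
they say nothing about the accuracy of any folding model, which is out
of scope — the package consumes samples from whatever model produced
them.

## Numerical choices and problem sizes

All logarithms are base 2; all information quantities are in bits.
Probabilities are clipped to [0, 1] within 1e−9 before entropy
evaluation; uniform-weight marginals are computed as exact count
fractions so deterministic pairs land on exactly 0 or 1.  Default
analysis sizes follow the sampling rule of thumb that ~1000 samples
estimate pairing probabilities adequately; tests and the acceptance
script use 1000-sample ensembles for pipeline runs, 10^4 samples for
Monte-Carlo consistency checks (3-sigma binomial tolerance), and
enumerable sequences of 8–20 nt for exact oracles.  The minimum hairpin
loop defaults to 3 unpaired bases (j − i ≥ 4), the behavior of the
samplers whose output is consumed; structure validity itself only
demands non-adjacency (j − i ≥ 2), available via `min_loop=1`.

## Visualization conventions

Circle diagrams place position p at angle 2π(p−1)/L from 12 o'clock,
clockwise, with ticks every 10 nt; basepairs are straight chords whose
opacity is the affine map 0.08 + 0.92·p of the node-conditional
probability (p = 1 fully opaque), chords below a configurable floor
(default 0.01) are omitted, and the constraints on a node's path are
always drawn — red for constrained-present, blue (dashed) for
constrained-absent.  The report is fully static (inline SVG,
details/summary collapsing, no scripts); all coordinates are written
with fixed precision, so rendering is byte-reproducible from the JSON
report alone.

## Known limitations

Exact mode is exponential in sequence length and capped at 30 nt; long
sequences require an external sampler.  MI from small clusters is
noisy, hence the min-members leaf guard rather than any correction; no
MI confidence intervals are provided.  The stopping rule reads the
candidate MIBP's MI sum; other aggregates (e.g. total pairwise MI) are
defensible but not implemented.  Per-cluster marginals are sample
subsets, not constrained-partition-function recomputations, so deep
leaves inherit sampling error.
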