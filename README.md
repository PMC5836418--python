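# mibp — most informative basepairs of an RNA Boltzmann ensemble

An RNA sequence does not fold into one secondary structure but into a
Boltzmann-weighted ensemble of them, and that ensemble is usually
multimodal: alternative helices compete for the same bases, so whole
groups of basepairs stand or fall together.  `mibp` characterizes a
sampled ensemble through the information its basepairs carry about each
other.  It is written for structural bioinformaticians who already have
ensemble samples — from a stochastic sampler such as RNAstructure's or
from the built-in exact toy generator — and want to know *which* pairs
drive the multimodality, how the ensemble decomposes into conformations,
and how large the compatible structure space is.

## The method

Every candidate pair {i, j} defines a binary indicator X_ij over the
ensemble, with marginal p_ij and entropy

    H[X_ij] = -p_ij log2 p_ij - (1 - p_ij) log2(1 - p_ij)   (bits).

The information one pair carries about another is the mutual information
I(X_ij; X_kl) = H[X_ij] - H[X_ij | X_kl], estimated from the sampled
2x2 joint.  The **most informative basepair** maximizes the summed MI
over all candidate pairs:

    MIBP = argmax_kl  Σ_ij I(X_ij; X_kl).

Conditioning on the MIBP splits the ensemble into two simpler halves;
applied greedily this yields a binary tree of nested clusters, growing
while (cluster probability) x (MI sum) ≥ 2 bits.  Each node records the
basepairs *conflicting* with its MIBP — pairs that share an endpoint or
cross it, and hence can never coexist with it.  For conflicting pairs
the MI has a closed form in the two marginals alone, monotone in the
competitor's probability: the more probable the rival pair, the more
informative the switch.  Finally, pairs with entropy below 0.002 bits
are locked to their near-certain state and the surviving structure
space is counted exactly by dynamic programming (a partition function
with all energies set to zero).

## A worked example

`CAGAAUGAAAC` is a designed two-conformation switch shipped with the
package: the left conformation {(1,7), (2,6)} and the right conformation
{(3,11), (6,10)} are mutually exclusive pair sets.  Running
`python examples/01_bistable_switch.py`:

```
CAGAAUGAAAC: 9 structures in the exact ensemble

Per-pair marginals and entropies (bits):
 i  j  count        p   H_bits
 1  7      2 0.323244 0.907874
 2  6      3 0.583600 0.979739
 3 11      2 0.323244 0.907874
 6 10      2 0.298887 0.879926
 7 11      2 0.323244 0.907874

MIBP: (3,11) with an information sum of 2.571 bits
...
Most probable conflicting pairs (mutually exclusive with the MIBP):
  (2,6)  -- cannot coexist with (3,11) in any structure
```

Every pair is uncertain (entropies near 1 bit), yet observing the single
pair (3,11) resolves 2.57 bits of summed uncertainty, and its most
probable conflicting pair (2,6) belongs to the opposite conformation.
Clustering 1000 sampled structures (`examples/02_cluster_tree.py`)
splits the ensemble once, into a (3,11)-present cluster (p = 0.32,
residual entropy 0.56 bits) and a (3,11)-absent cluster (p = 0.68,
2.74 bits), cutting the 4.57-bit ensemble entropy to 2.04 bits —
that is, one basepair explains over half the structural uncertainty.
`examples/03_count_structures.py` shows the counting side: forbidding
the 20 sub-0.002-bit pairs of a decorated hairpin shrinks its structure
space from 2940 to 2281 while retaining 100% of the sampled probability
mass.

## Command line

The same pipeline is available as a thin CLI:

```
mibp simulate CAGAAUGAAAC --n 1000 --seed 7 --out samples.db
mibp analyze --samples samples.db --out report/
mibp count GGGAAACCC
```

`analyze` accepts multi-structure dot-bracket or concatenated CT sample
files (the convention of external stochastic samplers), an optional
FASTA sequence and an optional reference structure, and writes
`report.html` (collapsible cluster tree of circle-chord diagrams: red
chords constrained present, blue absent, darkness proportional to
conditional probability), `report.json` (the full tree with per-node
marginals and the resolved configuration) and `pair_stats.tsv`.

## Scope

Pseudoknots and base triples are excluded from the structure space, as
in standard secondary-structure prediction.  The package consumes
samples; it does not implement a thermodynamic folding model — the
built-in toy generator uses a per-pair additive energy (G-C -3, A-U -2,
G-U -1, kT = 1) and exhaustive enumeration, which is exact but limited
to short sequences.  Structure counts are of distinct basepair sets;
engines that distinguish coaxial stacking states count the same pair
set multiple times, so absolute counts are not comparable with theirs.
See `docs/methods.md` for the full model description and design notes.
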