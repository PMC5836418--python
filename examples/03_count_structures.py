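"""Count the structure space exactly, with and without constraints.

Counts distinct basepair sets by dynamic programming (a partition
function with every structure's energy set to zero), shows the exact
forced/forbidden partition identity, and applies entropy constraints
derived from a sampled ensemble.
"""

from mibp import (
    BasePair,
    ConstraintSet,
    Sequence,
    build_ensemble,
    count_structures,
    entropy_constraints,
    exact_ensemble,
    retained_mass,
    sample_structures,
)

seq = Sequence("GGGAAACCC")
total = count_structures(seq)
print(f"{seq.residues}: {total.count} valid structures "
      f"(log10 = {total.log10_count:.3f})")

q = BasePair(1, 9)
with_q = count_structures(seq, ConstraintSet(forced_pairs={q}))
without_q = count_structures(seq, ConstraintSet(forbidden_pairs={q}))
print(f"containing {q}: {with_q.count}; lacking it: {without_q.count} "
      f"(sum = {with_q.count + without_q.count}, the whole space)")

# entropy constraints: lock pairs that are (almost) never / always sampled
hairpin = exact_ensemble("GGGGAAAACCCCUUUUAAAA")
ens = build_ensemble(sample_structures(hairpin, 1000, seed=3))
cs = entropy_constraints(ens, threshold_bits=0.002)
before = count_structures(ens.sequence)
after = count_structures(ens.sequence, cs)
print(f"\n{ens.sequence.residues}:")
print(f"  {len(cs.forbidden_pairs)} pairs below 0.002 bits forbidden, "
      f"{len(cs.forced_pairs)} forced")
print(f"  structure count {before.count} -> {after.count} "
      f"(log10 {before.log10_count:.3f} -> {after.log10_count:.3f})")
print(f"  retained probability mass: {retained_mass(ens, cs):.4f}")
print("  most of the space vanishes; almost none of the probability does")
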