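"""Counting pseudoknot-free structures under basepair constraints.

The number of secondary structures compatible with a set of constraints is
the partition function with every structure's free energy set to zero:
each admissible structure contributes weight 1.  The count obeys the
classical interval recursion

    N(i, j) = [i may be unpaired] N(i+1, j)
            + sum_{k : (i, k) admissible} N(i+1, k-1) * N(k+1, j)

evaluated with exact (arbitrary-precision) integer arithmetic, with the
admissibility mask carrying both the pairing rules (Watson-Crick/wobble,
minimum hairpin loop) and the constraints: forbidden pairs and forced-
unpaired positions simply mask entries, while a forced pair {a, b} removes
the option of leaving a or b unpaired or pairing them elsewhere — any
decomposition that cannot realize the forced pair then counts zero, which
is exactly the set of structures that would have crossed it.

Counts are of distinct *basepair sets*.  Folding engines that enumerate
coaxial-stacking states count the same basepair set several times, so
absolute counts from such engines are not comparable with these.

Entropy constraints shrink the space: over the universe of all pairable
(i, j) at the minimum separation, any pair whose marginal entropy falls
below a threshold (default 0.002 bits) is locked to its near-certain
state — forced present when p > 0.5, forbidden when p < 0.5.  At that
threshold the two cases are separated by p < 1.2e-4 vs p > 1 - 1.2e-4, so
the cut is unambiguous.  Constraining these nearly-deterministic pairs
removes almost none of the probability mass yet excludes the vast
majority of possible structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble_stats import SampleEnsemble, pair_entropy
from .secondary_structure import (
    BasePair,
    SecondaryStructure,
    Sequence,
    can_pair,
    conflicts,
)

__all__ = [
    "ConstraintSet",
    "StructureCount",
    "count_structures",
    "candidate_universe",
    "entropy_constraints",
    "retained_mass",
    "structure_satisfies",
]

#: Default minimum hairpin loop: 3 unpaired bases between paired ends (j - i >= 4).
DEFAULT_MIN_LOOP = 3


@dataclass(frozen=True)
class ConstraintSet:
    """Presence/absence constraints on the structure space.

    forced_pairs must all be present, forbidden_pairs absent, and
    forced_unpaired positions unpaired.  Internal consistency (forced pairs
    mutually compatible, not simultaneously forbidden, not touching a
    forced-unpaired position) is checked at construction.
    """

    forced_pairs: frozenset[BasePair] = field(default_factory=frozenset)
    forbidden_pairs: frozenset[BasePair] = field(default_factory=frozenset)
    forced_unpaired: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "forced_pairs", frozenset(self.forced_pairs))
        object.__setattr__(self, "forbidden_pairs", frozenset(self.forbidden_pairs))
        object.__setattr__(self, "forced_unpaired", frozenset(self.forced_unpaired))
        forced = sorted(self.forced_pairs)
        for a in range(len(forced)):
            for b in range(a + 1, len(forced)):
                if conflicts(forced[a], forced[b]):
                    raise ValueError(
                        f"inconsistent constraints: forced pairs {forced[a]} and "
                        f"{forced[b]} conflict"
                    )
        clash = self.forced_pairs & self.forbidden_pairs
        if clash:
            raise ValueError(
                f"inconsistent constraints: {sorted(clash)} both forced and forbidden"
            )
        for p in forced:
            if p.i in self.forced_unpaired or p.j in self.forced_unpaired:
                raise ValueError(
                    f"inconsistent constraints: forced pair {p} touches a "
                    f"forced-unpaired position"
                )

    def is_empty(self) -> bool:
        return not (self.forced_pairs or self.forbidden_pairs or self.forced_unpaired)


@dataclass(frozen=True)
class StructureCount:
    """Exact structure count with its base-10 order of magnitude."""

    count: int
    log10_count: float

    @classmethod
    def of(cls, count: int) -> "StructureCount":
        if count < 0:
            raise ValueError("count must be nonnegative")
        log10 = -math.inf if count == 0 else _log10_bigint(count)
        return cls(count, log10)


def _log10_bigint(n: int) -> float:
    # math.log10 overflows above ~1e308; go via digit count for big ints
    if n < 10**300:
        return math.log10(n)
    s = str(n)
    mant = float("0." + s[:17])
    return len(s) + math.log10(mant)


def count_structures(
    seq: Sequence,
    constraints: ConstraintSet | None = None,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> StructureCount:
    """Exact count of valid constrained structures by interval DP.

    Validity: every pair Watson-Crick or wobble, j - i >= min_loop + 1, no
    triples, no pseudoknots; plus all constraints.  Python integers keep
    the arithmetic exact at any magnitude.
    """
    cs = constraints or ConstraintSet()
    n = len(seq)
    for p in cs.forced_pairs | cs.forbidden_pairs:
        if not (1 <= p.i < p.j <= n):
            raise ValueError(f"constraint pair {p} out of range for length {n}")
    for p in cs.forced_pairs:
        if not can_pair(seq.base(p.i), seq.base(p.j)) or p.j - p.i <= min_loop:
            raise ValueError(f"forced pair {p} is not admissible for this sequence")

    partner: dict[int, int] = {}
    for p in cs.forced_pairs:
        partner[p.i] = p.j
        partner[p.j] = p.i
    forbidden = cs.forbidden_pairs
    unpaired = cs.forced_unpaired

    res = seq.residues

    def admissible(i: int, k: int) -> bool:
        if k - i <= min_loop:
            return False
        if not can_pair(res[i - 1], res[k - 1]):
            return False
        if BasePair(i, k) in forbidden:
            return False
        if i in unpaired or k in unpaired:
            return False
        if partner.get(i, k) != k or partner.get(k, i) != i:
            return False
        return True

    # N[i][j] over 1-based closed intervals; empty interval (i > j) counts 1.
    # Bottom-up over interval length avoids recursion limits.
    N = [[1] * (n + 2) for _ in range(n + 3)]
    for length in range(1, n + 1):
        for i in range(1, n - length + 2):
            j = i + length - 1
            total = N[i + 1][j] if i not in partner else 0
            for k in range(i + min_loop + 1, j + 1):
                if admissible(i, k):
                    inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 1
                    outer = N[k + 1][j] if j >= k + 1 else 1
                    total += inner * outer
            N[i][j] = total
    return StructureCount.of(N[1][n])


def candidate_universe(seq: Sequence, min_loop: int = DEFAULT_MIN_LOOP) -> list[BasePair]:
    """All pairable (i, j) at the minimum separation — the universe over
    which entropy constraints are decided (unobserved pairs have p = 0)."""
    n = len(seq)
    return [
        BasePair(i, j)
        for i in range(1, n + 1)
        for j in range(i + min_loop + 1, n + 1)
        if can_pair(seq.base(i), seq.base(j))
    ]


def entropy_constraints(
    ensemble: SampleEnsemble,
    threshold_bits: float = 0.002,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> ConstraintSet:
    """Lock nearly-deterministic pairs to their near-certain state.

    Over the full candidate universe of the ensemble's sequence, pairs with
    H[X_ij] < threshold_bits are forced present when p > 0.5 and forbidden
    when p < 0.5; pairs never observed in any sample have p = 0 exactly.
    """
    marg = dict(zip(ensemble.candidates, ensemble.marginals()))
    forced, forbidden = set(), set()
    for cand in candidate_universe(ensemble.sequence, min_loop):
        p = float(marg.get(cand, 0.0))
        if pair_entropy(p) < threshold_bits:
            (forced if p > 0.5 else forbidden).add(cand)
    return ConstraintSet(frozenset(forced), frozenset(forbidden))


def structure_satisfies(s: SecondaryStructure, cs: ConstraintSet) -> bool:
    """True iff the structure satisfies every constraint in ``cs``."""
    if not cs.forced_pairs <= s.pairs:
        return False
    if cs.forbidden_pairs & s.pairs:
        return False
    if cs.forced_unpaired:
        occupied = {pos for p in s.pairs for pos in (p.i, p.j)}
        if cs.forced_unpaired & occupied:
            return False
    return True


def retained_mass(ensemble: SampleEnsemble, cs: ConstraintSet) -> float:
    """Weight fraction of the sample satisfying every constraint, in [0, 1]."""
    keep = np.fromiter(
        (structure_satisfies(s, cs) for s in ensemble.structures),
        dtype=bool,
        count=ensemble.n_samples,
    )
    return float(min(ensemble.weights[keep].sum(), 1.0))
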