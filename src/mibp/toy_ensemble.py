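"""Exact toy Boltzmann ensembles for short sequences.

For sequences short enough to enumerate (default cap 30 nt) this module
lists *every* valid secondary structure, assigns each an energy under a
deliberately simple per-pair additive model (G-C -3, A-U -2, G-U -1 in
arbitrary units, no stacking or loop terms — the package's scope is
ensemble summarization, not folding thermodynamics), and normalizes the
Boltzmann weights exp(-E/kT) into an exact distribution.  From this exact
distribution it provides:

* exact marginals p_ij and exact 2x2 joints for any pair of basepairs —
  the brute-force oracle against which sample-based statistics are tested;
* an exact-weights conversion into a :class:`SampleEnsemble` (one row per
  distinct structure, weight = its probability), so the whole analysis
  stack can be run with zero Monte-Carlo error;
* a seeded inverse-CDF sampler emitting i.i.d. draws, and standard
  multi-structure dot-bracket files, so the main pipeline consumes toy
  data through the same readers as real sampler output.

A designed bistable sequence, CAGAAUGAAAC, is exported for tests and
examples.  It folds into one of two nested pair sets — the "left"
conformation {(1,7), (2,6)} (a C1-G7 anchor over an A2-U6 switch) or the
"right" conformation {(3,11), (6,10)} (a G3-C11 anchor over a U6-A10
switch) — and every left pair conflicts with every right pair, either
through the shared switch position 6 or by crossing.  Under the additive
model the two conformations carry equal energy, so the exact ensemble is
genuinely bimodal; the only other deep state swaps the left anchor for
the incidental G7-C11 pair, a register alternative within the left mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .ensemble_stats import SampleEnsemble, build_ensemble
from .secondary_structure import (
    BasePair,
    SecondaryStructure,
    Sequence,
    can_pair,
)

__all__ = [
    "ToyEnergyModel",
    "ToyEnsembleExact",
    "enumerate_structures",
    "exact_ensemble",
    "sample_structures",
    "BISTABLE_SEQUENCE",
    "BISTABLE_LEFT",
    "BISTABLE_RIGHT",
]

#: Two-conformation switch: every pair of BISTABLE_LEFT conflicts with
#: every pair of BISTABLE_RIGHT (shared position 6 or crossing).
BISTABLE_SEQUENCE = "CAGAAUGAAAC"
BISTABLE_LEFT = (BasePair(1, 7), BasePair(2, 6))
BISTABLE_RIGHT = (BasePair(3, 11), BasePair(6, 10))

DEFAULT_ENUMERATION_CAP = 30


@dataclass(frozen=True)
class ToyEnergyModel:
    """Per-pair additive energies (arbitrary units) with Boltzmann factor kT."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    kT: float = 1.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        for e in (self.gc, self.au, self.gu):
            if not np.isfinite(e):
                raise ValueError("energies must be finite")

    def pair_energy(self, a: str, b: str) -> float:
        key = frozenset((a.upper(), b.upper()))
        table = {
            frozenset("GC"): self.gc,
            frozenset("AU"): self.au,
            frozenset("GU"): self.gu,
        }
        try:
            return table[key]
        except KeyError:
            raise ValueError(f"{a}-{b} is not a pairable combination") from None

    def energy(self, s: SecondaryStructure) -> float:
        seq = s.sequence
        return sum(self.pair_energy(seq.base(p.i), seq.base(p.j)) for p in s.pairs)


def enumerate_structures(
    seq: Sequence | str,
    model: ToyEnergyModel | None = None,
    max_len: int = DEFAULT_ENUMERATION_CAP,
) -> list[SecondaryStructure]:
    """Every valid structure of ``seq`` (incl. the empty one), duplicate-free.

    Ordered lexicographically by sorted pair list, so downstream oracle
    output is deterministic.  Enumeration is exponential in length; beyond
    ``max_len`` use the stochastic sampler of a folding engine instead.
    """
    if isinstance(seq, str):
        seq = Sequence(seq)
    model = model or ToyEnergyModel()
    n = len(seq)
    if n > max_len:
        raise ValueError(
            f"length {n} exceeds the enumeration cap ({max_len}); "
            "use a stochastic sampler for long sequences"
        )
    res = seq.residues
    min_loop = model.min_loop

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> tuple[frozenset[BasePair], ...]:
        # all pair sets over the closed interval [i, j]
        if j - i < min_loop + 1:
            return (frozenset(),)
        out = list(structures(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(res[i - 1], res[k - 1]):
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        out.append(inner | outer | {BasePair(i, k)})
        return tuple(out)

    all_sets = structures(1, n)
    structures.cache_clear()
    ordered = sorted(all_sets, key=lambda ps: sorted(ps))
    return [SecondaryStructure(seq, ps, validate=False) for ps in ordered]


@dataclass
class ToyEnsembleExact:
    """Exhaustive Boltzmann distribution over all structures of a short sequence."""

    sequence: Sequence
    model: ToyEnergyModel
    structures: list[SecondaryStructure]
    energies: np.ndarray
    probabilities: np.ndarray
    candidates: list[BasePair] = field(init=False)
    _indicator: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.candidates = sorted({p for s in self.structures for p in s.pairs})
        index = {p: c for c, p in enumerate(self.candidates)}
        self._indicator = np.zeros(
            (len(self.structures), len(self.candidates)), dtype=np.uint8
        )
        for r, s in enumerate(self.structures):
            for p in s.pairs:
                self._indicator[r, index[p]] = 1
        self._index = index

    def marginal(self, p: BasePair) -> float:
        """Exact p_ij: summed probability of structures containing {i, j}."""
        if p not in self._index:
            return 0.0
        return float(self.probabilities @ self._indicator[:, self._index[p]])

    def marginals(self) -> dict[BasePair, float]:
        vals = self.probabilities @ self._indicator
        return {c: float(v) for c, v in zip(self.candidates, vals)}

    def joint(self, a: BasePair, b: BasePair) -> np.ndarray:
        """Exact 2x2 joint P(X_a = r, X_b = c) by direct summation."""
        xa = (
            self._indicator[:, self._index[a]].astype(bool)
            if a in self._index
            else np.zeros(len(self.structures), bool)
        )
        xb = (
            self._indicator[:, self._index[b]].astype(bool)
            if b in self._index
            else np.zeros(len(self.structures), bool)
        )
        w = self.probabilities
        return np.array(
            [
                [w[~xa & ~xb].sum(), w[~xa & xb].sum()],
                [w[xa & ~xb].sum(), w[xa & xb].sum()],
            ]
        )

    def to_sample_ensemble(self) -> SampleEnsemble:
        """Exact-weights mode: one 'sample' per structure, weight = probability."""
        return build_ensemble(self.structures, weights=self.probabilities)


def exact_ensemble(
    seq: Sequence | str,
    model: ToyEnergyModel | None = None,
    max_len: int = DEFAULT_ENUMERATION_CAP,
) -> ToyEnsembleExact:
    """Enumerate and Boltzmann-weight all structures of a short sequence."""
    if isinstance(seq, str):
        seq = Sequence(seq)
    model = model or ToyEnergyModel()
    structs = enumerate_structures(seq, model, max_len)
    energies = np.array([model.energy(s) for s in structs])
    # softmax of -E/kT, stabilized
    logw = -energies / model.kT
    logw -= logw.max()
    w = np.exp(logw)
    return ToyEnsembleExact(seq, model, structs, energies, w / w.sum())


def sample_structures(
    exact: ToyEnsembleExact, n: int, seed: int
) -> list[SecondaryStructure]:
    """``n`` i.i.d. seeded draws from the exact distribution (inverse CDF)."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(exact.structures), size=n, p=exact.probabilities)
    return [exact.structures[i] for i in idx]
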