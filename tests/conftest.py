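"""Shared fixtures: random sequences with enumerable ensembles, and a
hand-constructed two-state sample set with known information content."""

from __future__ import annotations

import numpy as np
import pytest

from mibp import (
    BasePair,
    SecondaryStructure,
    Sequence,
    build_ensemble,
    exact_ensemble,
)


def random_sequence(rng: np.random.Generator, length: int) -> Sequence:
    """Random ACGU sequence guaranteed to have at least one admissible pair."""
    while True:
        seq = Sequence("".join(rng.choice(list("ACGU"), size=length)))
        ex = exact_ensemble(seq)
        if len(ex.structures) >= 2:
            return seq


@pytest.fixture(scope="session")
def bistable_exact():
    from mibp import BISTABLE_SEQUENCE

    return exact_ensemble(BISTABLE_SEQUENCE)


@pytest.fixture(scope="session")
def two_state_ensemble():
    """20 samples over a 20-nt sequence: pair A=(2,10) in half, its crossing
    conflict B=(5,14) in the other half, and C=(16,20) in all.

    With the default frequency filter C (frequency 1.0) is dropped, leaving
    A and B as complementary equiprobable indicators: H(A) = H(B) = 1 bit,
    I(A;B) = 1 bit, so the MI sum of either is exactly 2 bits.
    """
    residues = list("A" * 20)
    for i, j in ((2, 10), (5, 14), (16, 20)):
        residues[i - 1], residues[j - 1] = "G", "C"
    seq = Sequence("".join(residues))
    A, B, C = BasePair(2, 10), BasePair(5, 14), BasePair(16, 20)
    with_a = SecondaryStructure(seq, frozenset({A, C}))
    with_b = SecondaryStructure(seq, frozenset({B, C}))
    return build_ensemble([with_a] * 10 + [with_b] * 10), (A, B, C)
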