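"""Entropy and mutual information over basepair indicator variables.

Each candidate basepair {i, j} of an ensemble defines a binary random
variable X_ij that is 1 when the pair is present in a structure drawn from
the Boltzmann distribution.  Its uncertainty is the binary entropy

    H[X_ij] = -p_ij log2 p_ij - (1 - p_ij) log2 (1 - p_ij)       (bits)

with the 0 log 0 = 0 convention, and the information one pair carries
about another is the mutual information

    I(X_ij; X_kl) = H[X_ij] - H[X_ij | X_kl]

estimated here from the empirical (optionally weighted) 2x2 joint of the
two indicator columns.  Weighted samples let an exactly enumerated toy
distribution be fed as a degenerate "sample set" (one row per distinct
structure, weight = exact Boltzmann probability), turning Monte-Carlo
checks into exact ones.

For two *conflicting* pairs, joint presence has probability zero and the
mutual information collapses to the closed form

    I = (1-p-q) log2 (1-p-q) - (1-p) log2 (1-p) - (1-q) log2 (1-q)

which is monotone increasing in q for fixed p > 0: the more probable the
competing pair, the more informative observing either one becomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .secondary_structure import BasePair, SecondaryStructure, Sequence

__all__ = [
    "SampleEnsemble",
    "build_ensemble",
    "pair_entropy",
    "conditional_entropy",
    "mutual_information",
    "mi_matrix",
    "filter_candidates",
    "mi_conflicting_closed_form",
    "mi_conflicting_derivative",
    "ensemble_entropy",
    "pair_stats_table",
    "mi_table",
]

#: MI estimates below this are floating noise and are clamped to zero.
MI_CLAMP = 1e-12

_LN2 = np.log(2.0)


def pair_entropy(p):
    """Binary entropy in bits; accepts scalars or arrays, p in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError(f"probability outside [0, 1]: {p!r}")
    arr = np.clip(arr, 0.0, 1.0)
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / _LN2
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


@dataclass
class SampleEnsemble:
    """Sampled structures as a binary sample-by-candidate indicator matrix.

    Attributes
    ----------
    sequence : Sequence
    structures : list of the n sampled structures, input order preserved.
    candidates : observed basepairs, sorted ascending by (i, j).
    indicator : (n, m) uint8 matrix; entry [s, c] is X_c realized in sample s.
    weights : per-sample weights summing to 1 (uniform 1/n by default).
    """

    sequence: Sequence
    structures: list[SecondaryStructure]
    candidates: list[BasePair]
    indicator: np.ndarray
    weights: np.ndarray
    _index: dict[BasePair, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {p: c for c, p in enumerate(self.candidates)}

    @property
    def n_samples(self) -> int:
        return self.indicator.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.indicator.shape[1]

    def candidate_index(self, p: BasePair) -> int:
        try:
            return self._index[p]
        except KeyError:
            raise KeyError(f"{p} is not a candidate pair of this ensemble") from None

    def marginals(self, members: np.ndarray | None = None) -> np.ndarray:
        """Weighted frequency of each candidate, optionally within a subset.

        ``members`` is an index array into the samples; weights are
        renormalized over the subset.
        """
        if members is None:
            w, x = self.weights, self.indicator
        else:
            w, x = self.weights[members], self.indicator[members]
        if w.size == 0 or w.sum() <= 0:
            raise ValueError("member subset has zero weight")
        if np.all(w == w[0]):
            # uniform weights: exact count fractions
            return x.sum(axis=0, dtype=float) / x.shape[0]
        # same dot-product reduction for numerator and normalizer, so a
        # constant column yields exactly 0 or 1
        total = float(w @ np.ones_like(w))
        return np.clip((w @ x) / total, 0.0, 1.0)

    def entropies(self, members: np.ndarray | None = None) -> np.ndarray:
        return pair_entropy(self.marginals(members))


def build_ensemble(
    structures: TypingSequence[SecondaryStructure],
    weights: TypingSequence[float] | None = None,
) -> SampleEnsemble:
    """Assemble sampled structures into a :class:`SampleEnsemble`.

    All structures must share one sequence; candidates are the union of
    observed pairs, ordered by (i, j) ascending.  Weights default to
    uniform 1/n and are otherwise normalized to sum to 1.
    """
    structures = list(structures)
    if len(structures) < 2:
        raise ValueError("need at least 2 sampled structures")
    seq = structures[0].sequence
    for s in structures[1:]:
        if s.sequence.residues != seq.residues:
            raise ValueError(
                "all structures must be over the same sequence "
                f"(found lengths {len(seq)} and {len(s.sequence)} or differing bases)"
            )
    candidates = sorted({p for s in structures for p in s.pairs})
    index = {p: c for c, p in enumerate(candidates)}
    indicator = np.zeros((len(structures), len(candidates)), dtype=np.uint8)
    for r, s in enumerate(structures):
        for p in s.pairs:
            indicator[r, index[p]] = 1
    if weights is None:
        w = np.full(len(structures), 1.0 / len(structures))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(structures),) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per structure")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        w = w / total
    return SampleEnsemble(seq, structures, candidates, indicator, w)


def joint_2x2(
    ensemble: SampleEnsemble,
    a: BasePair,
    b: BasePair,
    members: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical weighted joint P(X_a = r, X_b = c) as a 2x2 array."""
    ia, ib = ensemble.candidate_index(a), ensemble.candidate_index(b)
    xa = ensemble.indicator[:, ia].astype(bool)
    xb = ensemble.indicator[:, ib].astype(bool)
    w = ensemble.weights
    if members is not None:
        xa, xb, w = xa[members], xb[members], w[members]
        w = w / w.sum()
    joint = np.empty((2, 2))
    joint[1, 1] = w[xa & xb].sum()
    joint[1, 0] = w[xa & ~xb].sum()
    joint[0, 1] = w[~xa & xb].sum()
    joint[0, 0] = w[~xa & ~xb].sum()
    return joint


def conditional_entropy(joint: np.ndarray) -> float:
    """H[X | Y] in bits from a 2x2 joint with rows X, columns Y.

    Returns (1 - p_y) H[X | Y=0] + p_y H[X | Y=1]; conditions of zero
    probability contribute nothing.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.shape != (2, 2):
        raise ValueError("joint must be 2x2")
    if np.any(joint < -1e-12):
        raise ValueError("joint entries must be nonnegative")
    if abs(joint.sum() - 1.0) > 1e-9:
        raise ValueError(f"joint must sum to 1 (got {joint.sum()})")
    joint = np.clip(joint, 0.0, None)
    h = 0.0
    for y in (0, 1):
        py = joint[:, y].sum()
        if py > 0:
            h += py * pair_entropy(joint[1, y] / py)
    return h


def mutual_information(
    ensemble: SampleEnsemble,
    a: BasePair,
    b: BasePair,
    members: np.ndarray | None = None,
) -> float:
    """I(X_a; X_b) in bits from the empirical weighted joint; >= 0, symmetric."""
    joint = joint_2x2(ensemble, a, b, members)
    p_a = joint[1, :].sum()
    mi = pair_entropy(p_a) - conditional_entropy(joint)
    return 0.0 if mi < MI_CLAMP else mi


def mi_matrix(indicator: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """All-pairs mutual information (bits) between indicator columns.

    Vectorized over the m candidate columns: joints come from weighted
    column co-occurrence, I = H(a) + H(b) - H(joint).  Values below the
    clamp are set to 0, so the matrix is nonnegative and symmetric.
    """
    x = indicator.astype(float)
    w = np.asarray(weights, dtype=float)
    p = w @ x  # marginals
    p11 = (x * w[:, None]).T @ x
    p10 = p[:, None] - p11
    p01 = p[None, :] - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = np.stack([np.clip(c, 0.0, None) for c in (p00, p01, p10, p11)])
    h_joint = -xlogy(cells, cells).sum(axis=0) / _LN2
    h = pair_entropy(p)
    mi = h[:, None] + h[None, :] - h_joint
    mi[mi < MI_CLAMP] = 0.0
    return mi


def filter_candidates(
    ensemble: SampleEnsemble,
    low_frac: float = 0.01,
    high_frac: float = 0.99,
    members: np.ndarray | None = None,
) -> list[BasePair]:
    """Candidates at informative frequencies: low_frac <= p <= high_frac.

    Pairs seen in almost none or almost all samples have near-zero entropy
    and cannot contribute mutual information, so they are dropped before
    the MIBP search.  The defaults generalize the absolute cut of 10 / 990
    out of 1000 samples to fractions, stable for any sample size.
    """
    if not (0 <= low_frac < high_frac <= 1):
        raise ValueError("need 0 <= low_frac < high_frac <= 1")
    p = ensemble.marginals(members)
    keep = (p >= low_frac - 1e-12) & (p <= high_frac + 1e-12)
    return [ensemble.candidates[c] for c in np.nonzero(keep)[0]]


def mi_conflicting_closed_form(p_ij: float, p_kl: float) -> float:
    """Exact MI (bits) between two conflicting pairs with marginals p_ij, p_kl.

    Because conflicting pairs never co-occur, P(X_ij=1, X_kl=1) = 0 and the
    mutual information reduces to a closed form in the marginals alone.
    Monotone increasing in p_kl for fixed p_ij > 0.
    """
    if p_ij < 0 or p_kl < 0:
        raise ValueError("marginals must be nonnegative")
    if p_ij + p_kl > 1 + 1e-12:
        raise ValueError(
            f"conflicting pairs cannot have p_ij + p_kl > 1 (got {p_ij + p_kl})"
        )
    r = min(max(1.0 - p_ij - p_kl, 0.0), 1.0)
    val = (
        xlogy(r, r) - xlogy(1.0 - p_ij, 1.0 - p_ij) - xlogy(1.0 - p_kl, 1.0 - p_kl)
    ) / _LN2
    return 0.0 if val < MI_CLAMP else float(val)


def mi_conflicting_derivative(p_ij: float, p_kl: float) -> float:
    """d/dp_kl of :func:`mi_conflicting_closed_form` = log2((1-p_kl)/(1-p_ij-p_kl)).

    Strictly positive whenever p_ij > 0, which proves the monotonicity of
    the closed form in the competing pair's probability.
    """
    if p_ij + p_kl >= 1:
        raise ValueError("derivative defined for p_ij + p_kl < 1")
    return float(np.log2((1.0 - p_kl) / (1.0 - p_ij - p_kl)))


def ensemble_entropy(
    marginals: np.ndarray | Iterable[float],
    subset: np.ndarray | Iterable[int] | None = None,
) -> float:
    """Sum of per-pair entropies H[X_ij] (bits) over a candidate subset.

    With the full candidate set this is the ensemble entropy reported per
    sequence; restricted to a cluster's conditional marginals it is that
    cluster's conditional entropy contribution.
    """
    p = np.asarray(list(marginals) if not isinstance(marginals, np.ndarray) else marginals,
                   dtype=float)
    if subset is not None:
        p = p[np.asarray(list(subset), dtype=int)]
    return float(np.sum(pair_entropy(p)))


# ---------------------------------------------------------------------------
# Tabular exports


def pair_stats_table(ensemble: SampleEnsemble) -> pd.DataFrame:
    """Per-candidate marginal statistics: i, j, count, p, H (bits)."""
    p = ensemble.marginals()
    counts = ensemble.indicator.sum(axis=0)
    return pd.DataFrame(
        {
            "i": [c.i for c in ensemble.candidates],
            "j": [c.j for c in ensemble.candidates],
            "count": counts.astype(int),
            "p": p,
            "H_bits": pair_entropy(p),
        }
    )


def mi_table(ensemble: SampleEnsemble, focal: BasePair) -> pd.DataFrame:
    """I(X_ij; X_focal) for every candidate {i,j}; attrs carry the MI sum."""
    mi = mi_matrix(ensemble.indicator, ensemble.weights)
    col = mi[:, ensemble.candidate_index(focal)]
    df = pd.DataFrame(
        {
            "i": [c.i for c in ensemble.candidates],
            "j": [c.j for c in ensemble.candidates],
            "mi_bits": col,
        }
    )
    df.attrs["focal"] = (focal.i, focal.j)
    df.attrs["mi_sum_bits"] = float(col.sum())
    return df
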