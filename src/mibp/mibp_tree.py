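"""Greedy MIBP clustering of a sampled Boltzmann ensemble.

The most informative basepair (MIBP) of an ensemble is the candidate pair
{k, l} maximizing the summed mutual information with all candidate pairs,

    MIBP = argmax_kl  sum_ij I(X_ij; X_kl),

the sum running over the frequency-filtered candidates (and, by default,
including the focal pair itself, whose self-term is H[X_kl]).  Knowing
whether the MIBP is present resolves not just that pair but much of the
rest of the structure, so conditioning on it splits the ensemble into two
markedly simpler sub-ensembles.  Applying the search greedily — split on
the MIBP, recurse into the present and absent halves — yields a binary
tree of nested clusters; recursion stops when the product of a node's
probability mass and its MIBP's information sum falls below a cutoff
(default 2 bits), so only splits that buy a substantial expected entropy
reduction are made.  The leaves are an exhaustive partition of the sample
set.

Each node also records the basepairs that *conflict* with its MIBP: the
most probable candidate conflicting with the MIBP, then repeatedly the
most probable candidate conflicting with the MIBP and all previously
chosen pairs, up to five.  These mutually exclusive alternatives are what
drive the multimodality that the tree exposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ensemble_stats import (
    SampleEnsemble,
    ensemble_entropy,
    mi_matrix,
    pair_entropy,
)
from .secondary_structure import BasePair, SecondaryStructure, conflicts

__all__ = [
    "Constraint",
    "ClusterNode",
    "ClusterTree",
    "find_mibp",
    "split_cluster",
    "build_tree",
    "conditional_entropy_of_tree",
    "find_conflicting_pairs",
    "locate_structure",
    "tree_to_dict",
    "tree_to_json",
]


@dataclass(frozen=True)
class Constraint:
    """Presence or absence of one basepair, accumulated along a tree path."""

    pair: BasePair
    present: bool

    def satisfied_by(self, s: SecondaryStructure) -> bool:
        return (self.pair in s.pairs) == self.present


@dataclass
class ClusterNode:
    """One cluster: the samples satisfying all constraints on its path.

    ``marginals`` and ``entropy`` are conditional on membership;
    ``probability`` is absolute mass relative to the root.
    """

    node_id: int
    constraints: tuple[Constraint, ...]
    members: np.ndarray
    probability: float
    marginals: np.ndarray
    entropy: float
    mibp: BasePair | None = None
    mibp_mi_sum: float = 0.0
    conflicting_pairs: list[BasePair] = field(default_factory=list)
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterTree:
    """Binary tree of nested clusters over one :class:`SampleEnsemble`."""

    root: ClusterNode
    ensemble: SampleEnsemble
    cutoff_bits: float
    config: dict

    @property
    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out

    @property
    def nodes(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            out.append(node)
            if not node.is_leaf:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out


def _filtered_indices(
    ensemble: SampleEnsemble,
    members: np.ndarray | None,
    low_frac: float,
    high_frac: float,
) -> np.ndarray:
    p = ensemble.marginals(members)
    keep = (p >= low_frac - 1e-12) & (p <= high_frac + 1e-12)
    return np.nonzero(keep)[0]


def find_mibp(
    ensemble: SampleEnsemble,
    members: np.ndarray | None = None,
    low_frac: float = 0.01,
    high_frac: float = 0.99,
    include_self: bool = True,
) -> tuple[BasePair, float] | None:
    """The candidate maximizing the MI sum over filtered candidates, or None.

    Ties are broken by smallest (i, then j).  ``include_self`` keeps the
    focal pair's own term H[X_kl] in the sum (the default reading of the
    unrestricted double index); switching it off subtracts that constant.
    Returns None when no candidate survives frequency filtering.
    """
    idx = _filtered_indices(ensemble, members, low_frac, high_frac)
    if idx.size == 0:
        return None
    if members is None:
        sub = ensemble.indicator[:, idx]
        w = ensemble.weights
    else:
        sub = ensemble.indicator[np.asarray(members)][:, idx]
        w = ensemble.weights[np.asarray(members)]
        w = w / w.sum()
    mi = mi_matrix(sub, w)
    sums = mi.sum(axis=1)
    if not include_self:
        sums = sums - np.diag(mi)
    # argmax with (i, j) tie-break: candidates are already (i, j)-sorted;
    # sums within 1e-9 bits count as tied so symmetric sequences resolve
    # deterministically regardless of float summation order
    best = int(np.flatnonzero(sums >= sums.max() - 1e-9)[0])
    return ensemble.candidates[idx[best]], float(sums[best])


def split_cluster(
    ensemble: SampleEnsemble, members: np.ndarray, p: BasePair
) -> tuple[np.ndarray, np.ndarray]:
    """Partition ``members`` by presence of ``p`` -> (present, absent) index arrays."""
    members = np.asarray(members)
    col = ensemble.indicator[members, ensemble.candidate_index(p)].astype(bool)
    present, absent = members[col], members[~col]
    if present.size == 0 or absent.size == 0:
        raise ValueError(f"degenerate split: pair {p} does not divide the cluster")
    return present, absent


def find_conflicting_pairs(
    ensemble: SampleEnsemble,
    mibp: BasePair,
    members: np.ndarray | None = None,
    max_n: int = 5,
) -> list[BasePair]:
    """Greedy mutually conflicting alternatives to the MIBP, most probable first.

    Element t is the highest-marginal candidate (within the cluster) that
    conflicts with the MIBP and with all previously selected pairs; the
    list stops at ``max_n`` or when no conflicting candidate with positive
    probability remains.  Probability ties break by smallest (i, j).
    """
    p = ensemble.marginals(members)
    order = sorted(
        range(len(ensemble.candidates)),
        key=lambda c: (-p[c], ensemble.candidates[c]),
    )
    chosen: list[BasePair] = []
    for c in order:
        if len(chosen) >= max_n:
            break
        cand = ensemble.candidates[c]
        if p[c] <= 0 or cand == mibp:
            continue
        if conflicts(cand, mibp) and all(conflicts(cand, q) for q in chosen):
            chosen.append(cand)
    return chosen


def build_tree(
    ensemble: SampleEnsemble,
    cutoff_bits: float = 2.0,
    low_frac: float = 0.01,
    high_frac: float = 0.99,
    max_conflicting: int = 5,
    min_node_samples: int = 10,
    include_self: bool = True,
    max_splits: int | None = None,
) -> ClusterTree:
    """Greedily grow the MIBP cluster tree.

    A node splits when (its probability mass) x (its MIBP's MI sum) is at
    least ``cutoff_bits`` and the split is non-degenerate; nodes with fewer
    than ``min_node_samples`` members become leaves regardless, since MI
    estimates from a handful of samples are noise.  ``max_splits`` caps the
    number of splits (breadth-first by score) for entropy-vs-cluster-count
    scans; None means unlimited.  Deterministic given the ensemble and
    configuration, and invariant to sample order.
    """
    counter = [0]

    def make_node(members: np.ndarray, constraints: tuple[Constraint, ...]) -> ClusterNode:
        prob = float(ensemble.weights[members].sum())
        marg = ensemble.marginals(members)
        node = ClusterNode(
            node_id=counter[0],
            constraints=constraints,
            members=members,
            probability=prob,
            marginals=marg,
            entropy=ensemble_entropy(marg),
        )
        counter[0] += 1
        return node

    all_members = np.arange(ensemble.n_samples)
    root = make_node(all_members, ())

    # Greedy expansion, best-score-first so a max_splits cap keeps the most
    # informative splits; without a cap the order does not change the tree.
    frontier: list[tuple[float, ClusterNode]] = []

    def score(node: ClusterNode) -> float | None:
        if node.members.size < min_node_samples:
            return None
        found = find_mibp(ensemble, node.members, low_frac, high_frac, include_self)
        if found is None:
            return None
        node.mibp, node.mibp_mi_sum = found
        node.conflicting_pairs = find_conflicting_pairs(
            ensemble, node.mibp, node.members, max_conflicting
        )
        return node.probability * node.mibp_mi_sum

    s = score(root)
    if s is not None:
        frontier.append((s, root))
    n_splits = 0
    while frontier:
        frontier.sort(key=lambda t: (-t[0], t[1].node_id))
        sc, node = frontier.pop(0)
        if sc < cutoff_bits - 1e-9:
            break
        if max_splits is not None and n_splits >= max_splits:
            break
        try:
            present, absent = split_cluster(ensemble, node.members, node.mibp)
        except ValueError:
            continue  # filter tolerance admitted a non-dividing pair; leaf
        child_p = make_node(present, node.constraints + (Constraint(node.mibp, True),))
        child_a = make_node(absent, node.constraints + (Constraint(node.mibp, False),))
        node.children = (child_p, child_a)
        n_splits += 1
        for child in (child_p, child_a):
            cs = score(child)
            if cs is not None:
                frontier.append((cs, child))

    config = {
        "cutoff_bits": cutoff_bits,
        "low_frac": low_frac,
        "high_frac": high_frac,
        "max_conflicting": max_conflicting,
        "min_node_samples": min_node_samples,
        "include_self": include_self,
        "max_splits": max_splits,
    }
    return ClusterTree(root, ensemble, cutoff_bits, config)


def conditional_entropy_of_tree(tree: ClusterTree) -> float:
    """Leaf-probability-weighted sum of within-leaf summed pair entropies (bits).

    The uncertainty remaining after learning which leaf cluster a structure
    falls in; never exceeds the root ensemble entropy when computed from
    exact distributions.
    """
    return float(sum(leaf.probability * leaf.entropy for leaf in tree.leaves))


def locate_structure(tree: ClusterTree, s: SecondaryStructure) -> ClusterNode:
    """The unique leaf whose constraint path ``s`` satisfies."""
    if s.sequence.residues != tree.ensemble.sequence.residues:
        raise ValueError("structure is over a different sequence than the tree")
    node = tree.root
    while not node.is_leaf:
        present_child, absent_child = node.children
        node = present_child if node.mibp in s.pairs else absent_child
    return node


# ---------------------------------------------------------------------------
# Serialization (the contract consumed by the report renderer)


def _pair_list(pairs) -> list[list[int]]:
    return [[p.i, p.j] for p in pairs]


def _node_to_dict(node: ClusterNode, ensemble: SampleEnsemble) -> dict:
    d = {
        "id": node.node_id,
        "constraints": [
            {"pair": [c.pair.i, c.pair.j], "present": c.present}
            for c in node.constraints
        ],
        "n_members": int(node.members.size),
        "probability": round(node.probability, 12),
        "entropy_bits": round(node.entropy, 12),
        "mibp": list(node.mibp) if node.mibp is not None else None,
        "mibp_mi_sum_bits": round(node.mibp_mi_sum, 12),
        "conflicting_pairs": _pair_list(node.conflicting_pairs),
        "marginals": [
            [c.i, c.j, round(float(p), 12)]
            for c, p in zip(ensemble.candidates, node.marginals)
        ],
        "children": None,
    }
    if not node.is_leaf:
        d["children"] = [
            _node_to_dict(node.children[0], ensemble),
            _node_to_dict(node.children[1], ensemble),
        ]
    return d


def tree_to_dict(tree: ClusterTree) -> dict:
    """JSON-ready description of the tree: constraints, masses, entropies,
    conflicting pairs and per-node conditional marginal tables."""
    return {
        "sequence": tree.ensemble.sequence.residues,
        "sequence_name": tree.ensemble.sequence.name,
        "n_samples": tree.ensemble.n_samples,
        "config": tree.config,
        "ensemble_entropy_bits": round(tree.root.entropy, 12),
        "conditional_entropy_bits": round(conditional_entropy_of_tree(tree), 12),
        "n_leaves": len(tree.leaves),
        "root": _node_to_dict(tree.root, tree.ensemble),
    }


def tree_to_json(tree: ClusterTree, indent: int = 2) -> str:
    return json.dumps(tree_to_dict(tree), indent=indent, sort_keys=True)
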