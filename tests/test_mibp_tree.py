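"""MIBP search, greedy cluster tree, conflicting pairs, leaf location."""

import json

import numpy as np
import pytest

from mibp import (
    BISTABLE_LEFT,
    BISTABLE_RIGHT,
    BasePair,
    SecondaryStructure,
    build_ensemble,
    build_tree,
    conditional_entropy_of_tree,
    find_conflicting_pairs,
    find_mibp,
    locate_structure,
    mi_conflicting_closed_form,
    sample_structures,
    split_cluster,
    tree_to_json,
)
from mibp.toy_ensemble import exact_ensemble

from conftest import random_sequence


class TestFindMIBP:
    def test_two_state_construction(self, two_state_ensemble):
        """A and its complementary conflict B tie at 2 bits (self H + 1 bit
        of MI); the constant pair C is filtered out; tie broken to A."""
        ens, (A, B, C) = two_state_ensemble
        pair, mi_sum = find_mibp(ens)
        assert pair == A
        assert mi_sum == pytest.approx(2.0, abs=1e-12)

    def test_zero_entropy_ensemble_has_no_mibp(self):
        from mibp import Sequence

        seq = Sequence("GGAAACC")
        s = SecondaryStructure(seq, {BasePair(1, 7)})
        ens = build_ensemble([s] * 12)
        assert find_mibp(ens) is None

    def test_exclude_self_term_shifts_sum_not_choice(self, two_state_ensemble):
        ens, (A, B, C) = two_state_ensemble
        pair, mi_sum = find_mibp(ens, include_self=False)
        assert pair == A
        assert mi_sum == pytest.approx(1.0, abs=1e-12)

    def test_exact_vs_sampled_agree(self, bistable_exact):
        exact_pair, _ = find_mibp(bistable_exact.to_sample_ensemble())
        sampled = build_ensemble(sample_structures(bistable_exact, 10_000, seed=5))
        sampled_pair, _ = find_mibp(sampled)
        assert sampled_pair == exact_pair

    def test_brute_force_oracle(self):
        """find_mibp equals an explicit argmax over per-candidate MI sums
        computed pair-by-pair from exact joints."""
        from mibp import conditional_entropy, mutual_information, pair_entropy

        rng = np.random.default_rng(31)
        for _ in range(3):
            ex = exact_ensemble(random_sequence(rng, 13))
            ens = ex.to_sample_ensemble()
            marg = ens.marginals()
            kept = [
                c
                for c, p in zip(ens.candidates, marg)
                if 0.01 - 1e-12 <= p <= 0.99 + 1e-12
            ]
            if not kept:
                assert find_mibp(ens) is None
                continue
            sums = {
                k: sum(mutual_information(ens, q, k) for q in kept) for k in kept
            }
            top = max(sums.values())
            best = min(k for k, v in sums.items() if v >= top - 1e-9)
            pair, mi_sum = find_mibp(ens)
            assert pair == best
            assert mi_sum == pytest.approx(top, abs=1e-9)


class TestSplitCluster:
    def test_partition_and_conditioning(self, two_state_ensemble):
        ens, (A, B, C) = two_state_ensemble
        members = np.arange(ens.n_samples)
        present, absent = split_cluster(ens, members, A)
        assert len(present) == 10 and len(absent) == 10
        assert sorted(np.concatenate([present, absent])) == list(members)
        ia = ens.candidate_index(A)
        assert ens.marginals(present)[ia] == 1.0
        assert ens.marginals(absent)[ia] == 0.0

    def test_degenerate_split_rejected(self, two_state_ensemble):
        ens, (A, B, C) = two_state_ensemble
        with pytest.raises(ValueError, match="degenerate"):
            split_cluster(ens, np.arange(ens.n_samples), C)


class TestBuildTree:
    def test_zero_entropy_single_leaf(self):
        from mibp import Sequence

        seq = Sequence("GGAAACC")
        s = SecondaryStructure(seq, {BasePair(1, 7)})
        tree = build_tree(build_ensemble([s] * 12))
        assert tree.root.is_leaf and len(tree.leaves) == 1

    def test_two_state_single_split(self, two_state_ensemble):
        """MI sum 2.0 at probability 1 meets the 2-bit cutoff: one split,
        two deterministic leaves of mass 0.5."""
        ens, (A, B, C) = two_state_ensemble
        tree = build_tree(ens, cutoff_bits=2.0)
        assert len(tree.leaves) == 2
        assert [leaf.probability for leaf in tree.leaves] == [0.5, 0.5]
        assert all(leaf.entropy == 0.0 for leaf in tree.leaves)
        assert conditional_entropy_of_tree(tree) == 0.0

    def test_leaf_masses_partition_unity(self, bistable_exact):
        samples = sample_structures(bistable_exact, 2000, seed=17)
        tree = build_tree(build_ensemble(samples))
        assert sum(l.probability for l in tree.leaves) == pytest.approx(1, abs=1e-12)
        all_members = np.sort(np.concatenate([l.members for l in tree.leaves]))
        assert all_members.tolist() == list(range(2000))

    def test_split_never_increases_conditional_entropy(self):
        rng = np.random.default_rng(91)
        for _ in range(4):
            ens = exact_ensemble(random_sequence(rng, 12)).to_sample_ensemble()
            unsplit = build_tree(ens, cutoff_bits=float("inf"))
            for cutoff in (2.0, 1.0, 0.25):
                tree = build_tree(ens, cutoff_bits=cutoff, min_node_samples=2)
                assert (
                    conditional_entropy_of_tree(tree)
                    <= unsplit.root.entropy + 1e-9
                )

    def test_order_invariance(self, bistable_exact):
        samples = sample_structures(bistable_exact, 500, seed=23)
        rng = np.random.default_rng(0)
        shuffled = [samples[i] for i in rng.permutation(500)]
        t1 = build_tree(build_ensemble(samples))
        t2 = build_tree(build_ensemble(shuffled))
        assert t1.root.mibp == t2.root.mibp
        assert sorted(l.probability for l in t1.leaves) == pytest.approx(
            sorted(l.probability for l in t2.leaves)
        )

    def test_min_node_samples_guard(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        tree = build_tree(ens, min_node_samples=50)
        assert tree.root.is_leaf  # 20 samples < 50: never split

    def test_constraint_paths_consistent(self, bistable_exact):
        samples = sample_structures(bistable_exact, 1000, seed=29)
        tree = build_tree(build_ensemble(samples), cutoff_bits=0.5, min_node_samples=10)
        for leaf in tree.leaves:
            pairs = [c.pair for c in leaf.constraints]
            assert len(set(pairs)) == len(pairs)
            # each leaf's constraints are satisfied by each of its members
            for idx in leaf.members[:5]:
                s = tree.ensemble.structures[idx]
                assert all(c.satisfied_by(s) for c in leaf.constraints)


class TestConflictingPairs:
    def test_no_conflicts_empty(self, two_state_ensemble):
        ens, (A, B, C) = two_state_ensemble
        assert find_conflicting_pairs(ens, C) == []

    def test_greedy_mutual_conflict_rule(self):
        """Chosen pairs all conflict with the MIBP and with each other,
        most probable first."""
        from mibp import Sequence

        residues = list("A" * 24)
        for i, j in ((4, 12), (8, 16), (10, 18), (2, 22)):
            residues[i - 1], residues[j - 1] = "G", "C"
        seq = Sequence("".join(residues))
        M, B, D, E = BasePair(4, 12), BasePair(8, 16), BasePair(10, 18), BasePair(2, 22)
        # B crosses M; D crosses M and B; E nests them all (no conflict)
        structs = (
            [SecondaryStructure(seq, {M})] * 4
            + [SecondaryStructure(seq, {B})] * 8
            + [SecondaryStructure(seq, {D})] * 6
            + [SecondaryStructure(seq, {E})] * 2
        )
        ens = build_ensemble(structs)
        assert find_conflicting_pairs(ens, M) == [B, D]
        assert find_conflicting_pairs(ens, M, max_n=1) == [B]

    def test_truncates_at_limit(self):
        from mibp import Sequence

        # 7 mutually conflicting pairs: all share position 12
        residues = list("A" * 24)
        residues[11] = "C"
        for i in (1, 2, 3, 4, 5, 6, 7):
            residues[i - 1] = "G"
        seq = Sequence("".join(residues))
        pairs = [BasePair(i, 12) for i in range(1, 8)]
        structs = [SecondaryStructure(seq, {p}) for p in pairs for _ in (0, 1)]
        ens = build_ensemble(structs)
        got = find_conflicting_pairs(ens, pairs[6], max_n=5)
        assert len(got) == 5
        assert all(p.j == 12 for p in got)

    def test_most_probable_conflict_maximizes_pairwise_mi(self, bistable_exact):
        """On exact ensembles the most probable conflicting pair also has the
        most pairwise MI with the MIBP (closed-form monotonicity)."""
        from mibp import mutual_information, conflicts

        ens = bistable_exact.to_sample_ensemble()
        mibp, _ = find_mibp(ens)
        first = find_conflicting_pairs(ens, mibp)[0]
        conflicting = [
            c for c in ens.candidates if c != mibp and conflicts(c, mibp)
        ]
        best_mi = max(mutual_information(ens, mibp, c) for c in conflicting)
        assert mutual_information(ens, mibp, first) == pytest.approx(
            best_mi, abs=1e-12
        )


class TestLocateStructure:
    def test_membership_consistency(self, bistable_exact):
        samples = sample_structures(bistable_exact, 800, seed=41)
        ens = build_ensemble(samples)
        tree = build_tree(ens, cutoff_bits=1.0)
        assert len(tree.leaves) >= 2
        for idx in range(0, 800, 97):
            leaf = locate_structure(tree, ens.structures[idx])
            assert idx in leaf.members

    def test_two_state_leaf_probability(self, two_state_ensemble):
        ens, (A, B, C) = two_state_ensemble
        tree = build_tree(ens)
        leaf = locate_structure(tree, ens.structures[0])  # contains A
        assert leaf.probability == 0.5
        assert leaf.constraints[0].pair == A and leaf.constraints[0].present


def test_json_serialization_roundtrips(two_state_ensemble):
    ens, _ = two_state_ensemble
    tree = build_tree(ens)
    data = json.loads(tree_to_json(tree))
    assert data["n_leaves"] == 2
    assert data["root"]["children"] is not None
    present = data["root"]["children"][0]
    assert present["constraints"][0]["present"] is True
    assert present["probability"] == 0.5
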