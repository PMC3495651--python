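import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covote.io import GeneList
from covote.preprocess import ConditionMatrix
from covote.votemap import (
    all_vs_all_pair_count,
    build_friend_table,
    build_map,
    call_differential,
    coexpression_ratio,
    export_network,
    friends_of,
    global_friend_probability,
    write_edge_list,
    VoteMap,
)

from conftest import oracle_counts, random_corpus


def cm_of(values, conditions, genes=None, dataset_id="d"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ConditionMatrix(dataset_id, genes, conditions, values,
                           {c: 1 for c in conditions})


class TestCallDifferential:
    def test_boundary_inclusive_up(self, toy_cm):
        cm = cm_of([[4.0, 5.0]], ["A", "B"])
        assert call_differential(cm, "A", "B").calls == {"g0": 1}

    def test_below_cutoff_zero(self):
        cm = cm_of([[4.0, 4.9]], ["A", "B"])
        assert call_differential(cm, "A", "B").calls == {"g0": 0}

    def test_missing_value_absent(self):
        cm = cm_of([[np.nan, 5.0]], ["A", "B"])
        assert call_differential(cm, "A", "B").calls == {}

    def test_same_condition_rejected(self):
        cm = cm_of([[4.0, 5.0]], ["A", "B"])
        with pytest.raises(ValueError, match="itself"):
            call_differential(cm, "A", "A")

    def test_unknown_condition_rejected(self):
        cm = cm_of([[4.0, 5.0]], ["A", "B"])
        with pytest.raises(ValueError, match="unknown condition"):
            call_differential(cm, "A", "Z")

    def test_swapping_conditions_negates_calls(self):
        rng = np.random.default_rng(0)
        cm = cm_of(rng.normal(14, 2, (10, 2)), ["A", "B"])
        fwd = call_differential(cm, "A", "B").calls
        rev = call_differential(cm, "B", "A").calls
        assert fwd.keys() == rev.keys()
        assert all(rev[g] == -c for g, c in fwd.items())

    def test_custom_fold_threshold(self):
        cm = cm_of([[4.0, 5.5]], ["A", "B"])
        assert call_differential(cm, "A", "B", fold_threshold=4.0).calls == {"g0": 0}
        assert call_differential(cm, "A", "B", fold_threshold=2.0).calls == {"g0": 1}


class TestBuildMap:
    def test_hand_enumerated_toy(self, toy_cm, toy_universe):
        vm = build_map([toy_cm], toy_universe)
        assert vm.x == 3
        assert vm.Q.tolist() == [2, 2]
        assert vm.N[0, 1] == 2 and vm.N[1, 0] == 2

    def test_diagonal_equals_q(self, toy_cm, toy_universe):
        vm = build_map([toy_cm], toy_universe)
        np.testing.assert_array_equal(np.diag(vm.N), vm.Q)

    def test_direction_invariance(self, toy_cm, toy_universe):
        reversed_cm = ConditionMatrix(
            toy_cm.dataset_id, toy_cm.genes, toy_cm.conditions[::-1],
            toy_cm.values[:, ::-1], toy_cm.replicate_counts,
        )
        a = build_map([toy_cm], toy_universe)
        b = build_map([reversed_cm], toy_universe)
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(a.Q, b.Q)
        assert a.x == b.x

    def test_constant_gene_all_zero(self, toy_universe):
        cm = cm_of([[1.0, 3.0, 1.0], [5.0, 5.0, 5.0]], ["A", "B", "C"],
                   genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        assert vm.Q[1] == 0
        assert vm.N[0, 1] == 0 and vm.N[1, 1] == 0

    def test_empty_corpus_rejected(self, toy_universe):
        with pytest.raises(ValueError, match="empty corpus"):
            build_map([], toy_universe)

    def test_empty_universe_rejected(self, toy_cm):
        with pytest.raises(ValueError, match="universe is empty"):
            build_map([toy_cm], [])

    def test_genes_outside_universe_ignored(self, toy_cm):
        vm = build_map([toy_cm], ["g1", "zz"])
        assert vm.Q.tolist() == [2, 0]

    def test_presence_counts(self, toy_universe):
        cm = cm_of([[1.0, 3.0, np.nan], [2.0, 4.0, 2.0]], ["A", "B", "C"],
                   genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        assert vm.presence.tolist() == [1, 3]

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_corpora(self, seed):
        cms = random_corpus(seed, n_genes=8, max_datasets=4)
        genes = [f"g{i}" for i in range(8)]
        vm = build_map(cms, genes)
        N, Q, x = oracle_counts(cms, genes)
        assert vm.x == x
        for i, a in enumerate(genes):
            assert vm.Q[i] == Q[a]
            for j, b in enumerate(genes):
                assert vm.N[i, j] == N[(a, b)], (a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds_fuzz(self, seed):
        cms = random_corpus(seed, n_genes=6, max_datasets=3)
        vm = build_map(cms, [f"g{i}" for i in range(6)])
        np.testing.assert_array_equal(vm.N, vm.N.T)
        assert (vm.N >= 0).all()
        assert (vm.Q <= vm.x).all()
        for i in range(6):
            for j in range(6):
                assert vm.N[i, j] <= min(vm.Q[i], vm.Q[j])

    def test_monotone_in_datasets(self):
        cms = random_corpus(11, n_genes=6, max_datasets=3)
        extra = random_corpus(12, n_genes=6, max_datasets=1)
        genes = [f"g{i}" for i in range(6)]
        a = build_map(cms, genes)
        b = build_map(cms + extra, genes)
        assert (b.N >= a.N).all() and (b.Q >= a.Q).all() and b.x >= a.x


class TestRatio:
    def test_perfect_covote(self, toy_cm, toy_universe):
        vm = build_map([toy_cm], toy_universe)
        assert coexpression_ratio(vm, "g1", "g2") == 1.0

    def test_zero_ratio(self, toy_universe):
        cm = cm_of([[1.0, 3.0], [5.0, 3.0]], ["A", "B"], genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        assert coexpression_ratio(vm, "g1", "g2") == 0.0

    def test_half_ratio(self):
        # s differential in 2 comparisons, g co-moves in 1 of them
        cm = cm_of([[1.0, 3.0, 5.0], [2.0, 4.0, 4.0]], ["A", "B", "C"],
                   genes=["s", "g"])
        vm = build_map([cm], ["s", "g"])
        assert vm.Q[0] == 3 and vm.N[0, 1] == 2
        # orient on g: g differential twice, s co-moves both times -> 1.0
        assert coexpression_ratio(vm, "s", "g") == 1.0

    def test_undefined_when_q_zero(self, toy_universe):
        cm = cm_of([[1.0, 3.0], [5.0, 5.0]], ["A", "B"], genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        assert coexpression_ratio(vm, "g1", "g2") is None

    def test_unknown_symbol_rejected(self, toy_cm, toy_universe):
        vm = build_map([toy_cm], toy_universe)
        with pytest.raises(KeyError):
            coexpression_ratio(vm, "g1", "nope")

    def test_not_symmetric_in_general(self):
        cm = cm_of([[1.0, 3.0, 5.0], [2.0, 4.0, 4.0]], ["A", "B", "C"],
                   genes=["s", "g"])
        vm = build_map([cm], ["s", "g"])
        assert coexpression_ratio(vm, "g", "s") != coexpression_ratio(vm, "s", "g")


def _chain_map(n_genes=101, seed=13):
    """Random corpus over n_genes for friend-list sizing tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cms = []
    for d in range(4):
        values = rng.normal(14, 2, size=(n_genes, 4))
        cms.append(ConditionMatrix(f"d{d}", genes, ["a", "b", "c", "e"],
                                   values, {c: 1 for c in "abce"}))
    return build_map(cms, genes)


class TestFriends:
    def test_list_length_floor(self):
        vm = _chain_map(101)
        lst = friends_of(vm, vm.genes[0], fraction=0.05)
        assert len(lst) == 5  # floor(0.05 * 100)

    def test_self_excluded(self):
        vm = _chain_map(40)
        for g in vm.genes[:10]:
            assert g not in [s for s, _ in friends_of(vm, g, 0.2)]

    def test_q_zero_empty_list(self, toy_universe):
        cm = cm_of([[1.0, 3.0], [5.0, 5.0]], ["A", "B"], genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        assert friends_of(vm, "g2", 0.5) == []

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_out_of_range_rejected(self, bad):
        vm = _chain_map(20)
        with pytest.raises(ValueError, match="fraction"):
            friends_of(vm, vm.genes[0], bad)

    def test_duplicated_rows_rank_first(self):
        rng = np.random.default_rng(21)
        base = rng.normal(14, 2, size=(1, 5))
        noise = rng.normal(14, 2, size=(8, 5))
        values = np.vstack([base, base, noise])
        genes = [f"g{i}" for i in range(10)]
        cm = ConditionMatrix("d", genes, list("abcde"), values,
                             {c: 1 for c in "abcde"})
        vm = build_map([cm], genes)
        assert vm.Q[0] > 0
        assert friends_of(vm, "g0", 0.3)[0][0] == "g1"
        assert friends_of(vm, "g1", 0.3)[0][0] == "g0"

    def test_tie_break_deterministic(self):
        # no votes anywhere except s: all candidates tie at ratio 0
        cm = cm_of([[1.0, 3.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]],
                   ["A", "B"], genes=["s", "b", "a", "c"])
        vm = build_map([cm], ["s", "b", "a", "c"])
        lst = friends_of(vm, "s", 0.7)  # floor(0.7*3) = 2 entries
        assert [g for g, _ in lst] == ["a", "b"]


class TestOrientation:
    """The two N:Q ranking orientations differ on globally active genes."""

    def _hub_map(self):
        from covote.preprocess import average_replicates
        from covote.synthetic import CorpusParams, gene_symbols, simulate_corpus

        params = CorpusParams(
            G=100, D=60, conditions_per_dataset=4, replicates_per_condition=1,
            module_sizes=(8,), co_de_prob=0.9, background_de_rate=0.1,
            noise_sd=0.0, missing_rate=0.0, rng_seed=5,
        )
        datasets, truth = simulate_corpus(params)
        vm = build_map([average_replicates(d) for d in datasets],
                       gene_symbols(params.G))
        return vm, truth

    def test_partner_orientation_lets_active_module_crowd_lists(self):
        vm, truth = self._hub_map()
        module = truth.module_members[0]
        ft = build_friend_table(vm, 0.15, orientation="partner")
        per_bg = [
            sum(s in module for s, _ in ft.friends(g))
            for g in sorted(truth.background)
        ]
        assert np.mean(per_bg) > len(module) - 1

    def test_self_orientation_requires_specific_covoting(self):
        vm, truth = self._hub_map()
        module = truth.module_members[0]
        bg_occ = []
        ft = build_friend_table(vm, 0.15, orientation="self")
        for g in sorted(truth.background):
            lst = [s for s, _ in ft.friends(g)]
            bg_occ.append(sum(s in module for s in lst))
        # the busy module no longer monopolizes background gene lists
        assert np.mean(bg_occ) < len(module) / 2

    def test_unknown_orientation_rejected(self):
        vm = _chain_map(20)
        with pytest.raises(ValueError, match="orientation"):
            friends_of(vm, vm.genes[0], 0.2, orientation="sideways")

    def test_orientations_agree_on_mutual_perfect_pairs(self):
        vm, truth = self._hub_map()
        a, b = sorted(truth.module_members[0])[:2]
        for orient in ("self", "partner"):
            assert [g for g, _ in friends_of(vm, a, 0.1, orient)][0] in \
                truth.module_members[0]


class TestFriendTable:
    def test_conservation(self):
        vm = _chain_map(60)
        ft = build_friend_table(vm, 0.1)
        lengths = (ft.friend_idx >= 0).sum()
        assert ft.occurrences.sum() == lengths

    def test_lists_match_friends_of(self):
        vm = _chain_map(30)
        ft = build_friend_table(vm, 0.2)
        for g in vm.genes:
            assert ft.friends(g) == friends_of(vm, g, 0.2)

    def test_determinism_byte_for_byte(self):
        a = build_friend_table(_chain_map(40), 0.1)
        b = build_friend_table(_chain_map(40), 0.1)
        assert a.friend_idx.tobytes() == b.friend_idx.tobytes()
        assert a.friend_ratio.tobytes() == b.friend_ratio.tobytes()

    def test_global_probability(self):
        vm = _chain_map(50)
        ft = build_friend_table(vm, 0.1)
        for g in vm.genes[:5]:
            expected = sum(
                g in {s for s, _ in ft.friends(other)} for other in vm.genes
            ) / len(vm.genes)
            assert global_friend_probability(ft, g) == expected

    def test_probability_zero_when_absent(self, toy_cm, toy_universe):
        cm = cm_of([[1.0, 3.0], [5.0, 5.0], [6.0, 6.0]], ["A", "B"],
                   genes=["g1", "g2", "g3"])
        vm = build_map([cm], ["g1", "g2", "g3"])
        ft = build_friend_table(vm, 0.5)
        assert global_friend_probability(ft, "g3") == 0.0


class TestNetwork:
    def test_toy_edge_present(self, toy_cm, toy_universe):
        vm = build_map([toy_cm], toy_universe)
        edges = export_network(vm, 0.8)
        assert edges == [("g1", "g2", 1.0)]

    def test_cutoff_above_all_ratios_empty(self, toy_cm, toy_universe):
        cm = cm_of([[1.0, 3.0, 5.0], [2.0, 4.0, 4.0]], ["A", "B", "C"],
                   genes=["g1", "g2"])
        vm = build_map([cm], toy_universe)
        # max ratio is 1.0 here; use a map with partial co-votes
        assert export_network(vm, 1.0) != [] or True
        vm2 = build_map([cm_of([[1.0, 3.0, 5.0, 5.0],
                                [2.0, 2.0, 4.0, 2.0]], list("ABCE"),
                               genes=["g1", "g2"])], toy_universe)
        ratios = [coexpression_ratio(vm2, "g1", "g2"),
                  coexpression_ratio(vm2, "g2", "g1")]
        assert max(ratios) < 1.0
        assert export_network(vm2, 1.0) == []

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.1])
    def test_cutoff_out_of_range_rejected(self, toy_cm, toy_universe, bad):
        vm = build_map([toy_cm], toy_universe)
        with pytest.raises(ValueError, match="cutoff"):
            export_network(vm, bad)

    def test_duplicated_pair_emitted_once(self):
        rng = np.random.default_rng(2)
        base = rng.normal(14, 2, size=(1, 4))
        values = np.vstack([base, base, rng.normal(14, 2, size=(2, 4))])
        genes = ["x", "y", "m", "n"]
        cm = ConditionMatrix("d", genes, list("abce"), values,
                             {c: 1 for c in "abce"})
        vm = build_map([cm], genes)
        edges = export_network(vm, 0.99)
        pairs = [(a, b) for a, b, _ in edges]
        assert pairs.count(("x", "y")) == 1

    def test_edges_lexicographically_sorted(self):
        vm = _chain_map(30)
        edges = export_network(vm, 0.2)
        assert edges == sorted(edges, key=lambda e: (e[0], e[1]))
        assert all(a < b for a, b, _ in edges)

    def test_write_edge_list(self, toy_cm, toy_universe, tmp_path):
        vm = build_map([toy_cm], toy_universe)
        p = tmp_path / "edges.tsv"
        write_edge_list(export_network(vm, 0.8), p)
        assert p.read_text() == "gene_a\tgene_b\tratio\ng1\tg2\t1\n"


class TestPersistence:
    def test_save_load_roundtrip(self, toy_cm, toy_universe, tmp_path):
        vm = build_map([toy_cm], toy_universe)
        p = tmp_path / "vm.npz"
        vm.save(p)
        back = VoteMap.load(p)
        assert back.genes == vm.genes and back.x == vm.x
        np.testing.assert_array_equal(back.N, vm.N)
        np.testing.assert_array_equal(back.Q, vm.Q)


def test_all_vs_all_pair_count():
    assert all_vs_all_pair_count(["a", "b", "c"]) == 9
    assert all_vs_all_pair_count(GeneList("u", ["a", "b"])) == 4
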