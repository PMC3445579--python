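"""Heuristic search, exhaustive enumeration, consensus trees and bootstrap."""
from collections import Counter

import numpy as np
import pytest

from metriomorph import PipelineConfig
from metriomorph.errors import ValidationError
from metriomorph.parsimony import (
    CharacterMatrix,
    Tree,
    bootstrap_support,
    exhaustive_search,
    majority_consensus,
    min_steps,
    random_tree,
    rf_distance,
    search,
    strict_consensus,
    tree_length,
)
from metriomorph.synthetic import MatrixSimSpec, gen_matrix


class TestSearch:
    def test_homoplasy_free_five_taxa_unique_mpt(self):
        # one clean binary character per internal branch of ((A,B),(C,D),E)
        states = np.array(
            [
                [1, 0],  # A
                [1, 0],  # B
                [0, 1],  # C
                [0, 1],  # D
                [0, 0],  # E
            ],
            dtype=np.int8,
        )
        m = CharacterMatrix(taxa=tuple("ABCDE"), states=states)
        truth = Tree.from_newick("((A,B),(C,D),E);")
        res = search(m, PipelineConfig(rng_seed=0, n_random_additions=4))
        assert res.length == sum(min_steps(states[:, j]) for j in range(2))
        assert len(res.mpt_set) == 1
        assert rf_distance(res.mpt_set[0], truth) == 0
        ex = exhaustive_search(m)
        assert ex.length == res.length

    def test_equal_support_keeps_both_resolutions(self):
        # char 1 supports AB|CD, char 2 supports AC|BD, equally weighted
        states = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        m = CharacterMatrix(taxa=tuple("ABCD"), states=states)
        res = search(m, PipelineConfig(rng_seed=1, n_random_additions=6))
        ex = exhaustive_search(m)
        assert res.length == ex.length == 3
        keys = {t.topology_key() for t in res.mpt_set}
        assert {t.topology_key() for t in ex.mpt_set} == keys
        # AB|CD and AC|BD both cost 3; AD|BC costs 4
        assert keys == {
            frozenset({frozenset({"C", "D"})}),
            frozenset({frozenset({"B", "D"})}),
        }

    def test_determinism_under_seed(self):
        m, _ = gen_matrix(MatrixSimSpec(n_taxa=8, n_characters=30, seed=11))
        cfg = PipelineConfig(rng_seed=42, n_random_additions=3)
        r1, r2 = search(m, cfg), search(m, cfg)
        assert r1.length == r2.length
        assert [t.to_newick() for t in r1.mpt_set] == [
            t.to_newick() for t in r2.mpt_set
        ]

    def test_mpt_pool_cap_truncates_with_flag(self):
        states = np.zeros((6, 1), dtype=np.int8)  # invariant: every tree optimal
        m = CharacterMatrix(taxa=tuple("ABCDEF"), states=states)
        res = search(
            m, PipelineConfig(rng_seed=0, n_random_additions=4, max_saved_trees=3)
        )
        assert res.length == 0
        assert len(res.mpt_set) == 3
        assert res.truncated

    def test_too_few_taxa_rejected(self):
        m = CharacterMatrix(taxa=("A", "B", "C"), states=np.zeros((3, 1), np.int8))
        with pytest.raises(ValidationError):
            search(m)

    def test_search_length_never_above_any_sampled_tree(self, rng):
        m, _ = gen_matrix(
            MatrixSimSpec(n_taxa=7, n_characters=25, rate=0.3, seed=5)
        )
        res = search(m, PipelineConfig(rng_seed=9, n_random_additions=3))
        for _ in range(20):
            t = random_tree(list(m.taxa), rng)
            assert res.length <= tree_length(t, m)


class TestConsensus:
    def test_identical_trees_unchanged(self):
        t = Tree.from_newick("((A,B),(C,D),E);")
        assert rf_distance(strict_consensus([t, t, t]), t) == 0
        assert rf_distance(majority_consensus([t, t]), t) == 0

    def test_total_conflict_gives_star(self):
        trees = [
            Tree.from_newick("((A,B),(C,D));"),
            Tree.from_newick("((A,C),(B,D));"),
        ]
        assert strict_consensus(trees).bipartitions() == {}

    def test_majority_keeps_two_thirds_clade(self):
        trees = [
            Tree.from_newick("((A,B),(C,D),E);"),
            Tree.from_newick("((A,B),C,(D,E));"),
            Tree.from_newick("((A,C),(B,D),E);"),
        ]
        maj = majority_consensus(trees)
        bips = maj.bipartitions()
        # {A,B} is canonicalised to its complement side (reference 'A')
        ab_complement = frozenset({"C", "D", "E"})
        assert bips[ab_complement] == pytest.approx(2 / 3)
        assert strict_consensus(trees).bipartitions() == {}

    def test_exact_half_is_excluded(self):
        trees = [
            Tree.from_newick("((A,B),(C,D),E);"),
            Tree.from_newick("((A,C),(B,D),E);"),
        ]
        assert majority_consensus(trees).bipartitions() == {}

    def test_matches_direct_bipartition_counting(self, rng):
        labels = [f"t{i}" for i in range(8)]
        trees = [random_tree(labels, rng) for _ in range(7)]
        counts = Counter()
        for t in trees:
            counts.update(t.bipartitions("t0").keys())
        strict = strict_consensus(trees)
        maj = majority_consensus(trees)
        assert set(strict.bipartitions("t0")) == {
            b for b, c in counts.items() if c == len(trees)
        }
        expected_majority = {b for b, c in counts.items() if c / len(trees) > 0.5}
        assert set(maj.bipartitions("t0")) == expected_majority
        for b, sup in maj.bipartitions("t0").items():
            assert sup == pytest.approx(counts[b] / len(trees))

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValidationError):
            strict_consensus(
                [Tree.from_newick("((A,B),(C,D));"), Tree.from_newick("((A,B),(C,E));")]
            )


class TestRobinsonFoulds:
    def test_agrees_with_dendropy(self, rng):
        import dendropy

        labels = [f"t{i}" for i in range(9)]
        for _ in range(8):
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.to_newick(), schema="newick", taxon_namespace=tns
            )
            d2 = dendropy.Tree.get(
                data=t2.to_newick(), schema="newick", taxon_namespace=tns
            )
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        m, _ = gen_matrix(
            MatrixSimSpec(n_taxa=6, n_characters=30, rate=0.1, seed=2,
                          missing_fraction=0, fraction_ordered=0)
        )
        support = bootstrap_support(m, PipelineConfig(rng_seed=0), n_replicates=1)
        assert set(support.values()) <= {0.0, 1.0}

    def test_strong_signal_gives_high_support(self):
        # homoplasy-free characters repeated 10x: resampling keeps the signal
        base = np.array(
            [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 1], [0, 1, 1], [0, 0, 0]],
            dtype=np.int8,
        )
        states = np.tile(base, (1, 10))
        m = CharacterMatrix(taxa=tuple("ABCDEF"), states=states)
        truth_clades = [
            frozenset({"C", "D", "E", "F"}),  # complement of {A,B}, ref 'A'
            frozenset({"C", "D", "E"}),
            frozenset({"D", "E"}),
        ]
        support = bootstrap_support(m, PipelineConfig(rng_seed=3), n_replicates=25)
        for clade in truth_clades:
            assert support.get(clade, 0.0) >= 0.9

    def test_determinism(self):
        m, _ = gen_matrix(MatrixSimSpec(n_taxa=6, n_characters=20, seed=8))
        cfg = PipelineConfig(rng_seed=5)
        s1 = bootstrap_support(m, cfg, n_replicates=5)
        s2 = bootstrap_support(m, cfg, n_replicates=5)
        assert s1 == s2
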