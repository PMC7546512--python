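"""Parsimony engine: character lengths, indices, search, consensus.

Lengths are validated against independent brute-force oracles: explicit
minimization over all internal-node state assignments for tiny trees,
and exhaustive enumeration of all unrooted topologies for the search.
"""

import itertools
import math
import random

import numpy as np
import pytest

from morphocline.parsimony import (
    Character,
    CharacterMatrix,
    SearchConfig,
    Tree,
    build_combined_matrix,
    char_length,
    exhaustive_search,
    max_steps,
    min_steps,
    ratchet_search,
    score_tree,
    strict_consensus,
)
from morphocline.datasets import PUBLISHED_ADDITIVE, PUBLISHED_K

from conftest import random_discrete_matrix


# --------------------------------------------------------------------------
# brute-force oracles


def brute_force_length(tree: Tree, states, additive: bool) -> float:
    """Minimize total change cost over all internal state assignments."""
    internal = [v for v in tree.adj if v >= tree.n_leaves]
    obs = set()
    for s in states:
        if s is not None:
            obs |= set(s)
    candidates = sorted(obs)
    edges = [(a, b) for a in tree.adj for b in tree.adj[a] if a < b]

    def cost(a, b):
        return abs(a - b) if additive else (0 if a == b else 1)

    best = math.inf
    leaf_choices = []
    for i in range(tree.n_leaves):
        s = states[i]
        leaf_choices.append(candidates if s is None else sorted(s))
    for leaf_assign in itertools.product(*leaf_choices):
        for inner in itertools.product(candidates, repeat=len(internal)):
            assign = dict(zip(internal, inner))
            for i, v in enumerate(leaf_assign):
                assign[i] = v
            total = sum(cost(assign[a], assign[b]) for a, b in edges)
            best = min(best, total)
    return best


def simple_tree(newick, taxa):
    return Tree.from_newick(newick, taxa)


# --------------------------------------------------------------------------
# char_length examples


class TestCharLength:
    def test_constant_column_is_free(self):
        taxa = list("abcd")
        m = CharacterMatrix(taxa, [Character([frozenset([1])] * 4)])
        t = simple_tree("((a,b),(c,d));", taxa)
        assert char_length(t, m, 0) == 0

    def test_two_state_split_costs_one(self):
        taxa = ["a1", "a2", "b1", "b2"]
        states = [frozenset([0]), frozenset([0]), frozenset([1]), frozenset([1])]
        m = CharacterMatrix(taxa, [Character(states)])
        t = simple_tree("((a1,a2),(b1,b2));", taxa)
        assert char_length(t, m, 0) == 1

    def test_additive_gap_costs_span(self):
        # states {0,2} on a cherry: the ordered scale forces 2 steps
        taxa = list("abcd")
        states = [frozenset([0]), frozenset([2]), frozenset([0]), frozenset([0])]
        m = CharacterMatrix(taxa, [Character(states, additive=True)])
        t = simple_tree("((a,b),(c,d));", taxa)
        assert char_length(t, m, 0) == 2

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_assignment_minimum(self, trial):
        """Fitch/Farris downpass equals explicit minimization (<=6 taxa)."""
        rng = random.Random(1000 + trial)
        ntax = rng.choice([4, 5, 6])
        m = random_discrete_matrix(rng, ntax, nchar=3, max_states=4,
                                   missing_p=0.15)
        t = Tree.random(ntax, rng)
        for j, ch in enumerate(m.characters):
            if not ch.observed():
                continue
            expected = brute_force_length(t, ch.states, ch.additive)
            assert char_length(t, m, j) == expected

    def test_missing_state_costs_nothing_extra(self):
        taxa = list("abcd")
        states = [frozenset([0]), None, frozenset([1]), frozenset([1])]
        m = CharacterMatrix(taxa, [Character(states)])
        t = simple_tree("((a,b),(c,d));", taxa)
        assert char_length(t, m, 0) == 1

    def test_polymorphic_leaf_satisfiable_free(self):
        taxa = list("abcd")
        states = [frozenset([0, 1]), frozenset([0]), frozenset([0]), frozenset([0])]
        m = CharacterMatrix(taxa, [Character(states)])
        t = simple_tree("((a,b),(c,d));", taxa)
        assert char_length(t, m, 0) == 0


# --------------------------------------------------------------------------
# min / max steps


class TestMinMaxSteps:
    def test_nonadditive_min_is_states_minus_one(self):
        m = CharacterMatrix(
            list("abc"), [Character([frozenset([0]), frozenset([1]), frozenset([2])])]
        )
        assert min_steps(m, 0) == 2

    def test_star_max_nonadditive_counts_minority(self):
        states = [frozenset([0])] * 3 + [frozenset([1])]
        m = CharacterMatrix(list("abcd"), [Character(states)])
        assert max_steps(m, 0) == 1

    def test_additive_min_and_star_max(self):
        states = [frozenset([0]), frozenset([0]), frozenset([2]), frozenset([2])]
        m = CharacterMatrix(list("abcd"), [Character(states, additive=True)])
        assert min_steps(m, 0) == 2
        assert max_steps(m, 0) == 4

    def test_all_missing_column_rejected(self):
        m = CharacterMatrix(list("ab"), [Character([None, None])])
        with pytest.raises(ValueError):
            min_steps(m, 0)

    @pytest.mark.parametrize("trial", range(15))
    def test_star_max_bounds_every_tree(self, trial):
        rng = random.Random(2000 + trial)
        ntax = rng.choice([5, 6])
        m = random_discrete_matrix(rng, ntax, nchar=4)
        t = Tree.random(ntax, rng)
        for j in range(m.nchar):
            s = char_length(t, m, j)
            assert min_steps(m, j) <= s <= max_steps(m, j)


# --------------------------------------------------------------------------
# score_tree


class TestScoreTree:
    def test_clean_matrix_scores_perfectly(self):
        # hierarchical, homoplasy-free characters
        taxa = list("abcdef")
        cols = [
            [0, 0, 0, 1, 1, 1],
            [0, 0, 0, 0, 1, 1],
            [0, 1, 1, 0, 0, 0],
        ]
        chars = [Character([frozenset([v]) for v in col]) for col in cols]
        m = CharacterMatrix(taxa, chars)
        t = simple_tree("((a,(b,c)),(d,(e,f)));", taxa)
        sc = score_tree(t, m, k=5.0)
        assert sc.implied_weights_score == 0
        assert sc.ci == 1 and sc.ri == 1

    def test_homoplasy_equal_to_k_contributes_half(self):
        # binary character alternating on a caterpillar: s=3, m=1, h=2
        taxa = list("abcd")
        states = [frozenset([0]), frozenset([1]), frozenset([0]), frozenset([1])]
        m = CharacterMatrix(taxa, [Character(states)])
        t = simple_tree("((a,b),(c,d));", taxa)
        sc = score_tree(t, m, k=float(char_length(t, m, 0) - 1))
        (h,) = sc.homoplasy
        assert sc.fit_contributions[0] == pytest.approx(h / (h + sc.k))
        sc2 = score_tree(t, m, k=float(h))
        assert sc2.fit_contributions[0] == pytest.approx(0.5)

    def test_stronger_concavity_never_raises_contribution(self):
        for h in range(0, 8):
            assert h / (h + 2.0) >= h / (h + 10.0) - 1e-12

    def test_convergent_taxon_lowers_retention_index(self):
        taxa = list("abcdef")
        base = [0, 0, 0, 1, 1, 1]
        chars = [Character([frozenset([v]) for v in base])]
        m = CharacterMatrix(taxa, chars)
        good = simple_tree("((a,(b,c)),(d,(e,f)));", taxa)
        assert score_tree(good, m, 3.0).ri == 1
        # move one derived taxon inside the plesiomorphic clade -> convergence
        bad = simple_tree("((a,(b,f)),(d,(e,c)));", taxa)
        assert score_tree(bad, m, 3.0).ri < 1


# --------------------------------------------------------------------------
# search


class TestSearch:
    def test_recovers_generating_tree_on_clean_matrix(self):
        taxa = list("abcdef")
        cols = [
            [0, 0, 1, 1, 1, 1],
            [0, 0, 0, 1, 1, 1],
            [0, 0, 0, 0, 1, 1],
            [1, 0, 0, 0, 0, 0],
        ]
        m = CharacterMatrix(
            taxa, [Character([frozenset([v]) for v in c]) for c in cols]
        )
        res = ratchet_search(m, SearchConfig(k=3.0, iterations=5, seed=1))
        best_sc, best_trees = exhaustive_search(m, k=3.0)
        assert res.best_score == pytest.approx(best_sc)
        assert any(res.best_tree == t for t in best_trees)

    def test_same_seed_gives_identical_trees(self):
        rng = random.Random(5)
        m = random_discrete_matrix(rng, 8, 10)
        cfg = SearchConfig(k=4.0, iterations=8, seed=42)
        r1 = ratchet_search(m, cfg)
        r2 = ratchet_search(m, SearchConfig(k=4.0, iterations=8, seed=42))
        assert r1.best_score == r2.best_score
        assert [t.bipartitions() for t in r1.trees] == [
            t.bipartitions() for t in r2.trees
        ]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_optimum_small(self, trial):
        rng = random.Random(3000 + trial)
        ntax = rng.choice([5, 6, 7])
        m = random_discrete_matrix(rng, ntax, nchar=rng.randrange(4, 9),
                                   missing_p=0.1)
        k = rng.choice([3.0, PUBLISHED_K, 12.0])
        best_sc, _ = exhaustive_search(m, k=k)
        res = ratchet_search(m, SearchConfig(k=k, iterations=4, seed=trial,
                                             n_starts=2))
        assert res.best_score == pytest.approx(best_sc, abs=1e-9)

    def test_too_few_taxa_rejected(self):
        m = CharacterMatrix(
            list("abc"),
            [Character([frozenset([0]), frozenset([1]), frozenset([1])])],
        )
        with pytest.raises(ValueError):
            ratchet_search(m, SearchConfig(k=3.0, iterations=1))


# --------------------------------------------------------------------------
# consensus


class TestStrictConsensus:
    def test_single_tree_is_its_own_consensus(self):
        t = Tree.random(7, random.Random(3))
        assert strict_consensus([t]) == t

    def test_incompatible_trees_collapse_to_star(self):
        taxa = list("abcde")
        t1 = simple_tree("((a,b),(c,d),e);", taxa)
        t2 = simple_tree("((a,c),(b,d),e);", taxa)
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == frozenset()

    def test_shared_clade_is_retained(self):
        taxa = list("abcde")
        t1 = simple_tree("(((a,b),c),d,e);", taxa)
        t2 = simple_tree("(((a,b),d),c,e);", taxa)
        cons = strict_consensus([t1, t2])
        splits = cons.bipartitions()
        ab = (1 << 0) | (1 << 1)
        full = (1 << 5) - 1
        assert splits == frozenset({ab if not ab & 1 else full ^ ab})

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            strict_consensus(
                [Tree.random(5, random.Random(0)), Tree.random(6, random.Random(0))]
            )


# --------------------------------------------------------------------------
# combined matrices


class TestCombinedMatrix:
    def make_rgb_table(self, taxa, points):
        import pandas as pd

        cols = {}
        for p in points:
            for b in "RGB":
                cols[f"p{p}_{b}"] = np.linspace(10, 200, len(taxa))
        return pd.DataFrame(cols, index=taxa)

    def test_column_arithmetic(self, specimen_table):
        m = CharacterMatrix.from_dataframe(
            specimen_table, additive=PUBLISHED_ADDITIVE, outgroup="FAS579"
        )
        rgb = self.make_rgb_table(m.taxa, range(1, 28))
        combined = build_combined_matrix(
            m, rgb, replaced_characters=range(9), equivalent_points=range(1, 13)
        )
        assert combined.nchar == 24 - 9 + 81
        assert sum(c.continuous for c in combined.characters) == 81
        assert all(c.additive for c in combined.characters if c.continuous)

    def test_empty_rgb_table_rejected(self, specimen_table):
        import pandas as pd

        m = CharacterMatrix.from_dataframe(specimen_table)
        with pytest.raises(ValueError):
            build_combined_matrix(m, pd.DataFrame(), range(9), range(1, 13))

    def test_specimen_without_point_gets_missing_cells(self, specimen_table):
        m = CharacterMatrix.from_dataframe(specimen_table)
        rgb = self.make_rgb_table(m.taxa[:-1], range(1, 28))
        combined = build_combined_matrix(m, rgb, range(9), range(1, 13))
        last = m.ntax - 1
        cont_chars = [c for c in combined.characters if c.continuous]
        assert all(c.states[last] is None for c in cont_chars)


# --------------------------------------------------------------------------
# trees and newick


class TestTree:
    def test_newick_round_trip_preserves_topology(self):
        rng = random.Random(9)
        taxa = [f"t{i}" for i in range(10)]
        t = Tree.random(10, rng)
        t2 = Tree.from_newick(t.to_newick(taxa), taxa)
        assert t == t2

    def test_search_with_continuous_characters_matches_exhaustive(self):
        rng = random.Random(77)
        taxa = [f"t{i}" for i in range(6)]
        chars = [
            Character([0.0, 0.4, 1.1, 2.0, 2.2, 3.0], additive=True,
                      continuous=True),
            Character([2.0, 0.0, 1.0, 0.5, None, 2.5], additive=True,
                      continuous=True),
            Character([frozenset([0]), frozenset([0]), frozenset([1]),
                       frozenset([1]), frozenset([2]), frozenset([2])]),
            Character([frozenset([1]), frozenset([0]), frozenset([1]),
                       frozenset([0]), frozenset([1]), frozenset([0])],
                      additive=True),
        ]
        m = CharacterMatrix(taxa, chars)
        best_sc, _ = exhaustive_search(m, k=5.0)
        res = ratchet_search(m, SearchConfig(k=5.0, iterations=5, seed=3))
        assert res.best_score == pytest.approx(best_sc, abs=1e-9)

    def test_continuous_character_interval_length(self):
        taxa = list("abcd")
        states = [0.0, 1.0, 5.0, 6.0]
        m = CharacterMatrix(taxa, [Character(states, additive=True, continuous=True)])
        t = simple_tree("((a,b),(c,d));", taxa)
        # spans: 1 within each cherry + 4 between intervals [0,1] and [5,6]
        assert char_length(t, m, 0) == pytest.approx(6.0)
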