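"""Irreversible parsimony: scoring, search, consensus, Newick."""

import itertools

import numpy as np
import pytest

from retromark.markers import MarkerMatrix
from retromark.parsimony import (
    Node,
    PhyloTree,
    SearchConfig,
    branch_length_bounds,
    build_from_clades,
    character_scores,
    collapse_zero_length_branches,
    consistency_index,
    heuristic_search,
    irreversible_parsimony_score,
    read_newick,
    strict_consensus,
    write_newick,
)

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_score(tree: PhyloTree, matrix: MarkerMatrix) -> int:
    """Minimum gains by exhaustive enumeration of every state assignment.

    Internal nodes and unscored leaves each take 0 or 1; the root is fixed
    at 0; any 1->0 edge disqualifies an assignment; gains are counted on
    0->1 edges.  Exponential - for small trees only.
    """
    nodes = list(tree.root.postorder())
    binary = matrix.to_binary()
    row = {t: binary[i] for i, t in enumerate(matrix.taxa)}
    total = 0
    for j in range(matrix.n_markers):
        free = [n for n in nodes
                if (not n.is_leaf and n.parent is not None)
                or (n.is_leaf and row[n.label][j] == -1)]
        best = None
        for assignment in itertools.product((0, 1), repeat=len(free)):
            state = {id(n): s for n, s in zip(free, assignment)}
            state[id(tree.root)] = 0
            for n in nodes:
                if n.is_leaf and row[n.label][j] != -1:
                    state[id(n)] = int(row[n.label][j])
            gains = 0
            ok = True
            for n in nodes:
                if n.parent is None:
                    continue
                p, s = state[id(n.parent)], state[id(n)]
                if p == 1 and s == 0:
                    ok = False
                    break
                gains += (p == 0 and s == 1)
            if ok and (best is None or gains < best):
                best = gains
        total += best
    return total


def _insertions(shape, x):
    """All ways of attaching leaf ``x`` to a nested-tuple tree shape."""
    out = [(shape, x)]
    if isinstance(shape, tuple):
        a, b = shape
        out += [(ia, b) for ia in _insertions(a, x)]
        out += [(a, ib) for ib in _insertions(b, x)]
    return out


def _all_shapes(taxa):
    if len(taxa) == 1:
        return [taxa[0]]
    return [s for smaller in _all_shapes(taxa[:-1])
            for s in _insertions(smaller, taxa[-1])]


def all_rooted_topologies(taxa: list[str], outgroup: str) -> list[PhyloTree]:
    """Every binary topology over ``taxa`` rooted by the outgroup."""

    def nwk(s):
        if isinstance(s, tuple):
            return f"({nwk(s[0])},{nwk(s[1])})"
        return s

    ingroup = [t for t in taxa if t != outgroup]
    return [read_newick(f"({outgroup},{nwk(s)});")
            for s in _all_shapes(ingroup)]


def random_matrix(rng, taxa, n_chars, missing=0.2, outgroup="OG"):
    symbols = np.array(["+", "-", "?"])
    probs = [(1 - missing) / 2, (1 - missing) / 2, missing]
    states = rng.choice(symbols, size=(len(taxa), n_chars), p=probs)
    states[taxa.index(outgroup)] = "-"
    return MarkerMatrix(taxa, [f"c{j}" for j in range(n_chars)], states,
                        outgroup=outgroup)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


class TestScoring:
    def test_single_gain_for_clean_ingroup_character(self):
        m = MarkerMatrix(["OG", "A", "B", "C"], ["c1"],
                         [["-"], ["+"], ["+"], ["+"]], outgroup="OG")
        tree = read_newick("(OG,(A,(B,C)));")
        assert irreversible_parsimony_score(tree, m) == 1

    def test_dp_equals_exhaustive_assignment_oracle(self):
        rng = np.random.default_rng(42)
        taxa = ["OG", "A", "B", "C", "D", "E"]
        for trial in range(12):
            m = random_matrix(rng, taxa, n_chars=8)
            tree = read_newick("(OG,((A,B),(C,(D,E))));") if trial % 2 else \
                read_newick("(OG,(A,(B,(C,(D,E)))));")
            assert irreversible_parsimony_score(tree, m) == \
                brute_force_score(tree, m)

    def test_score_invariant_under_child_reordering(self):
        t1 = read_newick("(OG,((A,B),(C,D)));")
        t2 = read_newick("(((D,C),(B,A)),OG);")
        rng = np.random.default_rng(0)
        m = random_matrix(rng, ["OG", "A", "B", "C", "D"], 10)
        assert irreversible_parsimony_score(t1, m) == \
            irreversible_parsimony_score(t2, m)

    def test_score_invariant_under_character_relabeling(self):
        rng = np.random.default_rng(1)
        taxa = ["OG", "A", "B", "C", "D"]
        m = random_matrix(rng, taxa, 10)
        perm = rng.permutation(10)
        m2 = MarkerMatrix(taxa, [m.markers[j] for j in perm],
                          m.states[:, perm], outgroup="OG")
        tree = read_newick("(OG,((A,B),(C,D)));")
        assert irreversible_parsimony_score(tree, m) == \
            irreversible_parsimony_score(tree, m2)

    def test_all_missing_character_adds_nothing(self):
        taxa = ["OG", "A", "B", "C"]
        m1 = MarkerMatrix(taxa, ["c1"], [["-"], ["+"], ["+"], ["-"]],
                          outgroup="OG")
        m2 = MarkerMatrix(taxa, ["c1", "c2"],
                          [["-", "?"], ["+", "?"], ["+", "?"], ["-", "?"]],
                          outgroup="OG")
        tree = read_newick("(OG,(A,(B,C)));")
        assert irreversible_parsimony_score(tree, m1) == \
            irreversible_parsimony_score(tree, m2)

    def test_unknown_leaf_rejected(self):
        m = MarkerMatrix(["OG", "A"], ["c1"], [["-"], ["+"]], outgroup="OG")
        with pytest.raises(ValueError, match="absent from matrix"):
            irreversible_parsimony_score(read_newick("(OG,(A,Z));"), m)

    def test_packaged_matrix_scores_53_on_published_topology(self, marsupial):
        """The published tree (polytomies included) explains every marker
        with a single gain."""
        newick = (
            "(Homo_sapiens,((Monodelphis_domestica,(Didelphis_virginiana,"
            "Metachirus_nudicaudatus)),((Rhyncholestes_raphanurus,"
            "Caenolestes_fuliginosus),(Dromiciops_gliroides,((Notoryctes_typhlops,"
            "(Phascogale_tapoatafa,Dasyurus_geoffroii,Sminthopsis_crassicaudata,"
            "Myrmecobius_fasciatus),(Macrotis_lagotis,Perameles_gunnii,"
            "Isoodon_obesulus)),(((Tarsipes_rostratus,Pseudocheirus_peregrinus),"
            "(Macropus_robustus,Potorous_tridactylus),Trichosurus_vulpecula),"
            "Vombatus_ursinus))))));"
        )
        tree = read_newick(newick)
        assert irreversible_parsimony_score(tree, marsupial) == 53
        assert (character_scores(tree, marsupial) == 1).all()


class TestConsistencyIndex:
    def test_arithmetic(self):
        taxa = ["OG", "A", "B", "C"]
        states = [["-"] * 10,
                  ["+"] * 10,
                  ["+"] * 5 + ["-"] * 5,
                  ["-"] * 5 + ["+"] * 5]
        m = MarkerMatrix(taxa, [f"c{j}" for j in range(10)],
                         np.array(states), outgroup="OG")
        assert consistency_index(m, 12) == pytest.approx(10 / 12)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        taxa = ["OG", "A", "B", "C", "D", "E"]
        tree = read_newick("(OG,((A,B),(C,(D,E))));")
        for _ in range(5):
            m = random_matrix(rng, taxa, 8)
            steps = brute_force_score(tree, m)
            n_var = int((m.to_binary() == 1).any(axis=0).sum())
            assert consistency_index(m, steps) == pytest.approx(n_var / steps)

    def test_zero_length_with_variable_characters_rejected(self):
        m = MarkerMatrix(["OG", "A"], ["c1"], [["-"], ["+"]], outgroup="OG")
        with pytest.raises(ValueError):
            consistency_index(m, 0)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


class TestHeuristicSearch:
    def test_clean_four_taxon_matrix_single_topology(self):
        m = MarkerMatrix(
            ["OG", "A", "B", "C"],
            ["c1", "c2"],
            [["-", "-"], ["+", "+"], ["+", "+"], ["-", "+"]],
            outgroup="OG",
        )
        trees, score = heuristic_search(m, SearchConfig(n_random_additions=10, seed=0))
        assert score == 2
        assert len(trees) == 1
        assert frozenset({"A", "B"}) in trees[0].clades()

    def test_matches_exhaustive_search_on_six_taxa(self):
        rng = np.random.default_rng(3)
        taxa = ["OG", "A", "B", "C", "D", "E"]
        topologies = all_rooted_topologies(taxa, "OG")
        assert len(topologies) == 105
        for trial in range(5):
            m = random_matrix(rng, taxa, 10, missing=0.15)
            exhaustive = min(irreversible_parsimony_score(t, m) for t in topologies)
            exhaustive_set = {
                t.canonical_key() for t in topologies
                if irreversible_parsimony_score(t, m) == exhaustive
            }
            trees, score = heuristic_search(
                m, SearchConfig(n_random_additions=30, seed=trial)
            )
            assert score == exhaustive
            assert {t.canonical_key() for t in trees} == exhaustive_set

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, ["OG", "A", "B", "C", "D", "E"], 12)
        runs = [heuristic_search(m, SearchConfig(n_random_additions=15, seed=5))
                for _ in range(2)]
        assert runs[0][1] == runs[1][1]
        assert [t.canonical_key() for t in runs[0][0]] == \
            [t.canonical_key() for t in runs[1][0]]

    @pytest.mark.parametrize("swap", ["SPR", "NNI"])
    def test_alternative_swap_modes_find_clean_optimum(self, swap):
        m = MarkerMatrix(
            ["OG", "A", "B", "C", "D"],
            ["c1", "c2", "c3"],
            [["-", "-", "-"], ["+", "+", "-"], ["+", "+", "-"],
             ["+", "-", "+"], ["+", "-", "+"]],
            outgroup="OG",
        )
        trees, score = heuristic_search(
            m, SearchConfig(n_random_additions=10, swap=swap, seed=1)
        )
        assert score == 3
        assert frozenset({"A", "B"}) in trees[0].clades()

    def test_too_few_taxa_rejected(self):
        m = MarkerMatrix(["OG", "A", "B"], ["c1"],
                         [["-"], ["+"], ["+"]], outgroup="OG")
        with pytest.raises(ValueError):
            heuristic_search(m)

    def test_conflict_free_simulation_scores_marker_count(self, small_dataset):
        """Without homoplasy every marker needs exactly one gain, so the
        best length equals the marker count and CI is 1."""
        trees, score = heuristic_search(
            small_dataset.matrix, SearchConfig(n_random_additions=10, seed=2)
        )
        assert score == small_dataset.matrix.n_markers
        assert consistency_index(small_dataset.matrix, score) == 1.0
        true_key = small_dataset.true_tree.canonical_key()
        assert any(t.canonical_key() == true_key for t in trees)


# ---------------------------------------------------------------------------
# Branch lengths / collapsing
# ---------------------------------------------------------------------------


class TestBranchBounds:
    def test_forced_and_optional_gains(self):
        # c1 forces a gain on the (A,B) edge; c2's gain can sit on (A,B) or
        # on A alone because B is unscored.
        m = MarkerMatrix(
            ["OG", "A", "B", "C"],
            ["c1", "c2"],
            [["-", "-"], ["+", "+"], ["+", "?"], ["-", "-"]],
            outgroup="OG",
        )
        tree = read_newick("(OG,((A,B),C));")
        lo, hi = branch_length_bounds(tree, m)[frozenset({"A", "B"})]
        assert (lo, hi) == (1, 2)

    def test_min_rule_collapses_unforced_branch(self):
        m = MarkerMatrix(
            ["OG", "A", "B", "C"],
            ["c1"],
            [["-"], ["+"], ["?"], ["-"]],
            outgroup="OG",
        )
        tree = read_newick("(OG,((A,B),C));")
        collapsed = collapse_zero_length_branches(tree, m, rule="min")
        assert frozenset({"A", "B"}) not in collapsed.clades()


# ---------------------------------------------------------------------------
# Consensus and Newick
# ---------------------------------------------------------------------------


class TestConsensus:
    def test_identical_trees_consensus_is_the_tree(self):
        t = read_newick("(OG,((A,B),(C,D)));")
        assert strict_consensus([t, t]) == t

    def test_conflicting_resolution_collapses_to_star(self):
        t1 = read_newick("(OG,((A,B),C));")
        t2 = read_newick("(OG,(A,(B,C)));")
        consensus = strict_consensus([t1, t2])
        assert consensus.clades() == frozenset({frozenset({"A", "B", "C"})})

    def test_clades_equal_intersection_oracle(self, marsupial_search):
        trees, _ = marsupial_search
        sample = trees[:25]
        consensus = strict_consensus(sample)
        expected = frozenset.intersection(*(t.clades() for t in sample))
        assert consensus.clades() == expected

    def test_differing_leaf_sets_rejected(self):
        t1 = read_newick("(OG,(A,B));")
        t2 = read_newick("(OG,(A,C));")
        with pytest.raises(ValueError):
            strict_consensus([t1, t2])

    def test_build_from_clades_round_trip(self):
        t = read_newick("(OG,((A,B),(C,(D,E))));")
        rebuilt = build_from_clades(t.leaf_labels, t.clades())
        assert rebuilt == t


class TestNewick:
    @pytest.mark.parametrize("newick", [
        "(A,B);",
        "(A,(B,C));",
        "((A,B),(C,D),E);",          # root polytomy
        "(A,(B,C,D),(E,(F,G,H)));",  # nested polytomies
    ])
    def test_round_trip_preserves_topology(self, newick):
        tree = read_newick(newick)
        again = read_newick(write_newick(tree))
        assert again == tree

    def test_cherry(self):
        tree = read_newick("(A,B);")
        assert tree.leaf_labels == {"A", "B"}
        assert len(tree.root.children) == 2

    def test_branch_lengths_preserved(self):
        tree = read_newick("(A:0.5,(B:1,C:2):0.25);")
        assert "B:1" in write_newick(tree)

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(9)]
        for _ in range(5):
            order = [str(t) for t in rng.permutation(taxa)]
            root = Node(children=[Node(label=order[0]), Node(label=order[1])])
            for leaf in order[2:]:
                edges = [n for n in root.postorder() if n.parent is not None]
                target = edges[int(rng.integers(len(edges)))]
                p = target.parent
                m = Node(children=[target, Node(label=leaf)])
                p.children[p.children.index(target)] = m
                m.parent = p
            tree = PhyloTree(root)
            assert read_newick(write_newick(tree)) == tree

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("((A,B);")
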