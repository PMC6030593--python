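"""Congruence metrics: worked examples, oracle equivalence, invariants."""

import random

import pytest

from stratcong import (
    MissingTaxonError,
    RangeTable,
    TaxonRange,
    UndefinedMetricError,
    compute_ger,
    compute_gmax,
    compute_gmin,
    compute_mig,
    compute_msm_star,
    compute_rci,
    compute_sci,
    date_nodes,
    score_tree,
)

from conftest import (
    make_ranges,
    oracle_gmin_gmax,
    oracle_mig,
    parse_newick,
    pectinate_newick,
)


class TestDateNodes:
    def test_max_fad_rule(self, good_tree, three_taxon_ranges):
        dated = date_nodes(good_tree, three_taxon_ranges)
        assert dated.root_age == 10
        internal = sorted(
            dated.node_ages[i]
            for i in range(dated.index.n_nodes)
            if dated.index.children[i]
        )
        assert internal == [5, 10]  # node(B,C)=5, root=10

    def test_all_equal_fads(self, good_tree):
        rt = make_ranges({"A": 7, "B": 7, "C": 7})
        dated = date_nodes(good_tree, rt)
        assert all(a == 7 for a in dated.node_ages)

    def test_missing_tip_named(self, three_taxon_ranges):
        tree = parse_newick("((B,C),(A,D));")
        with pytest.raises(MissingTaxonError, match="D"):
            date_nodes(tree, three_taxon_ranges)

    @pytest.mark.parametrize("seed", range(5))
    def test_recursive_invariant(self, seed):
        """Each internal age equals the max over child ages; parents >= children."""
        from stratcong import simulate_ranges, simulate_tree

        tree = simulate_tree(15, 0.1, seed=seed)
        rt = simulate_ranges(tree, 3.0, 3.0, seed=seed)
        dated = date_nodes(tree, rt)
        idx, ages = dated.index, dated.node_ages
        for i in range(idx.n_nodes):
            if idx.children[i]:
                assert ages[i] == max(ages[j] for j in idx.children[i])
            if idx.parent[i] >= 0:
                assert ages[idx.parent[i]] >= ages[i]


class TestMig:
    def test_worked_examples(self, good_tree, bad_tree, three_taxon_ranges):
        assert compute_mig(date_nodes(good_tree, three_taxon_ranges)) == 9.0
        assert compute_mig(date_nodes(bad_tree, three_taxon_ranges)) == 14.0

    def test_all_equal_is_zero(self, bad_tree):
        rt = make_ranges({"A": 4, "B": 4, "C": 4})
        assert compute_mig(date_nodes(bad_tree, rt)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_trees(self, seed):
        """Package MIG equals the independent recursive oracle."""
        from conftest import enumerate_rooted_binary, tuple_to_newick

        rng = random.Random(seed)
        taxa = [f"x{i}" for i in range(5)]
        fads = {t: rng.uniform(0, 50) for t in taxa}
        shapes = enumerate_rooted_binary(taxa)
        shape = shapes[rng.randrange(len(shapes))]
        tree = parse_newick(tuple_to_newick(shape))
        rt = make_ranges(fads)
        assert compute_mig(date_nodes(tree, rt)) == pytest.approx(
            oracle_mig(shape, fads), abs=1e-9
        )

    def test_invariant_to_child_order(self, three_taxon_ranges):
        a = parse_newick("((B,C),A);")
        b = parse_newick("(A,(C,B));")
        assert compute_mig(date_nodes(a, three_taxon_ranges)) == compute_mig(
            date_nodes(b, three_taxon_ranges)
        )

    def test_polytomy(self):
        """MIG generalizes to polytomies: every child edge to the node's age."""
        tree = parse_newick("(A,B,C);")
        rt = make_ranges({"A": 10, "B": 5, "C": 1})
        # root age 10; gaps 0 + 5 + 9
        assert compute_mig(date_nodes(tree, rt)) == 14.0


class TestExtremalBounds:
    def test_worked_three_taxa(self):
        assert compute_gmin([10, 5, 1]) == 9.0
        assert compute_gmax([10, 5, 1]) == 14.0

    def test_worked_four_taxa(self):
        assert compute_gmin([10, 5, 3, 1]) == 9.0
        assert compute_gmax([10, 5, 3, 1]) == 21.0

    def test_all_tied(self):
        assert compute_gmin([5, 5, 5]) == 0.0
        assert compute_gmax([5, 5, 5]) == 0.0

    def test_fewer_than_two_taxa(self):
        with pytest.raises(ValueError):
            compute_gmin([5])
        with pytest.raises(ValueError):
            compute_gmax([5])

    @pytest.mark.parametrize("n", [4, 5])
    def test_closed_forms_match_bruteforce(self, n):
        """Closed-form Gmin/Gmax equal exhaustive-topology extremes
        (the full n=4,5,6 sweep runs in the acceptance suite)."""
        rng = random.Random(n)
        for _ in range(5):
            fads = {f"x{i}": rng.uniform(0, 100) for i in range(n)}
            lo, hi = oracle_gmin_gmax(fads)
            assert compute_gmin(list(fads.values())) == pytest.approx(lo, abs=1e-9)
            assert compute_gmax(list(fads.values())) == pytest.approx(hi, abs=1e-9)

    def test_depends_only_on_fad_multiset(self):
        assert compute_gmin([1, 5, 10]) == compute_gmin([10, 1, 5])
        assert compute_gmax([1, 5, 10]) == compute_gmax([10, 1, 5])


class TestSci:
    def test_worked_examples(self, good_tree, bad_tree, three_taxon_ranges):
        assert compute_sci(good_tree, three_taxon_ranges) == 1.0
        assert compute_sci(bad_tree, three_taxon_ranges) == 0.0

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_age_ordered_pectinate_is_one(self, n):
        labels = [f"x{i}" for i in range(n)]
        fads = {lab: float(n - i) for i, lab in enumerate(labels)}
        tree = parse_newick(pectinate_newick(labels))
        assert compute_sci(tree, make_ranges(fads)) == 1.0

    def test_tie_is_consistent(self):
        tree = parse_newick("((B,C),A);")
        rt = make_ranges({"A": 5, "B": 5, "C": 1})
        assert compute_sci(tree, rt) == 1.0

    def test_count_root_option(self, bad_tree, three_taxon_ranges):
        """Root-included convention adds one consistent node to both counts."""
        assert compute_sci(bad_tree, three_taxon_ranges, count_root=True) == 0.5

    def test_too_few_tips(self):
        tree = parse_newick("(A,B);")
        with pytest.raises(ValueError):
            compute_sci(tree, make_ranges({"A": 2, "B": 1}))

    def test_polytomy_pooled_sister(self):
        """Child of a polytomy is judged against all remaining children pooled."""
        tree = parse_newick("((A,B),C,D);")
        rt = make_ranges({"A": 3, "B": 2, "C": 10, "D": 1})
        # one assessed node (A,B): pooled sister {C,D} max 10 >= 3 -> consistent
        assert compute_sci(tree, rt) == 1.0


class TestRatioMetrics:
    def test_rci(self):
        assert compute_rci(9, 4) == -125.0
        assert compute_rci(0, 4) == 100.0
        with pytest.raises(UndefinedMetricError):
            compute_rci(3, 0)

    def test_ger(self):
        assert compute_ger(9, 9, 14) == 1.0
        assert compute_ger(14, 9, 14) == 0.0
        with pytest.raises(UndefinedMetricError):
            compute_ger(3, 3, 3)
        with pytest.raises(ValueError):
            compute_ger(20, 9, 14)

    def test_msm_star(self):
        assert compute_msm_star(9, 9) == 1.0
        assert compute_msm_star(9, 14) == pytest.approx(9 / 14)
        with pytest.raises(UndefinedMetricError):
            compute_msm_star(0, 0)


class TestScoreTree:
    def test_worked_good(self, good_tree, three_taxon_ranges):
        s = score_tree(good_tree, three_taxon_ranges)
        assert s.as_dict() == {
            "mig": 9.0, "g_min": 9.0, "g_max": 14.0, "srl": 4.0,
            "sci": 1.0, "rci": -125.0, "ger": 1.0, "msm_star": 1.0,
        }

    def test_worked_bad(self, bad_tree, three_taxon_ranges):
        s = score_tree(bad_tree, three_taxon_ranges)
        assert s.mig == 14.0
        assert s.sci == 0.0
        assert s.rci == -250.0
        assert s.ger == 0.0
        assert s.msm_star == pytest.approx(9 / 14)

    def test_all_fads_equal_flags_undefined(self, good_tree):
        rt = RangeTable(
            [TaxonRange("A", 7, 5), TaxonRange("B", 7, 6), TaxonRange("C", 7, 7)]
        )
        s = score_tree(good_tree, rt)
        assert s.mig == 0.0 and s.sci == 1.0
        assert s.ger is None and s.msm_star is None
        assert s.rci == 100.0  # SRL = 3 > 0

    def test_point_occurrences_flag_rci(self, good_tree):
        rt = make_ranges({"A": 10, "B": 5, "C": 1}, duration=0.0)
        s = score_tree(good_tree, rt)
        assert s.rci is None and s.ger == 1.0

    def test_unmatched_tip_errors_unless_pruned(self, three_taxon_ranges):
        tree = parse_newick("(((B,C),A),D);")
        with pytest.raises(MissingTaxonError, match="D"):
            score_tree(tree, three_taxon_ranges)
        s = score_tree(tree, three_taxon_ranges, prune_unmatched=True)
        assert s.mig == 9.0  # reduces to the worked good tree

    def test_pectinate_perfect(self):
        n = 7
        labels = [f"x{i}" for i in range(n)]
        fads = {lab: float(n - i) for i, lab in enumerate(labels)}
        tree = parse_newick(pectinate_newick(labels))
        s = score_tree(tree, make_ranges(fads, duration=0.5))
        assert s.sci == 1.0 and s.ger == 1.0 and s.msm_star == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_bound_sandwich_random(self, seed):
        """g_min <= mig <= g_max, hence GER in [0,1] and MSM* in (0,1]."""
        from stratcong import simulate_ranges, simulate_tree

        tree = simulate_tree(12, 0.1, seed=seed)
        rt = simulate_ranges(tree, 4.0, 4.0, seed=seed + 100)
        s = score_tree(tree, rt)
        assert s.g_min <= s.mig <= s.g_max
        if s.ger is not None:
            assert 0.0 <= s.ger <= 1.0
        if s.msm_star is not None:
            assert 0.0 < s.msm_star <= 1.0
        if s.sci is not None:
            assert 0.0 <= s.sci <= 1.0
        if s.rci is not None:
            assert s.rci <= 100.0


class TestBoundProperties:
    """Property-based invariants of the extremal bounds."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _random_shape(labels, picks):
        """Deterministically build one rooted binary shape from attach picks."""
        shape = labels[0]
        from conftest import _attach_everywhere

        for lab, pick in zip(labels[1:], picks):
            options = _attach_everywhere(shape, lab)
            shape = options[pick % len(options)]
        return shape

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        fads=st.lists(
            st.floats(min_value=0, max_value=500, allow_nan=False, width=32),
            min_size=3,
            max_size=8,
        ),
        picks=st.lists(st.integers(min_value=0, max_value=10**6), min_size=7, max_size=7),
    )
    def test_any_topology_mig_within_bounds(self, fads, picks):
        """For every FAD multiset and any rooted binary topology,
        Gmin <= MIG <= Gmax."""
        from conftest import make_ranges, oracle_mig, parse_newick, tuple_to_newick

        labels = [f"x{i}" for i in range(len(fads))]
        table = dict(zip(labels, [float(f) for f in fads]))
        shape = self._random_shape(labels, picks)
        g_min = compute_gmin(list(table.values()))
        g_max = compute_gmax(list(table.values()))
        tree = parse_newick(tuple_to_newick(shape))
        mig = compute_mig(date_nodes(tree, make_ranges(table)))
        assert g_min - 1e-6 <= mig <= g_max + 1e-6
        assert mig == pytest.approx(oracle_mig(shape, table), abs=1e-6)
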