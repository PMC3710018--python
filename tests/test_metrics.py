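"""C_tax, R_tax, mean C_tax, report assembly, and the Rand baselines."""

import itertools

import numpy as np
import pandas as pd
import pytest

from taxcomp import (
    NonLaminarError,
    TaxonomyCollection,
    TaxonomyError,
    adjusted_rand_index,
    compare_all,
    ctax_pair,
    mean_ctax,
    rand_index,
    round_half_up,
    rtax,
)
from taxcomp.simulate import (
    SimulationConfig,
    generate_guide_tree,
    generate_nested_taxonomies,
)
from taxcomp.tree import tree_from_string

from conftest import cluster_sets, make_partition


class TestCtaxPair:
    def test_identity_is_one(self, abcd):
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        b = make_partition("B", {"p": "ab", "q": "cd"}, abcd)
        assert ctax_pair(a, b).ctax == 1.0

    def test_hand_enumerated_example_both_modes(self, abcd):
        # A = ab|cd (event: root), B = a|b|cd (events: root, anc(a,b))
        t = tree_from_string("((a,b),(c,d));")
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        b = make_partition("B", {"p": "a", "q": "b", "r": "cd"}, abcd)
        for mode in ("free", "tree"):
            pc = ctax_pair(a, b, mode=mode, t=t)
            assert (pc.n_shared, pc.n_union, pc.ctax) == (1, 2, 0.5)

    def test_single_species_pair_is_one_with_warning(self, abcd):
        a = make_partition("A", {"x": "abcd"}, abcd)
        b = make_partition("B", {"y": "abcd"}, abcd)
        with pytest.warns(UserWarning, match="single"):
            assert ctax_pair(a, b).ctax == 1.0

    def test_tree_mode_without_tree_is_an_error(self, abcd):
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        with pytest.raises(TaxonomyError, match="guide tree"):
            ctax_pair(a, a, mode="tree")

    def test_coarsening_formula(self):
        # for nested partitions C_tax = (k_coarse - 1)/(k_fine - 1) exactly
        cfg = SimulationConfig(seed=5, n_specimens=25)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (4, 11), seed=5, chain=True)
        pc = ctax_pair(coll["M1"], coll["M2"])
        assert pc.ctax == (4 - 1) / (11 - 1)


class TestRtax:
    def test_refinement_pair(self):
        cfg = SimulationConfig(seed=3, n_specimens=12)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (4, 9), seed=3, chain=True)
        r = rtax(coll)
        assert r["M2"] == 1.0
        assert r["M1"] == (4 - 1) / (9 - 1)

    def test_nested_chain_2_3_5(self):
        # brute-force oracle: on any compatible tree the union of event nodes
        # of a nested chain equals the finest partition's events
        cfg = SimulationConfig(seed=9, n_specimens=10)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (2, 3, 5), seed=9, chain=True)
        for mode, tree in (("free", None), ("tree", t)):
            r = rtax(coll, mode=mode, t=tree)
            assert (r["M1"], r["M2"], r["M3"]) == (1 / 4, 2 / 4, 1.0)

    def test_non_laminar_collection_refused_with_witness(self, abcd):
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        b = make_partition("B", {"p": "ac", "q": "bd"}, abcd)
        with pytest.raises(NonLaminarError):
            rtax(TaxonomyCollection(abcd, (a, b)))


class TestMeanCtax:
    def test_two_methods_mean_is_the_single_value(self):
        m = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["A", "B"], columns=["A", "B"])
        assert mean_ctax(m, "A") == pytest.approx(0.4)

    def test_all_ones(self):
        methods = list("ABCD")
        m = pd.DataFrame(1.0, index=methods, columns=methods)
        assert mean_ctax(m, "C") == 1.0

    def test_published_itax_mean_from_printed_values(self):
        methods = ["ITAX", "MTMC", "BAT", "HW", "BSD", "GMYC", "WP"]
        m = pd.DataFrame(np.nan, index=methods, columns=methods)
        for other, v in zip(methods[1:], (0.72, 0.91, 0.64, 0.57, 0.33, 0.53)):
            m.at["ITAX", other] = v
        assert round_half_up(mean_ctax(m, "ITAX"), 2) == 0.62

    def test_missing_pair_is_an_error(self):
        m = pd.DataFrame(np.nan, index=["A", "B"], columns=["A", "B"])
        with pytest.raises(TaxonomyError, match="missing"):
            mean_ctax(m, "A")


class TestCompareAll:
    def test_report_matrix_symmetric_unit_diagonal(self):
        cfg = SimulationConfig(seed=21, n_specimens=15)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (3, 6, 10), seed=21, chain=True)
        rep = compare_all(coll)
        mat = rep.ctax_matrix.values
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert all(0.0 <= v <= 1.0 for v in mat.ravel())

    def test_conservation_law_every_pair(self):
        cfg = SimulationConfig(seed=22, n_specimens=18)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (4, 7, 12), seed=22, chain=False)
        rep = compare_all(coll)
        for pc in rep.pairwise.values():
            assert pc.n_shared + pc.n_union == pc.n_a + pc.n_b

    def test_serialization_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=23, n_specimens=12)
        t = generate_guide_tree(cfg)
        coll = generate_nested_taxonomies(t, (3, 8), seed=23)
        rep = compare_all(coll)
        csv_path = tmp_path / "report.csv"
        rep.to_csv(csv_path)
        back = pd.read_csv(csv_path, index_col="method")
        assert list(back.columns) == ["M1", "M2", "Nb_species", "Rtax", "mean_Ctax"]
        js = rep.to_json_dict(decimals=2)
        assert js["species_counts"] == {"M1": 3, "M2": 8}


class TestMetricProperties:
    """Randomized invariants: symmetry, range, identity, triangle inequality."""

    @pytest.mark.parametrize("seed", range(20))
    def test_jaccard_distance_triangle_inequality(self, seed):
        cfg = SimulationConfig(seed=seed, n_specimens=16)
        t = generate_guide_tree(cfg)
        rng = np.random.default_rng(seed)
        ks = sorted(rng.integers(2, 16, size=3))
        coll = generate_nested_taxonomies(t, tuple(int(k) for k in ks), seed=seed, chain=True)
        d = {}
        for a, b in itertools.combinations(coll.method_names, 2):
            d[(a, b)] = d[(b, a)] = 1.0 - ctax_pair(coll[a], coll[b]).ctax
        for x, y, z in itertools.permutations(coll.method_names, 3):
            assert d[(x, z)] <= d[(x, y)] + d[(y, z)] + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_ctax_one_iff_identical_event_sets(self, seed):
        from taxcomp import extract_event_nodes

        cfg = SimulationConfig(seed=seed, n_specimens=14)
        t = generate_guide_tree(cfg)
        rng = np.random.default_rng(seed + 1000)
        ks = [int(k) for k in rng.integers(2, 14, size=2)]
        coll = generate_nested_taxonomies(t, tuple(ks), seed=seed, chain=False)
        a, b = coll["M1"], coll["M2"]
        pc = ctax_pair(a, b, mode="tree", t=t)
        same_events = extract_event_nodes(a, t).nodes == extract_event_nodes(b, t).nodes
        assert (pc.ctax == 1.0) == same_events


class TestRandBaselines:
    def test_identical_partitions(self, abcd):
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        b = make_partition("B", {"p": "ab", "q": "cd"}, abcd)
        assert rand_index(a, b) == 1.0
        assert adjusted_rand_index(a, b) == 1.0

    def test_crossing_example_against_pair_enumeration(self, abcd):
        a = make_partition("A", {"x": "ab", "y": "cd"}, abcd)
        b = make_partition("B", {"p": "ac", "q": "bd"}, abcd)
        assert rand_index(a, b) == pytest.approx(2 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_rand_matches_brute_force_pair_counting(self, seed):
        # independent oracle: enumerate all specimen pairs directly
        rng = np.random.default_rng(seed)
        ids = tuple(f"s{i}" for i in range(10))
        from taxcomp import SpeciesPartition, SpecimenUniverse

        uni = SpecimenUniverse(ids)
        la = {s: f"c{rng.integers(4)}" for s in ids}
        lb = {s: f"c{rng.integers(4)}" for s in ids}
        a = SpeciesPartition("A", uni, la)
        b = SpeciesPartition("B", uni, lb)
        agree = sum(
            (la[x] == la[y]) == (lb[x] == lb[y])
            for x, y in itertools.combinations(ids, 2)
        )
        assert rand_index(a, b) == pytest.approx(agree / len(list(itertools.combinations(ids, 2))))

    def test_duplication_moves_rand_but_not_ctax(self):
        # ab|cd vs a|b|cd, then clone c and d 5x: the Rand index shifts with
        # cluster occupancy while the event-set index depends only on boundaries
        from taxcomp import SpecimenUniverse

        base_uni = SpecimenUniverse(("a", "b", "c", "d"))
        a0 = make_partition("A", {"x": "ab", "y": "cd"}, base_uni)
        b0 = make_partition("B", {"p": "a", "q": "b", "r": "cd"}, base_uni)
        coll = TaxonomyCollection(base_uni, (a0, b0))
        from taxcomp import inflate_specimens

        fat = inflate_specimens(coll, {"c": 5, "d": 5})
        a1, b1 = fat["A"], fat["B"]
        assert rand_index(a0, b0) == pytest.approx(5 / 6)
        assert rand_index(a1, b1) == pytest.approx(65 / 66)
        assert ctax_pair(a0, b0).ctax == ctax_pair(a1, b1).ctax == 0.5
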