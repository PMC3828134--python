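import numpy as np
import networkx as nx
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_residue, simple_structure
from oracles import (
    brute_force_max_clique_size,
    numeric_superimposition_rmsd,
)

from bsfp.core_model import surface_residues
from bsfp.errors import DegenerateGeometryError, EmptyRegionError, InvalidInputError
from bsfp.fixtures import default_motif, make_toy_protein
from bsfp.sitegraph import (
    CompareParams,
    ProteinGraph,
    FunctionalPoint,
    assign_z_scores,
    build_product_graph,
    build_protein_graph,
    compare_sites,
    functional_points,
    max_clique,
    superimpose,
    Hit,
)


def alanine_line(spacing=4.0, count=3):
    residues = []
    for i in range(count):
        x = spacing * i
        residues.append(make_residue("A", i + 1, "ALA",
                                     [("CA", "C", (x, 3, 0)),
                                      ("CB", "C", (x, 0, 0))]))
    return simple_structure(residues)


class TestProteinGraph:
    def test_three_alanines_within_cutoff(self):
        s = alanine_line()
        g = build_protein_graph(s, {r.key for r in s.residues},
                                CompareParams(d_max=15.0))
        assert len(g) == 3
        assert set(g.ptypes) == {"aliphatic"}
        assert len(g.edges()) == 3

    def test_short_cutoff_drops_far_edge(self):
        s = alanine_line()
        g = build_protein_graph(s, {r.key for r in s.residues},
                                CompareParams(d_max=5.0))
        assert len(g.edges()) == 2  # ends are 8 Å apart

    def test_typing_of_charged_and_aromatic(self):
        s = simple_structure([
            make_residue("A", 1, "ARG", [("CA", "C", (0, 0, 0)),
                                         ("NH1", "N", (0, 3, 0))]),
            make_residue("A", 2, "ASP", [("CA", "C", (6, 0, 0)),
                                         ("OD1", "O", (6, 3, 0))]),
            make_residue("A", 3, "PHE", [("CA", "C", (12, 0, 0)),
                                         ("CG", "C", (12, 3, 0))]),
        ])
        points = functional_points(s)
        assert {p.ptype for p in points} == {"donor", "acceptor", "aromatic"}

    def test_empty_region_rejected(self):
        s = alanine_line()
        with pytest.raises(EmptyRegionError):
            build_protein_graph(s, {("Z", 1)}, CompareParams())

    def test_stored_distances_are_euclidean(self, motif_protein):
        g = build_protein_graph(motif_protein, None, CompareParams())
        for i in range(min(len(g), 10)):
            for j in range(i + 1, min(len(g), 10)):
                expected = np.linalg.norm(g.positions[i] - g.positions[j])
                assert g.distances[i, j] == pytest.approx(expected)


def random_graph(seed, n=8, d_max=15.0):
    rng = np.random.default_rng(seed)
    ptypes = ["donor", "acceptor", "mixed", "aromatic", "aliphatic"]
    points = [
        FunctionalPoint(rng.uniform(0, 12, 3), ptypes[rng.integers(0, 5)],
                        ("A", i + 1, "", "ALA"))
        for i in range(n)
    ]
    return ProteinGraph(points, d_max)


class TestProductGraph:
    def test_self_product_contains_identity_clique(self):
        g = random_graph(1, n=4)
        pg = build_product_graph(g, g, 0.5)
        identity = [pg.vertices.index((i, i)) for i in range(4)]
        for a in identity:
            for b in identity:
                if a != b:
                    assert pg.adjacency[a, b]
        assert len(max_clique(pg)) >= 4

    def test_type_incompatibility_gives_empty_graph(self):
        donors = ProteinGraph([FunctionalPoint(np.array([i, 0, 0.0]), "donor",
                                               ("A", i, "", "ARG"))
                               for i in range(3)], 15.0)
        acceptors = ProteinGraph([FunctionalPoint(np.array([i, 0, 0.0]), "acceptor",
                                                  ("A", i, "", "ASP"))
                                  for i in range(3)], 15.0)
        pg = build_product_graph(donors, acceptors, 2.0)
        assert len(pg) == 0
        assert max_clique(pg) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_edges_match_double_loop_oracle(self, seed):
        gq = random_graph(seed, n=8)
        gt = random_graph(seed + 100, n=8)
        eps = 2.0
        pg = build_product_graph(gq, gt, eps)
        for a, (i, j) in enumerate(pg.vertices):
            for b, (k, l) in enumerate(pg.vertices):
                dq = np.linalg.norm(gq.positions[i] - gq.positions[k])
                dt = np.linalg.norm(gt.positions[j] - gt.positions[l])
                expected = (a != b and i != k and j != l
                            and dq <= gq.d_max and dt <= gt.d_max
                            and abs(dq - dt) <= eps)
                assert bool(pg.adjacency[a, b]) == expected


class TestMaxClique:
    def test_complete_graph(self):
        adj = ~np.eye(5, dtype=bool)
        assert len(max_clique(adj)) == 5

    def test_edgeless_graph(self):
        adj = np.zeros((7, 7), dtype=bool)
        assert len(max_clique(adj)) == 1

    def test_empty_graph(self):
        assert max_clique(np.zeros((0, 0), dtype=bool)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        adj = np.triu(rng.random((n, n)) < 0.5, 1)
        adj = adj | adj.T
        result = max_clique(adj)
        for i in result:
            for j in result:
                if i != j:
                    assert adj[i, j]
        assert len(result) == brute_force_max_clique_size(adj)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bron_kerbosch_on_larger_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(12, 19))
        adj = np.triu(rng.random((n, n)) < 0.5, 1)
        adj = adj | adj.T
        expected = max(len(c) for c in
                       nx.find_cliques(nx.from_numpy_array(adj)))
        assert len(max_clique(adj)) == expected

    def test_deterministic(self):
        rng = np.random.default_rng(42)
        adj = np.triu(rng.random((15, 15)) < 0.5, 1)
        adj = adj | adj.T
        assert max_clique(adj) == max_clique(adj)


class TestSuperimpose:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(0, 10, (5, 3))
        t = superimpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert t.rmsd == pytest.approx(0, abs=1e-9)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 10, (6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = a @ rot.T + np.array([1.0, 2.0, 3.0])
        t = superimpose(a, b)
        assert t.rmsd == pytest.approx(0, abs=1e-9)
        np.testing.assert_allclose(t.apply(a), b, atol=1e-8)

    def test_noisy_tetrahedron_matches_numeric_optimizer(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                      [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3)]])
        rng = np.random.default_rng(3)
        b = a + rng.normal(0, 0.1, a.shape)
        t = superimpose(a, b)
        assert t.rmsd == pytest.approx(numeric_superimposition_rmsd(a, b),
                                       abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            superimpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superimpose(line, line + 1.0)


class TestCompareSites:
    def test_self_comparison_full_coverage(self, motif_protein):
        region = surface_residues(motif_protein)
        copy = motif_protein.copy()
        copy.id = "copy"
        hit = compare_sites(motif_protein, region, copy)
        assert hit is not None
        assert hit.rmsd < 1e-6
        aligned_query = {(c, n, i) for (c, n, i, _), _t in hit.correspondence}
        assert aligned_query == region

    def test_rigid_transform_invariance(self, motif_protein):
        region = surface_residues(motif_protein)
        reference = compare_sites(motif_protein, region, motif_protein)
        moved = motif_protein.copy()
        moved.id = "moved"
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        moved.transform(rot, np.array([7.0, -4.0, 2.0]))
        hit = compare_sites(motif_protein, region, moved)
        assert hit is not None
        assert hit.rmsd < 1e-6
        assert hit.score == reference.score

    def test_target_residue_order_permutation_invariance(self, motif_protein):
        region = {tuple(k) for k in motif_protein.metadata["motif_residues"]}
        target = motif_protein.copy()
        target.id = "perm"
        rng = np.random.default_rng(8)
        order = rng.permutation(len(target.residues))
        target.residues = [target.residues[i] for i in order]
        hit = compare_sites(motif_protein, region, target)
        ref = compare_sites(motif_protein, region, motif_protein)
        assert hit.score == ref.score

    def test_score_symmetry(self):
        a = make_toy_protein(20, default_motif(), seed=31, struct_id="a")
        b = a.copy()
        b.id = "b"
        rot = Rotation.random(rng=np.random.default_rng(6)).as_matrix()
        b.transform(rot, np.array([1.0, 1.0, 1.0]))
        region_a = surface_residues(a)
        region_b = surface_residues(b)
        fwd = compare_sites(a, region_a, b)
        rev = compare_sites(b, region_b, a)
        assert fwd.score == rev.score

    def test_planted_motif_recovery_in_decoy(self):
        motif = default_motif(0.0, 0)
        query = make_toy_protein(10, motif, seed=41, struct_id="q")
        region = {tuple(k) for k in query.metadata["motif_residues"]}
        rot = Rotation.random(rng=np.random.default_rng(42)).as_matrix()
        from bsfp.fixtures import MotifSpec
        planted = MotifSpec(motif.residue_types, motif.geometry @ rot.T,
                            0.2, 43)
        carrier = make_toy_protein(40, planted, seed=44, struct_id="carrier")
        hit = compare_sites(query, region, carrier)
        assert hit is not None
        target_motif = {tuple(k) for k in carrier.metadata["motif_residues"]}
        matched = {(c, n, i) for _q, (c, n, i, _name) in hit.correspondence}
        assert len(matched & target_motif) >= 5

    def test_no_hit_below_min_clique(self):
        s = alanine_line(spacing=4.0, count=3)
        # target distances incompatible with the query's
        t = alanine_line(spacing=9.0, count=3)
        t.id = "t"
        hit = compare_sites(s, {r.key for r in s.residues}, t,
                            CompareParams(epsilon=0.5))
        assert hit is None


class TestZScores:
    def test_two_point_standardization(self):
        hits = [Hit("a", [], np.eye(3), np.zeros(3), 0.0, 4.0),
                Hit("b", [], np.eye(3), np.zeros(3), 0.0, 6.0)]
        z = [h.z_score for h in assign_z_scores(hits)]
        assert z == pytest.approx([-1.0, 1.0])

    def test_zero_variance(self):
        hits = [Hit(str(i), [], np.eye(3), np.zeros(3), 0.0, 5.0)
                for i in range(4)]
        assert all(h.z_score == 0 for h in assign_z_scores(hits))

    def test_hand_computed_standardization(self):
        scores = [2.0, 4.0, 4.0, 5.0, 10.0]
        hits = [Hit(str(i), [], np.eye(3), np.zeros(3), 0.0, s)
                for i, s in enumerate(scores)]
        mean = np.mean(scores)
        sd = np.std(scores)
        expected = [(s - mean) / sd for s in scores]
        z = [h.z_score for h in assign_z_scores(hits)]
        assert z == pytest.approx(expected)
        # ranking by z preserves ranking by score
        assert np.argsort(z).tolist() == np.argsort(scores, kind="stable").tolist()

    def test_single_hit_gets_zero(self):
        hits = [Hit("a", [], np.eye(3), np.zeros(3), 0.0, 9.0)]
        assert assign_z_scores(hits)[0].z_score == 0


class TestParams:
    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            CompareParams(d_max=-1.0)
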