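"""Bipartite data model, file I/O and topological metrics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import ecorestore as er
from ecorestore.network import FormatError, IsolatedSpeciesError

from conftest import staircase


# ---------------------------------------------------------------------------
# NODF oracle: literal enumeration of all row and column pairs
# ---------------------------------------------------------------------------

def nodf_bruteforce(mat: np.ndarray) -> float:
    """Independent NODF computation: sort by marginal totals, enumerate all
    pairs, paired overlap only under strictly decreasing fill."""
    mat = (np.asarray(mat) > 0).astype(int)

    def half(m):
        rows = sorted(range(m.shape[0]), key=lambda i: -m[i].sum())
        vals = []
        for x in range(len(rows)):
            for y in range(x + 1, len(rows)):
                hi, lo = m[rows[x]], m[rows[y]]
                if hi.sum() > lo.sum() > 0:
                    vals.append(100.0 * (hi & lo).sum() / lo.sum())
                else:
                    vals.append(0.0)
        return vals

    pairs = half(mat) + half(mat.T)
    return sum(pairs) / len(pairs)


class TestNodf:
    def test_perfectly_nested_staircase_scores_100(self):
        assert er.nodf(staircase(5)) == pytest.approx(100.0)
        assert er.nodf(staircase(4)) == pytest.approx(100.0)

    def test_unique_partner_matrix_scores_0(self):
        assert er.nodf(np.eye(5, dtype=int)) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            r, c = rng.integers(2, 7, size=2)
            mat = (rng.random((r, c)) < rng.uniform(0.2, 0.8)).astype(int)
            if mat.sum(axis=1).min() == 0 or mat.sum(axis=0).min() == 0:
                continue  # keep within the isolate-free domain
            assert er.nodf(mat) == pytest.approx(nodf_bruteforce(mat), abs=1e-10)
            checked += 1

    def test_single_species_side_warns_and_returns_zero(self, star_net):
        with pytest.warns(UserWarning):
            assert er.nodf(star_net) == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        mat = staircase(5)
        shuffled = mat[rng.permutation(5)][:, rng.permutation(5)]
        assert er.nodf(shuffled) == pytest.approx(er.nodf(mat))


class TestAttributes:
    def test_direct_formulas(self, small_net):
        att = er.attributes(small_net)
        assert (att.size_S, att.asymmetry_A, att.connectance_C) == (5, 1.5, 0.5)
        assert att.L_links == 3

    def test_complete_bipartite_has_connectance_one(self):
        net = er.BipartiteNetwork(("p1", "p2", "p3", "p4"),
                                  ("a1", "a2", "a3", "a4"),
                                  np.ones((4, 4), dtype=int))
        assert er.attributes(net).connectance_C == 1.0

    def test_size_of_74_species_community(self):
        # 31 plants and 43 pollinators, the size of a documented field network
        net = er.generate(er.GeneratorConfig(31, 43, 0.1, 1.0, seed=0))
        assert er.attributes(net).size_S == 74

    def test_identities_hold_on_generated_networks(self):
        for seed in range(20):
            net = er.generate(er.GeneratorConfig(6, 9, 0.3, float(seed % 3), seed=seed))
            att = er.attributes(net)
            assert att.size_S == att.n_plants + att.m_pollinators
            assert att.connectance_C * att.n_plants * att.m_pollinators == pytest.approx(att.L_links)
            assert 0 <= att.nestedness_NODF <= 100


class TestCentrality:
    def test_degree_equals_incidence_margins(self, small_net):
        scores = er.centrality(small_net, "degree").scores
        inc = small_net.incidence
        for i, p in enumerate(small_net.plant_labels):
            assert scores[p] == inc[i].sum()
        for j, a in enumerate(small_net.pollinator_labels):
            assert scores[a] == inc[:, j].sum()

    def test_star_hub_dominates_degree_and_closeness(self, star_net):
        deg = er.centrality(star_net, "degree").scores
        assert deg["hub"] == 4 and all(deg[a] == 1 for a in star_net.pollinator_labels)
        clo = er.centrality(star_net, "closeness").scores
        assert clo["hub"] > clo["a1"]

    def test_bridge_node_has_highest_betweenness(self):
        # bipartite path p1 - a1 - p2: a1 is the only bridge
        net = er.BipartiteNetwork(("p1", "p2"), ("a1",), np.ones((2, 1), dtype=int))
        btw = er.centrality(net, "betweenness").scores
        assert btw["a1"] > btw["p1"] == btw["p2"]

    def test_unknown_measure_rejected(self, small_net):
        with pytest.raises(ValueError):
            er.centrality(small_net, "eigenvector")

    def test_degree_betweenness_strongly_correlated_on_heterogeneous_nets(self):
        # hubs lie on many shortest paths, so the two rankings agree
        rhos = []
        for seed in range(5):
            net = er.generate(er.GeneratorConfig(12, 18, 0.2, 2.0, seed=seed))
            deg = er.centrality(net, "degree").scores
            btw = er.centrality(net, "betweenness").scores
            sp = [deg[s] for s in net.species], [btw[s] for s in net.species]
            rhos.append(spearmanr(*sp).statistic)
        assert np.mean(rhos) > 0.7


class TestProjection:
    def test_shared_plant_yields_clique(self, star_net):
        proj = er.project(star_net, "pollinators")
        off = proj.adjacency[~np.eye(4, dtype=bool)]
        assert (off == 1).all()

    def test_disjoint_partner_sets_give_no_edge(self, small_net):
        proj = er.project(small_net, "plants")
        assert proj.adjacency[0, 1] == 0

    def test_edge_weight_counts_shared_partners(self):
        inc = np.array([[1, 1, 0], [1, 1, 1]], dtype=int)
        net = er.BipartiteNetwork(("p1", "p2"), ("a1", "a2", "a3"), inc)
        assert er.project(net, "plants").adjacency[0, 1] == 2

    def test_beta_eff_star_projection(self, star_net):
        # pollinator projection is K4: 3-regular, so beta_eff = 3
        assert er.beta_eff(er.project(star_net, "pollinators")) == pytest.approx(3.0)

    def test_beta_eff_hand_computed_star(self):
        # unweighted star on 4 nodes: degrees (3,1,1,1) -> (9+1+1+1)/6 = 2
        adj = np.zeros((4, 4))
        adj[0, 1:] = adj[1:, 0] = 1
        proj = er.ProjectedNetwork("plants", ("a", "b", "c", "d"), adj)
        assert er.beta_eff(proj) == pytest.approx(2.0)

    def test_beta_eff_edgeless_projection_is_zero(self, pair_net):
        assert er.beta_eff(er.project(pair_net, "plants")) == 0.0

    def test_beta_eff_invariant_under_relabeling(self):
        net = er.generate(er.GeneratorConfig(7, 9, 0.3, 1.0, seed=11))
        perm = np.random.default_rng(0).permutation(7)
        relabeled = er.BipartiteNetwork(
            tuple(net.plant_labels[i] for i in perm),
            net.pollinator_labels, net.incidence[perm])
        for side in ("plants", "pollinators"):
            assert er.beta_eff(er.project(relabeled, side)) == pytest.approx(
                er.beta_eff(er.project(net, side)))


class TestIO:
    @pytest.mark.parametrize("dialect", ["weblife_csv", "edge_list"])
    def test_round_trip_identity(self, tmp_path, dialect):
        for seed in range(10):
            net = er.generate(er.GeneratorConfig(5, 8, 0.3, 1.0, seed=seed))
            path = tmp_path / f"net_{dialect}_{seed}.csv"
            er.write_incidence(net, path, dialect)
            back = er.read_incidence(path, dialect)
            assert back.plant_labels == net.plant_labels
            assert back.pollinator_labels == net.pollinator_labels
            assert (back.incidence == net.incidence).all()

    def test_complete_2x2(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(",a1,a2\np1,1,1\np2,1,1\n")
        net = er.read_incidence(path)
        assert (net.n_plants, net.m_pollinators, net.n_links) == (2, 2, 4)

    def test_positive_weights_binarized(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(",a1,a2\np1,7,0\np2,0,3\n")
        assert er.read_incidence(path).n_links == 2

    def test_negative_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",a1,a2\np1,1,-1\np2,1,1\n")
        with pytest.raises(FormatError):
            er.read_incidence(path)

    def test_isolated_species_named_in_error(self, tmp_path):
        path = tmp_path / "iso.csv"
        path.write_text(",a1,a2\np1,1,0\np2,0,0\n")
        with pytest.raises(IsolatedSpeciesError, match="p2"):
            er.read_incidence(path)

    def test_edge_list_row_per_link_and_determinism(self, tmp_path, small_net):
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        er.write_incidence(small_net, p1, "edge_list")
        er.write_incidence(small_net, p2, "edge_list")
        lines = p1.read_text().strip().split("\n")
        assert len(lines) == 1 + small_net.n_links
        assert p1.read_bytes() == p2.read_bytes()


class TestInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            er.BipartiteNetwork(("x",), ("x",), np.ones((1, 1), dtype=int))

    def test_nonbinary_entries_rejected(self):
        with pytest.raises(ValueError):
            er.BipartiteNetwork(("p",), ("a",), np.array([[2]]))

    def test_incidence_is_immutable(self, small_net):
        with pytest.raises(ValueError):
            small_net.incidence[0, 0] = 0
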