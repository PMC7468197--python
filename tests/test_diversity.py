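import numpy as np
import pytest

import oracles
from crucivir.diversity import (
    build_similarity_network,
    cluster_by_threshold,
    matrix_stats,
    one_way_anova,
    pairwise_identity_matrix,
    pairwise_percent_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=120):
    return "".join(rng.choice(list(AA), size=n))


def _family(rng, ancestor, size, rate=0.08):
    members = []
    for _ in range(size):
        seq = [rng.choice(list(AA)) if rng.random() < rate else a for a in ancestor]
        members.append("".join(seq))
    return members


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_percent_identity("MKVLAW", "MKVLAW") == 100.0

    def test_single_mismatch(self):
        assert pairwise_percent_identity("AAAA", "AATA") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = _random_protein(rng, 60), _random_protein(rng, 80)
            assert pairwise_percent_identity(a, b) == pytest.approx(
                pairwise_percent_identity(b, a))

    def test_matrix_structure(self):
        rng = np.random.default_rng(1)
        m = pairwise_identity_matrix([(f"p{i}", _random_protein(rng)) for i in range(5)])
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)
        assert np.all(np.isfinite(m.values))

    def test_empty_sequence_named_in_error(self):
        with pytest.raises(ValueError, match="bad_id"):
            pairwise_identity_matrix([("ok", "MKV"), ("bad_id", "")])

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            pairwise_identity_matrix([("only", "MKV")])


class TestMatrixStats:
    def test_two_by_two(self):
        m = pairwise_identity_matrix([("a", "MKVLAW"), ("b", "MKVLAW")])
        mean, sd = matrix_stats(m)
        assert mean == 100.0 and sd == 0.0

    def test_mean_invariant_under_reordering(self):
        rng = np.random.default_rng(2)
        prots = [(f"p{i}", _random_protein(rng)) for i in range(4)]
        mean1, _ = matrix_stats(pairwise_identity_matrix(prots))
        mean2, _ = matrix_stats(pairwise_identity_matrix(prots[::-1]))
        assert mean1 == pytest.approx(mean2)


class TestClustering:
    def _uniform_matrix(self, n, pi):
        from crucivir.diversity import IdentityMatrix

        vals = np.full((n, n), pi, dtype=float)
        np.fill_diagonal(vals, 100.0)
        return IdentityMatrix(ids=[f"s{i}" for i in range(n)], values=vals)

    def test_mutual_high_identity_forms_one_cluster(self):
        cs = cluster_by_threshold(self._uniform_matrix(8, 80.0), 70.0, 100.0, min_size=7)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 8

    def test_identical_pair_collapses_to_representative(self):
        m = self._uniform_matrix(8, 80.0)
        m.values[0, 1] = m.values[1, 0] = 100.0  # s0 and s1 identical
        cs = cluster_by_threshold(m, 70.0, 98.0, min_size=7)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 7
        assert "s0" in cs.representatives

    def test_single_linkage_chain(self):
        from crucivir.diversity import IdentityMatrix

        vals = np.array([[100, 75, 40], [75, 100, 75], [40, 75, 100]], dtype=float)
        m = IdentityMatrix(ids=["a", "b", "c"], values=vals)
        cs = cluster_by_threshold(m, 70.0, 100.0, min_size=3)
        assert cs.clusters == [["a", "b", "c"]]

    def test_planted_families_recovered_exactly(self):
        rng = np.random.default_rng(3)
        proteins = []
        for f in range(3):
            for i, seq in enumerate(_family(rng, _random_protein(rng, 100), 4)):
                proteins.append((f"f{f}_{i}", seq))
        m = pairwise_identity_matrix(proteins)
        cs = cluster_by_threshold(m, 60.0, 100.0, min_size=2)
        assert len(cs.clusters) == 3
        for cluster in cs.clusters:
            assert len({pid.split("_")[0] for pid in cluster}) == 1

    def test_order_independence(self):
        rng = np.random.default_rng(4)
        proteins = [(f"p{i}", s) for f in range(2)
                    for i, s in enumerate(_family(rng, _random_protein(rng, 80), 3))]
        proteins = [(f"p{i}", s) for i, (_, s) in enumerate(proteins)]
        c1 = cluster_by_threshold(pairwise_identity_matrix(proteins), 60.0, 100.0)
        c2 = cluster_by_threshold(pairwise_identity_matrix(proteins[::-1]), 60.0, 100.0)
        assert c1.clusters == c2.clusters

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            cluster_by_threshold(self._uniform_matrix(3, 50.0), 80.0, 70.0)


class TestAnova:
    def test_identical_groups_degenerate_convention(self):
        assert one_way_anova([[5, 5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        f, p = one_way_anova([[0, 0.01, -0.01], [10, 10.01, 9.99]])
        assert p < 0.001

    def test_matches_closed_form_f(self):
        groups = [[50, 60, 70, 80, 90], [55, 65, 75, 85, 95], [10, 20, 30, 40, 50]]
        f, p = one_way_anova(groups)
        assert f == pytest.approx(oracles.anova_f_closed_form(groups))
        assert 0 <= p <= 1

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [3]])


class TestSimilarityNetwork:
    def test_identical_proteins_connected_at_strict_cutoff(self):
        rng = np.random.default_rng(5)
        prot = _random_protein(rng, 200)
        g = build_similarity_network([("a", prot), ("b", prot)], cutoff=1e-20)
        assert g.graph.has_edge("a", "b")

    def test_unrelated_proteins_stay_isolated(self):
        rng = np.random.default_rng(6)
        prots = [(f"p{i}", _random_protein(rng, 100)) for i in range(10)]
        g = build_similarity_network(prots, cutoff=1e-20)
        assert g.graph.number_of_edges() == 0
        assert len(g.isolated_nodes()) == 10

    def test_edge_sets_nest_with_cutoff(self):
        rng = np.random.default_rng(7)
        fam = _family(rng, _random_protein(rng, 150), 4, rate=0.3)
        prots = [(f"p{i}", s) for i, s in enumerate(fam)]
        strict = set(build_similarity_network(prots, cutoff=1e-20).graph.edges)
        loose = set(build_similarity_network(prots, cutoff=1e-10).graph.edges)
        assert strict <= loose

    def test_no_self_loops_and_groups_attached(self):
        rng = np.random.default_rng(8)
        prot = _random_protein(rng, 150)
        g = build_similarity_network([("a", prot), ("b", prot)],
                                     groups={"a": "crucivirus", "b": "tombusvirus"})
        assert all(u != v for u, v in g.graph.edges)
        assert g.graph.nodes["a"]["group"] == "crucivirus"

    def test_edge_tsv_export(self, tmp_path):
        rng = np.random.default_rng(9)
        prot = _random_protein(rng, 150)
        g = build_similarity_network([("a", prot), ("b", prot)])
        out = tmp_path / "edges.tsv"
        g.to_edge_tsv(out)
        assert out.read_text().startswith("id1\tid2\tevalue")
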