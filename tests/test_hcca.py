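import numpy as np
import pandas as pd
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from coexpatlas import ValidationError
from coexpatlas.hcca import (cluster_tightness, cluster_tissue_profile,
                             hcca_cluster, ClusterSet)


def clique_union(sizes):
    g = nx.Graph()
    truth, off = [], 0
    for k in sizes:
        nodes = [f"n{off + i:03d}" for i in range(k)]
        g.add_edges_from((a, b) for i, a in enumerate(nodes)
                         for b in nodes[i + 1:])
        truth.append(frozenset(nodes))
        off += k
    return g, truth


def planted_partition(seed, k=4, n=25, p_in=0.6, p_out=0.02):
    rng = np.random.default_rng(seed)
    names = [f"v{i:03d}" for i in range(k * n)]
    labels = np.repeat(np.arange(k), n)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(k * n):
        for j in range(i + 1, k * n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g, labels, names


def predicted_labels(clusters: ClusterSet, names):
    assign = {}
    for ci, members in enumerate(clusters.clusters.values()):
        for u in members:
            assign[u] = ci
    nxt = len(clusters.clusters)
    for u in clusters.unassigned:
        assign[u] = nxt
        nxt += 1
    return [assign[u] for u in names]


class TestHccaCluster:
    def test_two_disjoint_triangles_are_the_two_clusters(self):
        g, truth = clique_union([3, 3])
        cs = hcca_cluster(g)
        assert sorted(map(frozenset, cs.clusters.values())) \
            == sorted(truth, key=sorted)
        assert cs.unassigned == []

    def test_bridged_six_cliques_split_at_the_bridge(self):
        g, truth = clique_union([6, 6])
        g.add_edge("n000", "n006")
        cs = hcca_cluster(g)
        got = {frozenset(m) for m in cs.clusters.values()}
        assert got == set(truth)

    def test_clique_unions_recovered_exactly_for_all_sizes(self):
        g, truth = clique_union([3, 4, 5, 6, 7, 8])
        cs = hcca_cluster(g)
        got = {frozenset(m) for m in cs.clusters.values()}
        assert got == set(truth)
        assert cs.unassigned == []

    def test_planted_partition_blocks_recovered(self):
        aris = []
        for seed in range(5):
            g, labels, names = planted_partition(seed)
            cs = hcca_cluster(g)
            aris.append(adjusted_rand_score(labels,
                                            predicted_labels(cs, names)))
        assert np.mean(aris) >= 0.9

    def test_output_is_always_a_disjoint_cover(self):
        for seed in range(5):
            g = nx.gnp_random_graph(80, 0.08, seed=seed)
            g = nx.relabel_nodes(g, {i: f"x{i:02d}" for i in g.nodes})
            cs = hcca_cluster(g)
            seen = list(cs.unassigned)
            for members in cs.clusters.values():
                assert len(members) >= 2
                seen.extend(members)
            assert sorted(seen) == sorted(g.nodes)

    def test_deterministic_across_runs_and_node_order(self):
        g, _, _ = planted_partition(3)
        a = hcca_cluster(g)
        h = nx.Graph()
        h.add_nodes_from(reversed(list(g.nodes)))
        h.add_edges_from(g.edges)
        b = hcca_cluster(h)
        assert a.clusters == b.clusters and a.unassigned == b.unassigned

    def test_max_cluster_bound_respected(self):
        g, _ = clique_union([12])
        cs = hcca_cluster(g, max_cluster=10)
        # the 12-clique cannot be accepted whole; the cover is still disjoint
        for members in cs.clusters.values():
            assert len(members) <= 10 or cs.n_clusters == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            hcca_cluster(nx.Graph())


def profiles_matrix(profiles, tissues, reps=3):
    """TPM matrix realizing exact per-tissue values for each gene."""
    cols, tissue_of = [], []
    for t in tissues:
        for r in range(reps):
            cols.append(f"{t}_r{r}")
            tissue_of.append(t)
    idx = np.repeat(np.arange(len(tissues)), reps)
    tpm = pd.DataFrame(np.asarray(profiles, float)[:, idx],
                       index=pd.Index([f"g{i}" for i in range(len(profiles))],
                                      name="gene_id"),
                       columns=cols)
    samples = pd.DataFrame({"sample_id": cols, "tissue": tissue_of})
    return tpm, samples


def as_cluster(genes, cid="C0001"):
    return ClusterSet(clusters={cid: sorted(genes)}, unassigned=[],
                      stats=pd.DataFrame())


class TestClusterTightness:
    def test_identical_profiles_are_all_tight(self):
        tpm, samples = profiles_matrix([[10, 20, 40]] * 5,
                                       ["t1", "t2", "t3"])
        res = cluster_tightness(tpm, samples, as_cluster(tpm.index))
        assert res.cluster_fraction["C0001"] == 1.0
        assert res.grand_average == 1.0

    def test_one_orthogonal_profile_gives_fraction_point_nine(self):
        profiles = [[10, 20, 40]] * 9 + [[40, 20, 10]]
        tpm, samples = profiles_matrix(profiles, ["t1", "t2", "t3"])
        res = cluster_tightness(tpm, samples, as_cluster(tpm.index))
        assert res.cluster_fraction["C0001"] == pytest.approx(0.9)
        table = res.gene_table.set_index("gene_id")
        assert not table.at["g9", "tight"]

    def test_flat_profile_member_flagged_with_reason(self):
        profiles = [[10, 20, 40]] * 4 + [[7, 7, 7]]
        tpm, samples = profiles_matrix(profiles, ["t1", "t2", "t3"])
        res = cluster_tightness(tpm, samples, as_cluster(tpm.index))
        table = res.gene_table.set_index("gene_id")
        assert not table.at["g4", "tight"]
        assert table.at["g4", "reason"] == "flat profile"

    def test_fraction_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(2)
        profiles = rng.uniform(1, 100, size=(8, 5))
        tpm, samples = profiles_matrix(profiles, [f"t{i}" for i in range(5)])
        a = cluster_tightness(tpm, samples, as_cluster(tpm.index))
        b = cluster_tightness(tpm * 13.0, samples, as_cluster(tpm.index),
                              log_transform=False)
        c = cluster_tightness(tpm, samples, as_cluster(tpm.index),
                              log_transform=False)
        assert b.cluster_fraction["C0001"] == c.cluster_fraction["C0001"]
        assert 0.0 <= a.grand_average <= 1.0

    def test_member_missing_from_matrix_rejected(self):
        tpm, samples = profiles_matrix([[1, 2, 3]], ["t1", "t2", "t3"])
        with pytest.raises(ValidationError, match="ghost"):
            cluster_tightness(tpm, samples, as_cluster(["g0", "ghost"]))


class TestClusterTissueProfile:
    def test_hand_computed_z_row(self):
        tpm, samples = profiles_matrix([[10, 10, 40]], ["t1", "t2", "t3"])
        res = cluster_tissue_profile(tpm, samples, as_cluster(["g0"]))
        np.testing.assert_allclose(res.z.loc["C0001"].values,
                                   [-0.57735, -0.57735, 1.154701], atol=1e-5)

    def test_flat_profile_gives_zero_row_not_distinct(self):
        tpm, samples = profiles_matrix([[5, 5, 5]], ["t1", "t2", "t3"])
        res = cluster_tissue_profile(tpm, samples, as_cluster(["g0"]))
        assert (res.z.loc["C0001"] == 0).all()
        assert not res.distinct["C0001"]

    def test_distinct_needs_enough_extreme_tissues(self):
        # |Z| > 1 in exactly two tissues -> not distinct at the default
        # three-tissue requirement
        profile = [[1, 1, 1, 1, 30, 30]]
        tpm, samples = profiles_matrix(profile, [f"t{i}" for i in range(6)])
        res = cluster_tissue_profile(tpm, samples, as_cluster(["g0"]))
        assert int((res.z.loc["C0001"].abs() > 1).sum()) == 2
        assert not res.distinct["C0001"]
        relaxed = cluster_tissue_profile(tpm, samples, as_cluster(["g0"]),
                                         distinct_min_tissues=2)
        assert relaxed.distinct["C0001"]

    def test_z_rows_standardized_for_every_cluster(self, default_bundle):
        from coexpatlas.network import hrr_transform, pcc_matrix

        tpm, samples = default_bundle["tpm"], default_bundle["samples"]
        net = hrr_transform(pcc_matrix(tpm))
        cs = hcca_cluster(net)
        res = cluster_tissue_profile(tpm, samples, cs)
        z = res.z.values
        nonzero = z.std(axis=1) > 0
        np.testing.assert_allclose(z[nonzero].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z[nonzero].std(axis=1, ddof=1), 1.0,
                                   atol=1e-10)
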