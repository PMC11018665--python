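import numpy as np
import pandas as pd
import pytest
from fractions import Fraction
from math import comb

from coexpatlas import ValidationError
from coexpatlas.enrichment import (enrich_clusters, hypergeom_tail,
                                   propagate_annotations, summarize_enrichment)
from coexpatlas.hcca import ClusterSet


def exact_tail(k, n, K, N):
    num = sum(Fraction(comb(K, i) * comb(N - K, n - i))
              for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


class TestHypergeomTail:
    def test_all_draws_annotated_from_small_pool(self):
        # N=20, K=5, n=5, k=5 -> 1 / C(20,5)
        assert hypergeom_tail(5, 5, 5, 20) == pytest.approx(1 / 15504,
                                                            rel=1e-12)

    def test_every_background_gene_annotated_gives_p_one(self):
        assert hypergeom_tail(7, 7, 30, 30) == 1.0

    def test_k_at_expectation_is_not_significant(self):
        # k equal to the expected count n*K/N with weak enrichment
        N, K, n = 100, 20, 10
        k = 2
        p = hypergeom_tail(k, n, K, N)
        assert p == pytest.approx(float(exact_tail(k, n, K, N)), rel=1e-12)
        assert p > 0.05

    def test_tail_below_support_is_one_and_above_is_zero(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0
        assert hypergeom_tail(6, 5, 5, 20) == 0.0

    def test_matches_exact_summation_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(5, 500))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            expected = float(exact_tail(k, n, K, N))
            if expected > 0:
                assert hypergeom_tail(k, n, K, N) == pytest.approx(
                    expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 5, 30, 20)


def make_clusters(members_by_cluster, unassigned=()):
    return ClusterSet(
        clusters={cid: sorted(m) for cid, m in members_by_cluster.items()},
        unassigned=sorted(unassigned), stats=pd.DataFrame())


class TestEnrichClusters:
    def test_private_term_in_one_cluster_is_strongly_enriched(self):
        genes = [f"g{i:02d}" for i in range(40)]
        cs = make_clusters({"C1": genes[:10], "C2": genes[10:20]},
                           unassigned=genes[20:])
        go = {g: frozenset({"GO:bg"}) for g in genes}
        go.update({g: frozenset({"GO:bg", "GO:hit"}) for g in genes[:10]})
        res = enrich_clusters(cs, go)
        hit = res[(res["cluster_id"] == "C1") & (res["term_id"] == "GO:hit")]
        assert hit.iloc[0]["enriched"]
        assert hit.iloc[0]["k"] == 10 and hit.iloc[0]["K"] == 10
        assert hit.iloc[0]["p"] == pytest.approx(
            float(exact_tail(10, 10, 10, 40)), rel=1e-12)

    def test_background_restricted_to_annotated_genes(self):
        genes = [f"g{i}" for i in range(20)]
        cs = make_clusters({"C1": genes[:5]}, unassigned=genes[5:])
        go = {g: frozenset({"GO:x"}) for g in genes[:10]}   # half annotated
        res = enrich_clusters(cs, go)
        assert (res["N"] == 10).all()
        res_all = enrich_clusters(cs, go, background="all")
        assert (res_all["N"] == 20).all()

    def test_enriched_count_non_increasing_in_alpha(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(120)]
        terms = [f"GO:{i}" for i in range(8)]
        go = {g: frozenset(rng.choice(terms, size=2, replace=False))
              for g in genes}
        cs = make_clusters({"C1": genes[:30], "C2": genes[30:60]},
                           unassigned=genes[60:])
        strict = enrich_clusters(cs, go, alpha=0.01)
        loose = enrich_clusters(cs, go, alpha=0.10)
        assert strict["enriched"].sum() <= loose["enriched"].sum()
        # BH keeps adjusted p monotone in p
        s = strict.sort_values("p")
        assert (np.diff(s["p_adj"].values) >= -1e-12).all()

    def test_empty_go_map_rejected(self):
        cs = make_clusters({"C1": ["a", "b"]})
        with pytest.raises(ValidationError):
            enrich_clusters(cs, {})

    def test_annotations_outside_network_are_dropped_and_counted(self):
        cs = make_clusters({"C1": ["a", "b"]}, unassigned=["c"])
        go = {g: frozenset({"GO:x"}) for g in ["a", "b", "c", "offnet"]}
        res = enrich_clusters(cs, go)
        assert res.attrs["n_dropped_annotations"] == 1


class TestSummaryAndControls:
    def test_no_passing_test_gives_fraction_zero(self):
        cs = make_clusters({"C1": ["a", "b"], "C2": ["c", "d"]})
        go = {g: frozenset({"GO:x"}) for g in "abcd"}   # K == N -> p == 1
        res = enrich_clusters(cs, go)
        summary = summarize_enrichment(res, cs)
        assert summary["fraction_clusters_enriched"] == 0.0

    def test_planted_module_terms_top_their_clusters(self):
        from coexpatlas.network import hrr_transform, pcc_matrix
        from coexpatlas.hcca import hcca_cluster
        from coexpatlas.simulate import (SimulationDesign,
                                         simulate_annotations,
                                         simulate_expression)

        hits = total = 0
        for seed in range(3):
            design = SimulationDesign(
                n_hk=100, n_ts=0, n_modules=6, module_size_range=(15, 30),
                n_noise=400, n_silent=20, module_clade_amp_log2=0.0,
                module_tissue_jitter_log2=1.0, seed=seed)
            tpm, samples, truth = simulate_expression(design)
            go = simulate_annotations(truth, seed=seed + 50)
            cs = hcca_cluster(hrr_transform(pcc_matrix(tpm)))
            res = enrich_clusters(cs, go)
            cluster_of = {g: cid for cid, mem in cs.clusters.items()
                          for g in mem}
            top = {cid: grp.iloc[0]["term_id"]
                   for cid, grp in res.groupby("cluster_id")}
            enriched = {(r.cluster_id, r.term_id)
                        for r in res.itertuples() if r.enriched}
            for module_id, grp in truth[truth["role"] == "module"].groupby("detail"):
                term = f"GO:8{int(module_id[1:]):06d}"
                homes = pd.Series([cluster_of.get(g)
                                   for g in grp["gene_id"]]).dropna()
                total += 1
                if len(homes):
                    cid = homes.mode()[0]
                    hits += (top.get(cid) == term and (cid, term) in enriched)
        assert hits / total >= 0.9

    def test_permuting_memberships_destroys_planted_enrichment(self):
        from coexpatlas.simulate import (SimulationDesign,
                                         simulate_annotations,
                                         simulate_expression)

        design = SimulationDesign(
            n_hk=100, n_ts=0, n_modules=6, module_size_range=(15, 30),
            n_noise=400, n_silent=0, seed=3)
        _, _, truth = simulate_expression(design)
        go = simulate_annotations(truth, seed=4)
        genes = sorted(truth["gene_id"])
        rng = np.random.default_rng(5)
        perm = list(rng.permutation(genes))
        sizes = truth[truth["role"] == "module"].groupby("detail").size()
        clusters, start = {}, 0
        for i, size in enumerate(sizes):
            clusters[f"C{i}"] = perm[start:start + size]
            start += size
        cs = make_clusters(clusters, unassigned=perm[start:])
        res = enrich_clusters(cs, go)
        planted = res[res["term_id"].str.startswith("GO:8")]
        assert planted["p_adj"].median() > 0.05


def test_parent_map_propagation_is_transitive():
    go = {"g1": frozenset({"GO:leaf"})}
    parents = {"GO:leaf": ["GO:mid"], "GO:mid": ["GO:root"]}
    out = propagate_annotations(go, parents)
    assert out["g1"] == frozenset({"GO:leaf", "GO:mid", "GO:root"})
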