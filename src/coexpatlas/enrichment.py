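"""Per-cluster GO term over-representation by the hypergeometric tail.

For a background of N annotated genes of which K carry a term, a cluster of
n background genes containing k term carriers is scored by the upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n),

the probability of seeing at least k carriers under random draws without
replacement.  For the tail lengths enrichment actually meets the sum is
carried out in exact integer arithmetic with one correctly-rounded division
at the end, so even astronomically small p-values keep full double
precision; very long tails over huge backgrounds fall back to log space
(log-gamma binomials combined by log-sum-exp).  Benjamini-Hochberg
correction is applied across all (cluster, term) tests.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .hcca import ClusterSet


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


_EXACT_TAIL_LIMIT = 5000     # max number of exact big-integer terms


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("hypergeometric parameters require 0 <= K, n <= N")
    kmax = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if k > kmax:
        return 0.0
    if kmax - k < _EXACT_TAIL_LIMIT:
        numerator = sum(comb(K, i) * comb(N - K, n - i)
                        for i in range(k, kmax + 1))
        return float(Fraction(numerator, comb(N, n)))
    i = np.arange(k, kmax + 1, dtype=float)
    log_terms = (
        _log_binom(float(K), i)
        + _log_binom(float(N - K), float(n) - i)
        - _log_binom(float(N), float(n))
    )
    return float(np.exp(logsumexp(log_terms)))


def enrich_clusters(
    clusters: ClusterSet,
    go_map: dict[str, frozenset[str]],
    alpha: float = 0.05,
    min_k: int = 2,
    background: str = "annotated",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Test each cluster for over-represented terms.

    The background is the set of network genes (cluster members plus
    unassigned) carrying at least one annotation, or all network genes with
    ``background="all"``.  A (cluster, term) pair is tested only when the
    cluster holds at least ``min_k`` annotated carriers.  Annotated genes
    absent from the background are dropped (their count is recorded in
    ``result.attrs["n_dropped_annotations"]``).
    """
    if not go_map:
        raise ValidationError("the GO annotation map is empty")
    network_genes = set(clusters.unassigned)
    for members in clusters.clusters.values():
        network_genes.update(members)
    if background == "annotated":
        bg = sorted(g for g in network_genes if g in go_map)
    elif background == "all":
        bg = sorted(network_genes)
    else:
        raise ValidationError(f"unknown background mode {background!r}")
    n_dropped = len(set(go_map) - network_genes)
    bg_set = set(bg)
    N = len(bg)
    if N == 0:
        raise ValidationError("no annotated genes in the network background")

    term_genes: dict[str, set[str]] = {}
    for g in bg:
        for t in go_map.get(g, ()):
            term_genes.setdefault(t, set()).add(g)

    rows = []
    for cid in sorted(clusters.clusters):
        members_bg = set(clusters.clusters[cid]) & bg_set
        n = len(members_bg)
        if n == 0:
            continue
        counts: dict[str, int] = {}
        for g in members_bg:
            for t in go_map.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            k = counts[t]
            if k < min_k:
                continue
            K = len(term_genes[t])
            rows.append((cid, t, k, n, K, N, hypergeom_tail(k, n, K, N)))

    result = pd.DataFrame(rows, columns=["cluster_id", "term_id", "k", "n",
                                         "K", "N", "p"])
    if len(result):
        method = "bonferroni" if bonferroni else "fdr_bh"
        _, p_adj, _, _ = multipletests(result["p"].values, method=method)
        result["p_adj"] = p_adj
    else:
        result["p_adj"] = pd.Series(dtype=float)
    result["enriched"] = result["p_adj"] < alpha
    result = result.sort_values(["p_adj", "p", "cluster_id", "term_id"],
                                kind="mergesort").reset_index(drop=True)
    result.attrs["n_dropped_annotations"] = n_dropped
    return result


def propagate_annotations(
    go_map: dict[str, frozenset[str]],
    parents: dict[str, frozenset[str] | set[str] | list[str]],
) -> dict[str, frozenset[str]]:
    """Extend annotations up a term parent map (transitive closure)."""
    closure: dict[str, frozenset[str]] = {}

    def ancestors(term: str) -> frozenset[str]:
        if term not in closure:
            closure[term] = frozenset()   # break cycles defensively
            out = set()
            for p in parents.get(term, ()):
                out.add(p)
                out |= ancestors(p)
            closure[term] = frozenset(out)
        return closure[term]

    return {
        g: frozenset(set(terms) | {a for t in terms for a in ancestors(t)})
        for g, terms in go_map.items()
    }


def summarize_enrichment(results: pd.DataFrame, clusters: ClusterSet) -> dict:
    """Per-cluster best term and the fraction of clusters with a hit."""
    best = {}
    enriched_clusters = set()
    for cid, grp in results.groupby("cluster_id"):
        top = grp.iloc[0]       # results are sorted by p_adj
        best[cid] = {"term_id": top["term_id"], "p_adj": float(top["p_adj"]),
                     "k": int(top["k"]), "K": int(top["K"])}
        if bool(grp["enriched"].any()):
            enriched_clusters.add(cid)
    n_clusters = clusters.n_clusters
    fraction = len(enriched_clusters) / n_clusters if n_clusters else 0.0
    return {
        "top_terms": best,
        "n_clusters_enriched": len(enriched_clusters),
        "fraction_clusters_enriched": fraction,
    }
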