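"""Heuristic Cluster Chiseling Algorithm (HCCA) and cluster profiling.

HCCA detects clusters in a co-expression network by local sculpting rather
than global optimization:

1. every node seeds a *node vicinity* -- its breadth-first neighborhood up
   to ``step_size`` steps in the residual (not-yet-clustered) network;
2. the vicinity is *chiseled*: every non-seed node with more edges leaving
   the candidate set than staying inside is removed, repeatedly, until
   stable -- the surviving "clusterette" is internally cohesive;
3. clusterettes are scored by their internal-edge fraction
   internal / (internal + boundary) and the highest-scoring, pairwise
   disjoint ones of admissible size are accepted;
4. accepted nodes are removed and the procedure repeats on the residual
   network until no admissible clusterette remains;
5. remaining nodes join the accepted cluster they share most edges with,
   or stay unassigned when isolated.

Edge counts during chiseling and scoring are taken against the full
network, so nodes left over after earlier rounds are not mistaken for
well-separated groups merely because their strongly-connected partners were
already clustered away; the residual only defines which nodes are still
available.  Vicinity growth beyond the first step stops once the vicinity
would exceed half the residual network: chiseling needs a non-trivial
boundary, and on dense graphs an unbounded multi-step neighborhood would
swallow the whole network.  The procedure is fully deterministic: seeds are
visited in lexicographic order and all ties break lexicographically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ValidationError
from .tissue_specificity import tissue_means


@dataclass
class ClusterSet:
    """Disjoint gene clusters plus the unassigned remainder."""

    clusters: dict[str, list[str]]   # cluster id -> sorted member genes
    unassigned: list[str]
    stats: pd.DataFrame              # cluster_id, size, internal_edges, boundary_edges

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> pd.DataFrame:
        rows = [(g, cid) for cid, members in self.clusters.items() for g in members]
        rows += [(g, "") for g in self.unassigned]
        return pd.DataFrame(rows, columns=["gene_id", "cluster_id"])

    def sizes(self) -> pd.Series:
        return pd.Series({cid: len(m) for cid, m in self.clusters.items()},
                         name="size")


def _bounded_vicinity(seed, adj, residual, step_size, frac):
    """BFS within the residual: depth 1 always, deeper only while the
    vicinity stays within ``frac`` of the residual node count."""
    cap = frac * len(residual)
    seen = {seed}
    frontier = {seed}
    for depth in range(1, step_size + 1):
        nxt = set()
        for u in frontier:
            nxt |= adj[u] & residual
        nxt -= seen
        if not nxt:
            break
        if depth > 1 and len(seen) + len(nxt) > cap:
            break
        seen |= nxt
        frontier = nxt
    return seen


def _chisel(seed, members, adj, degree):
    """Iteratively drop non-seed nodes with more edges out than in."""
    members = set(members)
    while True:
        drop = [
            u for u in members
            if u != seed and 2 * len(adj[u] & members) < degree[u]
        ]
        if not drop:
            return members
        members -= set(drop)


def _score(members, adj, degree):
    internal = sum(len(adj[u] & members) for u in members) // 2
    boundary = sum(degree[u] for u in members) - 2 * internal
    total = internal + boundary
    return internal / total if total else 0.0, internal, boundary


def hcca_cluster(
    net: nx.Graph,
    step_size: int = 3,
    max_cluster: int = 300,
    min_cluster: int = 2,
    vicinity_frac: float = 0.5,
) -> ClusterSet:
    """Cluster an (HRR) network with the chiseling procedure above."""
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty network")
    if step_size < 1:
        raise ValidationError("step_size must be >= 1")
    nodes = sorted(net.nodes)
    adj = {u: set(net[u]) for u in nodes}
    degree = {u: len(adj[u]) for u in nodes}

    residual = set(nodes)
    accepted: list[list] = []
    while True:
        seen_cands: dict[frozenset, tuple] = {}
        for seed in sorted(residual):
            if not adj[seed] & residual:
                continue
            nvn = _bounded_vicinity(seed, adj, residual, step_size, vicinity_frac)
            members = _chisel(seed, nvn, adj, degree)
            if not min_cluster <= len(members) <= max_cluster:
                continue
            key = frozenset(members)
            if key not in seen_cands:
                sc, _, _ = _score(members, adj, degree)
                seen_cands[key] = (-sc, -len(members), tuple(sorted(members)))
        if not seen_cands:
            break
        order = sorted(seen_cands.items(), key=lambda kv: kv[1])
        taken: set = set()
        for key, _ in order:
            if key & taken:
                continue
            accepted.append(sorted(key))
            taken |= key
        residual -= taken

    # leftover nodes join the accepted cluster they share most edges with
    member_of = {}
    for ci, members in enumerate(accepted):
        for u in members:
            member_of[u] = ci
    unassigned = []
    joined: dict[int, list] = {}
    for u in sorted(residual):
        votes: dict[int, int] = {}
        for v in adj[u]:
            ci = member_of.get(v)
            if ci is not None:
                votes[ci] = votes.get(ci, 0) + 1
        if votes:
            best = min(votes, key=lambda ci: (-votes[ci], ci))
            joined.setdefault(best, []).append(u)
        else:
            unassigned.append(u)
    for ci, extra in joined.items():
        accepted[ci] = sorted(accepted[ci] + extra)

    width = max(4, len(str(len(accepted))))
    clusters = {f"C{ci + 1:0{width}d}": members
                for ci, members in enumerate(accepted)}
    rows = []
    for cid, members in clusters.items():
        _, internal, boundary = _score(set(members), adj, degree)
        rows.append((cid, len(members), internal, boundary))
    stats = pd.DataFrame(rows, columns=["cluster_id", "size",
                                        "internal_edges", "boundary_edges"])
    return ClusterSet(clusters=clusters, unassigned=unassigned, stats=stats)


# ---------------------------------------------------------------------------
# cluster expression profiles


def _standardized_profiles(tpm, samples, genes, log_transform=True):
    """Per-gene tissue-mean profiles standardized across tissues (Z rows).

    Returns (z DataFrame, flat gene list); genes with a flat (zero
    variance) profile have no Z row.
    """
    sub = tpm.loc[genes]
    x = np.log2(sub + 1.0) if log_transform else sub
    prof = tissue_means(x, samples, log_transform=False)
    vals = prof.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    zdf = pd.DataFrame(z[~flat], index=prof.index[~flat], columns=prof.columns)
    return zdf, prof.index[flat].tolist()


@dataclass
class TightnessResult:
    gene_table: pd.DataFrame       # gene_id, cluster_id, tight, reason
    cluster_fraction: pd.Series    # cluster_id -> tight fraction
    grand_average: float


def cluster_tightness(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    clusters: ClusterSet,
    tight_z: float = 1.0,
    log_transform: bool = True,
) -> TightnessResult:
    """Flag tightly co-expressed members of each cluster.

    Each member's tissue-mean log2(TPM+1) profile is standardized to mean 0
    / SD 1 across tissues; the cluster consensus is the per-tissue mean of
    member Z profiles.  A member is tight iff its Z profile deviates from
    the consensus by less than ``tight_z`` in every tissue.  Members with a
    flat profile (zero variance across tissues) cannot follow any pattern
    and are untight with reason "flat profile".
    """
    all_members = [g for m in clusters.clusters.values() for g in m]
    missing = sorted(set(all_members) - set(tpm.index))
    if missing:
        raise ValidationError(f"cluster members absent from matrix: {missing[:5]}")
    rows = []
    fractions = {}
    for cid, members in clusters.clusters.items():
        z, flat = _standardized_profiles(tpm, samples, members, log_transform)
        tight_genes = set()
        if len(z):
            consensus = z.values.mean(axis=0)
            dev = np.abs(z.values - consensus[None, :]).max(axis=1)
            tight_genes = set(z.index[dev < tight_z])
        for g in members:
            if g in flat:
                rows.append((g, cid, False, "flat profile"))
            else:
                rows.append((g, cid, g in tight_genes, ""))
        fractions[cid] = len(tight_genes) / len(members)
    table = pd.DataFrame(rows, columns=["gene_id", "cluster_id", "tight", "reason"])
    frac = pd.Series(fractions, name="tight_fraction")
    grand = float(frac.mean()) if len(frac) else float("nan")
    return TightnessResult(table, frac, grand)


@dataclass
class ClusterTissueMatrix:
    """Cluster x tissue Z profiles with the distinct-pattern flag."""

    z: pd.DataFrame                # clusters x tissues
    distinct: pd.Series            # cluster_id -> bool

    @property
    def fraction_distinct(self) -> float:
        return float(self.distinct.mean()) if len(self.distinct) else float("nan")


def cluster_tissue_profile(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    clusters: ClusterSet,
    distinct_z: float = 1.0,
    distinct_min_tissues: int = 3,
) -> ClusterTissueMatrix:
    """Average cluster expression per tissue, Z-standardized across tissues.

    For each cluster, member genes' per-tissue mean TPM values are averaged
    and the resulting profile standardized to mean 0 / SD 1 (sample SD)
    across tissues.  A cluster shows a distinct pattern when |Z| exceeds
    ``distinct_z`` in at least ``distinct_min_tissues`` tissues; a cluster
    with a flat average profile gets an all-zero row and is not distinct.
    """
    means = tissue_means(tpm, samples, log_transform=False)
    if means.shape[1] < 2:
        raise ValidationError("cluster profiling needs at least 2 tissues")
    rows, flags = {}, {}
    for cid, members in clusters.clusters.items():
        avg = means.loc[members].values.mean(axis=0)
        sd = avg.std(ddof=1)
        z = (avg - avg.mean()) / sd if sd > 0 else np.zeros_like(avg)
        rows[cid] = z
        flags[cid] = bool((np.abs(z) > distinct_z).sum() >= distinct_min_tissues)
    zdf = pd.DataFrame.from_dict(rows, orient="index", columns=means.columns)
    zdf.index.name = "cluster_id"
    return ClusterTissueMatrix(zdf, pd.Series(flags, name="distinct"))


def cluster_summary(
    clusters: ClusterSet,
    tightness: TightnessResult | None = None,
    profile: ClusterTissueMatrix | None = None,
) -> dict:
    """Headline numbers of a clustering run (for the summary JSON)."""
    sizes = clusters.sizes()
    out = {
        "n_clusters": int(clusters.n_clusters),
        "n_unassigned": len(clusters.unassigned),
        "size_min": int(sizes.min()) if len(sizes) else 0,
        "size_median": float(sizes.median()) if len(sizes) else 0.0,
        "size_max": int(sizes.max()) if len(sizes) else 0,
        "pct_size_2": float((sizes == 2).mean() * 100) if len(sizes) else 0.0,
    }
    if tightness is not None:
        out["average_tight_fraction"] = tightness.grand_average
    if profile is not None:
        out["pct_distinct"] = profile.fraction_distinct * 100
    return out
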