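"""Sample-level quality control and correlation-based sample clustering.

Three operations: read-mapping filters applied to a per-sample statistics
table, expressed-gene classification of a TPM matrix, and hierarchical
clustering of samples on Pearson correlation of log2(count+1) profiles with
majority-clade mislabel flagging.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError

FILTER_RULES = ("min_reads", "min_trim_frac", "max_unmapped", "max_multi")


@dataclass
class QcReport:
    """Per-sample pass/fail with the list of failed rules."""

    table: pd.DataFrame            # sample_id, passed, failed_rules
    retained: list[str]

    @property
    def failed(self) -> list[str]:
        return [s for s in self.table["sample_id"] if s not in set(self.retained)]


def filter_samples(
    stats: pd.DataFrame,
    min_reads: int = 100_000,
    min_trim_frac: float = 0.5,
    max_unmapped: float = 0.5,
    max_multi: float = 0.4,
    samples: list[str] | None = None,
) -> QcReport:
    """Apply the read-count and mapping-rate sample filters.

    A sample fails when fewer than ``min_reads`` reads remain after
    trimming, when less than ``min_trim_frac`` of its reads survive
    trimming, when the fraction of reads failing to map is >=
    ``max_unmapped``, or when the fraction unable to map uniquely is >=
    ``max_multi``.  Count thresholds are strict (<); rate thresholds are
    inclusive (>=), so a sample with exactly 50% unmapped reads fails.
    """
    if samples is not None:
        missing = sorted(set(samples) - set(stats["sample_id"]))
        if missing:
            raise ValidationError(f"mapping stats missing for samples: {missing}")
        stats = stats[stats["sample_id"].isin(samples)]
    rows = []
    for _, r in stats.iterrows():
        failed = []
        total = float(r["total_reads"])
        after = float(r["reads_after_trim"])
        if after < min_reads:
            failed.append("min_reads")
        if total > 0 and after / total < min_trim_frac:
            failed.append("min_trim_frac")
        if (100.0 - float(r["mapped_pct"])) / 100.0 >= max_unmapped:
            failed.append("max_unmapped")
        if (100.0 - float(r["uniquely_mapped_pct"])) / 100.0 >= max_multi:
            failed.append("max_multi")
        rows.append((r["sample_id"], not failed, ",".join(failed)))
    table = pd.DataFrame(rows, columns=["sample_id", "passed", "failed_rules"])
    retained = table.loc[table["passed"], "sample_id"].tolist()
    return QcReport(table=table, retained=retained)


@dataclass
class ExpressedSummary:
    """Expressed-gene classification of a TPM matrix."""

    gene_table: pd.DataFrame       # gene_id, expressed, n_samples_expressed
    per_sample: pd.Series          # expressed-gene count per sample
    per_tissue: pd.Series | None   # expressed-gene count per tissue

    @property
    def expressed_genes(self) -> list[str]:
        return self.gene_table.loc[self.gene_table["expressed"], "gene_id"].tolist()

    @property
    def n_expressed(self) -> int:
        return int(self.gene_table["expressed"].sum())


def classify_expressed(
    tpm: pd.DataFrame,
    threshold: float = 1.0,
    samples: pd.DataFrame | None = None,
) -> ExpressedSummary:
    """Classify each gene as expressed iff TPM >= threshold in >= 1 sample.

    Also reports, per gene, the number of samples at or above the threshold
    and, per sample (and per tissue when metadata is given), the number of
    expressed genes.
    """
    if tpm.empty:
        raise ValidationError("expression matrix is empty")
    above = tpm.values >= threshold
    gene_table = pd.DataFrame({
        "gene_id": tpm.index,
        "expressed": above.any(axis=1),
        "n_samples_expressed": above.sum(axis=1),
    }).reset_index(drop=True)
    per_sample = pd.Series(above.sum(axis=0), index=tpm.columns,
                           name="n_genes_expressed")
    per_tissue = None
    if samples is not None:
        tissue_of = dict(zip(samples["sample_id"], samples["tissue"]))
        counts = {}
        for tissue in sorted(set(tissue_of.get(c) for c in tpm.columns) - {None}):
            cols = [c for c in tpm.columns if tissue_of.get(c) == tissue]
            counts[tissue] = int((tpm[cols].values >= threshold).any(axis=1).sum())
        per_tissue = pd.Series(counts, name="n_genes_expressed")
    return ExpressedSummary(gene_table, per_sample, per_tissue)


@dataclass
class SampleClustering:
    """Result of correlation-based sample clustering."""

    linkage: np.ndarray
    sample_ids: list[str]
    cut: pd.Series                 # sample_id -> cut-cluster label (1..k)
    cluster_clade: dict[int, str]  # cut-cluster -> majority declared clade
    flags: pd.DataFrame            # sample_id, declared_clade, assigned_clade, flagged

    @property
    def flagged(self) -> list[str]:
        return self.flags.loc[self.flags["flagged"], "sample_id"].tolist()


def cluster_samples(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    mean_log_min: float = 1.0,
    linkage_method: str = "average",
) -> SampleClustering:
    """Cluster samples on 1 - Pearson correlation and flag clade mislabels.

    Genes with mean log2(count+1) below ``mean_log_min`` are dropped; the
    remaining log2 profiles give a sample-sample Pearson correlation matrix,
    the tree is built by agglomerative clustering (average linkage by
    default) and cut into as many groups as there are declared clades.  Each
    cut group is labelled with its majority declared clade; a sample is
    flagged as mislabelled when its declared clade is not among the majority
    clades of its group (majority ties favour the sample's own declaration).
    """
    if "clade" not in samples.columns:
        raise ValidationError("sample metadata lacks the clade column")
    meta = samples.set_index("sample_id").loc[list(counts.columns)]
    clades = sorted(set(meta["clade"]))
    k = len(clades)
    if counts.shape[1] < max(3, k):
        raise ValidationError("need at least max(3, n_clades) samples to cluster")

    logc = np.log2(counts.values.astype(float) + 1.0)
    keep = logc.mean(axis=1) >= mean_log_min
    if not keep.any():
        raise ValidationError("no genes pass the mean log2(count+1) filter")
    profiles = logc[keep]
    corr = np.corrcoef(profiles.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    cut = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    cut_series = pd.Series(cut, index=counts.columns, name="cut_cluster")
    cluster_clade: dict[int, str] = {}
    rows = []
    for cl in sorted(set(cut)):
        members = cut_series.index[cut_series.values == cl]
        declared = meta.loc[members, "clade"]
        vc = declared.value_counts()
        winners = set(vc[vc == vc.max()].index)
        cluster_clade[int(cl)] = sorted(winners)[0]
        for s in members:
            own = meta.at[s, "clade"]
            rows.append((s, own, cluster_clade[int(cl)], own not in winners))
    flags = pd.DataFrame(rows, columns=["sample_id", "declared_clade",
                                        "assigned_clade", "flagged"])
    flags = flags.set_index("sample_id").loc[list(counts.columns)].reset_index()
    return SampleClustering(Z, list(counts.columns), cut_series,
                            cluster_clade, flags)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths kept)."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
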