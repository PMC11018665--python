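"""PCC co-expression structure and the Highest-Reciprocal-Rank network.

For every pair of (expressed) genes a Pearson correlation is computed
across samples on log2(TPM+1).  Each gene then ranks all other genes by
descending correlation (rank 1 = best partner); the highest reciprocal rank
of a pair is the worse of its two mutual ranks,
``HRR(a, b) = max(rank_a(b), rank_b(a))``.  An edge is kept iff
HRR <= hrr_max and PCC >= pcc_cutoff, yielding a sparse network in which
every edge is a mutually high-ranking association.

Two execution modes share one numeric kernel (row-standardized matrix
product), so the blocked mode -- which never materializes the full
gene x gene matrix and keeps only per-gene top-k lists -- is bit-identical
to the dense mode.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .errors import ValidationError


@dataclass
class PccStructure:
    """Row-standardized expression and bookkeeping for correlation ranking."""

    genes: list[str]               # lexicographically sorted
    standardized: np.ndarray       # genes x samples, centered rows of unit norm
    excluded_zero_variance: list[str]
    log_transform: bool

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def corr(self) -> np.ndarray:
        """Dense gene x gene Pearson correlation matrix."""
        return self.standardized @ self.standardized.T


def pcc_matrix(
    tpm: pd.DataFrame,
    expressed_only: bool = True,
    threshold: float = 1.0,
    log_transform: bool = True,
) -> PccStructure:
    """Prepare the correlation structure over (expressed) genes.

    Genes are filtered to the expressed set (TPM >= threshold in >= 1
    sample) when ``expressed_only``; values are log2(TPM+1)-transformed by
    default; genes with zero variance across samples have no defined
    correlation and are excluded from ranking (recorded separately).
    """
    if tpm.shape[1] < 3:
        raise ValidationError("correlation ranking needs at least 3 samples")
    matrix = tpm
    if expressed_only:
        matrix = matrix[(matrix.values >= threshold).any(axis=1)]
    matrix = matrix.sort_index(kind="mergesort")
    x = matrix.values.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    excluded = matrix.index[flat].tolist()
    kept = ~flat
    standardized = centered[kept] / norms[kept, None]
    return PccStructure(
        genes=matrix.index[kept].tolist(),
        standardized=standardized,
        excluded_zero_variance=excluded,
        log_transform=log_transform,
    )


def _top_ranks(corr_rows: np.ndarray, row_indices: np.ndarray, k: int):
    """Per row: the k best partners by (descending PCC, ascending gene index).

    Yields (row_index, partner_indices, ranks, pccs) with ranks 1..k taken
    from the full ordering, self excluded.  The index tie-break makes the
    ranking deterministic and independent of input row order (genes are
    already sorted lexicographically).
    """
    n = corr_rows.shape[1]
    cols = np.arange(n)
    for local, i in enumerate(row_indices):
        row = corr_rows[local]
        order = np.lexsort((cols, -row))
        order = order[order != i][: k]
        ranks = np.arange(1, len(order) + 1)
        yield i, order, ranks, row[order]


def hrr_transform(
    pcc: PccStructure,
    hrr_max: int = 50,
    pcc_cutoff: float = 0.5,
    block_size: int | None = None,
) -> nx.Graph:
    """Threshold the correlation structure into the HRR network.

    With ``block_size`` set, correlations are computed in row blocks and
    only per-gene top-``hrr_max`` partner lists are retained; an edge needs
    both mutual ranks <= hrr_max, so the blocked result is identical to the
    dense one.
    """
    if hrr_max < 1:
        raise ValidationError("hrr_max must be a positive integer")
    n = pcc.n_genes
    genes = pcc.genes
    top: dict[int, dict[int, tuple[int, float]]] = {}
    if block_size is None:
        corr = pcc.corr()
        blocks = [(np.arange(n), corr)]
    else:
        blocks = (
            (idx, pcc.standardized[idx] @ pcc.standardized.T)
            for idx in (
                np.arange(s, min(s + block_size, n))
                for s in range(0, n, block_size)
            )
        )
    for idx, corr_rows in blocks:
        for i, partners, ranks, pccs in _top_ranks(corr_rows, idx, hrr_max):
            top[i] = {
                int(j): (int(r), float(c))
                for j, r, c in zip(partners, ranks, pccs)
            }

    net = nx.Graph(pcc_cutoff=pcc_cutoff, hrr_max=hrr_max)
    net.add_nodes_from(genes)
    for i in range(n):
        for j, (rank_ij, pcc_ij) in top[i].items():
            if j <= i:
                continue
            back = top[j].get(i)
            if back is None or pcc_ij < pcc_cutoff:
                continue
            hrr = max(rank_ij, back[0])
            if hrr <= hrr_max:
                net.add_edge(genes[i], genes[j], pcc=pcc_ij, hrr=hrr)
    return net


def edges_frame(net: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene_a < gene_b, sorted rows)."""
    rows = [
        (min(a, b), max(a, b), d["pcc"], d["hrr"])
        for a, b, d in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "hrr"])
    return df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)


@dataclass
class DegreeDiagnostics:
    """Degree histogram and the log-log power-law regression."""

    histogram: pd.DataFrame        # degree, n_nodes (degree >= 1)
    n_isolated: int
    slope: float | None
    r_squared: float | None


def degree_diagnostics(net: nx.Graph) -> DegreeDiagnostics:
    """Scale-free diagnostics: OLS of log10(node count) on log10(degree).

    Only degrees >= 1 enter the fit; a negative slope with a good fit is
    the signature of a heavy-tailed, scale-free-like degree distribution.
    With fewer than two distinct positive degrees the slope is undefined
    and reported as missing.
    """
    degrees = np.array([d for _, d in net.degree()], dtype=int)
    n_isolated = int((degrees == 0).sum())
    pos = degrees[degrees > 0]
    values, counts = np.unique(pos, return_counts=True)
    hist = pd.DataFrame({"degree": values, "n_nodes": counts})
    if len(values) < 2:
        return DegreeDiagnostics(hist, n_isolated, None, None)
    fit = stats.linregress(np.log10(values), np.log10(counts))
    return DegreeDiagnostics(hist, n_isolated, float(fit.slope),
                             float(fit.rvalue**2))


def ego_graph(net: nx.Graph, gene: str, depth: int = 2) -> nx.Graph:
    """Neighborhood of a query gene up to the given depth (for export)."""
    if gene not in net:
        raise ValidationError(f"gene {gene!r} is not a network node")
    return nx.ego_graph(net, gene, radius=depth)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
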