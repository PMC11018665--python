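"""Tau tissue-specificity index and all-vs-all overexpression calls.

Tau summarizes how concentrated a gene's expression is across tissues:
tau = sum_i (1 - x_i / max(x)) / (N - 1) over the N per-tissue mean
expression values, giving 0 for perfectly uniform and 1 for single-tissue
expression.  Independently, every ordered tissue pair (T, O) is tested for
overexpression of each gene in T versus O on log2(TPM+1) values; a gene
overexpressed in one tissue against *all* others is pairwise-specific, and
tissue-specific when additionally tau exceeds a threshold.

The pairwise test is Welch's t on log2(TPM+1) by default; an optional
empirical-Bayes mode shrinks per-gene variances toward a pooled prior by a
method-of-moments estimate and inflates the degrees of freedom accordingly,
stabilizing calls when per-tissue sample counts are small (and providing
the fallback for tissues with a single sample).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def tissue_means(
    tpm: pd.DataFrame, samples: pd.DataFrame, log_transform: bool = False
) -> pd.DataFrame:
    """Per-gene, per-tissue mean expression (genes x tissues).

    Means are taken on the TPM scale; with ``log_transform`` the means are
    then transformed to log2(mean+1).
    """
    tissue_of = dict(zip(samples["sample_id"], samples["tissue"]))
    missing = [c for c in tpm.columns if c not in tissue_of]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    groups = pd.Series([tissue_of[c] for c in tpm.columns], index=tpm.columns)
    means = tpm.T.groupby(groups).mean().T
    means = means[sorted(means.columns)]
    if log_transform:
        means = np.log2(means + 1.0)
    return means


def tau_index(profile, log_transform: bool = True):
    """Tau index of one profile (Series) or many (genes x tissues DataFrame).

    Computed on log2(x+1)-transformed per-tissue means by default.  An
    all-zero profile has no defined tau and yields NaN.
    """
    single = isinstance(profile, pd.Series)
    prof = profile.to_frame().T if single else profile
    if prof.shape[1] < 2:
        raise ValidationError("tau needs at least 2 tissues")
    x = prof.values.astype(float)
    if (x < 0).any():
        raise ValidationError("tau profiles must be non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau = np.where(xmax > 0, tau, np.nan)
    if single:
        return float(tau[0])
    return pd.Series(tau, index=prof.index, name="tau")


@dataclass
class ContrastResult:
    """All-vs-all overexpression contrasts.

    Arrays are indexed (gene, tissue_T, tissue_O); ``log2fc[g, i, j]`` is
    mean_i - mean_j of gene g on log2(TPM+1), ``p_adj`` is BH-adjusted
    across genes within each contrast, and ``overexpressed`` applies the
    combined fold-change / significance rule.
    """

    genes: pd.Index
    tissues: list[str]
    log2fc: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    overexpressed: np.ndarray
    moderated: bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format records (gene, tissue, other, log2fc, p, p_adj)."""
        recs = []
        for i, t in enumerate(self.tissues):
            for j, o in enumerate(self.tissues):
                if i == j:
                    continue
                recs.append(pd.DataFrame({
                    "gene_id": self.genes,
                    "tissue": t,
                    "other": o,
                    "log2fc": self.log2fc[:, i, j],
                    "p": self.p[:, i, j],
                    "p_adj": self.p_adj[:, i, j],
                    "overexpressed": self.overexpressed[:, i, j],
                }))
        return pd.concat(recs, ignore_index=True)


def _moderate_variances(var: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments shrinkage of per-gene variances toward their mean.

    For each tissue (column) with df >= 1, the prior variance is the mean
    per-gene variance and the prior df d0 comes from matching the observed
    between-gene scatter of variances against the chi-square scatter
    expected at the given df; shrunk variances are the df-weighted average
    of prior and observed, with df inflated by d0.
    """
    var_mod = np.empty_like(var)
    df_mod = np.empty_like(var)
    for j in range(var.shape[1]):
        d = df[j]
        if d < 1:
            raise ValidationError("cannot moderate a tissue with no replicate")
        v = var[:, j]
        v0 = float(v.mean())
        if v0 <= 0:
            var_mod[:, j] = v
            df_mod[:, j] = d
            continue
        scatter = float(v.var(ddof=1)) if len(v) > 1 else 0.0
        chi2_part = 2.0 * v0**2 / d
        tau2 = max(scatter - chi2_part, 1e-12 * v0**2)
        d0 = float(np.clip(2.0 * v0**2 / tau2, 1.0, 100.0))
        var_mod[:, j] = (d0 * v0 + d * v) / (d0 + d)
        df_mod[:, j] = d + d0
    return var_mod, df_mod


def overexpression_contrasts(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    log2fc_min: float = 2.0,
    alpha: float = 0.05,
    moderated: bool = False,
) -> ContrastResult:
    """Test every gene for overexpression in every ordered tissue pair.

    For each pair (T, O): log2FC = mean_T - mean_O on log2(TPM+1); p from a
    two-sided Welch t test (variance-moderated when ``moderated``); BH
    correction across genes within each contrast.  A gene is overexpressed
    in T vs O iff log2FC >= ``log2fc_min`` and adjusted p <= ``alpha``.
    """
    tissue_of = dict(zip(samples["sample_id"], samples["tissue"]))
    groups = pd.Series([tissue_of.get(c) for c in tpm.columns], index=tpm.columns)
    if groups.isna().any():
        raise ValidationError("every matrix sample needs a tissue label")
    tissues = sorted(groups.unique())
    if len(tissues) < 2:
        raise ValidationError("contrasts need at least 2 tissues")

    y = np.log2(tpm.values.astype(float) + 1.0)
    n_genes, T = y.shape[0], len(tissues)
    n_t = np.zeros(T, dtype=int)
    mean = np.zeros((n_genes, T))
    var = np.zeros((n_genes, T))
    for i, t in enumerate(tissues):
        cols = np.flatnonzero(groups.values == t)
        n_t[i] = len(cols)
        block = y[:, cols]
        mean[:, i] = block.mean(axis=1)
        var[:, i] = block.var(axis=1, ddof=1) if len(cols) > 1 else np.nan

    small = [tissues[i] for i in range(T) if n_t[i] < 2]
    if small and not moderated:
        raise ValidationError(
            f"tissue(s) with < 2 samples: {small}; enable the "
            "variance-moderation fallback to test them"
        )
    df_per = np.maximum(n_t - 1, 0).astype(float)
    if moderated:
        ok = df_per >= 1
        v_ok, d_ok = _moderate_variances(var[:, ok], df_per[ok])
        var_use = var.copy()
        df_use = np.broadcast_to(df_per, (n_genes, T)).copy()
        var_use[:, ok] = v_ok
        df_use[:, ok] = d_ok
        if (~ok).any():
            # single-sample tissue: prior variance only, prior df
            prior_v = v_ok.mean(axis=(0, 1)) if v_ok.size else 0.0
            prior_d = float(d_ok.mean() - df_per[ok].mean()) if d_ok.size else 1.0
            var_use[:, ~ok] = prior_v
            df_use[:, ~ok] = max(prior_d, 1.0)
    else:
        var_use = var
        df_use = np.broadcast_to(df_per, (n_genes, T)).copy()

    log2fc = mean[:, :, None] - mean[:, None, :]
    p = np.ones((n_genes, T, T))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(T):
            for j in range(i + 1, T):
                se2_i = var_use[:, i] / n_t[i]
                se2_j = var_use[:, j] / n_t[j]
                se2 = se2_i + se2_j
                t_stat = np.where(se2 > 0, log2fc[:, i, j] / np.sqrt(se2), 0.0)
                df_w = np.where(
                    se2 > 0,
                    se2**2 / (se2_i**2 / df_use[:, i] + se2_j**2 / df_use[:, j]),
                    1.0,
                )
                pij = 2.0 * stats.t.sf(np.abs(t_stat), df_w)
                p[:, i, j] = p[:, j, i] = np.clip(pij, 0.0, 1.0)

    p_adj = np.ones_like(p)
    for i in range(T):
        for j in range(i + 1, T):
            _, adj, _, _ = multipletests(p[:, i, j], method="fdr_bh")
            p_adj[:, i, j] = p_adj[:, j, i] = adj

    over = (log2fc >= log2fc_min) & (p_adj <= alpha)
    for i in range(T):
        over[:, i, i] = False
    return ContrastResult(tpm.index, tissues, log2fc, p, p_adj, over, moderated)


def call_tissue_specific(
    contrasts: ContrastResult,
    tau: pd.Series,
    tau_threshold: float = 0.8,
) -> pd.DataFrame:
    """Combine the pairwise calls and tau into the tissue-specific table.

    A gene is pairwise-specific to tissue T iff it is overexpressed in T
    versus every other tissue (at most one such T can exist, because
    overexpression in both directions of a pair is impossible); it is
    tissue-specific (``is_ts``) when additionally tau > ``tau_threshold``.
    """
    over = contrasts.overexpressed.copy()
    T = len(contrasts.tissues)
    eye = np.eye(T, dtype=bool)
    all_others = np.where(eye[None, :, :], True, over).all(axis=2)
    n_spec = all_others.sum(axis=1)
    if (n_spec > 1).any():
        raise AssertionError("a gene cannot be specific to two tissues")
    assigned_idx = np.where(n_spec == 1, all_others.argmax(axis=1), -1)

    tau_aligned = tau.reindex(contrasts.genes)
    rows = []
    for g, gene in enumerate(contrasts.genes):
        if assigned_idx[g] >= 0:
            i = assigned_idx[g]
            others = [j for j in range(T) if j != i]
            min_fc = float(contrasts.log2fc[g, i, others].min())
            max_padj = float(contrasts.p_adj[g, i, others].max())
            tissue = contrasts.tissues[i]
        else:
            tissue, min_fc, max_padj = "", np.nan, np.nan
        t = tau_aligned.iloc[g]
        rows.append((gene, tissue, min_fc, max_padj, t,
                     assigned_idx[g] >= 0,
                     bool(assigned_idx[g] >= 0 and t > tau_threshold)))
    return pd.DataFrame(rows, columns=[
        "gene_id", "assigned_tissue", "min_log2fc", "max_p_adj",
        "tau", "is_specific", "is_ts",
    ])
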