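"""Housekeeping-gene identification by the MFC*CoV first-quartile rule.

A candidate gene (expressed in every sample) is scored by the product of its
coefficient of variation (SD/mean of TPM across samples) and its maximum
fold change (max/min TPM); candidates whose score falls within the first
quartile of candidate scores are called housekeeping.  Low CoV means little
scatter around the mean, low MFC means no extreme sample; the product
penalizes either kind of instability.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def score_stability(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Compute per-gene stability scores.

    A gene is a housekeeping candidate iff TPM >= ``threshold`` in every
    sample.  For candidates, the table carries mean, sample SD (n-1
    denominator), CoV = SD/mean, MFC = max/min and score = CoV * MFC;
    non-candidates carry NaN in those columns.
    """
    if tpm.shape[1] < 2:
        raise ValidationError("stability scoring needs at least 2 samples")
    if threshold <= 0:
        raise ValidationError("expression threshold must be positive")
    x = tpm.values.astype(float)
    candidate = (x >= threshold).all(axis=1)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.nan)
        mfc = np.where(x.min(axis=1) > 0, x.max(axis=1) / x.min(axis=1), np.nan)
    score = cov * mfc
    out = pd.DataFrame({
        "gene_id": tpm.index,
        "candidate": candidate,
        "mean_tpm": mean,
        "sd_tpm": sd,
        "cov": cov,
        "mfc": mfc,
        "score": score,
    }).reset_index(drop=True)
    out.loc[~out["candidate"], ["mean_tpm", "sd_tpm", "cov", "mfc", "score"]] = np.nan
    return out


def call_housekeeping(scores: pd.DataFrame, quartile: float = 0.25) -> pd.DataFrame:
    """Flag candidates whose MFC*CoV score lies within the first quartile.

    The quartile is the linear-interpolation quantile of candidate scores;
    ties at the boundary are included (score <= quantile).  Returns a copy
    of the table with an ``is_hk`` column, sorted ascending by score with
    non-candidates last.
    """
    if not 0 < quartile < 1:
        raise ValidationError("quartile must lie strictly between 0 and 1")
    cand = scores.loc[scores["candidate"], "score"].values
    if len(cand) < 4:
        raise ValidationError(
            f"insufficient candidates for the quartile rule: {len(cand)} < 4"
        )
    cutoff = float(np.quantile(cand, quartile))
    out = scores.copy()
    out["is_hk"] = out["candidate"] & (out["score"] <= cutoff)
    out = out.sort_values(
        by=["score", "gene_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    out.attrs["quartile_cutoff"] = cutoff
    out.attrs["n_hk"] = int(out["is_hk"].sum())
    out.attrs["n_candidates"] = int(out["candidate"].sum())
    return out
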