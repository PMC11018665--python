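"""Tissue-structured synthetic expression data with known ground truth.

The generator emulates the structure of a bulk RNA-Seq expression atlas:
a gene x sample TPM matrix over a panel of tissues grouped into three major
clades (aerial, underground, pollen), containing

* housekeeping genes -- per-gene constant log2 mean plus small log-normal
  sample noise calibrated to a target coefficient of variation,
* tissue-specific genes -- near-silent baseline everywhere except a single
  tissue elevated by a fixed log2 fold-change,
* co-expressed modules -- genes sharing a latent tissue profile (a clade
  effect plus a smaller tissue effect) with independent noise calibrated so
  the expected within-module correlation on the log2 scale hits a target,
* independent noise genes, and all-zero silent genes.

Values are exponentiated to the TPM scale and each sample column rescaled to
a constant sum of 10^6, mimicking the compositional nature of TPM.  A paired
count matrix can be drawn Poisson from the TPM values and a library size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LN2 = float(np.log(2.0))

#: 15 tissues of a potato-style atlas with their major clade.
DEFAULT_TISSUES: tuple[tuple[str, str], ...] = (
    ("leaf", "aerial"), ("stem", "aerial"), ("petiole", "aerial"),
    ("flower", "aerial"), ("fruit", "aerial"), ("seed", "aerial"),
    ("shoot_apex", "aerial"), ("style", "aerial"), ("sepal", "aerial"),
    ("axillary_bud", "aerial"),
    ("root", "underground"), ("tuber", "underground"),
    ("stolon", "underground"), ("tuber_sprout", "underground"),
    ("pollen", "pollen"),
)


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic atlas.

    ``n_tissues`` tissues (taken from a 15-tissue panel, or generic names
    beyond that) each receive ``samples_per_tissue`` samples.  Gene counts
    per role are explicit; module sizes are drawn uniformly from
    ``module_size_range``.  ``hk_cov_target`` is the coefficient of
    variation the housekeeping genes are calibrated to; ``ts_log2fc`` the
    spike height of tissue-specific genes over their baseline
    ``ts_baseline_log2`` (log2-TPM units); ``module_within_pcc`` the
    expected within-module Pearson correlation on the log2 scale.
    """

    n_tissues: int = 15
    samples_per_tissue: int = 10
    n_hk: int = 250
    n_ts: int = 150
    n_modules: int = 20
    module_size_range: tuple[int, int] = (10, 40)
    n_noise: int = 1040
    n_silent: int = 60
    hk_cov_target: float = 0.1
    ts_log2fc: float = 5.0
    ts_baseline_log2: float = -5.0
    ts_noise_log2_sd: float = 0.5
    module_within_pcc: float = 0.8
    module_clade_amp_log2: float = 1.0
    module_tissue_jitter_log2: float = 0.3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 1.5
    renormalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_tissues, self.samples_per_tissue)
        if any(c < 1 for c in counts):
            raise ValidationError("n_tissues and samples_per_tissue must be >= 1")
        roles = (self.n_hk, self.n_ts, self.n_modules, self.n_noise, self.n_silent)
        if any(c < 0 for c in roles):
            raise ValidationError("gene counts must be non-negative")
        lo, hi = self.module_size_range
        if self.n_modules > 0 and (lo < 2 or hi < lo):
            raise ValidationError(
                f"infeasible module_size_range {self.module_size_range}: "
                "need 2 <= min <= max"
            )
        if not 0 < self.module_within_pcc < 1:
            raise ValidationError("module_within_pcc must lie in (0, 1)")
        if self.n_ts > 0 and self.n_tissues < 2:
            raise ValidationError("tissue-specific genes require >= 2 tissues")


def _tissue_panel(n_tissues: int) -> list[tuple[str, str]]:
    panel = list(DEFAULT_TISSUES[:n_tissues])
    for i in range(len(panel), n_tissues):
        panel.append((f"tissue_{i + 1:02d}", "aerial"))
    if n_tissues < len(DEFAULT_TISSUES):
        # keep at least one tissue per clade where possible
        clades = {c for _, c in panel}
        if n_tissues >= 3 and len(clades) < 3:
            panel[-2] = ("root", "underground")
            panel[-1] = ("pollen", "pollen")
    return panel


def simulate_expression(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (tpm matrix, sample table, truth table) for a design.

    The truth table has one row per gene with its planted role: ``hk``,
    ``ts`` (with the spiked tissue in ``detail``), ``module`` (with the
    module id), ``noise`` or ``silent``.
    """
    rng = np.random.default_rng(design.seed)
    panel = _tissue_panel(design.n_tissues)
    tissues = [t for t, _ in panel]
    clade_of = dict(panel)

    sample_ids, sample_tissue = [], []
    for t in tissues:
        for r in range(design.samples_per_tissue):
            sample_ids.append(f"{t}_s{r + 1:02d}")
            sample_tissue.append(t)
    n_samples = len(sample_ids)
    tissue_idx = np.array([tissues.index(t) for t in sample_tissue])

    module_sizes = [
        int(rng.integers(design.module_size_range[0], design.module_size_range[1] + 1))
        for _ in range(design.n_modules)
    ]
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    roles: list[str] = []
    details: list[str] = []

    def add_genes(prefix, n, role, detail_list=None):
        for i in range(n):
            gene_ids.append(f"{prefix}{i + 1:04d}")
            roles.append(role)
            details.append(detail_list[i] if detail_list is not None else "")

    # housekeeping: constant per-gene mean, noise sd set from the CoV target
    if design.n_hk:
        mu = rng.uniform(2.5, 6.0, size=design.n_hk)
        sd_log2 = np.sqrt(np.log1p(design.hk_cov_target**2)) / LN2
        log2x = mu[:, None] + rng.normal(0.0, sd_log2, size=(design.n_hk, n_samples))
        blocks.append(log2x)
        add_genes("HK", design.n_hk, "hk")

    # tissue-specific: baseline everywhere, one tissue spiked by ts_log2fc
    if design.n_ts:
        spike_tissue = [tissues[i % len(tissues)] for i in range(design.n_ts)]
        mu = np.full((design.n_ts, n_samples), design.ts_baseline_log2)
        for g, t in enumerate(spike_tissue):
            mu[g, tissue_idx == tissues.index(t)] += design.ts_log2fc
        log2x = mu + rng.normal(0.0, design.ts_noise_log2_sd,
                                size=(design.n_ts, n_samples))
        blocks.append(log2x)
        add_genes("TS", design.n_ts, "ts", spike_tissue)

    # co-expressed modules: shared latent tissue profile + calibrated noise.
    # Each module draws independent clade offsets from a BOUNDED uniform
    # (support +- module_clade_amp_log2) plus a small Gaussian tissue
    # jitter: modules are tissue/clade-BIASED -- which is what gives the
    # samples their clade structure -- but the bounded support keeps any
    # single tissue from standing out by a tissue-specific-sized fold
    # change, and independent draws keep distinct modules decorrelated.
    rho = design.module_within_pcc
    g_c = design.module_clade_amp_log2
    g_t = design.module_tissue_jitter_log2
    clade_names = sorted({c for _, c in panel})
    for k, size in enumerate(module_sizes):
        clade_eff = {c: float(rng.uniform(-1.0, 1.0)) for c in clade_names}
        tissue_eff = rng.normal(0.0, 1.0, size=len(tissues))
        latent_t = np.array([
            g_c * clade_eff[clade_of[t]] + g_t * tissue_eff[i]
            for i, t in enumerate(tissues)
        ])
        latent_s = latent_t[tissue_idx]
        # per-module noise calibration: signal-to-total variance ratio on
        # the log2 scale equals the target correlation for every module
        signal_var = float(latent_s.var())
        noise_sd = (np.sqrt(signal_var * (1.0 - rho) / rho)
                    if signal_var > 0 else g_t + 1e-6)
        mu = rng.normal(design.baseline_log2_mean, 0.75, size=size)
        log2x = (
            mu[:, None]
            + latent_s[None, :]
            + rng.normal(0.0, noise_sd, size=(size, n_samples))
        )
        blocks.append(log2x)
        prev = sum(module_sizes[:k])
        for i in range(size):
            gene_ids.append(f"MOD{prev + i + 1:04d}")
            roles.append("module")
            details.append(f"M{k + 1:02d}")

    # independent noise genes
    if design.n_noise:
        mu = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd,
                        size=design.n_noise)
        log2x = mu[:, None] + rng.normal(0.0, design.noise_log2_sd,
                                         size=(design.n_noise, n_samples))
        blocks.append(log2x)
        add_genes("NOISE", design.n_noise, "noise")

    tpm_parts = [np.exp2(b) for b in blocks]
    if design.n_silent:
        tpm_parts.append(np.zeros((design.n_silent, n_samples)))
        add_genes("SILENT", design.n_silent, "silent")

    tpm = np.vstack(tpm_parts) if tpm_parts else np.zeros((0, n_samples))
    if design.renormalize and tpm.size:
        colsum = tpm.sum(axis=0)
        if (colsum <= 0).any():
            raise ValidationError("cannot renormalize: a sample column sums to zero")
        tpm = tpm * (1e6 / colsum)

    matrix = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "tissue": sample_tissue,
        "clade": [clade_of[t] for t in sample_tissue],
    })
    truth = pd.DataFrame({
        "gene_id": gene_ids, "role": roles, "detail": details,
    })
    return matrix, samples, truth


def simulate_counts(
    tpm: pd.DataFrame,
    library_sizes: float | np.ndarray | pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a raw count matrix: counts ~ Poisson(tpm * library_size / 10^6)."""
    sizes = np.broadcast_to(np.asarray(library_sizes, dtype=float),
                            (tpm.shape[1],))
    if (sizes <= 0).any():
        raise ValidationError("library sizes must be strictly positive")
    rng = np.random.default_rng(seed)
    lam = tpm.values * (sizes[None, :] / 1e6)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=tpm.index.copy(), columns=tpm.columns.copy())


def corrupt_labels(
    samples: pd.DataFrame, n_swaps: int, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Relabel ``n_swaps`` samples with a tissue from a different clade.

    Returns the corrupted table and the list of swapped sample ids; the
    expression data itself is untouched, so the swapped samples are known
    mislabels for testing the mislabel detector.
    """
    if n_swaps < 0 or n_swaps > len(samples) // 2:
        raise ValidationError(
            f"n_swaps={n_swaps} must lie in [0, {len(samples) // 2}]"
        )
    out = samples.copy(deep=True)
    if n_swaps == 0:
        return out, []
    if "clade" not in out.columns:
        raise ValidationError("corrupt_labels requires a clade column")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(out), size=n_swaps, replace=False).tolist())
    tissue_clade = out[["tissue", "clade"]].drop_duplicates()
    swapped = []
    for i in chosen:
        own_clade = out.at[i, "clade"]
        foreign = tissue_clade[tissue_clade["clade"] != own_clade]
        if foreign.empty:
            raise ValidationError("cannot swap labels: only one clade present")
        pick = foreign.iloc[int(rng.integers(len(foreign)))]
        out.at[i, "tissue"] = pick["tissue"]
        out.at[i, "clade"] = pick["clade"]
        swapped.append(out.at[i, "sample_id"])
    return out, swapped


def simulate_annotations(
    truth: pd.DataFrame,
    n_background_terms: int = 40,
    terms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Build a synthetic gene -> GO-terms map from a truth table.

    Every gene receives 1-3 random background terms; additionally each
    planted module gets a private term annotated to all of its members and
    to no other gene, so module-level enrichment has a known positive
    control.
    """
    rng = np.random.default_rng(seed)
    bg_terms = [f"GO:{7000000 + i}" for i in range(n_background_terms)]
    lo, hi = terms_per_gene
    mapping: dict[str, set[str]] = {}
    for _, row in truth.iterrows():
        n = int(rng.integers(lo, hi + 1))
        terms = set(rng.choice(bg_terms, size=n, replace=False).tolist())
        mapping[row["gene_id"]] = terms
    for module_id, grp in truth[truth["role"] == "module"].groupby("detail"):
        planted = f"GO:8{int(module_id[1:]):06d}"
        for g in grp["gene_id"]:
            mapping[g].add(planted)
    return {g: frozenset(t) for g, t in mapping.items()}
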