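"""Pipeline configuration.

All thresholds used across the stages live in a single :class:`PipelineConfig`
record so that a run is fully described by one object: the TPM expressed
cut-off, the PCC and HRR thresholds of the network stage, the log2
fold-change / adjusted-p rule and the Tau cut-off of the tissue-specificity
stage, the first-quartile rule of the housekeeping stage, the Z thresholds
of the cluster profiling stage, and the enrichment significance level.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and parameters shared by every pipeline stage.

    Attributes
    ----------
    tpm_expressed_threshold:
        A gene counts as expressed when TPM >= this value in at least one
        sample (default 1.0 TPM).
    pcc_cutoff, hrr_max:
        Co-expression edge thresholds: Pearson correlation >= ``pcc_cutoff``
        (default 0.5) and highest reciprocal rank <= ``hrr_max`` (default 50).
    ts_log2fc_min, ts_alpha:
        Overexpression call per tissue contrast: log2 fold-change >= 2 with
        BH-adjusted p <= 0.05.
    tau_specific_threshold:
        Tau index above which a pairwise-specific gene is called
        tissue-specific (default 0.8).
    hk_quartile:
        Quantile of the MFC*CoV score below which candidates are called
        housekeeping (default 0.25, the first quartile).
    tight_z, distinct_z, distinct_min_tissues:
        Cluster profiling thresholds: a member gene is tightly co-expressed
        when its standardized profile stays within ``tight_z`` of the cluster
        consensus; a cluster is distinct when |Z| > ``distinct_z`` in at
        least ``distinct_min_tissues`` tissues.
    hcca_step_size, hcca_max_cluster:
        Vicinity depth and maximum accepted cluster size of the HCCA stage.
    enrichment_alpha:
        BH-adjusted significance level for GO over-representation.
    excluded_tissues:
        Tissue labels (e.g. mixed-tissue categories such as callus or whole
        plant) whose samples are dropped before any analysis.
    """

    tpm_expressed_threshold: float = 1.0
    pcc_cutoff: float = 0.5
    hrr_max: int = 50
    ts_log2fc_min: float = 2.0
    ts_alpha: float = 0.05
    tau_specific_threshold: float = 0.8
    hk_quartile: float = 0.25
    tight_z: float = 1.0
    distinct_z: float = 1.0
    distinct_min_tissues: int = 3
    hcca_step_size: int = 3
    hcca_max_cluster: int = 300
    enrichment_alpha: float = 0.05
    rng_seed: int = 0
    excluded_tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        positive = [
            "tpm_expressed_threshold", "pcc_cutoff", "hrr_max", "ts_log2fc_min",
            "ts_alpha", "tau_specific_threshold", "tight_z", "distinct_z",
            "distinct_min_tissues", "enrichment_alpha", "hcca_max_cluster",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be strictly positive")
        if not 0 < self.hk_quartile < 1:
            raise ValidationError("hk_quartile must lie strictly between 0 and 1")
        if self.hcca_step_size < 1:
            raise ValidationError("hcca_step_size must be >= 1")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_tissues"] = list(self.excluded_tissues)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_tissues" in data:
            data = {**data, "excluded_tissues": tuple(data["excluded_tissues"])}
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; missing keys keep defaults."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
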