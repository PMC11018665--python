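"""End-to-end pipeline: TPM matrix + metadata -> all stage outputs.

Stage order: sample QC, expressed-gene classification, housekeeping
scoring, tissue-specificity calls, HRR network, HCCA clusters with tissue
profiles, GO enrichment, manifest.  Every output is a TSV (or JSON) file in
the output directory; the run manifest records the config snapshot, input
digests, stage timings and the digest of every written file, so identical
inputs and seed reproduce identical outputs byte for byte (timings aside).
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as aio
from .config import PipelineConfig
from .errors import StageError, ValidationError
from .housekeeping import call_housekeeping, score_stability
from .hcca import (cluster_summary, cluster_tightness, cluster_tissue_profile,
                   hcca_cluster)
from .network import degree_diagnostics, edges_frame, hrr_transform, pcc_matrix
from .enrichment import enrich_clusters, summarize_enrichment
from .qc import classify_expressed, cluster_samples, filter_samples
from .tissue_specificity import (call_tissue_specific, overexpression_contrasts,
                                 tau_index, tissue_means)


@dataclass
class InputPaths:
    expression: str | Path
    metadata: str | Path
    counts: str | Path | None = None
    mapping_stats: str | Path | None = None
    go_map: str | Path | None = None


@dataclass
class RunManifest:
    config: dict
    inputs: dict
    outputs: dict
    timings: dict
    notes: list[str]
    seed: int
    version: str

    def to_dict(self) -> dict:
        return {
            "version": self.version, "seed": self.seed, "config": self.config,
            "inputs": self.inputs, "outputs": self.outputs,
            "timings": self.timings, "notes": self.notes,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def run_pipeline(
    config: PipelineConfig, inputs: InputPaths, outdir: str | Path
) -> RunManifest:
    """Run every stage and write the nine standard outputs.

    Raises :class:`StageError` naming the failing stage; outputs written
    before the failure stay on disk and are flagged partial in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    input_digests = {
        name: aio.sha256_of(p)
        for name, p in (("expression", inputs.expression),
                        ("metadata", inputs.metadata),
                        ("counts", inputs.counts),
                        ("mapping_stats", inputs.mapping_stats),
                        ("go_map", inputs.go_map))
        if p is not None
    }

    def record(name: str, path: Path) -> None:
        outputs[name] = aio.sha256_of(path)

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False
        return _Timer()

    # ---- load inputs --------------------------------------------------
    with stage("load"):
        tpm = aio.read_expression_matrix(inputs.expression)
        samples = aio.read_sample_metadata(inputs.metadata)
        aio.check_samples_covered(tpm, samples)
        if config.excluded_tissues:
            drop = samples["tissue"].isin(config.excluded_tissues)
            dropped = samples.loc[drop, "sample_id"].tolist()
            if dropped:
                notes.append(f"excluded {len(dropped)} samples from excluded tissues")
                samples = samples[~drop].reset_index(drop=True)
                tpm = tpm[[c for c in tpm.columns if c not in set(dropped)]]
        counts = (aio.read_expression_matrix(inputs.counts)
                  if inputs.counts else None)
        stats = (aio.read_mapping_stats(inputs.mapping_stats)
                 if inputs.mapping_stats else None)
        go_map = aio.read_go_map(inputs.go_map) if inputs.go_map else None

    # ---- stage 1: sample QC ------------------------------------------
    with stage("qc"):
        if stats is not None:
            report = filter_samples(stats, samples=list(tpm.columns))
            qc_table = report.table
            retained = [s for s in tpm.columns if s in set(report.retained)]
        else:
            qc_table = pd.DataFrame({
                "sample_id": tpm.columns, "passed": True, "failed_rules": "",
            })
            retained = list(tpm.columns)
            notes.append("no mapping statistics provided; read filters skipped")
        tpm = tpm[retained]
        samples = samples[samples["sample_id"].isin(retained)].reset_index(drop=True)
        if counts is not None:
            counts = counts[[c for c in retained if c in counts.columns]]

        if counts is not None and "clade" in samples.columns:
            clustering = cluster_samples(counts, samples)
            qc_table = qc_table.merge(
                clustering.flags.rename(columns={"flagged": "mislabel_flag"}),
                on="sample_id", how="left",
            )
            mislabeled = clustering.flagged
            if mislabeled:
                notes.append(f"excluded {len(mislabeled)} flagged mislabels")
                keep = [s for s in tpm.columns if s not in set(mislabeled)]
                tpm = tpm[keep]
                samples = samples[samples["sample_id"].isin(keep)].reset_index(drop=True)
        else:
            notes.append("no counts matrix or clade labels; mislabel check skipped")
        qc_path = outdir / "qc_report.tsv"
        qc_table.to_csv(qc_path, sep="\t", index=False)
        record("qc_report", qc_path)

    # ---- stage 2: expressed genes ------------------------------------
    with stage("expressed"):
        summary = classify_expressed(tpm, config.tpm_expressed_threshold, samples)
        path = outdir / "expressed_genes.tsv"
        summary.gene_table.to_csv(path, sep="\t", index=False)
        record("expressed_genes", path)

    # ---- stage 3: housekeeping ---------------------------------------
    with stage("housekeeping"):
        scores = score_stability(tpm, config.tpm_expressed_threshold)
        hk = call_housekeeping(scores, config.hk_quartile)
        path = outdir / "hk_scores.tsv"
        hk.to_csv(path, sep="\t", index=False)
        record("hk_scores", path)

    # ---- stage 4: tissue specificity ---------------------------------
    with stage("tissue_specificity"):
        contrasts = overexpression_contrasts(
            tpm, samples, config.ts_log2fc_min, config.ts_alpha)
        tau = tau_index(tissue_means(tpm, samples), log_transform=True)
        ts = call_tissue_specific(contrasts, tau, config.tau_specific_threshold)
        path = outdir / "ts_calls.tsv"
        ts.to_csv(path, sep="\t", index=False)
        record("ts_calls", path)

    # ---- stage 5: HRR network ----------------------------------------
    with stage("network"):
        pcc = pcc_matrix(tpm, expressed_only=True,
                         threshold=config.tpm_expressed_threshold)
        net = hrr_transform(pcc, config.hrr_max, config.pcc_cutoff)
        edges = edges_frame(net)
        path = outdir / "edges.tsv"
        aio.write_edge_list(edges, path)
        record("edges", path)
        diag = degree_diagnostics(net)

    # ---- stage 6: HCCA clusters --------------------------------------
    with stage("clusters"):
        clusters = hcca_cluster(net, config.hcca_step_size,
                                config.hcca_max_cluster)
        tightness = cluster_tightness(tpm, samples, clusters, config.tight_z)
        membership = clusters.membership()
        tight_of = dict(zip(tightness.gene_table["gene_id"],
                            tightness.gene_table["tight"]))
        membership["tight"] = [bool(tight_of.get(g, False))
                               for g in membership["gene_id"]]
        path = outdir / "clusters.tsv"
        aio.write_clusters(membership, path)
        record("clusters", path)

        profile = cluster_tissue_profile(
            tpm, samples, clusters, config.distinct_z,
            config.distinct_min_tissues)
        ztab = profile.z.copy()
        ztab["distinct"] = profile.distinct
        zpath = outdir / "cluster_tissue_z.tsv"
        ztab.to_csv(zpath, sep="\t")
        record("cluster_tissue_z", zpath)

        summary_json = cluster_summary(clusters, tightness, profile)
        summary_json["degree_slope"] = diag.slope
        summary_json["degree_r_squared"] = diag.r_squared
        spath = outdir / "cluster_summary.json"
        spath.write_text(json.dumps(summary_json, indent=2, sort_keys=True))
        record("cluster_summary", spath)

    # ---- stage 7: enrichment -----------------------------------------
    with stage("enrichment"):
        if go_map is not None:
            results = enrich_clusters(clusters, go_map,
                                      alpha=config.enrichment_alpha)
            path = outdir / "enrichment.tsv"
            results.to_csv(path, sep="\t", index=False)
            record("enrichment", path)
            esummary = summarize_enrichment(results, clusters)
            espath = outdir / "enrichment_summary.json"
            espath.write_text(json.dumps(esummary, indent=2, sort_keys=True))
            record("enrichment_summary", espath)
        else:
            notes.append("no GO map provided; enrichment skipped")

    manifest = RunManifest(
        config=config.to_dict(), inputs=input_digests, outputs=outputs,
        timings=timings, notes=notes, seed=config.rng_seed,
        version=__version__,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
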