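# coexpatlas

Downstream analysis of a bulk RNA-Seq expression atlas: from a gene × sample
TPM matrix with tissue labels to housekeeping genes, tissue-specific genes,
a co-expression network, co-expression clusters, and GO enrichment.

The package is aimed at groups who have already quantified a large,
tissue-structured transcriptome collection (for example a crop expression
atlas spanning leaves, roots, tubers, pollen and more) and need the
standard downstream battery, reproducibly and with every rule explicit:

* **Sample QC** — read-count and mapping-rate filters on a per-sample
  statistics table, plus correlation-based hierarchical clustering of
  samples with automatic flagging of clade-level label mix-ups.
* **Housekeeping genes** — for every gene expressed in all samples, the
  coefficient of variation CoV = SD/mean, the maximum fold change
  MFC = max/min, and the product score MFC·CoV; genes in the first
  quartile of scores are called housekeeping (candidate qPCR references).
* **Tissue-specific genes** — the Tau index
  τ = Σᵢ(1 − xᵢ/max x)/(N−1) on per-tissue means, and all-vs-all
  overexpression tests on log2(TPM+1) (log2FC ≥ 2, BH-adjusted p ≤ 0.05);
  a gene overexpressed in one tissue versus **all** others is
  pairwise-specific, and tissue-specific when τ > 0.8.
* **HRR network** — Pearson correlations between expressed genes; each
  gene ranks its partners, and a pair is an edge iff the *highest
  reciprocal rank* HRR(a,b) = max(rank_a(b), rank_b(a)) ≤ 50 and
  PCC ≥ 0.5, with scale-free degree diagnostics.
* **HCCA clusters** — the Heuristic Cluster Chiseling Algorithm carves
  disjoint, internally dense clusters out of the network; clusters get
  per-gene tightness flags and tissue Z-profiles (distinct pattern when
  |Z| > 1 in ≥ 3 tissues).
* **GO enrichment** — exact hypergeometric upper-tail tests per cluster
  with BH correction.
* **Synthetic atlas generator** — tissue-structured TPM and count matrices
  with planted housekeeping genes, tissue-specific genes, co-expressed
  modules, noise and silent genes plus ground-truth labels, so every stage
  is verifiable without downloading anything.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a synthetic 15-tissue atlas (~2,000 genes × 150 samples) and run
the full pipeline:

```bash
coexpatlas simulate --seed 42 --outdir atlas
# wrote synthetic bundle (2022 genes x 150 samples) to atlas

coexpatlas all --matrix atlas/tpm.tsv --metadata atlas/samples.tsv \
    --counts atlas/counts.tsv --go atlas/go_map.tsv --seed 42 --outdir results
# wrote 10 outputs to results
```

`results/` now holds `qc_report.tsv`, `expressed_genes.tsv`,
`hk_scores.tsv`, `ts_calls.tsv`, `edges.tsv`, `clusters.tsv`,
`cluster_tissue_z.tsv`, `enrichment.tsv` and a `manifest.json` with config,
input digests and output digests — two runs with the same seed are
byte-identical.

Individual stages are also standalone subcommands:

```bash
coexpatlas hk --matrix atlas/tpm.tsv --out hk.tsv
# 451 housekeeping genes of 1804 candidates

coexpatlas ts --matrix atlas/tpm.tsv --metadata atlas/samples.tsv --outdir ts_out
# 150 pairwise-specific genes, 150 tissue-specific (tau-filtered)

coexpatlas network --matrix atlas/tpm.tsv --outdir net_out
# 1962 nodes, 11385 edges
```

The housekeeping call is the first quartile of the 1,804 all-sample
candidates (451 ≈ 1804/4); the 150 recovered tissue-specific genes are
exactly the 150 the generator planted.  The head of `hk.tsv` (sorted by
MFC·CoV score, most stable first):

```
gene_id   mean_tpm    sd_tpm      cov      mfc    score  is_hk
 HK0193 148.209361 15.508404 0.104638 1.865771 0.195231   True
 HK0151  56.304813  6.212805 0.110342 1.849721 0.204103   True
 HK0106 347.457513 40.382107 0.116222 1.831422 0.212851   True
```

CoV ≈ 0.1 is the stability level the generator plants for housekeeping
genes; MFC < 2 means no sample deviates even two-fold from any other.
`results/cluster_summary.json` reports 19 clusters (median size 10,
largest 204), an average tight-member fraction of 83.5%, and 47% of
clusters with a distinct tissue pattern — the planted co-expression
modules, recovered from the network alone.

The same functionality is available as a library:

```python
from coexpatlas import (SimulationDesign, simulate_expression,
                        pcc_matrix, hrr_transform, hcca_cluster)

tpm, samples, truth = simulate_expression(SimulationDesign(seed=42))
net = hrr_transform(pcc_matrix(tpm), hrr_max=50, pcc_cutoff=0.5)
clusters = hcca_cluster(net)
```

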