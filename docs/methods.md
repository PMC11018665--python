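# Methods

`coexpatlas` reimplements the downstream half of a bulk RNA-Seq
expression-atlas study as a reusable pipeline: from a gene × sample TPM
matrix with tissue labels to housekeeping genes, tissue-specific genes, a
Highest-Reciprocal-Rank (HRR) co-expression network, HCCA co-expression
clusters with tissue profiles, and per-cluster GO enrichment.  This note
documents the statistical procedures, the synthetic-data model used to
validate them, and the numerical and design choices that were genuinely
open.

## Sample quality control

Samples are filtered on a per-sample mapping-statistics table: a sample is
excluded when fewer than 100,000 reads remain after trimming, when less
than 50% of its reads survive trimming, when ≥ 50% of reads fail to map,
or when ≥ 40% cannot map uniquely.  Count thresholds are strict (`<`) and
rate thresholds inclusive (`≥`), so a sample with exactly half its reads
unmapped fails.  Filtering is monotone: relaxing any threshold can only
retain more samples.

Mislabel detection operates on the raw count matrix.  Genes with mean
log2(count+1) < 1 are dropped; the sample–sample distance is
1 − Pearson correlation of log2(count+1) profiles; the tree is built by
agglomerative clustering (average linkage by default — the common choice
for correlation distances; complete linkage is configurable) and cut into
as many groups as there are declared major clades (aerial, underground,
pollen).  Each cut group is labelled with its majority declared clade and a
sample is flagged when its declared clade is not among the majority clades
of its group; majority ties favour the sample's own declaration
(conservative flagging).  An explicit rule is required where a human would
inspect the tree; the k-clade cut with majority vote is this package's
operationalization of that inspection.

## Expressed genes, housekeeping genes

A gene is *expressed* when TPM ≥ 1 (configurable) in at least one sample.
Housekeeping candidates are genes expressed in **every** sample.  For each
candidate we compute the mean and sample SD (n−1 denominator) of TPM, the
coefficient of variation CoV = SD/mean, the maximum fold change
MFC = max/min, and the product score MFC·CoV.  Candidates whose score lies
within the first quartile of candidate scores are called housekeeping;
the quantile uses linear interpolation between order statistics (NumPy's
default) and the boundary is inclusive, which makes the called set size
⌈0.25·candidates⌉ up to boundary ties.  CoV is computed on the TPM scale,
not log-TPM.  All of CoV, MFC and the calls are invariant to rescaling the
whole matrix.

## Tissue specificity

Two complementary definitions are computed:

* **Tau index** on per-tissue mean expression x₁..x_N:
  τ = Σᵢ (1 − xᵢ/max x) / (N − 1), 0 for uniform expression and 1 for
  single-tissue expression.  Tissue means are taken on TPM and transformed
  to log2(mean+1) before the formula, following the index's original
  recommendation; a linear-scale mode is kept for closed-form tests.  An
  all-zero profile has no defined τ and is reported missing, not 0.
* **All-vs-all overexpression.**  Every ordered tissue pair (T, O) is
  tested per gene on log2(TPM+1): log2FC = mean_T − mean_O, p from a
  two-sided Welch t test, Benjamini–Hochberg correction across genes
  within each contrast, and an overexpression call at
  log2FC ≥ 2 and adjusted p ≤ 0.05.  A gene overexpressed in T against
  *every* other tissue is pairwise-specific to T (at most one such T can
  exist, because overexpression is directional); it is tissue-specific
  when additionally τ > 0.8.  Both the pairwise-specific set and the
  τ-filtered set are reported, since either can be the set of record
  depending on downstream use.

The test is Welch's t rather than a linear-model fit with empirical-Bayes
moderation; an optional moderation mode shrinks per-gene variances toward
the per-tissue mean variance by a method-of-moments estimate (prior df from
matching the observed between-gene variance scatter against the expected
chi-square scatter, clipped to [1, 100]) and inflates the degrees of
freedom accordingly.  Moderation is the required fallback when a tissue has
a single sample.  The pseudo-count in log2(TPM+1) makes zeros finite and is
the de-facto standard.

## HRR co-expression network

Pearson correlations are computed across samples on log2(TPM+1) (raw-TPM
mode configurable) over the expressed genes; zero-variance genes have no
defined correlation and are excluded from ranking with a flag.  Each gene
ranks all others by descending correlation (rank 1 = best partner; ties
broken lexicographically by gene id for determinism).  The highest
reciprocal rank of a pair is HRR(a,b) = max(rank_a(b), rank_b(a)); an edge
is kept iff HRR ≤ 50 and PCC ≥ 0.5 (both configurable).  A blocked mode
computes correlations in row blocks and keeps only per-gene top-k partner
lists; because an edge needs both mutual ranks ≤ hrr_max, the blocked
result is identical to the dense one (verified bit-for-bit in tests), and
the full n × n matrix never needs to be materialized.  Both modes share one
numeric kernel (row-standardized matrix product).  Note that gene-row
permutations of the input can change low-level BLAS summation order, so
correlations are reproducible to within ~1 ulp rather than bitwise under
reordering; edge sets and ranks are unaffected in practice.

Degree diagnostics fit an ordinary least-squares line to log10(node count)
versus log10(degree) over degrees ≥ 1; a negative slope with high R² is
the signature of a heavy-tailed, scale-free-like degree distribution.  With
fewer than two distinct positive degrees the slope is reported missing.

## HCCA clustering

The Heuristic Cluster Chiseling Algorithm detects clusters by local
sculpting: each node seeds a breadth-first *vicinity* up to `step_size`
steps (default 3) in the residual network; the vicinity is *chiseled* by
repeatedly removing every non-seed node with more edges leaving the
candidate set than staying inside; surviving "clusterettes" are scored by
internal/(internal+boundary) edges, and the highest-scoring pairwise
disjoint ones of size ∈ [2, 300] are accepted.  Accepted nodes are removed
and the procedure repeats until no admissible clusterette remains; leftover
nodes then join the accepted cluster they share most edges with, or stay
unassigned when isolated.  Seeds are visited in lexicographic order and all
ties break lexicographically, so the procedure is fully deterministic.

Two operationalizations in this implementation matter and are deliberate:

* **Edge counts are taken against the full network**, with the residual
  only defining which nodes are still available.  Counting against the
  residual would let late-round leftovers masquerade as well-separated
  clusters merely because their strongly connected partners were already
  clustered away; the full-network reference collapses such fragments
  during chiseling and routes them through the leftover-attachment step
  instead.
* **Vicinity growth beyond the first step stops once the vicinity would
  exceed half the residual node count.**  Chiseling needs a non-trivial
  boundary; on the sparse rank-thresholded networks the method is designed
  for, depth-3 vicinities are naturally local and the cap never binds, but
  on dense graphs an unbounded multi-step neighborhood swallows the whole
  network and the algorithm would degenerate to a single cluster.  With
  the cap, benchmark graphs (disjoint cliques, bridged cliques,
  planted-partition graphs) are recovered correctly at the default
  `step_size`.

Cluster quality is profiled two ways.  *Tightness*: each member's
tissue-mean log2(TPM+1) profile is standardized to mean 0 / SD 1 across
tissues; the cluster consensus is the per-tissue mean of member Z profiles;
a member is tight when its profile deviates from the consensus by less than
1 Z unit in every tissue (max-deviation rule; a per-tissue-Z mode is
configurable).  Members with a flat profile cannot follow any pattern and
are untight with the reason recorded.  *Tissue profile*: per cluster the
member genes' per-tissue mean TPM values are averaged and standardized
across tissues (sample SD); a cluster is *distinct* when |Z| > 1 in at
least three tissues.

## GO enrichment

For a background of N annotated network genes of which K carry a term, a
cluster with n background genes and k carriers is scored by the
hypergeometric upper tail p = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n).  For the tail
lengths enrichment actually meets, the sum is evaluated in exact integer
arithmetic with one correctly-rounded division, so even astronomically
small p-values carry full double precision (relative error below 1e-12 is
guaranteed and tested); very long tails over huge backgrounds fall back to
a log-space evaluation (log-gamma binomials combined by log-sum-exp).
Benjamini–Hochberg correction is applied across all (cluster, term) tests
(Bonferroni configurable); terms are tested only when a cluster holds at
least two carriers.  The background is the annotated network genes
(standard practice; all network genes configurable).  Annotation
propagation up a user-provided term parent map is available but off by
default.

## Synthetic data model

The generator emulates a tissue-structured atlas on the log2 scale and is
the ground truth for every recovery test.  With the default design —
15 tissues in three clades (10 aerial, 4 underground, pollen), 10 samples
per tissue, 250 housekeeping, 150 tissue-specific, 20 modules of 10–40
genes, 1,040 noise and 60 silent genes, ≈ 2,000 genes in total:

* **Housekeeping genes**: per-gene constant log2 mean drawn uniformly in
  [2.5, 6] with Gaussian sample noise of SD √(ln(1+CoV²))/ln 2, giving
  log-normal TPM with CoV ≈ 0.1.
* **Tissue-specific genes**: baseline log2 TPM of −5 everywhere with one
  tissue (round-robin) elevated by 5 log2 units, sample noise SD 0.5.  The
  baseline sits near the detection limit deliberately: after column
  renormalization the baseline lands around 0.5 TPM and the spike around
  15 TPM, which is what keeps τ of the planted genes above 0.8 — real
  tissue-specific genes are essentially silent outside their tissue.
* **Modules**: each module draws one latent tissue profile — a per-clade
  offset from a *bounded* uniform (±1 log2 unit) plus Gaussian per-tissue
  jitter (SD 0.3 log2) — shared by all members, plus independent per-gene
  noise whose SD is calibrated per module so the expected within-module
  Pearson correlation on the log2 scale equals the design target (0.8).
  The bounded clade offsets are the load-bearing choice: they give samples
  their clade structure (what the mislabel detector relies on) while
  guaranteeing that no single tissue stands out by a tissue-specific-sized
  fold change, so modules are never spuriously called tissue-specific.
  Because the clade space has few degrees of freedom, modules built this
  way can correlate with each other and merge into larger clusters; tests
  that need a 1:1 module-to-cluster mapping (planted-term enrichment) use
  a variant design with the clade amplitude at 0 and the tissue jitter at
  1.0, i.e. smooth independent tissue profiles.
* **Noise genes** are independent log-normals (log2 SD 1.5, CoV ≈ 1.4),
  **silent genes** all-zero rows.

Values are exponentiated to TPM and each sample column rescaled to sum
10⁶.  This renormalization introduces mild compositional coupling between
genes — as in real TPM — and can be disabled for unit tests needing exact
independence.  Note that with only ~2,000 genes the mean TPM per gene
(10⁶/n_genes ≈ 500) is higher than in a real transcriptome; calibration
invariants (planted CoV, planted τ) are therefore stated and tested at the
default design scale, where the coupling is small.  Counts are drawn
Poisson with mean TPM · library_size/10⁶.  Label corruption reassigns a
chosen number of samples to a tissue from a different clade and records
the swapped ids.

What the generator does **not** emulate: batch and platform effects,
isoform structure, count overdispersion beyond Poisson, GO term hierarchy
in the generated annotations, and realistic gene counts.  Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under its stated model, not performance on heterogeneous public data.

## Problem sizes and parameters of record

Recovery metrics are averaged over 20 simulation seeds (10 for the heavier
tissue-specificity and enrichment runs in the acceptance script).  The
oracle-equivalence checks use 200-gene × 60-sample matrices against a
brute-force full-rank HRR oracle, a 10,000-case randomized grid (N ≤ 2,000)
against direct tail summation for the hypergeometric, and 4 × 25-node
planted-partition graphs (p_in 0.6, p_out 0.02) for clustering.  The
end-to-end pipeline runs at the default ≈ 2,000-gene × 150-sample scale and
is byte-for-byte reproducible for a fixed seed (manifest timings aside).

## Known limitations

* Welch/moderated t is an approximation of linear-model empirical-Bayes
  testing; with very small per-tissue n the moderated mode should be used.
* The HCCA vicinity cap (half the residual) is a heuristic; on graphs
  whose true communities span more than half the network it will prevent
  their recovery in one piece.
* BH correction treats all cluster × term tests as one family; per-cluster
  correction would be less conservative for many small clusters.
* The mislabel detector assumes the declared clade partition is the
  dominant axis of variation in the count matrix; it flags clade-level
  swaps only, not within-clade tissue swaps.
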