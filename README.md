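# g4scape

Analysis toolkit for genome-wide G-quadruplex (G4) landscapes across a stem-cell
differentiation step: from replicate G4-ChIP-seq peak sets to consensus maps,
annotation enrichment, promoter chromatin-state transitions, and the link
between promoter G4 maintenance and transcriptional stability.

It is written for computational epigenomicists who have per-replicate peak
calls (BED), histone-mark peak sets (H3K4me3 / H3K27me3), per-replicate
expression tables (TPM) and a differential-expression table for an embryonic
cell type (hESC) and its differentiated daughters (e.g. CNCC, NSC) — and who
want the downstream integration statistics reproducible and testable. A
first-class synthetic-data generator emulates the whole study design with
known ground truth, so every stage can be exercised end to end without any
sequencing data.

## What it computes

* **Replicate consensus** — `k_of_n_consensus` partitions the genome at every
  breakpoint and keeps segments supported by ≥ k of n peak sets
  (multiIntersectBed semantics). The study design is 2-of-3 technical
  replicates per biological replicate, then 2-of-3 biological replicates per
  cell type.
* **Permutation enrichment** — fold enrichment of a query set inside an
  annotation, restricted to a workspace. Each query interval is repositioned
  uniformly at random (length-preserved) inside the workspace;
  fold = observed bp overlap / mean permuted overlap, with the empirical
  p-value (1 + #{perm ≥ obs}) / (n_perm + 1).
* **Promoter classification** — promoter windows are TSS ± 1000 bp
  (strand-aware, 2001 bp). Histone classes per cell:
  *bivalent* (an H3K4me3∩H3K27me3 segment overlaps the window), *other*
  (both marks, never colocalised), *H3K4me3*, *H3K27me3*, *unmarked*.
  G4 status per cell is overlap with the consensus map; the embryonic →
  daughter pair defines the four transition classes
  G4_E±G4_D± (maintained / lost / gained / never).
* **Transcriptional stabilisation** — per transition class, weighted least
  squares of daughter on embryonic expression,
  y = a + b·x with x, y = log₂(median TPM + 0.1) and weights w = embryonic
  TPM. The residual variance quantifies transcriptional spread, groups are
  compared by one-tailed F-tests (is the comparison group more variable than
  the G4-maintained group?), and the weighted R² ranking compares features.
  Differential-expression categories (up/down at FDR < 0.05 and |log₂FC| > 1,
  not-DE otherwise) are compared by Pearson χ² proportion tests.
* **Integration clustering** — each gene's 6-vector (median TPM ×3 cells,
  median promoter G4 RPM ×3 cells) is capped per column at the 75th
  percentile, z-scored, and partitioned by PAM k-medoids (k = 6, Euclidean,
  BUILD + SWAP).
* **Signal tracks** — binned RPM coverage from read intervals, bin-wise
  median across replicates, per-region summaries and strand-oriented TSS
  metaprofiles.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes on a
2 × 5 Mb toy genome, 3 cell types × 3 biological × 3 technical replicates):

```bash
g4scape run --out run_default --seed 1
```

This takes about 20 s and writes per-stage outputs plus `run_report.json`
with SHA-256 hashes of every file (a rerun with the same seed is
byte-identical). Highlights from the run above:

`enrichment/enrichment.tsv` — G4 consensus maps are enriched at promoters
(by construction the generator plants a share of G4 peaks there):

```
query              observed_bp  expected_bp  fold    empirical_p
hESC_G4_consensus  154071       100533.954   1.532   0.000999
CNCC_G4_consensus  104474       80511.627    1.298   0.000999
```

`landscape/transitions_bivalent_CNCC.tsv` — among hESC-bivalent promoters,
the fraction resolving to active H3K4me3 in the daughter depends strongly on
the G4 transition class (generator rows: 79% maintained, 83% gained, 40%
lost, 30% never):

```
g4_group  daughter_class  count  proportion  group_n
G4E+GD+   H3K4me3         76     0.784       97
G4E+GD-   H3K4me3         37     0.425       87
G4E-GD+   H3K4me3         30     0.833       36
G4E-GD-   H3K4me3         82     0.312       263
```

`stabilise/CNCC_groups.tsv` — promoters that maintain their G4 have about
4-fold lower residual variance and the highest weighted R² (generator:
σ = 0.3 for maintained vs 0.8 for the rest); all one-tailed F-tests against
the maintained group are significant (F ≈ 4.3–4.5, p < 1e-20):

```
group     n    slope  residual_variance  r2_weighted
G4E+GD+   352  1.008  0.150              0.956
G4E+GD-   343  1.049  0.649              0.825
G4E-GD+   119  1.053  0.673              0.880
G4E-GD-   971  0.965  0.655              0.825
```

The same operations are available as library functions
(`g4scape.k_of_n_consensus`, `g4scape.permutation_enrichment`,
`g4scape.build_integration_matrix`, `g4scape.stability_report`,
`g4scape.pam_cluster`, …) and as individual subcommands
(`g4scape simulate|consensus|enrich|track|metaprofile|landscape|stabilise|cluster`).

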