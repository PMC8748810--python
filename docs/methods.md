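# Methods

This note documents the models and procedures g4scape implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED native); GTF input is converted
on read. Merging joins book-ended intervals ([0,5) + [5,10) → [0,10)),
matching the default of the standard BED tooling, so consensus segments are
maximal contiguous runs. Overlap anywhere means ≥ 1 bp; no minimum-fraction
option exists anywhere in the package. Duplicate coordinates within one
input set are deduplicated before interval counting, since replicate peak
callers emit unique regions.

`k_of_n_consensus` implements multiIntersectBed semantics with a sweep line:
the genome is partitioned at every breakpoint of every (merged) input,
segments with set-count ≥ k are kept, and adjacent survivors merge. A
per-base boolean-array oracle — deliberately sharing no code with the sweep —
verifies equivalence on randomised instances in the test suite.

"TSS ± 1000 bp" is realised as the 2001-bp window [tss − 1000, tss + 1001)
including the TSS base, clipped at chromosome bounds; the TSS is strand-aware
(transcript start on +, transcript end − 1 on −). Promoters clipped at an
edge remain classified on the clipped window.

Three-way overlap (Venn) tallies are reported per set: each interval of each
set is classified once by which other sets it touches. Because one interval
of set A may straddle several intervals of set B, the A-side and B-side
tallies of a shared region can differ; both are reported rather than forcing
a single merged count.

## Permutation enrichment

The null repositions each query interval independently: a workspace segment
is chosen with probability proportional to its number of valid start
positions (segment length − interval length + 1), then a uniform start within
it. This is the simplest exactly length-preserving null; permuted intervals
may overlap each other, and never leave the workspace. The statistic is
nucleotide (bp) overlap with the annotation — not interval counts — and the
empirical p-value carries the +1 correction, p = (1 + #{perm ≥ obs}) /
(n_perm + 1), so it is never zero; a two-sided variant doubles the smaller
tail. Query and annotation are clipped to the workspace (with a warning if
the query loses coverage); overlapping query intervals are merged before
both the observed count and the randomisation, so the placed segments match
the segments counted. Randomisation uses a named substream of the root seed,
so results are reproducible and independent of call order.

Because bp overlap is a discrete statistic, permutation ties make the
empirical p slightly conservative: in the null-calibration suite the
fraction of datasets with p ≤ 0.05 is typically 3–4.5% rather than exactly
5%. This is a property of discrete permutation tests, not a miscalibration.

Not implemented: GC- or isochore-matched randomisation, joint testing of
multiple annotations.

## Signal tracks

Reads are supplied as intervals; coverage is fractional by bp overlap with
each bin (default 10 bp), scaled to reads-per-million:
(read-bp in bin / bin_size) × 1e6 / library_size. Replicate aggregation is a
bin-wise median computed before any region summarisation. Per-region signal
is the median (or mean) over the bins intersecting the region. TSS
metaprofiles are strand-oriented (minus-strand rows reversed) and report the
across-promoter median per offset bin, in raw RPM; promoters whose window
leaves the chromosome are excluded and counted. bigWig I/O is out of scope —
tracks read and write bedGraph.

## Promoter classification

Histone classes are assigned with bivalency tested first: a promoter is
*bivalent* only if a segment of the base-pair intersection H3K4me3∩H3K27me3
overlaps the window itself. If both marks overlap the window but never
colocalise inside it, the class is *other*; then single-mark classes; then
*unmarked*. Requiring the colocalised segment to overlap the promoter (rather
than the two marks merely sharing a region anywhere) is the stricter of the
two possible readings of bivalency and is the one implemented. The
classification is invariant to coverage-preserving splits of the mark sets.

G4 transitions are a pure 2-bit function of (embryonic G4 status, daughter
G4 status): maintained (G4E+GD+), lost (G4E+GD−), gained (G4E−GD+), never
(G4E−GD−).

The integration matrix carries, per gene: promoter coordinates, per-cell
histone class, per-cell G4 status and overlap counts, per-cell median TPM
across replicates, per-cell median promoter G4 RPM, and per-daughter
transition class. Genes present in expression tables but absent from the
gene models are excluded and logged.

## Statistics

* **Two-proportion test** — Pearson χ² on the 2×2 table *without* continuity
  correction (prop.test(correct=FALSE) behaviour; R's default Yates
  correction is deliberately not applied, since the plain Pearson statistic
  is the documented choice). One-sided p is p/2 when the observed direction
  matches the alternative, 1 − p/2 otherwise.
* **One-sided KS** — D⁺ = sup(F_b − F_a) for the alternative "a
  stochastically greater", with the asymptotic one-sided tail
  p = exp(−2mnD²/(m+n)), capped at 1. No exact small-sample enumeration; the
  statistic is cross-checked against an independent ECDF enumeration and
  scipy in the tests.
* **Weighted regression** — (a, b) minimise Σ wᵢ(yᵢ − a − bxᵢ)² via WLS
  (statsmodels backend). x, y = log₂(median TPM + 0.1); the 0.1 pseudocount
  is required because genes may have TPM = 0 in one of the two cells and is
  the package's documented constant. Weights are raw (untransformed)
  embryonic median TPM — "expression of the reference state" — with a
  log-scale alternative behind a flag. Weighted R² = 1 − Σw·r² / Σw·(y−ȳ_w)²
  is primary; the unweighted R² is also reported. The weighted normal
  equations (Σw·r = 0, Σw·x·r = 0) are asserted to 1e-8.
* **Residual spread** — unweighted sample variance of the raw residuals
  (weighted alternative behind a flag). The F-test compares residual
  variances one-tailed in the fixed orientation "comparison group more
  variable than the G4-maintained reference", p = P(F_{df_b,df_a} ≥ F).
* **DE categories** — up in daughter: FDR < 0.05 and log₂FC > 1; up in
  embryonic: FDR < 0.05 and log₂FC < −1; not-DE: FDR > 0.05 and |log₂FC| < 1.
  Genes significant at small fold change satisfy none of the three published
  definitions; they are kept as *unclassified*, excluded from the proportion
  analysis, and counted in the log. The package consumes the DE table; it
  does not fit differential-expression models itself.

## Clustering

Per column: values above the 75th percentile are capped to it (linear
interpolation quantile — numpy default, R type 7 — matching the default of
the statistical environments this analysis is normally run in), then
z-scored using the post-capping mean and SD, in that order. A column with
zero post-capping SD cannot be standardised and raises.

PAM k-medoids uses the classical BUILD greedy initialisation followed by
SWAP: the best strictly-improving (medoid, non-medoid) exchange is applied
until none exists, so the total Euclidean distance-to-medoid cost is
non-increasing and termination is guaranteed. The algorithm is deterministic
on continuous data (the recorded seed exists only to describe tie behaviour;
exact ties resolve to the lowest index). The implementation holds the full
n×n distance matrix, which is the right trade-off at desk scale; choosing k
is out of scope (k = 6 per the study design).

## Synthetic-data generator

The generator emulates the statistical structure of a three-cell
differentiation study; its defaults are the study conditions:

* **Genome/genes** — 2 chromosomes × 5 Mb, 2,000 genes with non-overlapping
  promoters, alternating strands (20,000 genes on a scaled-up genome for the
  transition-recovery checks).
* **Promoter G4 design** — P(G4 at embryonic promoter) = 0.4;
  P(daughter G4 | embryonic G4) = 0.5, P(daughter G4 | none) = 0.111, which
  makes ~75% of daughter G4s occur where the embryonic cell already had one,
  matching the reported sharing structure. Background (non-promoter) peaks:
  500 per cell with 75% of daughter backgrounds re-used from the embryonic
  set. Peaks are 200 bp.
* **Replicates** — 3 biological × 3 technical per cell; each technical
  replicate drops each true interval with probability 0.1 and jitters both
  boundaries with rounded N(0, 10 bp). Expected consensus recall follows the
  two-stage binomial P(≥2 of 3) composition exactly when jitter is off.
* **Histone transitions** — the embryonic class prior is bivalent 0.25,
  H3K4me3 0.45, H3K27me3 0.10, unmarked 0.15, other 0.05. Daughter classes
  are drawn from row-stochastic matrices indexed by (embryonic class, G4
  transition group). The probability of carrying H3K4me3 in the daughter uses
  the published values: bivalent rows 0.79 / 0.83 / 0.40 / 0.30 and H3K4me3
  rows 0.98 / 0.99 / 0.79 / 0.84 for maintained / gained / lost / never; the
  remaining mass favours staying in (or near) the start class, and classes
  with no published G4 dependence get sticky, group-independent rows. Mark
  intervals are placed inside the promoter so that re-classification recovers
  the sampled label exactly (bivalent → overlapping K4/K27 segments, other →
  disjoint segments).
* **Expression** — embryonic log₂ expression ~ N(3, 2); daughter log₂
  expression = 1.0·x + 0 + N(0, σ_group) with σ = 0.3 for G4-maintained and
  0.8 for the other three groups; 10% of genes silent (TPM 0 everywhere);
  replicate TPMs add lognormal noise (log₂ SD 0.25), 3 replicates per cell.
  The DE table is produced by an honest Welch t-test on replicate log₂
  values with Benjamini–Hochberg adjustment; a direct-label mode copies the
  latent truth for exact-count tests.
* **Coverage** — 200,000 reads of 50 bp per replicate track, a uniform
  background plus a box component over G4-positive promoter windows with a
  5× plateau/background density ratio. The depth is chosen so that
  background promoter bins are mostly covered and the median promoter RPM is
  informative rather than exactly zero — at sparser depth the 75th-percentile
  cap of a daughter G4-RPM column can degenerate to zero and make the column
  unstandardisable.

All draws come from named substreams of one root seed (so adding a stage
never perturbs earlier streams), every written file carries the seed in a
header comment, and outputs are byte-reproducible per seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence content (no FASTA/FASTQ, no G4
motifs or GC structure), alignment artefacts and mappability, peak-caller
behaviour, correlated replicate failures, copy-number or batch structure,
overdispersed count noise in expression (lognormal replicate noise stands in
for it), and any dependence of histone transitions on factors other than the
modelled (class, G4 group) pair.

## Scale of the shipped analyses

The default pipeline (2,000 genes) runs in ~20 s on one CPU; the
transition-recovery analysis uses 20,000 promoters; stabilisation recovery
uses 2,000 genes per transition group over 20 seeds; enrichment calibration
uses 500 null datasets at 199 permutations. These sizes make every
distributional claim in the test suite measurable with comfortable
Monte-Carlo margins while keeping the full suite around a minute.

## Known limitations

* Genome-scale consensus counts and R² values from the original sequencing
  data are not reproducible from synthetic data; the package verifies the
  in-paper arithmetic, parameter recovery, and oracle equivalence instead.
* The permutation null randomises the query only; annotation structure
  (e.g. clustering of promoters) is conditioned on, not modelled.
* The one-sided KS p-value is asymptotic and anti-conservative for very
  small samples.
* PAM is O(n²) memory; the CLARA-style subsampling fallback for very large
  n is not implemented.
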