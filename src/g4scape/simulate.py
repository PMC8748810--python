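"""Synthetic multi-omic data with the statistical structure the pipeline assumes.

The generator emulates a three-cell-type differentiation study (one
embryonic cell, two daughters) observed through G4 ChIP-seq peak sets with a
3 biological × 3 technical replicate design, histone-mark (H3K4me3 /
H3K27me3) peak sets, replicate expression tables, a differential-expression
table and binned coverage reads — together with a truth record of every
latent label, so each analysis stage can be tested for parameter recovery
rather than merely for not crashing.

Default generative settings mirror the study design the analysis targets:

* promoter G4 state — the daughter-in-embryonic share of G4s is ~0.75
  (most daughter G4s occur where the embryonic cell already had one);
* replicate structure — per-interval Bernoulli dropout and Gaussian boundary
  jitter per technical replicate, recovered by 2-of-3 / 2-of-3 consensus;
* histone transitions — the probability that a bivalent or H3K4me3 promoter
  carries H3K4me3 in the daughter depends on the G4 transition group
  (bivalent rows 0.79 / 0.83 / 0.40 / 0.30 and H3K4me3 rows 0.98 / 0.99 /
  0.79 / 0.84 for maintained / gained / lost / never);
* expression — daughter log2 expression is a linear function of embryonic
  log2 expression with group-specific residual SD, tighter for promoters
  that maintain their G4 (0.3 vs 0.8).

Every file written carries ``# seed=N`` in its header and all draws come
from named substreams of one root seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    promoter_windows,
    write_bed,
    write_chrom_sizes,
)
from .landscape import HISTONE_CLASSES, TRANSITION_CLASSES, classify_g4_transition
from .rng import substream

__all__ = [
    "SimulationConfig",
    "default_transition_matrices",
    "make_toy_genome",
    "simulate_g4_truth",
    "simulate_g4_replicates",
    "simulate_histone_landscape",
    "simulate_expression",
    "simulate_coverage",
    "simulate_all",
]


def default_transition_matrices() -> dict[str, dict[str, dict[str, float]]]:
    """Row-stochastic daughter-class distributions per (start class, G4 group).

    The headline entry of each row is the probability of carrying H3K4me3 in
    the daughter; the remaining mass is spread over the other classes with
    the start class favoured (bivalent promoters that do not activate tend to
    stay bivalent or resolve to H3K27me3).
    """

    def k4_row(p_k4: float, rest: dict[str, float]) -> dict[str, float]:
        total = sum(rest.values())
        row = {c: (1 - p_k4) * v / total for c, v in rest.items()}
        row["H3K4me3"] = p_k4
        assert abs(sum(row.values()) - 1) < 1e-12
        return row

    biv_rest = {"bivalent": 0.60, "H3K27me3": 0.25, "unmarked": 0.10, "other": 0.05}
    k4_rest = {"bivalent": 0.30, "unmarked": 0.50, "other": 0.10, "H3K27me3": 0.10}
    p_k4_bivalent = {"G4E+GD+": 0.79, "G4E-GD+": 0.83, "G4E+GD-": 0.40, "G4E-GD-": 0.30}
    p_k4_active = {"G4E+GD+": 0.98, "G4E-GD+": 0.99, "G4E+GD-": 0.79, "G4E-GD-": 0.84}

    mats: dict[str, dict[str, dict[str, float]]] = {
        "bivalent": {g: k4_row(p, biv_rest) for g, p in p_k4_bivalent.items()},
        "H3K4me3": {g: k4_row(p, k4_rest) for g, p in p_k4_active.items()},
    }
    # classes without a published G4 dependence keep a sticky, group-free row
    sticky = {
        "H3K27me3": {"H3K27me3": 0.7, "bivalent": 0.1, "H3K4me3": 0.1, "unmarked": 0.1},
        "unmarked": {"unmarked": 0.8, "H3K4me3": 0.1, "H3K27me3": 0.05, "bivalent": 0.05},
        "other": {"other": 0.5, "H3K4me3": 0.2, "H3K27me3": 0.1, "bivalent": 0.1, "unmarked": 0.1},
    }
    for start, row in sticky.items():
        mats[start] = {g: dict(row) for g in TRANSITION_CLASSES}
    return mats


@dataclass
class SimulationConfig:
    """All generative parameters for one synthetic study."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 2000
    flank: int = 1000
    cells: tuple[str, ...] = ("hESC", "CNCC", "NSC")  # first entry is embryonic

    # promoter G4 design
    p_g4_embryonic: float = 0.4
    p_g4_maintain: float = 0.5  # P(daughter G4+ | embryonic G4+)
    p_g4_gain: float = 0.111  # P(daughter G4+ | embryonic G4-); 0.111 gives
    # a daughter-in-embryonic share of ~0.75
    peak_width: int = 200
    n_background_peaks: int = 500
    background_shared_fraction: float = 0.75

    # replicate structure
    jitter_sd: float = 10.0
    dropout: float = 0.1
    n_bio: int = 3
    n_tech: int = 3

    # histone landscape
    histone_prior: dict[str, float] = field(
        default_factory=lambda: {
            "bivalent": 0.25,
            "H3K4me3": 0.45,
            "H3K27me3": 0.10,
            "unmarked": 0.15,
            "other": 0.05,
        }
    )
    transition_matrices: dict = field(default_factory=default_transition_matrices)

    # expression model
    expr_slope: float = 1.0
    expr_intercept: float = 0.0
    sigma_by_group: dict[str, float] = field(
        default_factory=lambda: {
            "G4E+GD+": 0.3,
            "G4E+GD-": 0.8,
            "G4E-GD+": 0.8,
            "G4E-GD-": 0.8,
        }
    )
    embryonic_log2_mean: float = 3.0
    embryonic_log2_sd: float = 2.0
    silent_fraction: float = 0.10
    replicate_log2_sd: float = 0.25
    n_expr_reps: int = 3
    de_direct_labels: bool = False

    # coverage reads; the default depth keeps background promoter bins mostly
    # covered so that median promoter RPM is informative rather than zero
    library_size: int = 1_000_000
    n_reads: int = 200_000
    read_length: int = 50
    tss_enrichment: float = 5.0
    tss_window: int = 1000
    n_track_reps: int = 3
    bin_size: int = 10

    def __post_init__(self) -> None:
        for name in ("p_g4_embryonic", "p_g4_maintain", "p_g4_gain", "dropout",
                     "background_shared_fraction", "silent_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(sum(self.histone_prior.values()) - 1) > 1e-9:
            raise ValueError("histone_prior must sum to 1")
        for start, rows in self.transition_matrices.items():
            for g, row in rows.items():
                if abs(sum(row.values()) - 1) > 1e-9:
                    raise ValueError(f"transition row ({start}, {g}) does not sum to 1")
        for g, s in self.sigma_by_group.items():
            if s < 0:
                raise ValueError(f"sigma for {g} must be >= 0")

    @property
    def embryonic(self) -> str:
        return self.cells[0]

    @property
    def daughters(self) -> tuple[str, ...]:
        return tuple(self.cells[1:])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cells"] = list(self.cells)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cells" in d:
            d["cells"] = tuple(d["cells"])
        return cls(**d)


# ---------------------------------------------------------------------------


def make_toy_genome(config: SimulationConfig) -> tuple[dict[str, int], list[GeneModel]]:
    """Place genes with non-overlapping promoters on the toy chromosomes.

    Genes are distributed proportionally to chromosome length, with
    alternating strands and a per-gene uniform offset inside its slot (drawn
    from the ``genome`` substream, so placement is deterministic per seed).
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = substream(config.seed, "genome")
    window = 2 * config.flank + 1
    margin = config.flank + 10
    slot = window + 200  # promoter + guard gap so marks never merge across genes
    total = sum(config.chrom_sizes.values())
    capacity = sum((L - 2 * margin) // slot for L in config.chrom_sizes.values())
    if capacity < config.n_genes:
        raise ValueError(
            f"genome too small: capacity {capacity} promoter slots for "
            f"{config.n_genes} genes"
        )
    # apportion genes to chroms by length (largest remainder)
    chroms = list(config.chrom_sizes)
    quota = {c: config.n_genes * config.chrom_sizes[c] / total for c in chroms}
    counts = {c: int(quota[c]) for c in chroms}
    for c in sorted(chroms, key=lambda c: quota[c] - counts[c], reverse=True):
        if sum(counts.values()) == config.n_genes:
            break
        counts[c] += 1
    for c in chroms:  # never exceed per-chrom capacity
        cap = (config.chrom_sizes[c] - 2 * margin) // slot
        if counts[c] > cap:
            raise ValueError(f"chromosome {c} too small for {counts[c]} genes")

    genes: list[GeneModel] = []
    gi = 0
    for c in chroms:
        n = counts[c]
        if n == 0:
            continue
        usable = config.chrom_sizes[c] - 2 * margin
        spacing = usable // n
        slack = max(0, spacing - slot)
        offsets = rng.integers(0, slack + 1, size=n)
        for j in range(n):
            tss = margin + j * spacing + config.flank + int(offsets[j])
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(GeneModel(f"gene{gi:05d}", c, strand, tss))
            gi += 1
    return dict(config.chrom_sizes), genes


def simulate_g4_truth(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[dict[str, IntervalSet], pd.DataFrame]:
    """Per-cell true G4 peak sets plus the per-gene G4/transition labels.

    Promoter G4s sit centred on the TSS; daughter status is drawn
    conditionally on the embryonic status (maintain / gain probabilities).
    Background (non-promoter) peaks follow the configured inter-cell sharing:
    each daughter re-uses a fraction of the embryonic background peaks and
    draws the rest fresh.
    """
    rng = substream(config.seed, "g4_truth")
    half = config.peak_width // 2
    emb = config.embryonic

    g4 = {emb: rng.random(len(genes)) < config.p_g4_embryonic}
    for d in config.daughters:
        u = rng.random(len(genes))
        g4[d] = np.where(g4[emb], u < config.p_g4_maintain, u < config.p_g4_gain)

    rows = []
    for i, g in enumerate(genes):
        row = {"gene_id": g.gene_id}
        for cell in config.cells:
            row[f"g4_{cell}"] = bool(g4[cell][i])
        for d in config.daughters:
            row[f"transition_{d}"] = classify_g4_transition(
                bool(g4[emb][i]), bool(g4[d][i])
            )
        rows.append(row)
    labels = pd.DataFrame(rows).set_index("gene_id")

    _, windows = promoter_windows(genes, config.chrom_sizes, config.flank)

    def promoter_peak(g: GeneModel) -> GenomicInterval:
        length = config.chrom_sizes[g.chrom]
        start = max(0, g.tss - half)
        return GenomicInterval(g.chrom, start, min(length, start + config.peak_width))

    # background peaks avoid all promoter windows (padded by the peak width)
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}
    for w in windows.values():
        forbidden[w.chrom].append((w.start - config.peak_width, w.end + config.peak_width))
    for c in forbidden:  # sort and coalesce so the bisect probe below is exact
        merged: list[tuple[int, int]] = []
        for s, e in sorted(forbidden[c]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        forbidden[c] = merged

    def sample_background(n: int) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        chrom_names = list(config.chrom_sizes)
        lengths = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=float)
        p = lengths / lengths.sum()
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 100 * n + 1000:
                raise RuntimeError("could not place background peaks; genome too dense")
            c = chrom_names[rng.choice(len(chrom_names), p=p)]
            start = int(rng.integers(0, config.chrom_sizes[c] - config.peak_width))
            end = start + config.peak_width
            bad = False
            import bisect

            fb = forbidden[c]
            idx = bisect.bisect_right(fb, (start, end)) - 1
            for k in (idx, idx + 1):
                if 0 <= k < len(fb) and fb[k][0] < end and start < fb[k][1]:
                    bad = True
                    break
            if not bad:
                out.append(GenomicInterval(c, start, end))
        return out

    emb_bg = sample_background(config.n_background_peaks)
    truth: dict[str, IntervalSet] = {}
    for cell in config.cells:
        peaks = [promoter_peak(g) for i, g in enumerate(genes) if g4[cell][i]]
        if cell == emb:
            bg = emb_bg
        else:
            n_shared = int(round(config.background_shared_fraction * config.n_background_peaks))
            shared_idx = rng.choice(len(emb_bg), size=n_shared, replace=False)
            bg = [emb_bg[k] for k in shared_idx] + sample_background(
                config.n_background_peaks - n_shared
            )
        truth[cell] = IntervalSet(peaks + bg, config.chrom_sizes, f"g4_truth_{cell}")
    return truth, labels


def simulate_g4_replicates(
    truth: IntervalSet,
    config: SimulationConfig,
    cell: str,
) -> dict[tuple[int, int], IntervalSet]:
    """Replicate peak sets: (bio, tech) → truth with jitter and dropout.

    Each technical replicate independently omits each true interval with
    probability ``dropout`` and jitters both boundaries by rounded Gaussian
    noise (clipped to the chromosome; a collapsed interval is restored to
    1 bp).  With dropout < 0.5 the 2-of-3 / 2-of-3 consensus recovers truth
    in expectation; higher dropout is allowed (the expected recall follows
    the two-stage binomial formula either way).
    """
    rng = substream(config.seed, f"replicates_{cell}")
    out: dict[tuple[int, int], IntervalSet] = {}
    ivs = truth.intervals
    for b in range(config.n_bio):
        for t in range(config.n_tech):
            kept = []
            drop = rng.random(len(ivs))
            js = np.rint(
                rng.normal(0.0, config.jitter_sd, size=(len(ivs), 2))
            ).astype(int) if config.jitter_sd > 0 else np.zeros((len(ivs), 2), int)
            for i, iv in enumerate(ivs):
                if drop[i] < config.dropout:
                    continue
                length = truth.assembly[iv.chrom]
                s = max(0, min(length - 1, iv.start + js[i, 0]))
                e = max(0, min(length, iv.end + js[i, 1]))
                if e <= s:
                    e = s + 1
                kept.append(GenomicInterval(iv.chrom, s, e))
            out[(b, t)] = IntervalSet(
                kept, truth.assembly, f"{truth.name}_b{b}t{t}"
            )
    return out


def simulate_histone_landscape(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    g4_labels: pd.DataFrame,
) -> tuple[dict[str, IntervalSet], dict[str, IntervalSet], pd.DataFrame]:
    """Per-cell H3K4me3/H3K27me3 peak sets realising sampled promoter classes.

    The embryonic class is drawn from the prior; each daughter class from the
    transition-matrix row indexed by (embryonic class, that daughter's G4
    transition group).  Marks are placed inside the promoter window so that
    re-classification recovers the sampled label exactly: bivalent promoters
    get overlapping K4/K27 segments, "other" promoters disjoint ones.
    """
    rng = substream(config.seed, "histone")
    emb = config.embryonic
    classes = list(config.histone_prior)
    prior = np.array([config.histone_prior[c] for c in classes])

    emb_idx = rng.choice(len(classes), size=len(genes), p=prior)
    labels = {emb: [classes[i] for i in emb_idx]}
    for d in config.daughters:
        groups = g4_labels[f"transition_{d}"].to_dict()
        # one uniform draw per gene, mapped through the row's CDF
        u = rng.random(len(genes))
        lab = []
        for i, g in enumerate(genes):
            row = config.transition_matrices[labels[emb][i]][groups[g.gene_id]]
            acc = 0.0
            chosen = next(iter(row))
            for target, p in row.items():
                acc += p
                if u[i] < acc:
                    chosen = target
                    break
            else:
                chosen = target
            lab.append(chosen)
        labels[d] = lab

    k4_sets: dict[str, IntervalSet] = {}
    k27_sets: dict[str, IntervalSet] = {}
    for cell in config.cells:
        k4, k27 = [], []
        for i, g in enumerate(genes):
            cls = labels[cell][i]
            t = g.tss
            c = g.chrom
            if cls == "H3K4me3":
                k4.append(GenomicInterval(c, t - 200, t + 200))
            elif cls == "H3K27me3":
                k27.append(GenomicInterval(c, t - 200, t + 200))
            elif cls == "bivalent":
                k4.append(GenomicInterval(c, t - 150, t + 100))
                k27.append(GenomicInterval(c, t - 50, t + 200))
            elif cls == "other":
                k4.append(GenomicInterval(c, t - 800, t - 400))
                k27.append(GenomicInterval(c, t + 400, t + 800))
        k4_sets[cell] = IntervalSet(k4, config.chrom_sizes, f"k4_{cell}")
        k27_sets[cell] = IntervalSet(k27, config.chrom_sizes, f"k27_{cell}")

    lab_df = pd.DataFrame(
        {f"histone_{cell}": labels[cell] for cell in config.cells},
        index=[g.gene_id for g in genes],
    )
    lab_df.index.name = "gene_id"
    return k4_sets, k27_sets, lab_df


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    g4_labels: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Replicate TPM tables, DE tables and the latent expression truth.

    Daughter log2 expression is ``slope·x + intercept + N(0, σ_group)`` with
    the embryonic log2 expression x ~ N(mean, sd); a silent fraction of genes
    is zero everywhere.  Replicate TPMs add lognormal noise.  The DE table is
    produced by an honest Welch t-test on the replicate log2 values with
    Benjamini–Hochberg adjustment (or copied directly from the latent truth
    when ``de_direct_labels`` is set, for exact-count tests).
    """
    rng = substream(config.seed, "expression")
    n = len(genes)
    emb = config.embryonic
    ids = [g.gene_id for g in genes]

    silent = rng.random(n) < config.silent_fraction
    x = rng.normal(config.embryonic_log2_mean, config.embryonic_log2_sd, size=n)
    true_log2 = {emb: x}
    for d in config.daughters:
        groups = g4_labels[f"transition_{d}"].to_dict()
        sigma = np.array([config.sigma_by_group[groups[gid]] for gid in ids])
        eps = rng.normal(0.0, 1.0, size=n) * sigma
        true_log2[d] = config.expr_slope * x + config.expr_intercept + eps

    expr: dict[str, pd.DataFrame] = {}
    for cell in config.cells:
        reps = {}
        for r in range(config.n_expr_reps):
            noise = rng.normal(0.0, config.replicate_log2_sd, size=n)
            tpm = np.power(2.0, true_log2[cell] + noise)
            tpm[silent] = 0.0
            reps[f"rep{r + 1}"] = tpm
        expr[cell] = pd.DataFrame(reps, index=pd.Index(ids, name="gene_id"))

    de_tables: dict[str, pd.DataFrame] = {}
    for d in config.daughters:
        true_fc = true_log2[d] - true_log2[emb]
        if config.de_direct_labels:
            log2fc = true_fc.copy()
            log2fc[silent] = 0.0
            fdr = np.where(np.abs(log2fc) > 1, 0.0, 1.0)
        else:
            le = np.log2(expr[emb].to_numpy() + 0.1)
            ld = np.log2(expr[d].to_numpy() + 0.1)
            log2fc = ld.mean(axis=1) - le.mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                # silent genes have identical all-zero replicates; the t-test
                # warns and returns NaN there, which becomes p = 1 below
                warnings.simplefilter("ignore", RuntimeWarning)
                _, p = sstats.ttest_ind(ld, le, axis=1, equal_var=False)
            p = np.where(np.isnan(p), 1.0, p)
            fdr = multipletests(p, method="fdr_bh")[1]
        de_tables[d] = pd.DataFrame(
            {"log2fc": log2fc, "fdr": fdr}, index=pd.Index(ids, name="gene_id")
        )

    truth = pd.DataFrame(
        {f"true_log2_{cell}": true_log2[cell] for cell in config.cells}
        | {"silent": silent},
        index=pd.Index(ids, name="gene_id"),
    )
    return expr, de_tables, truth


def simulate_coverage(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    enriched_mask: np.ndarray,
    cell: str,
    replicate: int = 0,
) -> IntervalSet:
    """Read intervals from a uniform background plus a TSS-box component.

    The TSS component places reads uniformly in ±``tss_window`` around the
    TSS of enriched genes, with its share of reads chosen so the local read
    density at those TSSs is ``tss_enrichment`` times background — a box
    profile whose plateau/flank ratio a metaprofile should recover.
    """
    rng = substream(config.seed, f"coverage_{cell}_{replicate}")
    genome = sum(config.chrom_sizes.values())
    n_enriched = int(enriched_mask.sum())
    R = config.tss_enrichment
    width = 2 * config.tss_window
    if n_enriched == 0 or R <= 1:
        frac_tss = 0.0
    else:
        ratio = (R - 1) * n_enriched * width / genome  # ft/fb
        frac_tss = ratio / (1 + ratio)

    chrom_names = list(config.chrom_sizes)
    lengths = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    enriched_genes = [g for g, m in zip(genes, enriched_mask) if m]
    L = config.read_length
    n_tss = int(round(frac_tss * config.n_reads))

    reads: list[GenomicInterval] = []
    if n_tss:
        gene_idx = rng.integers(0, len(enriched_genes), size=n_tss)
        jitter = rng.integers(-config.tss_window, config.tss_window, size=n_tss)
        for gi, dj in zip(gene_idx, jitter):
            g = enriched_genes[gi]
            s = g.tss + int(dj) - L // 2
            s = max(0, min(config.chrom_sizes[g.chrom] - L, s))
            reads.append(GenomicInterval(g.chrom, s, s + L))
    n_bg = config.n_reads - n_tss
    # background: one uniform draw over the concatenated genome
    pos = rng.integers(0, int(lengths.sum()), size=n_bg)
    bounds = np.cumsum(lengths)
    which = np.searchsorted(bounds, pos, side="right")
    offsets = pos - np.concatenate([[0], bounds[:-1]])[which]
    for w, off in zip(which, offsets):
        c = chrom_names[w]
        s = int(min(off, config.chrom_sizes[c] - L))
        reads.append(GenomicInterval(c, s, s + L))
    return IntervalSet(reads, config.chrom_sizes, f"reads_{cell}_rep{replicate}")


# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator stage and write the pipeline's input files.

    Layout under ``outdir``: chrom.sizes, genes.tsv, peaks/{cell}_b{i}t{j}.bed,
    marks/{cell}_{k4,k27}.bed, expression/{cell}.tsv (gene × replicate TPM),
    de_{daughter}.tsv, reads/{cell}_rep{r}.bed and truth.json / truth TSVs
    with all latent labels.  Returns a manifest of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_note = f"seed={config.seed}"

    chrom_sizes, genes = make_toy_genome(config)
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write(f"# {seed_note}\n")
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")

    truth_g4, g4_labels = simulate_g4_truth(config, genes)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    peak_files: dict[str, dict[str, str]] = {}
    for cell in config.cells:
        reps = simulate_g4_replicates(truth_g4[cell], config, cell)
        peak_files[cell] = {}
        for (b, t), iset in reps.items():
            path = peaks_dir / f"{cell}_b{b + 1}t{t + 1}.bed"
            write_bed(iset, path, header=seed_note)
            peak_files[cell][f"b{b + 1}t{t + 1}"] = str(path)
        write_bed(truth_g4[cell], peaks_dir / f"{cell}_truth.bed", header=seed_note)

    k4_sets, k27_sets, histone_labels = simulate_histone_landscape(
        config, genes, g4_labels
    )
    marks_dir = outdir / "marks"
    marks_dir.mkdir(exist_ok=True)
    for cell in config.cells:
        write_bed(k4_sets[cell], marks_dir / f"{cell}_k4.bed", header=seed_note)
        write_bed(k27_sets[cell], marks_dir / f"{cell}_k27.bed", header=seed_note)

    expr, de_tables, expr_truth = simulate_expression(config, genes, g4_labels)
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    for cell in config.cells:
        with open(expr_dir / f"{cell}.tsv", "w") as fh:
            fh.write(f"# {seed_note}\n")
            expr[cell].to_csv(fh, sep="\t")
    for d in config.daughters:
        with open(outdir / f"de_{d}.tsv", "w") as fh:
            fh.write(f"# {seed_note}\n")
            de_tables[d].to_csv(fh, sep="\t")

    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for cell in config.cells:
        mask = g4_labels[f"g4_{cell}"].to_numpy()
        for r in range(config.n_track_reps):
            iset = simulate_coverage(config, genes, mask, cell, r)
            write_bed(iset, reads_dir / f"{cell}_rep{r + 1}.bed", header=seed_note)

    truth_df = g4_labels.join(histone_labels).join(expr_truth)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(f"# {seed_note}\n")
        truth_df.to_csv(fh, sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config": config.to_dict(),
                "n_genes": len(genes),
            },
            fh,
            indent=2,
            default=str,
        )

    # manifest paths are relative to outdir so identically-configured runs in
    # different directories produce byte-identical manifests
    rel = lambda p: str(Path(p).relative_to(outdir))  # noqa: E731
    return {
        "chrom_sizes": rel(outdir / "chrom.sizes"),
        "genes": rel(outdir / "genes.tsv"),
        "peaks": {
            cell: {r: rel(p) for r, p in reps.items()}
            for cell, reps in peak_files.items()
        },
        "marks": {
            cell: {
                "k4": rel(marks_dir / f"{cell}_k4.bed"),
                "k27": rel(marks_dir / f"{cell}_k27.bed"),
            }
            for cell in config.cells
        },
        "expression": {cell: rel(expr_dir / f"{cell}.tsv") for cell in config.cells},
        "de": {d: rel(outdir / f"de_{d}.tsv") for d in config.daughters},
        "reads": {
            cell: [
                rel(reads_dir / f"{cell}_rep{r + 1}.bed")
                for r in range(config.n_track_reps)
            ]
            for cell in config.cells
        },
        "truth": rel(outdir / "truth.tsv"),
    }
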