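"""Promoter classification by histone state and G4 status.

A promoter window is placed in exactly one of five histone classes per cell
type, with bivalency requiring that a segment where H3K4me3 and H3K27me3
physically colocalise (the base-pair intersection of the two mark sets)
overlaps the window itself — not merely that both marks touch the window
somewhere:

* ``bivalent`` — an H3K4me3∩H3K27me3 segment overlaps the promoter;
* ``other``   — both marks overlap the promoter but never colocalise in it;
* ``H3K4me3`` / ``H3K27me3`` — only that mark overlaps;
* ``unmarked`` — neither mark overlaps.

G4 status per cell is overlap with that cell's consensus peak set, and the
embryonic→daughter pair of G4 states defines four transition classes:
maintained (G4E+GD+), lost (G4E+GD-), gained (G4E-GD+), never (G4E-GD-).
All annotations are joined into one integration matrix (one row per gene)
carrying per-cell histone class, G4 status, median TPM, median promoter G4
RPM, and raw overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    intersect,
    merge,
    promoter_windows,
)
from .tracks import SignalTrack, region_signal

__all__ = [
    "HISTONE_CLASSES",
    "TRANSITION_CLASSES",
    "classify_histone_state",
    "classify_g4_transition",
    "build_integration_matrix",
    "transition_distribution",
    "two_proportion_test",
    "ks_one_sided",
]

logger = logging.getLogger(__name__)

HISTONE_CLASSES = ("H3K4me3", "H3K27me3", "bivalent", "other", "unmarked")
TRANSITION_CLASSES = ("G4E+GD+", "G4E+GD-", "G4E-GD+", "G4E-GD-")


class _OverlapIndex:
    """Sorted merged intervals of one set, queried per chromosome."""

    def __init__(self, iset: IntervalSet):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in merge(iset).by_chrom().items():
            self._by_chrom[chrom] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
            )

    def count(self, region: GenomicInterval) -> int:
        """Number of merged intervals overlapping the region by >= 1 bp."""
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        return int(max(0, hi - lo))

    def overlaps(self, region: GenomicInterval) -> bool:
        return self.count(region) > 0


def classify_histone_state(
    promoter: GenomicInterval,
    k4: IntervalSet | _OverlapIndex,
    k27: IntervalSet | _OverlapIndex,
    colocalised: IntervalSet | _OverlapIndex | None = None,
) -> str:
    """Five-way histone classification of one promoter window.

    ``colocalised`` (the k4∩k27 intersection) may be passed pre-computed when
    classifying many promoters against the same mark sets.
    """
    if isinstance(k4, IntervalSet):
        if colocalised is None:
            colocalised = _OverlapIndex(intersect(k4, k27))
        k4 = _OverlapIndex(k4)
    if isinstance(k27, IntervalSet):
        k27 = _OverlapIndex(k27)
    if colocalised is None:
        raise ValueError("colocalised index required when passing prebuilt indexes")
    if isinstance(colocalised, IntervalSet):
        colocalised = _OverlapIndex(colocalised)

    has_k4 = k4.overlaps(promoter)
    has_k27 = k27.overlaps(promoter)
    if colocalised.overlaps(promoter):
        return "bivalent"
    if has_k4 and has_k27:
        return "other"
    if has_k4:
        return "H3K4me3"
    if has_k27:
        return "H3K27me3"
    return "unmarked"


def classify_g4_transition(g4_e: bool, g4_d: bool) -> str:
    """Four-state transition code from (embryonic, daughter) G4 presence."""
    return f"G4E{'+' if g4_e else '-'}GD{'+' if g4_d else '-'}"


def build_integration_matrix(
    genes: Sequence[GeneModel],
    assembly: Mapping[str, int],
    g4_consensus: Mapping[str, IntervalSet],
    k4_marks: Mapping[str, IntervalSet],
    k27_marks: Mapping[str, IntervalSet],
    expression: Mapping[str, pd.DataFrame] | None = None,
    g4_tracks: Mapping[str, SignalTrack] | None = None,
    embryonic: str = "hESC",
    flank: int = 1000,
) -> pd.DataFrame:
    """Assemble the per-gene annotation matrix across cell types.

    ``expression[cell]`` is a gene × replicate TPM table (gene_id index);
    the matrix stores the median across replicates.  Genes present in an
    expression table but absent from the gene models are excluded and logged.
    Columns per cell: ``histone_{cell}``, ``g4_{cell}``, ``tpm_{cell}``,
    ``g4_rpm_{cell}``, ``n_g4_{cell}``, ``n_k4_{cell}``, ``n_k27_{cell}``;
    plus ``transition_{daughter}`` for every non-embryonic cell.
    """
    cells = list(g4_consensus)
    if embryonic not in cells:
        raise ValueError(f"embryonic cell {embryonic!r} missing from G4 consensus maps")
    _, windows = promoter_windows(genes, assembly, flank)
    known = set(windows)
    if expression:
        for cell, table in expression.items():
            orphans = set(table.index) - known
            if orphans:
                logger.info(
                    "%d expression genes absent from gene models for %s; excluded",
                    len(orphans),
                    cell,
                )

    g4_idx = {c: _OverlapIndex(s) for c, s in g4_consensus.items()}
    k4_idx = {c: _OverlapIndex(s) for c, s in k4_marks.items()}
    k27_idx = {c: _OverlapIndex(s) for c, s in k27_marks.items()}
    biv_idx = {
        c: _OverlapIndex(intersect(k4_marks[c], k27_marks[c])) for c in k4_marks
    }

    rows = []
    for g in genes:
        win = windows[g.gene_id]
        row: dict = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "promoter_start": win.start,
            "promoter_end": win.end,
        }
        for cell in cells:
            row[f"g4_{cell}"] = g4_idx[cell].overlaps(win)
            row[f"n_g4_{cell}"] = g4_idx[cell].count(win)
            if cell in k4_idx:
                row[f"histone_{cell}"] = classify_histone_state(
                    win, k4_idx[cell], k27_idx[cell], biv_idx[cell]
                )
                row[f"n_k4_{cell}"] = k4_idx[cell].count(win)
                row[f"n_k27_{cell}"] = k27_idx[cell].count(win)
            if expression and cell in expression:
                tbl = expression[cell]
                row[f"tpm_{cell}"] = (
                    float(np.median(tbl.loc[g.gene_id]))
                    if g.gene_id in tbl.index
                    else np.nan
                )
            if g4_tracks and cell in g4_tracks:
                row[f"g4_rpm_{cell}"] = region_signal(g4_tracks[cell], win, "median")
        for cell in cells:
            if cell != embryonic:
                row[f"transition_{cell}"] = classify_g4_transition(
                    row[f"g4_{embryonic}"], row[f"g4_{cell}"]
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def transition_distribution(
    matrix: pd.DataFrame,
    start_class: str,
    daughter: str,
    embryonic: str = "hESC",
) -> pd.DataFrame:
    """Histone-class transitions of one embryonic stratum, split by G4 group.

    Restricts to promoters whose embryonic histone class equals
    ``start_class``, cross-tabulates G4 transition group × daughter histone
    class, and reports counts with row proportions.  Empty strata keep their
    row with count 0 and NaN proportions (flagged rather than dropped).
    """
    if start_class not in HISTONE_CLASSES:
        raise ValueError(f"unknown histone class {start_class!r}")
    sub = matrix[matrix[f"histone_{embryonic}"] == start_class]
    records = []
    for group in TRANSITION_CLASSES:
        grp = sub[sub[f"transition_{daughter}"] == group]
        n = len(grp)
        counts = grp[f"histone_{daughter}"].value_counts()
        for target in HISTONE_CLASSES:
            c = int(counts.get(target, 0))
            records.append(
                {
                    "start_class": start_class,
                    "g4_group": group,
                    "daughter_class": target,
                    "count": c,
                    "proportion": c / n if n > 0 else np.nan,
                    "group_n": n,
                }
            )
    return pd.DataFrame(records)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pearson chi-square test for two proportions, no continuity correction.

    One-sided p is p/2 when the observed direction matches the alternative
    ("greater": p1 > p2), else 1 − p/2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        # a margin is empty: proportions identical by construction
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    if alternative == "two-sided":
        return float(chi2), float(p)
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    p1, p2 = x1 / n1, x2 / n2
    matches = p1 > p2 if alternative == "greater" else p1 < p2
    one_sided = p / 2 if matches else 1 - p / 2
    return float(chi2), float(one_sided)


def ks_one_sided(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "a_greater",
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov–Smirnov test.

    Under ``alternative="a_greater"`` (a stochastically greater than b) the
    statistic is D+ = sup_x (F_b(x) − F_a(x)); ``"a_less"`` uses
    sup_x (F_a(x) − F_b(x)).  The p-value is the asymptotic one-sided tail
    exp(−2 m n D² / (m + n)), capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    if alternative == "a_greater":
        d = float(np.max(fb - fa))
    elif alternative == "a_less":
        d = float(np.max(fa - fb))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    d = max(d, 0.0)
    m, n = a.size, b.size
    p = min(1.0, float(np.exp(-2 * m * n * d * d / (m + n))))
    return d, p
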