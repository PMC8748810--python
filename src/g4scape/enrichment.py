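"""Permutation fold-enrichment of a query interval set within an annotation.

The null model repositions each query interval independently: a workspace
segment is drawn with probability proportional to the number of valid start
positions it offers (segment length − interval length + 1), then a uniform
start within it.  Interval lengths are preserved exactly and permuted
intervals never leave the workspace; permuted intervals are allowed to overlap
one another.  The overlap statistic is nucleotide (base-pair) overlap with the
annotation, and fold enrichment is observed / mean-permuted overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import IntervalSet, merge
from .rng import substream

__all__ = ["EnrichmentResult", "permutation_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    observed_bp: int
    expected_bp: float
    fold: float  # math.inf flags expected_bp == 0
    empirical_p: float
    n_perm: int
    seed: int
    alternative: str = "greater"

    def as_row(self) -> dict:
        return {
            "observed_bp": self.observed_bp,
            "expected_bp": self.expected_bp,
            "fold": self.fold,
            "empirical_p": self.empirical_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _to_global(iset: IntervalSet, offsets: dict[str, int]) -> np.ndarray:
    ivs = merge(iset).intervals
    arr = np.empty((len(ivs), 2), dtype=np.int64)
    for i, iv in enumerate(ivs):
        off = offsets[iv.chrom]
        arr[i, 0] = off + iv.start
        arr[i, 1] = off + iv.end
    return arr


def _clip_to(arr: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Clip intervals (global coords) to a set of disjoint sorted segments."""
    out = []
    for s, e in arr:
        # segments overlapping [s, e)
        i = np.searchsorted(segs[:, 1], s, side="right")
        while i < len(segs) and segs[i, 0] < e:
            out.append((max(s, segs[i, 0]), min(e, segs[i, 1])))
            i += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def _overlap_bp(starts: np.ndarray, ends: np.ndarray, ann: np.ndarray) -> np.ndarray:
    """Total annotation overlap of each [start, end) pair, vectorised.

    ann is an (m, 2) array of disjoint sorted intervals in global coordinates.
    Uses the prefix-sum of covered bases: overlap(s, e) = C(e) − C(s) where C
    is covered-bp up to a position.
    """
    if len(ann) == 0:
        return np.zeros_like(starts)
    bnd = ann.ravel()  # [s0, e0, s1, e1, ...] sorted ascending
    lens = ann[:, 1] - ann[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])  # covered bp before ann[i]

    def covered_until(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(bnd, x, side="left")
        seg = idx // 2
        inside = idx % 2 == 1  # position falls within ann[seg]
        out = cum[np.minimum(seg, len(ann))]
        out = out + np.where(inside, x - ann[np.minimum(seg, len(ann) - 1), 0], 0)
        return out

    return covered_until(ends) - covered_until(starts)


def permutation_enrichment(
    query: IntervalSet,
    annotation: IntervalSet,
    workspace: IntervalSet,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fold enrichment of query in annotation over randomised placements.

    Query and annotation are clipped to the workspace (a warning is issued if
    the query loses coverage).  The empirical p-value carries the +1
    correction: p = (1 + #{permutations with overlap >= observed}) / (n_perm
    + 1) for ``alternative="greater"``; ``"two-sided"`` doubles the smaller
    tail (capped at 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    ws = merge(workspace)
    chroms = sorted(ws.assembly)
    offsets: dict[str, int] = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += ws.assembly[c]

    segs = _to_global(ws, offsets)
    if len(segs) == 0:
        raise ValueError("workspace is empty")
    q_raw = _to_global(query, offsets)
    q = _clip_to(q_raw, segs)
    lost = int((q_raw[:, 1] - q_raw[:, 0]).sum() - (q[:, 1] - q[:, 0]).sum()) if len(q_raw) else 0
    if lost > 0:
        warnings.warn(f"query extends {lost} bp outside workspace; clipped")
    ann = _clip_to(_to_global(annotation, offsets), segs)

    if len(q) == 0:
        raise ValueError("query is empty after clipping to workspace")
    seg_len = segs[:, 1] - segs[:, 0]
    raw_len = q_raw[:, 1] - q_raw[:, 0]
    if raw_len.max() > seg_len.max():
        raise ValueError(
            f"longest query interval ({raw_len.max()} bp) exceeds longest "
            f"workspace segment ({seg_len.max()} bp); "
            "length-preserving randomisation is impossible"
        )
    q_len = q[:, 1] - q[:, 0]

    observed = int(_overlap_bp(q[:, 0], q[:, 1], ann).sum())

    rng = substream(seed, "enrichment")
    perm_overlap = np.zeros(n_perm, dtype=np.int64)
    for i, L in enumerate(q_len):
        slots = seg_len - L + 1  # valid start positions per segment
        ok = slots > 0
        weights = np.where(ok, slots, 0).astype(float)
        weights /= weights.sum()
        seg_idx = rng.choice(len(segs), size=n_perm, p=weights)
        u = rng.random(n_perm)
        starts = segs[seg_idx, 0] + np.floor(u * slots[seg_idx]).astype(np.int64)
        perm_overlap += _overlap_bp(starts, starts + L, ann)

    expected = float(perm_overlap.mean())
    fold = observed / expected if expected > 0 else math.inf
    ge = int((perm_overlap >= observed).sum())
    le = int((perm_overlap <= observed).sum())
    p_greater = (1 + ge) / (n_perm + 1)
    p_less = (1 + le) / (n_perm + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return EnrichmentResult(observed, expected, fold, p, n_perm, seed, alternative)
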