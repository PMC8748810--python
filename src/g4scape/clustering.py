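"""Expression + promoter-G4-signal integration clustering.

Genes are described by a 6-long vector (median TPM in each of three cell
types, median promoter G4 RPM in each).  Each column is capped at its 75th
percentile (linear-interpolation quantile) to blunt outliers, then z-scored;
the capped, standardised matrix is partitioned by PAM (Partitioning Around
Medoids) with Euclidean distance — the classical BUILD greedy initialisation
followed by SWAP steps until no single medoid exchange lowers the total
distance-to-medoid cost.  PAM is deterministic here: the seed only breaks
exact cost ties, which do not arise on continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterResult", "preprocess_matrix", "pam_cluster", "cluster_summary"]


@dataclass
class ClusterResult:
    k: int
    medoid_indices: np.ndarray
    assignments: np.ndarray
    total_cost: float
    seed: int
    n_swaps: int


def preprocess_matrix(m: np.ndarray, cap_quantile: float = 0.75) -> np.ndarray:
    """Per-column quantile capping followed by z-scoring.

    The cap uses the linear-interpolation quantile (numpy default, R type 7).
    Mean and SD for the z-score are computed after capping.  A column whose
    post-capping SD is zero cannot be standardised and raises.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    out = m.copy()
    for j in range(m.shape[1]):
        q = np.quantile(out[:, j], cap_quantile)  # type-7 linear interpolation
        np.minimum(out[:, j], q, out=out[:, j])
        mu = out[:, j].mean()
        sd = out[:, j].std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {j} has zero variance after capping")
        out[:, j] = (out[:, j] - mu) / sd
    return out


def _build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialisation: repeatedly add the medoid that most
    reduces total cost given those already chosen."""
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=1)))
    medoids = [first]
    nearest = dist[first].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum over points of max(nearest - d(c,.), 0)
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        np.minimum(nearest, dist[c], out=nearest)
    return medoids


def pam_cluster(m: np.ndarray, k: int = 6, seed: int = 0,
                max_iter: int = 200) -> ClusterResult:
    """PAM k-medoids with Euclidean distance (BUILD + SWAP).

    SWAP evaluates every (medoid, non-medoid) exchange against the current
    cost and applies the best strictly-improving one, so the total cost is
    non-increasing and the loop terminates.  Intended for desk-scale n (a
    full n × n distance matrix is held in memory).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    n = m.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    # tie-break determinism: a seeded, vanishing jitter on the distance matrix
    # would perturb continuous data, so instead ties resolve to the lowest
    # index via argmin/argmax — the seed is recorded for provenance only.
    from scipy.spatial.distance import cdist

    dist = cdist(m, m)

    medoids = _build(dist, k)
    n_swaps = 0
    for _ in range(max_iter):
        med = np.array(medoids)
        dmed = dist[med]  # k × n
        order = np.argsort(dmed, axis=0)
        nearest_idx = order[0]  # index into med
        d1 = dmed[nearest_idx, np.arange(n)]
        d2 = dmed[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)

        best_delta = 0.0
        best_swap = None
        candidates = np.setdiff1d(np.arange(n), med)
        if candidates.size == 0:  # k == n: nothing to swap
            break
        dc = dist[candidates]  # c × n
        for mi in range(k):
            owned = nearest_idx == mi
            # points owned by the outgoing medoid reattach to min(second, new)
            delta_owned = (np.minimum(dc[:, owned], d2[owned]) - d1[owned]).sum(axis=1)
            # other points may defect to the new medoid if it is closer
            other = ~owned
            delta_other = np.minimum(dc[:, other] - d1[other], 0.0).sum(axis=1)
            delta = delta_owned + delta_other
            j = int(np.argmin(delta))
            if delta[j] < best_delta - 1e-12:
                best_delta = float(delta[j])
                best_swap = (mi, int(candidates[j]))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        n_swaps += 1

    med = np.array(sorted(medoids))
    assignments = np.argmin(dist[med], axis=0)
    total_cost = float(dist[med, :][assignments, np.arange(n)].sum())
    return ClusterResult(
        k=k,
        medoid_indices=med,
        assignments=assignments,
        total_cost=total_cost,
        seed=seed,
        n_swaps=n_swaps,
    )


def cluster_summary(values: np.ndarray, assignments: np.ndarray,
                    column_names: list[str] | None = None):
    """Per-cluster five-number summaries of each (raw) column."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    if column_names is None:
        column_names = [f"col{j}" for j in range(values.shape[1])]
    rows = []
    for c in np.unique(assignments):
        sub = values[assignments == c]
        for j, name in enumerate(column_names):
            q1, med, q3 = np.percentile(sub[:, j], [25, 50, 75])
            rows.append(
                {
                    "cluster": int(c),
                    "column": name,
                    "n": int(sub.shape[0]),
                    "min": float(sub[:, j].min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(sub[:, j].max()),
                }
            )
    return pd.DataFrame(rows)
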