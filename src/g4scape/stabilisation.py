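"""Transcriptional stabilisation of genes across a differentiation step.

For each promoter group (the four G4 transition classes, or analogous
maintenance groupings of accessibility / H3K4me3) the daughter-cell
log2-expression is regressed on the embryonic log2-expression by weighted
least squares, with raw embryonic TPM as the weight so that the fitted line
is anchored by genes already expressed in the reference state.  The spread
of the residuals quantifies how tightly daughter expression tracks the
embryonic programme; groups are compared by a one-tailed F-test on residual
variances, and the weighted R² ranking across features identifies which
chromatin feature's maintenance stabilises expression most.

Expression values enter the fit as log2(TPM + 0.1); genes with TPM = 0 in
both cells are excluded beforehand.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .landscape import TRANSITION_CLASSES, two_proportion_test

__all__ = [
    "LOG_PSEUDOCOUNT",
    "RegressionFit",
    "VarianceComparison",
    "expression_filter",
    "weighted_linear_fit",
    "residual_spread",
    "f_test_variances",
    "de_category",
    "stability_report",
]

logger = logging.getLogger(__name__)

LOG_PSEUDOCOUNT = 0.1

DE_CATEGORIES = ("up_hESC", "up_daughter", "not_DE", "unclassified")


@dataclass
class RegressionFit:
    group: str
    slope: float
    intercept: float
    weights: np.ndarray
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    r2_weighted: float
    r2_unweighted: float
    n: int

    def check_normal_equations(self, tol: float = 1e-8) -> bool:
        """Weighted orthogonality of residuals: Σw·r = 0 and Σw·x·r = 0."""
        scale = max(1.0, float(np.abs(self.weights).sum()))
        return (
            abs(float(self.weights @ self.residuals)) / scale < tol
            and abs(float((self.weights * self.x) @ self.residuals)) / scale < tol
        )


@dataclass(frozen=True)
class VarianceComparison:
    group_a: str
    group_b: str
    F: float
    df_a: int
    df_b: int
    p_one_tailed: float


def expression_filter(tpm_e: np.ndarray, tpm_d: np.ndarray) -> np.ndarray:
    """Keep genes expressed (TPM > 0) in at least one of the two cells."""
    tpm_e = np.asarray(tpm_e, dtype=float)
    tpm_d = np.asarray(tpm_d, dtype=float)
    if tpm_e.shape != tpm_d.shape:
        raise ValueError("expression vectors differ in length")
    return (tpm_e > 0) | (tpm_d > 0)


def weighted_linear_fit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, group: str = ""
) -> RegressionFit:
    """WLS fit y = a + b·x minimising Σ wᵢ(yᵢ − a − b·xᵢ)².

    Weighted R² uses the weighted mean of y: 1 − Σw·r² / Σw·(y − ȳ_w)².
    Zero-weight points contribute residuals but do not influence the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    active = w > 0
    if active.sum() < 2 or np.unique(x[active]).size < 2:
        raise ValueError("singular fit: fewer than 2 distinct x among weighted points")
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    resid = y - (intercept + slope * x)
    wsum = w.sum()
    ybar_w = float((w @ y) / wsum)
    ss_res = float(w @ resid**2)
    ss_tot = float(w @ (y - ybar_w) ** 2)
    r2_w = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ss_res_u = float(resid @ resid)
    ss_tot_u = float(((y - y.mean()) ** 2).sum())
    r2_u = 1.0 - ss_res_u / ss_tot_u if ss_tot_u > 0 else 1.0
    return RegressionFit(
        group=group,
        slope=slope,
        intercept=intercept,
        weights=w,
        x=x,
        y=y,
        residuals=resid,
        r2_weighted=r2_w,
        r2_unweighted=r2_u,
        n=int(x.size),
    )


def residual_spread(fit: RegressionFit, weighted: bool = False) -> float:
    """Sample variance of the residuals (unweighted by default)."""
    r = fit.residuals
    if r.size < 2:
        raise ValueError("need at least 2 residuals")
    if weighted:
        w = fit.weights
        mu = float((w @ r) / w.sum())
        return float((w @ (r - mu) ** 2) / w.sum())
    return float(np.var(r, ddof=1))


def f_test_variances(res_a: np.ndarray, res_b: np.ndarray, group_a: str = "a",
                     group_b: str = "b") -> VarianceComparison:
    """One-tailed F-test of "group b more variable than group a".

    F = var(res_b) / var(res_a); p = P(F_{df_b, df_a} >= F).
    """
    res_a = np.asarray(res_a, dtype=float)
    res_b = np.asarray(res_b, dtype=float)
    if res_a.size < 2 or res_b.size < 2:
        raise ValueError("need at least 2 residuals per group")
    va = float(np.var(res_a, ddof=1))
    vb = float(np.var(res_b, ddof=1))
    if va == 0:
        raise ValueError("zero variance in denominator group")
    df_a, df_b = res_a.size - 1, res_b.size - 1
    F = vb / va
    p = float(stats.f.sf(F, df_b, df_a))
    return VarianceComparison(group_a, group_b, F, df_a, df_b, p)


def de_category(log2fc: float, fdr: float) -> str:
    """Differential-expression call from a (log2FC, FDR) pair.

    Significant genes with |log2FC| <= 1 fall outside all three published
    categories and are returned as ``unclassified``.
    """
    if not (0 <= fdr <= 1):
        raise ValueError(f"FDR must be in [0,1], got {fdr}")
    if fdr < 0.05 and log2fc > 1:
        return "up_daughter"
    if fdr < 0.05 and log2fc < -1:
        return "up_hESC"
    if fdr > 0.05 and -1 < log2fc < 1:
        return "not_DE"
    return "unclassified"


@dataclass
class StabilityReport:
    daughter: str
    reference_group: str
    fits: dict[str, RegressionFit]
    group_stats: pd.DataFrame
    comparisons: list[VarianceComparison]
    de_proportions: pd.DataFrame | None = None
    proportion_tests: pd.DataFrame | None = None
    skipped_groups: list[str] = field(default_factory=list)

    def r2_ranking(self) -> list[str]:
        return sorted(self.fits, key=lambda g: self.fits[g].r2_weighted, reverse=True)


def stability_report(
    matrix: pd.DataFrame,
    daughter: str,
    embryonic: str = "hESC",
    de_table: pd.DataFrame | None = None,
    group_column: str | None = None,
    reference_group: str = "G4E+GD+",
    weighted_spread: bool = False,
    log_weights: bool = False,
) -> StabilityReport:
    """Per-group stabilisation fits, variance comparisons, DE proportions.

    ``matrix`` is the integration matrix (needs ``tpm_{embryonic}``,
    ``tpm_{daughter}`` and a grouping column, by default
    ``transition_{daughter}``).  ``de_table`` is indexed by gene_id with
    columns ``log2fc`` and ``fdr``.  Groups with fewer than 3 usable genes
    are skipped with a warning.  F-tests are oriented "comparison group more
    variable than the reference group".
    """
    col = group_column or f"transition_{daughter}"
    te = matrix[f"tpm_{embryonic}"].to_numpy(dtype=float)
    td = matrix[f"tpm_{daughter}"].to_numpy(dtype=float)
    keep = expression_filter(np.nan_to_num(te), np.nan_to_num(td))
    keep &= ~(np.isnan(te) | np.isnan(td))
    sub = matrix.loc[keep]

    groups = [g for g in TRANSITION_CLASSES if g in set(sub[col])]
    if not groups:  # non-transition grouping column
        groups = sorted(set(sub[col].dropna()))

    fits: dict[str, RegressionFit] = {}
    skipped: list[str] = []
    stats_rows = []
    for g in groups:
        rows = sub[sub[col] == g]
        if len(rows) < 3:
            logger.warning("group %s has %d genes (<3); skipped", g, len(rows))
            skipped.append(g)
            continue
        tpm_e = rows[f"tpm_{embryonic}"].to_numpy(dtype=float)
        tpm_d = rows[f"tpm_{daughter}"].to_numpy(dtype=float)
        x = np.log2(tpm_e + LOG_PSEUDOCOUNT)
        y = np.log2(tpm_d + LOG_PSEUDOCOUNT)
        w = np.log2(tpm_e + LOG_PSEUDOCOUNT) - np.log2(LOG_PSEUDOCOUNT) if log_weights else tpm_e
        try:
            fit = weighted_linear_fit(x, y, w, group=g)
        except ValueError as exc:
            logger.warning("group %s: %s; skipped", g, exc)
            skipped.append(g)
            continue
        fits[g] = fit
        stats_rows.append(
            {
                "group": g,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "residual_variance": residual_spread(fit, weighted=weighted_spread),
                "r2_weighted": fit.r2_weighted,
                "r2_unweighted": fit.r2_unweighted,
            }
        )
    group_stats = pd.DataFrame(stats_rows).set_index("group") if stats_rows else pd.DataFrame()

    comparisons: list[VarianceComparison] = []
    if reference_group in fits and len(fits) > 1:
        ref = fits[reference_group]
        for g, fit in fits.items():
            if g == reference_group:
                continue
            comparisons.append(
                f_test_variances(ref.residuals, fit.residuals, reference_group, g)
            )
    elif len(fits) > 1:
        for ga, gb in itertools.combinations(fits, 2):
            comparisons.append(
                f_test_variances(fits[ga].residuals, fits[gb].residuals, ga, gb)
            )

    de_props = None
    prop_tests = None
    if de_table is not None:
        joined = sub.join(de_table[["log2fc", "fdr"]], how="inner")
        cats = [de_category(r.log2fc, r.fdr) for r in joined.itertuples()]
        joined = joined.assign(de_category=cats)
        n_uncl = sum(c == "unclassified" for c in cats)
        if n_uncl:
            logger.info("%d significant-but-small-FC genes left unclassified", n_uncl)
        rows = []
        for g in fits:
            grp = joined[joined[col] == g]
            n = len(grp)
            counts = grp["de_category"].value_counts()
            row = {"group": g, "n": n}
            for cat in DE_CATEGORIES:
                c = int(counts.get(cat, 0))
                row[f"count_{cat}"] = c
                row[f"prop_{cat}"] = c / n if n else np.nan
            rows.append(row)
        de_props = pd.DataFrame(rows).set_index("group")
        if reference_group in de_props.index:
            test_rows = []
            n1 = int(de_props.loc[reference_group, "n"])
            x1 = int(de_props.loc[reference_group, "count_not_DE"])
            for g in de_props.index:
                if g == reference_group:
                    continue
                n2 = int(de_props.loc[g, "n"])
                x2 = int(de_props.loc[g, "count_not_DE"])
                if n1 == 0 or n2 == 0:
                    continue
                chi2, p = two_proportion_test(x1, n1, x2, n2, alternative="greater")
                test_rows.append(
                    {
                        "reference": reference_group,
                        "group": g,
                        "category": "not_DE",
                        "chi2": chi2,
                        "p_one_sided": p,
                        "prop_reference": x1 / n1,
                        "prop_group": x2 / n2,
                    }
                )
            prop_tests = pd.DataFrame(test_rows)

    return StabilityReport(
        daughter=daughter,
        reference_group=reference_group,
        fits=fits,
        group_stats=group_stats,
        comparisons=comparisons,
        de_proportions=de_props,
        proportion_tests=prop_tests,
        skipped_groups=skipped,
    )
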