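"""Group statistics: demographics and edge-wise two-sample FC comparison.

Demographics follow the modelled study's tests — Pearson chi-square (no
continuity correction) for sex x group and the Mann-Whitney U test (normal
approximation with tie correction) for age.  Edge-wise group differences in
Fisher-z FC use two-sample t-tests (Welch by default) with Benjamini-
Hochberg FDR across the tested edge family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import LoopManifest


@dataclass
class DemographicStats:
    chi2: float
    chi2_p: float
    mw_u: float
    mw_z: float
    mw_p: float


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(xs, ys) -> tuple[float, float, float]:
    """Mann-Whitney U with standardized z (tie-corrected normal approximation).

    Returns (U for xs, z, two-sided p); matches the usual statistical-package
    asymptotic output.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = xs.size, ys.size
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    combined = np.concatenate([xs, ys])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    return u, float(z), float(min(p, 1.0))


def bh_fdr(pvec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def demographic_stats(subjects_df: pd.DataFrame) -> DemographicStats:
    """Table-1 style demographics from a phenotype frame (columns group/sex/age)."""
    table = pd.crosstab(subjects_df["group"], subjects_df["sex"]).to_numpy()
    chi2, chi2_p = chi2_2x2(table)
    pat = subjects_df.loc[subjects_df["group"] == "patient", "age"].astype(float)
    ctl = subjects_df.loc[subjects_df["group"] == "control", "age"].astype(float)
    u, z, p = mann_whitney(pat, ctl)
    return DemographicStats(chi2, chi2_p, u, z, p)


def compare_groups(fc: pd.DataFrame, labels, hemisphere_filter: str | None = None,
                   variant: str = "welch", alpha: float = 0.05) -> pd.DataFrame:
    """Edge-wise two-sample t-test of z-FC (patients vs controls) with BH-FDR.

    ``fc`` is subjects x edges (columns ``loop:hemisphere:a-b``); ``labels``
    is per-subject group membership aligned to the rows.  The FDR family is
    every tested edge after the optional hemisphere filter.  Direction is
    ``patients<controls`` for negative t.
    """
    labels = np.asarray(labels)
    pat = fc.loc[labels == "patient"]
    ctl = fc.loc[labels == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("need at least two subjects per group")
    cols = list(fc.columns)
    if hemisphere_filter is not None:
        cols = [c for c in cols if c.split(":")[1] == hemisphere_filter]
        if not cols:
            raise ValueError(f"no edges in hemisphere {hemisphere_filter!r}")
    equal_var = {"student": True, "welch": False}[variant]
    res = stats.ttest_ind(pat[cols].to_numpy(), ctl[cols].to_numpy(),
                          axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    p = np.where(bad, 1.0, p)
    p_fdr = bh_fdr(p)
    parts = [c.split(":") for c in cols]
    out = pd.DataFrame({
        "edge": cols,
        "loop": [x[0] for x in parts],
        "hemisphere": [x[1] for x in parts],
        "t": t,
        "p": p,
        "p_fdr": p_fdr,
        "direction": np.where(t < 0, "patients<controls", "patients>controls"),
        "significant": p_fdr < alpha,
        "degenerate": bad,
    })
    return out


def save_edge_stats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
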