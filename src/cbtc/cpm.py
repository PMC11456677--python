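"""Connectome-based predictive modeling (CPM) of upper-limb motor scores.

Within each leave-one-out fold, edges whose FC correlates with the behavior
score across training subjects (p below a selection threshold) are split
into a positive and a negative network; each network's strength (sum of the
member edges' z values) feeds a least-squares linear model that predicts the
held-out subject's score.  Predictive performance is the Spearman
correlation between predicted and observed scores, with significance from a
behavior-shuffling permutation test.  Edges selected in (nearly) every fold
are reported as the well-represented contributing connections.

CPM runs on patients only: behavior scores exist only for that group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("positive", "negative", "combined")


@dataclass
class CPMResult:
    mode: str
    predicted: np.ndarray
    observed: np.ndarray
    spearman_r: float
    permutation_p: float | None
    n_permutations: int
    fold_positive: list[tuple[str, ...]]
    fold_negative: list[tuple[str, ...]]
    empty_folds: int
    p_sel: float
    corr_type: str
    well_represented: dict[str, str] = field(default_factory=dict)  # edge -> sign


def _corr_with_p(x: np.ndarray, y: np.ndarray, corr_type: str) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise correlation of x (n x m) with y (n,) plus two-sided t-approx p."""
    if corr_type == "spearman":
        x = stats.rankdata(x, axis=0)
        y = stats.rankdata(y)
    elif corr_type != "pearson":
        raise ValueError(f"unknown correlation type {corr_type!r}")
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def select_edges(train_fc: pd.DataFrame, train_behavior, p_sel: float = 0.05,
                 corr_type: str = "pearson") -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Edges positively / negatively correlated with behavior at p < p_sel (disjoint)."""
    y = np.asarray(train_behavior, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least four training subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior is constant in the training set")
    r, p = _corr_with_p(train_fc.to_numpy(dtype=float), y, corr_type)
    cols = np.asarray(train_fc.columns)
    sel = p < p_sel
    pos = tuple(cols[sel & (r > 0)])
    neg = tuple(cols[sel & (r < 0)])
    return pos, neg


def network_strength(fc_vector: pd.Series, edge_set) -> float:
    """Sum of z values over an edge set; 0 for the empty set."""
    return float(sum(fc_vector[e] for e in edge_set))


def _strengths(fc: pd.DataFrame, pos, neg, mode: str, combined: str) -> np.ndarray:
    sp = fc[list(pos)].sum(axis=1).to_numpy() if pos else np.zeros(len(fc))
    sn = fc[list(neg)].sum(axis=1).to_numpy() if neg else np.zeros(len(fc))
    if mode == "positive":
        return sp[:, None]
    if mode == "negative":
        return sn[:, None]
    if combined == "sum-diff":
        return (sp - sn)[:, None]
    return np.column_stack([sp, sn])


def loocv_cpm(fc: pd.DataFrame, behavior, mode: str = "positive",
              p_sel: float = 0.05, corr_type: str = "pearson",
              combined: str = "two-predictor") -> CPMResult:
    """Leave-one-out CPM predictions for one network mode.

    A fold that selects no edges for its mode predicts the training-mean
    behavior and is counted in ``empty_folds``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    y = np.asarray(behavior, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least five subjects for LOOCV CPM")
    x = fc.to_numpy(dtype=float)
    cols = np.asarray(fc.columns)
    predicted, fold_pos_idx, fold_neg_idx, empty = _loocv_core(
        x, y, mode, p_sel, corr_type, combined)
    fold_pos = [tuple(cols[i]) for i in fold_pos_idx]
    fold_neg = [tuple(cols[i]) for i in fold_neg_idx]
    r = evaluate_spearman(predicted, y)
    return CPMResult(mode, predicted, y, r, None, 0, fold_pos, fold_neg,
                     empty, p_sel, corr_type)


def _loocv_core(x: np.ndarray, y: np.ndarray, mode: str, p_sel: float,
                corr_type: str, combined: str):
    """Numpy LOOCV loop shared by :func:`loocv_cpm` and the permutation test."""
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("behavior is constant")
    idx = np.arange(n)
    # critical |r| at p_sel for the t approximation with df = n - 2
    df = n - 1 - 2
    t_crit = stats.t.isf(p_sel / 2, df=df)
    r_crit = t_crit / np.sqrt(df + t_crit ** 2)
    predicted = np.empty(n)
    fold_pos, fold_neg = [], []
    empty = 0
    for i in range(n):
        tr = np.concatenate([idx[:i], idx[i + 1:]])
        xt, yt = x[tr], y[tr]
        if np.ptp(yt) == 0:
            raise ValueError("behavior is constant in a training fold")
        if corr_type == "spearman":
            xr = stats.rankdata(xt, axis=0)
            yr = stats.rankdata(yt)
        else:
            xr, yr = xt, yt
        xc = xr - xr.mean(axis=0)
        yc = yr - yr.mean()
        denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, xc.T @ yc / denom, 0.0)
        pos = np.flatnonzero(r > r_crit)
        neg = np.flatnonzero(r < -r_crit)
        fold_pos.append(pos)
        fold_neg.append(neg)
        sp = xt[:, pos].sum(axis=1)
        sn = xt[:, neg].sum(axis=1)
        if mode == "positive":
            preds_tr = (sp,) if len(pos) else ()
        elif mode == "negative":
            preds_tr = (sn,) if len(neg) else ()
        elif combined == "sum-diff":
            preds_tr = (sp - sn,) if (len(pos) or len(neg)) else ()
        else:
            preds_tr = (sp, sn) if (len(pos) or len(neg)) else ()
        if not preds_tr:
            predicted[i] = yt.mean()
            empty += 1
            continue
        design = np.column_stack([np.ones(n - 1), *preds_tr])
        coef, *_ = np.linalg.lstsq(design, yt, rcond=None)
        sp_te = x[i, pos].sum()
        sn_te = x[i, neg].sum()
        if mode == "positive":
            row = [1.0, sp_te]
        elif mode == "negative":
            row = [1.0, sn_te]
        elif combined == "sum-diff":
            row = [1.0, sp_te - sn_te]
        else:
            row = [1.0, sp_te, sn_te]
        predicted[i] = float(np.asarray(row) @ coef)
    return predicted, fold_pos, fold_neg, empty


def evaluate_spearman(predicted, observed) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size < 3:
        raise ValueError("need at least three values")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float(stats.spearmanr(predicted, observed).statistic)


def permutation_test_cpm(fc: pd.DataFrame, behavior, mode: str = "positive",
                         n_perm: int = 5000, seed: int = 0, p_sel: float = 0.05,
                         corr_type: str = "pearson",
                         combined: str = "two-predictor",
                         plus_one: bool = False) -> tuple[float, np.ndarray]:
    """Behavior-shuffling permutation p for the CPM Spearman r (full LOOCV per shuffle)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(behavior, dtype=float)
    x = fc.to_numpy(dtype=float)
    obs = loocv_cpm(fc, y, mode, p_sel, corr_type, combined).spearman_r
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        try:
            pred, *_ = _loocv_core(x, yp, mode, p_sel, corr_type, combined)
            null[b] = evaluate_spearman(pred, yp)
        except ValueError:  # degenerate shuffle (constant predictions)
            null[b] = 0.0
    exceed = int((null >= obs).sum())
    p = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    return float(p), null


def well_represented(fold_positive, fold_negative, min_frac: float = 1.0) -> dict[str, str]:
    """Edges selected in >= min_frac of folds, annotated with their network sign."""
    n = len(fold_positive)
    out: dict[str, str] = {}
    for folds, sign in ((fold_positive, "positive"), (fold_negative, "negative")):
        counts: dict[str, int] = {}
        for sel in folds:
            for e in sel:
                counts[e] = counts.get(e, 0) + 1
        for e, c in counts.items():
            if c / n >= min_frac:
                out[e] = sign
    return out


def run_cpm(fc: pd.DataFrame, behavior, modes=MODES, p_sel: float = 0.05,
            corr_type: str = "pearson", combined: str = "two-predictor",
            n_perm: int = 0, seed: int = 0, min_frac: float = 1.0,
            ) -> dict[str, CPMResult]:
    """CPM over the requested modes, with optional permutation inference."""
    out: dict[str, CPMResult] = {}
    for mode in modes:
        res = loocv_cpm(fc, behavior, mode, p_sel, corr_type, combined)
        if n_perm > 0:
            p, _ = permutation_test_cpm(fc, behavior, mode, n_perm, seed,
                                        p_sel, corr_type, combined)
            res.permutation_p = p
            res.n_permutations = n_perm
        res.well_represented = well_represented(res.fold_positive, res.fold_negative,
                                                min_frac)
        out[mode] = res
    return out
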