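"""Group-discrimination statistics for the three one-vs-rest contrasts.

For every variable the comparison machinery reports: a two-sided exact
Mann–Whitney p-value (full permutation distribution of the rank-sum
statistic with mid-ranks for ties), the Bonferroni-adjusted p (× 3·1167,
capped at 1), sensitivity at 100% specificity and specificity at 100%
sensitivity over all thresholds in both orientations, a separation cutoff
(geometric mean of the two closest cross-group values under complete
separation, arithmetic mean if one of them is zero, otherwise the
threshold maximizing sensitivity + specificity), leave-one-out
cross-validated metrics of a class-balanced logistic regression at a 0.5
probability threshold, and the ROC AUC with DeLong's 95% confidence
interval (omitted when AUC = 1).  Complete separation by a predictor is
reported as 100% across the CV metrics without fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .variables import VariableMatrix, parse_variable

DEFAULT_M_COMPARISONS = 3 * 1167

_CLIP = 30.0  # coefficient cap on the standardized scale (quasi-separation guard)


# ---------------------------------------------------------------------------
# Exact Mann–Whitney

@lru_cache(maxsize=512)
def _ranksum_distribution(doubled_ranks: tuple[int, ...], n1: int) -> np.ndarray:
    """Exact null counts of the group-1 rank sum (doubled mid-rank scale).

    Shift-algorithm dynamic program over subsets of size ``n1``; counts are
    exact in float64 (they never exceed C(55, 27) < 2^53 for cohort-scale
    inputs).
    """
    smax = sum(sorted(doubled_ranks)[-n1:]) if n1 else 0
    dp = np.zeros((n1 + 1, smax + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            if r <= smax:
                dp[k, r:] += dp[k - 1, : smax + 1 - r]
    return dp[n1]


def exact_mann_whitney(x, y) -> float:
    """Two-sided exact Mann–Whitney p-value with mid-ranks for ties.

    The two-sided p is the null probability of a rank-sum statistic at
    least as far from its null mean as the observed one (distance from the
    mean; no doubling of a one-sided tail).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    ranks = rankdata(np.concatenate([x, y]))
    doubled = np.rint(2.0 * ranks).astype(int)
    r1 = int(doubled[:n1].sum())
    counts = _ranksum_distribution(tuple(sorted(doubled)), n1)
    n = n1 + n2
    mu = n1 * (n + 1)  # null mean of the doubled rank sum
    dev = abs(r1 - mu)
    sums = np.arange(counts.size)
    p = counts[np.abs(sums - mu) >= dev].sum() / math.comb(n, n1)
    return float(min(p, 1.0))


def bonferroni_adjust(p: float, m: int = DEFAULT_M_COMPARISONS) -> float:
    """min(1, p·m); significance is declared at adjusted p < 0.05."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# Separation metrics and cutoffs

def _split(values, labels):
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    if not pos or not neg:
        raise ValueError("both classes must be nonempty")
    return pos, neg


def separation_metrics(values, labels) -> tuple[float, float, bool]:
    """(sensitivity at 100% specificity %, specificity at 100% sensitivity %,
    complete-separation flag), maximized over both threshold orientations.

    Accepts floats or exact rationals (Fractions) — comparisons are exact.
    """
    pos, neg = _split(values, labels)
    sens_high = sum(v > max(neg) for v in pos) / len(pos)
    sens_low = sum(v < min(neg) for v in pos) / len(pos)
    spec_high = sum(v < min(pos) for v in neg) / len(neg)
    spec_low = sum(v > max(pos) for v in neg) / len(neg)
    sens = max(sens_high, sens_low)
    spec = max(spec_high, spec_low)
    complete = max(neg) < min(pos) or max(pos) < min(neg)
    return 100.0 * sens, 100.0 * spec, complete


def estimate_cutoff(values, labels) -> tuple[float, float | None]:
    """Separation cutoff and (under complete separation) the boundary ratio.

    Complete separation: cutoff is the geometric mean of the two closest
    cross-class values, or their arithmetic mean if one is zero; the ratio
    larger/smaller is reported only when both are nonzero.  Otherwise the
    cutoff is the threshold maximizing sensitivity + specificity (scanned
    over midpoints of adjacent distinct values in both orientations) and no
    ratio is reported.
    """
    pos, neg = _split(values, labels)
    lo_hi = (max(neg), min(pos)) if max(neg) < min(pos) else None
    if lo_hi is None and max(pos) < min(neg):
        lo_hi = (max(pos), min(neg))
    if lo_hi is not None:
        a, b = lo_hi
        if a <= 0:
            return float((a + b) / 2), None
        return math.sqrt(float(a) * float(b)), float(b / a)

    # overlapping classes: Youden scan
    distinct = sorted(set(values))
    mids = [(u + v) / 2 for u, v in zip(distinct, distinct[1:])]
    candidates = [distinct[0] - 1] + mids + [distinct[-1] + 1]
    best = (-1.0, None)
    for orientation in ("high", "low"):
        for t in candidates:
            if orientation == "high":
                sens = sum(v >= t for v in pos) / len(pos)
                spec = sum(v < t for v in neg) / len(neg)
            else:
                sens = sum(v <= t for v in pos) / len(pos)
                spec = sum(v > t for v in neg) / len(neg)
            score = sens + spec
            if score > best[0]:
                best = (score, t)
    return float(best[1]), None


# ---------------------------------------------------------------------------
# DeLong AUC

def delong_auc_ci(scores, labels, level: float = 0.95):
    """ROC AUC with DeLong's structural-components confidence interval.

    AUC counts tied score pairs as 1/2 (the Mann–Whitney statistic).  The
    Wald interval is truncated to [0, 1] and omitted (None) when AUC = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x = scores[labels]
    y = scores[~labels]
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be nonempty")
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    if auc == 1.0:
        return auc, None
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = float(v10.var(ddof=1)) if x.size > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if y.size > 1 else 0.0
    var = s10 / x.size + s01 / y.size
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


# ---------------------------------------------------------------------------
# LOOCV logistic regression with class-balancing weights

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def completely_separated(x, labels) -> bool:
    pos, neg = _split(list(x), list(labels))
    return max(neg) < min(pos) or max(pos) < min(neg)


def _loocv_single(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Held-out probabilities for a one-predictor model, all folds batched.

    Weighted IRLS per fold with fold-local standardization and class
    weights w_g = N_train / (2 n_g,train); coefficients are capped at ±30
    on the standardized scale so separable training folds saturate rather
    than diverge.
    """
    n = x.size
    y = y.astype(float)
    sum_x, sum_x2 = x.sum(), (x**2).sum()
    mean_f = (sum_x - x) / (n - 1)
    var_f = np.maximum((sum_x2 - x**2) / (n - 1) - mean_f**2, 0.0)
    sd_f = np.sqrt(var_f)
    sd_f[sd_f < 1e-300] = 1.0  # constant training predictor: intercept-only fit
    Z = (x[:, None] - mean_f[None, :]) / sd_f[None, :]  # Z[i, f]
    mask = ~np.eye(n, dtype=bool)
    npos_f = y.sum() - y
    nneg_f = (n - 1) - npos_f
    npos_f = np.maximum(npos_f, 1e-12)
    nneg_f = np.maximum(nneg_f, 1e-12)
    w_cls = np.where(y[:, None] > 0.5, (n - 1) / (2 * npos_f)[None, :], (n - 1) / (2 * nneg_f)[None, :])
    w_cls = w_cls * mask

    b0 = np.zeros(n)
    b1 = np.zeros(n)
    dev_prev = np.full(n, np.inf)
    for _ in range(max_iter):
        eta = b0[None, :] + b1[None, :] * Z
        mu = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
        wq = w_cls * mu * (1 - mu)
        z_work = eta + (y[:, None] - mu) / (mu * (1 - mu))
        s0 = wq.sum(axis=0)
        s1 = (wq * Z).sum(axis=0)
        s2 = (wq * Z * Z).sum(axis=0)
        t0 = (wq * z_work).sum(axis=0)
        t1 = (wq * Z * z_work).sum(axis=0)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        b0 = np.clip((s2 * t0 - s1 * t1) / det, -_CLIP, _CLIP)
        b1 = np.clip((s0 * t1 - s1 * t0) / det, -_CLIP, _CLIP)
        with np.errstate(divide="ignore"):
            dev = -2.0 * (w_cls * (y[:, None] * np.log(mu) + (1 - y[:, None]) * np.log(1 - mu))).sum(axis=0)
        if np.all(np.abs(dev - dev_prev) < tol):
            break
        dev_prev = dev
    held = (x - mean_f) / sd_f
    return _sigmoid(b0 + b1 * held)


def _fit_logistic(X: np.ndarray, y: np.ndarray, w: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Weighted logistic IRLS; returns coefficients for [1, X] columns."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    dev_prev = np.inf
    for _ in range(max_iter):
        eta = A @ beta
        mu = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
        wq = w * mu * (1 - mu)
        z_work = eta + (y - mu) / (mu * (1 - mu))
        AtW = A.T * wq
        try:
            beta = np.linalg.solve(AtW @ A, AtW @ z_work)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(AtW @ A, AtW @ z_work, rcond=None)[0]
        beta = np.clip(beta, -_CLIP, _CLIP)
        dev = -2.0 * float((w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))).sum())
        if abs(dev - dev_prev) < tol:
            break
        dev_prev = dev
    return beta


def _loocv_multi(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    probs = np.empty(n)
    yf = y.astype(float)
    for f in range(n):
        tr = np.arange(n) != f
        Xtr, ytr = X[tr], yf[tr]
        mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd < 1e-300] = 1.0
        Ztr = (Xtr - mean) / sd
        npos = ytr.sum()
        nneg = len(ytr) - npos
        w = np.where(ytr > 0.5, len(ytr) / (2 * max(npos, 1e-12)), len(ytr) / (2 * max(nneg, 1e-12)))
        beta = _fit_logistic(Ztr, ytr, w)
        zf = (X[f] - mean) / sd
        probs[f] = _sigmoid(np.array([beta[0] + beta[1:] @ zf]))[0]
    return probs


@dataclass
class LoocvResult:
    accuracy: float  # percent
    sensitivity: float
    specificity: float
    auc: float  # percent
    auc_ci: tuple[float, float] | None  # percent, None when AUC = 100
    predictions: np.ndarray | None
    separated: bool


def loocv_logistic(matrix: VariableMatrix, contrast: "Contrast", predictors: list[str]) -> LoocvResult:
    """Leave-one-out CV of a class-balanced logistic model; 0.5 threshold.

    If any single predictor completely separates the two groups on the
    full data, all metrics are reported as 100 without fitting, and the
    DeLong interval is omitted.
    """
    y = (matrix.groups == contrast.positive).to_numpy()
    cols = [np.asarray(matrix.resolve(p), dtype=float) for p in predictors]
    if any(completely_separated(c, y) for c in cols):
        return LoocvResult(100.0, 100.0, 100.0, 100.0, None, None, True)
    X = np.column_stack(cols)
    probs = _loocv_single(X[:, 0], y) if X.shape[1] == 1 else _loocv_multi(X, y)
    pred = probs >= 0.5
    acc = 100.0 * float((pred == y).mean())
    sens = 100.0 * float(pred[y].mean())
    spec = 100.0 * float((~pred[~y]).mean())
    auc, ci = delong_auc_ci(probs, y)
    ci_pct = None if ci is None else (100.0 * ci[0], 100.0 * ci[1])
    return LoocvResult(acc, sens, spec, 100.0 * auc, ci_pct, probs, False)


# ---------------------------------------------------------------------------
# Contrasts and the full comparison report

@dataclass(frozen=True)
class Contrast:
    """One-vs-rest contrast: one positive group against the other two pooled."""

    positive: str

    @property
    def name(self) -> str:
        return f"{self.positive}_vs_rest"


def make_contrasts(groups=("PCa", "HD", "BPH")) -> list[Contrast]:
    return [Contrast(g) for g in groups]


REPORT_FILTERS = {
    "table4": lambda df: (df["p_adj"] < 0.005) & (df["sens_at_100_spec"] > 70.0),
    "table5": lambda df: (df["p_adj"] < 1e-10) & df["complete_separation"],
    "table6": lambda df: df["p_adj"] < 3.5e-8,
    "none": lambda df: pd.Series(True, index=df.index),
}


def filter_report(report: pd.DataFrame, preset: str) -> pd.DataFrame:
    return report[REPORT_FILTERS[preset](report)]


def compare_all(
    matrix: VariableMatrix,
    contrasts: list[Contrast] | None = None,
    cv: bool = True,
    m_comparisons: int = DEFAULT_M_COMPARISONS,
) -> pd.DataFrame:
    """Full comparison report: one row per (contrast, variable or covariate).

    Proportions are reported on the percent scale; covariates keep their
    native units (their ``unit`` column says "raw").  Covariates run
    through the identical machinery but do not enlarge the Bonferroni
    family.
    """
    contrasts = contrasts or make_contrasts()
    masks = {c.name: (matrix.groups == c.positive).to_numpy() for c in contrasts}
    rows: list[dict] = []

    items: list[tuple[str, str]] = [(n, "variable") for n in matrix.variable_names]
    if matrix.covariates is not None:
        items += [(n, "covariate") for n in matrix.covariates.columns]

    for name, kind in items:
        if kind == "variable":
            fracs = matrix.column_fractions(name)
            floats = matrix.values[name].to_numpy()
            scale = 100.0
        else:
            floats = matrix.covariates[name].to_numpy(dtype=float)
            fracs = list(floats)
            scale = 1.0
        ranks = rankdata(floats)
        doubled = tuple(sorted(np.rint(2.0 * ranks).astype(int)))
        n = len(floats)
        for c in contrasts:
            y = masks[c.name]
            n1 = int(y.sum())
            r1 = int(np.rint(2.0 * ranks[y]).sum())
            counts = _ranksum_distribution(doubled, n1)
            mu = n1 * (n + 1)
            dev = abs(r1 - mu)
            sums = np.arange(counts.size)
            p = float(min(counts[np.abs(sums - mu) >= dev].sum() / math.comb(n, n1), 1.0))
            p_adj = bonferroni_adjust(p, m_comparisons)
            sens, spec, complete = separation_metrics(fracs, y)
            cutoff, ratio = estimate_cutoff(fracs, y)
            row = {
                "contrast": c.name,
                "variable": name,
                "kind": kind,
                "unit": "percent" if kind == "variable" else "raw",
                "p_raw": p,
                "p_adj": p_adj,
                "mean_pos": float(floats[y].mean()) * scale,
                "mean_neg": float(floats[~y].mean()) * scale,
                "sens_at_100_spec": sens,
                "spec_at_100_sens": spec,
                "cutoff": cutoff * scale,
                "ratio": ratio if ratio is not None else np.nan,
                "complete_separation": complete,
            }
            if cv:
                res = loocv_logistic(matrix, c, [name])
                row.update(
                    cv_accuracy=res.accuracy,
                    cv_sensitivity=res.sensitivity,
                    cv_specificity=res.specificity,
                    cv_auc=res.auc,
                    cv_auc_ci_low=np.nan if res.auc_ci is None else res.auc_ci[0],
                    cv_auc_ci_high=np.nan if res.auc_ci is None else res.auc_ci[1],
                )
            rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney_screen(
    matrix: VariableMatrix,
    contrasts: list[Contrast] | None = None,
    m_comparisons: int = DEFAULT_M_COMPARISONS,
) -> pd.DataFrame:
    """Adjusted exact Mann–Whitney p-values only, for every (contrast, variable).

    A light-weight screen (no separation metrics or CV) used for
    calibration studies over many simulated cohorts; ranks are computed
    once per variable and the permutation null is cached per tie pattern.
    """
    contrasts = contrasts or make_contrasts()
    values = matrix.values.to_numpy()
    all_ranks = rankdata(values, axis=0)
    n = values.shape[0]
    masks = {c.name: (matrix.groups == c.positive).to_numpy() for c in contrasts}
    rows = []
    for j, name in enumerate(matrix.variable_names):
        doubled_col = np.rint(2.0 * all_ranks[:, j]).astype(int)
        doubled = tuple(sorted(doubled_col))
        for c in contrasts:
            y = masks[c.name]
            n1 = int(y.sum())
            counts = _ranksum_distribution(doubled, n1)
            mu = n1 * (n + 1)
            dev = abs(int(doubled_col[y].sum()) - mu)
            sums = np.arange(counts.size)
            p = float(min(counts[np.abs(sums - mu) >= dev].sum() / math.comb(n, n1), 1.0))
            rows.append(
                {
                    "contrast": c.name,
                    "variable": name,
                    "p_raw": p,
                    "p_adj": bonferroni_adjust(p, m_comparisons),
                }
            )
    return pd.DataFrame(rows)


def forward_select(
    matrix: VariableMatrix,
    contrast: Contrast,
    candidates: list[str] | None = None,
    max_predictors: int = 3,
) -> list[dict]:
    """Greedy forward selection on LOOCV accuracy (ties: higher CV AUC, then
    canonical variable order).  Returns one record per accepted step."""
    candidates = list(candidates) if candidates is not None else list(matrix.variable_names)
    selected: list[str] = []
    history: list[dict] = []
    best_acc = -np.inf
    for _ in range(max_predictors):
        best = None  # (acc, auc, name, result)
        for name in candidates:
            if name in selected:
                continue
            res = loocv_logistic(matrix, contrast, selected + [name])
            key = (res.accuracy, res.auc)
            if best is None or key > (best[0], best[1]):
                best = (res.accuracy, res.auc, name, res)
        if best is None or best[0] <= best_acc:
            break
        best_acc = best[0]
        selected.append(best[2])
        history.append(
            {
                "predictors": tuple(selected),
                "cv_accuracy": best[3].accuracy,
                "cv_sensitivity": best[3].sensitivity,
                "cv_specificity": best[3].specificity,
                "cv_auc": best[3].auc,
            }
        )
        if best_acc >= 100.0:
            break
    return history
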