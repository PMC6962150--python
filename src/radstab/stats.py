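"""Agreement statistics: percent feature error vs. Dice, two-way
random-effects ICC with 95% confidence bounds, robust-feature selection,
and leave-p-out rater resampling.

The reliability index is the single-measure, absolute-agreement intraclass
correlation from the two-way random-effects ANOVA (lesions as targets, raters
as measurements),

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n),

with MSR/MSC/MSE the row (target), column (rater) and residual mean squares.
The 95% confidence interval follows the McGraw–Wong F-based procedure for
this form, using a Satterthwaite approximation for the denominator degrees
of freedom.  An average-measures variant (ICC of the k-rater mean) is
available via ``form="average"``.

A feature/scheme pair is called *robust* when the lower 95% confidence bound
(ICC_LB) is at least the selection threshold (default 0.950).  Leave-p-out
recomputes ICC_LB on every subset of k−p raters and averages, quantifying
how reliability degrades as raters are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .core import ConfigurationError, FeatureTable, GROUND_TRUTH_SOURCE
from .metrics import ContourScore, scores_to_frame

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "LeavePOutCurve",
    "percent_error",
    "spearman",
    "classify_correlation",
    "correlate_error_with_dice",
    "icc_two_way",
    "icc_per_feature",
    "select_robust",
    "leave_p_out",
]

CORRELATION_CATEGORIES = ("weak", "moderate", "relatively strong", "strong")


@dataclass
class CorrelationResult:
    feature: str
    gray_levels: int
    rho: float
    p_value: float
    category: str
    n_pairs: int
    n_excluded: int = 0  # pairs dropped because the ground-truth value was 0


@dataclass
class ICCResult:
    """Single-measure two-way random-effects ICC with 95% bounds."""

    feature: str
    gray_levels: int
    icc: float
    lb: float
    ub: float
    n_targets: int
    k_raters: int
    degenerate: bool = False  # perfect agreement or zero total variance


@dataclass
class LeavePOutCurve:
    feature: str
    gray_levels: int
    mean_lb: dict[int, float]  # p -> mean ICC_LB over all C(k, k-p) subsets
    n_subsets: dict[int, int]


def percent_error(f: float, f_gt: float) -> float:
    """Percent error 100·(f − f_gt)/|f_gt|; undefined for f_gt = 0."""
    if f_gt == 0:
        raise ZeroDivisionError("percent error undefined for a zero reference value")
    return 100.0 * (f - f_gt) / abs(f_gt)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (average-rank ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_correlation(rho: float) -> str:
    """Strength category of |ρ|: <0.4 weak, <0.6 moderate, <0.8 relatively
    strong, else strong."""
    a = abs(rho)
    if a > 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    if a < 0.400:
        return "weak"
    if a < 0.600:
        return "moderate"
    if a < 0.800:
        return "relatively strong"
    return "strong"


def correlate_error_with_dice(
    features: FeatureTable, scores: list[ContourScore] | pd.DataFrame
) -> list[CorrelationResult]:
    """Spearman ρ between per-contour percent feature error and Dice.

    For each (feature, G): the percent error of every rater contour relative
    to its lesion's ground-truth value is pooled over all lesion–rater pairs
    and correlated with that contour's Dice.  Pairs whose ground-truth value
    is zero are dropped (counted in ``n_excluded``); a (feature, G) with
    fewer than 3 usable pairs or zero rank variance is skipped with a
    warning.
    """
    sdf = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    dice_map = sdf.set_index(["lesion_id", "rater_id"])["dice"]
    df = features.df
    gt = df[df["source"] == GROUND_TRUTH_SOURCE].set_index(
        ["lesion_id", "gray_levels", "feature"]
    )["value"]
    raters = df[df["source"] != GROUND_TRUTH_SOURCE]
    out: list[CorrelationResult] = []
    for (feat, G), grp in raters.groupby(["feature", "gray_levels"], sort=True):
        errs, dices = [], []
        n_excl = 0
        for row in grp.itertuples():
            ref = gt.get((row.lesion_id, G, feat))
            if ref is None or not np.isfinite(ref):
                continue
            if ref == 0:
                n_excl += 1
                continue
            errs.append(100.0 * (row.value - ref) / abs(ref))
            dices.append(dice_map[(row.lesion_id, row.source)])
        if n_excl:
            warnings.warn(
                f"{feat}@G={G}: {n_excl} pair(s) excluded (zero ground-truth value)"
            )
        if len(errs) < 3:
            warnings.warn(f"{feat}@G={G}: fewer than 3 usable pairs, skipped")
            continue
        if np.ptp(errs) == 0 or np.ptp(dices) == 0:
            warnings.warn(f"{feat}@G={G}: zero rank variance, rho undefined; skipped")
            continue
        rho, p = spearman(errs, dices)
        out.append(
            CorrelationResult(
                feature=feat,
                gray_levels=int(G),
                rho=rho,
                p_value=p,
                category=classify_correlation(rho),
                n_pairs=len(errs),
                n_excluded=n_excl,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ICC


def _icc_anova(x: np.ndarray, alpha: float, form: str) -> tuple[float, float, float, bool]:
    """Core two-way random-effects ICC and CI; returns (icc, lb, ub, degenerate)."""
    n, k = x.shape
    grand = x.mean()
    scale = max(abs(grand), float(np.abs(x).max()), 1e-300)
    if np.ptp(x) <= 1e-12 * scale:
        # zero total variance: reliability undefined
        return np.nan, np.nan, np.nan, True
    row = x.mean(axis=1)
    if np.abs(x - row[:, None]).max() <= 1e-12 * max(np.ptp(x), scale):
        # all raters identical on every target: perfect absolute agreement
        return 1.0, 1.0, 1.0, True

    col = x.mean(axis=0)
    SST = float(((x - grand) ** 2).sum())
    SSR = k * float(((row - grand) ** 2).sum())
    SSC = n * float(((col - grand) ** 2).sum())
    SSE = max(SST - SSR - SSC, 0.0)
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))

    # single-measure estimate first; average form is its Spearman–Brown map
    denom = MSR + (k - 1) * MSE + (k / n) * (MSC - MSE)
    icc = (MSR - MSE) / denom if denom != 0 else np.nan
    icc = float(np.clip(icc, -1.0, 1.0))

    def _avg(r: float) -> float:
        den = 1.0 + (k - 1) * r
        return k * r / den if den > 0 else -1.0

    # McGraw–Wong F-based interval with Satterthwaite df
    if MSE <= 0:
        # residual-free (but columns not identical → MSC > 0); interval collapses
        out = _avg(icc) if form == "average" else icc
        return out, out, out, True
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        out = _avg(icc) if form == "average" else icc
        return out, out, out, True
    num = (a * MSC + b * MSE) ** 2
    den = (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_l = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (MSR - f_l * MSE) / (
        f_l * (k * MSC + (k * n - k - n) * MSE) + n * MSR
    )
    ub = n * (f_u * MSR - MSE) / (
        k * MSC + (k * n - k - n) * MSE + n * f_u * MSR
    )
    if form == "average":
        # Spearman–Brown map of the single-measure estimate and bounds
        icc, lb, ub = _avg(icc), _avg(lb), _avg(ub)
    lb = float(np.clip(lb, -1.0, icc))
    ub = float(np.clip(ub, icc, 1.0))
    return icc, lb, ub, False


def icc_two_way(
    data,
    alpha: float = 0.05,
    form: str = "single",
    feature: str = "",
    gray_levels: int = 0,
) -> ICCResult:
    """Two-way random-effects, absolute-agreement ICC of an n×k matrix.

    Rows are targets (lesions), columns raters.  ``form="single"`` (default)
    is the reliability of one rater's measurement; ``form="average"`` that
    of the k-rater mean.  Negative estimates are floored at −1.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need an n>=2 by k>=2 matrix, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("ICC input must be finite and complete")
    if form not in ("single", "average"):
        raise ConfigurationError(f"unknown ICC form {form!r}")
    icc, lb, ub, degen = _icc_anova(x, alpha, form)
    return ICCResult(
        feature=feature,
        gray_levels=gray_levels,
        icc=icc,
        lb=lb,
        ub=ub,
        n_targets=x.shape[0],
        k_raters=x.shape[1],
        degenerate=degen,
    )


def _feature_matrix(df: pd.DataFrame, feat: str, G: int) -> tuple[np.ndarray, list, list]:
    sub = df[
        (df["feature"] == feat)
        & (df["gray_levels"] == G)
        & (df["source"] != GROUND_TRUTH_SOURCE)
    ]
    pivot = sub.pivot(index="lesion_id", columns="source", values="value")
    if pivot.isna().any().any():
        missing = [
            (les, src)
            for (les, src) in zip(*np.nonzero(pivot.isna().values))
        ]
        names = [
            (pivot.index[i], pivot.columns[j]) for i, j in missing[:5]
        ]
        raise ValueError(f"{feat}@G={G}: missing rater cells, e.g. {names}")
    return pivot.values, list(pivot.index), list(pivot.columns)


def icc_per_feature(
    features: FeatureTable, alpha: float = 0.05, form: str = "single"
) -> list[ICCResult]:
    """One ICC per (feature, G): lesions × raters, ground truth excluded."""
    df = features.df
    out = []
    keys = (
        df[df["source"] != GROUND_TRUTH_SOURCE][["feature", "gray_levels"]]
        .drop_duplicates()
        .sort_values(["gray_levels", "feature"])
    )
    for feat, G in keys.itertuples(index=False):
        mat, _, _ = _feature_matrix(df, feat, int(G))
        out.append(
            icc_two_way(mat, alpha=alpha, form=form, feature=feat, gray_levels=int(G))
        )
    return out


def select_robust(
    results: list[ICCResult], threshold: float = 0.950
) -> list[tuple[str, int]]:
    """(feature, G) pairs whose lower 95% ICC bound is ≥ the threshold."""
    return [
        (r.feature, r.gray_levels)
        for r in results
        if np.isfinite(r.lb) and r.lb >= threshold
    ]


def leave_p_out(
    features: FeatureTable,
    selected: list[tuple[str, int]],
    p_max: int = 7,
    alpha: float = 0.05,
    form: str = "single",
) -> list[LeavePOutCurve]:
    """Mean ICC_LB over all rater subsets of size k−p, for p = 1..p_max.

    Requires k ≥ p_max + 2 so every submatrix keeps at least two raters.
    """
    df = features.df
    curves = []
    for feat, G in selected:
        mat, _, raters = _feature_matrix(df, feat, int(G))
        k = mat.shape[1]
        if p_max > k - 2:
            raise ConfigurationError(
                f"p_max={p_max} too large for k={k} raters (need k >= p_max + 2)"
            )
        mean_lb: dict[int, float] = {}
        n_subsets: dict[int, int] = {}
        for p in range(1, p_max + 1):
            lbs = [
                _icc_anova(mat[:, cols], alpha, form)[1]
                for cols in combinations(range(k), k - p)
            ]
            mean_lb[p] = float(np.mean(lbs))
            n_subsets[p] = len(lbs)
        curves.append(
            LeavePOutCurve(
                feature=feat, gray_levels=int(G), mean_lb=mean_lb, n_subsets=n_subsets
            )
        )
    return curves
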