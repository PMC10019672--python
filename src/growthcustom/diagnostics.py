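"""Assumption diagnostics for customization charts.

The constant-CV chart stands on two assumptions: birthweight is normal
around its customized mean, and its SD is proportional to that mean.
Both are examined by stratifying deliveries into eight contiguous
equal-length intervals of predicted term optimal weight and comparing,
per stratum, the empirical percentiles and SD of observed birthweight
with the model's; plus a QQ check of standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PregnancyRecord


def empirical_percentile(values, q: float):
    """Linear-interpolation sample quantile of the order statistics
    (numpy's default, the convention known as type 7)."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("empirical percentile of empty input")
    return float(np.quantile(arr, q))


@dataclass
class BinSummary:
    """One predicted-TOW stratum with empirical vs. model summaries."""

    lo: float
    hi: float
    closed_right: bool
    n: int
    mean_pred_tow: float
    mean_bw: float | None
    sd_bw: float | None
    empirical: dict        # q -> empirical percentile of observed birthweight
    model: dict            # q -> model percentile at the bin's mean predicted TOW
    cv_line: float | None  # cv * mean predicted TOW

    def contains(self, value: float) -> bool:
        if self.closed_right:
            return self.lo <= value <= self.hi
        return self.lo <= value < self.hi


_DEFAULT_QS = (0.05, 0.10, 0.50, 0.90, 0.95)


def _model_percentile_vector(results, X, pred, q):
    """Per-record model percentile under whichever engine ``results`` is."""
    from .gardosi import PercentileSpec, zscore

    if hasattr(results, "percentile_at_tow"):        # constant-CV chart
        return np.asarray(results.percentile_at_tow(
            pred, PercentileSpec(q, round_grams=False)), float)
    if hasattr(results, "customized_sigma"):         # heteroscedastic chart
        return pred + zscore(q) * np.asarray(results.customized_sigma(X), float)
    if hasattr(results, "predict_quantile"):         # quantile chart
        if q not in results.beta_by_tau:
            return None
        return np.asarray(results.predict_quantiles(X)[q], float)
    return None


def bin_by_predicted_tow(records: list[PregnancyRecord], results, k: int = 8,
                         qs=_DEFAULT_QS, min_sd_n: int = 2) -> list[BinSummary]:
    """Stratify a cohort into ``k`` equal-length predicted-TOW intervals.

    Intervals are equal in TOW length, not in count (the extreme strata
    are typically sparse); the rightmost interval is closed so the
    partition is exhaustive.  The bin's model percentile is the within-bin
    mean of each record's own model percentile (for the constant-CV chart
    this equals the percentile at the bin's mean predicted TOW, the chart
    being linear in TOW); empty strata are retained.
    """
    from .cohort import design_matrix

    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    X = design_matrix(records, results.convention)
    pred = np.asarray(results.predict_tow(X), float)
    bw = np.array([r.birthweight for r in records], float)
    model_vectors = {}
    for q in qs:
        try:
            vec = _model_percentile_vector(results, X, pred, q)
        except ValueError:
            vec = None
        if vec is not None:
            model_vectors[q] = vec
    lo_all, hi_all = float(pred.min()), float(pred.max())
    if hi_all == lo_all:
        raise ValueError("all predicted TOW values identical: zero-width range")
    edges = np.linspace(lo_all, hi_all, k + 1)
    cv = getattr(results, "cv", None)
    bins = []
    counted = 0
    for j in range(k):
        closed_right = j == k - 1
        if closed_right:
            mask = (pred >= edges[j]) & (pred <= edges[j + 1])
        else:
            mask = (pred >= edges[j]) & (pred < edges[j + 1])
        n = int(mask.sum())
        counted += n
        mean_tow = float(pred[mask].mean()) if n else float((edges[j] + edges[j + 1]) / 2)
        empirical = {q: empirical_percentile(bw[mask], q) for q in qs} if n else {}
        model = {q: float(vec[mask].mean())
                 for q, vec in model_vectors.items() if n} if n else {}
        bins.append(BinSummary(
            lo=float(edges[j]), hi=float(edges[j + 1]), closed_right=closed_right,
            n=n, mean_pred_tow=mean_tow,
            mean_bw=float(bw[mask].mean()) if n else None,
            sd_bw=float(bw[mask].std(ddof=1)) if n >= min_sd_n else None,
            empirical=empirical, model=model,
            cv_line=None if cv is None else cv * mean_tow,
        ))
    assert counted == len(records), "bin partition must be exhaustive and disjoint"
    return bins


def cv_constancy_table(bins: list[BinSummary], cv: float) -> dict:
    """Per-bin deviation of the empirical SD from the constant-CV line.

    Also fits the empirical SD on the bin mean predicted TOW by least
    squares, both free and constrained through the origin; under a true
    constant-CV model the through-origin slope estimates the CV.  Bins
    without an SD (n below the minimum) are retained in the table but
    excluded from the fits.
    """
    rows = []
    for b in bins:
        rows.append({
            "lo": b.lo, "hi": b.hi, "n": b.n, "mean_pred_tow": b.mean_pred_tow,
            "sd_bw": b.sd_bw, "cv_line": cv * b.mean_pred_tow,
            "deviation": None if b.sd_bw is None else b.sd_bw - cv * b.mean_pred_tow,
        })
    frame = pd.DataFrame(rows)
    usable = frame.dropna(subset=["sd_bw"])
    if len(usable) < 2:
        raise ValueError("need >= 2 bins with an estimable SD for the line fit")
    x = usable["mean_pred_tow"].to_numpy()
    y = usable["sd_bw"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    slope_origin = float((x @ y) / (x @ x))
    return {
        "table": frame,
        "slope": float(slope),
        "intercept": float(intercept),
        "slope_through_origin": slope_origin,
        "cv": cv,
    }


def percentile_agreement_table(bins: list[BinSummary],
                               qs=(0.05, 0.95)) -> pd.DataFrame:
    """Signed per-bin differences (empirical - model percentile), grams.

    Positive at a high quantile means the model under-estimates the
    empirical percentile there.
    """
    rows = []
    for b in bins:
        row = {"lo": b.lo, "hi": b.hi, "n": b.n, "mean_pred_tow": b.mean_pred_tow}
        for q in qs:
            emp = b.empirical.get(q)
            mod = b.model.get(q)
            row[f"empirical_{int(q*100):02d}"] = emp
            row[f"model_{int(q*100):02d}"] = mod
            row[f"diff_{int(q*100):02d}"] = None if emp is None or mod is None \
                else emp - mod
        rows.append(row)
    return pd.DataFrame(rows)


def residual_qq(results, records: list[PregnancyRecord] | None = None) -> dict:
    """Standardized-residual QQ pairs against the normal distribution.

    For the heteroscedastic engine each residual is scaled by its own
    customized sigma; for the constant-CV engine by the pooled residual
    SD.  Returns the ordered (theoretical, observed) pairs, the QQ line's
    slope/intercept, the largest absolute QQ deviation and a Shapiro-Wilk
    summary statistic (no decision is made here).
    """
    from .cohort import design_matrix

    if results.resid is not None:
        resid = np.asarray(results.resid, float)
        X = results.model.exog
    elif records is not None:
        X = design_matrix(records, results.convention)
        bw = np.array([r.birthweight for r in records], float)
        resid = bw - np.asarray(results.predict_tow(X), float)
    else:
        raise ValueError("need a fit with residuals or an evaluation cohort")

    if hasattr(results, "customized_sigma"):
        sigma = np.asarray(results.customized_sigma(X), float)
    else:
        sigma = np.full(len(resid), results.residual_sd or np.std(resid, ddof=1))
    degenerate = bool(np.allclose(resid, resid[0]) or np.any(sigma <= 0))
    if degenerate:
        return {"degenerate": True, "pairs": None, "slope": None,
                "intercept": None, "max_abs_deviation": None, "shapiro_w": None}
    std = np.sort(resid / sigma)
    n = len(std)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    slope, intercept = np.polyfit(theo, std, 1)
    sample = std if n <= 5000 else std[:: max(1, n // 5000)][:5000]
    w = float(stats.shapiro(sample).statistic) if len(sample) >= 3 else None
    return {
        "degenerate": False,
        "pairs": np.column_stack([theo, std]),
        "slope": float(slope),
        "intercept": float(intercept),
        "max_abs_deviation": float(np.max(np.abs(std - (intercept + slope * theo)))),
        "shapiro_w": w,
    }
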