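"""SGA/LGA classification and screening-performance evaluation.

A delivery is small-for-gestational-age (SGA) under a chart when its
birthweight falls strictly below the chart's customized 10th percentile
at the delivery's own profile, and large-for-gestational-age (LGA) when
strictly above the 90th.  Screening value against composite neonatal
morbidity is summarised by the usual 2x2 machinery: sensitivity,
specificity, PPV, NPV, the odds ratio with a Woolf log-scale CI, and the
c-statistic (for a binary classifier this is exactly
(sensitivity + specificity) / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PregnancyRecord, design_matrix

# composite neonatal morbidity components; SGA and LGA share the core
# list and each adds target-specific components
MORBIDITY_SHARED = (
    "metabolic_acidosis", "nicu_gt3d", "pneumonia", "rds", "pphn", "seizures",
    "exchange_transfusion", "aspiration", "neonatal_death",
    "mechanical_ventilation", "nec", "hypoglycemia", "hie",
)
MORBIDITY_SGA_ONLY = ("pvl", "sepsis", "bpd_cld", "rop")
MORBIDITY_LGA_ONLY = ("birth_injury",)


def morbidity_components(target: str) -> tuple:
    if target.upper() == "SGA":
        return MORBIDITY_SHARED + MORBIDITY_SGA_ONLY
    if target.upper() == "LGA":
        return MORBIDITY_SHARED + MORBIDITY_LGA_ONLY
    raise ValueError(f"target must be 'SGA' or 'LGA', got {target!r}")


def composite_morbidity(flags: pd.DataFrame, target: str) -> pd.Series:
    """Any-of aggregation over the target-specific component list.

    Missing component columns are treated as all-false; the returned
    Series records which columns were absent in ``.attrs['missing']``.
    """
    components = morbidity_components(target)
    present = [c for c in components if c in flags.columns]
    missing = [c for c in components if c not in flags.columns]
    if present:
        out = flags[present].fillna(False).astype(bool).any(axis=1)
    else:
        out = pd.Series(False, index=flags.index)
    out.attrs["missing"] = missing
    return out


# ------------------------------------------------------------------------
# classification
# ------------------------------------------------------------------------

def classify(records: list[PregnancyRecord], results,
             thresholds=(0.10, 0.90), label: str | None = None) -> pd.DataFrame:
    """Flag each delivery SGA / LGA against a chart's percentile cuts.

    Strict inequalities: a birthweight exactly on the 10th percentile is
    not SGA.  Records whose percentile cannot be evaluated are excluded
    and listed in ``.attrs['excluded']``.
    """
    lo_q, hi_q = thresholds
    X = design_matrix(records, results.convention)
    excluded = []
    rows = []
    for i, rec in enumerate(records):
        profile = X.iloc[i]
        try:
            p_lo = results.percentile(profile, lo_q, round_grams=False)
            p_hi = results.percentile(profile, hi_q, round_grams=False)
        except (ValueError, KeyError) as exc:
            excluded.append((i, str(exc)))
            continue
        sga = rec.birthweight < p_lo
        lga = rec.birthweight > p_hi
        assert not (sga and lga)
        rows.append({"index": i, "birthweight": rec.birthweight,
                     "cut_low": p_lo, "cut_high": p_hi, "sga": sga, "lga": lga})
    out = pd.DataFrame(rows).set_index("index")
    out.attrs["model"] = label or type(results).__name__
    out.attrs["thresholds"] = tuple(thresholds)
    out.attrs["excluded"] = excluded
    return out


@dataclass(frozen=True)
class PopulationReference:
    """Pluggable GA-by-sex external percentile lookup (population chart).

    ``table`` maps (completed week, sex, q) -> birthweight cutoff in g.
    """

    table: dict
    label: str = "population reference"

    def percentile(self, ga_days: float, sex: str, q: float) -> float:
        key = (int(ga_days // 7), sex, q)
        if key not in self.table:
            raise KeyError(f"no reference entry for week {key[0]}, {sex}, q={q}")
        return float(self.table[key])


def classify_population(records: list[PregnancyRecord],
                        reference: PopulationReference,
                        thresholds=(0.10, 0.90)) -> pd.DataFrame:
    """SGA/LGA against an external GA-by-sex population chart."""
    lo_q, hi_q = thresholds
    rows, excluded = [], []
    for i, rec in enumerate(records):
        try:
            p_lo = reference.percentile(rec.ga_delivery, rec.infant_sex, lo_q)
            p_hi = reference.percentile(rec.ga_delivery, rec.infant_sex, hi_q)
        except KeyError as exc:
            excluded.append((i, str(exc)))
            continue
        rows.append({"index": i, "birthweight": rec.birthweight,
                     "cut_low": p_lo, "cut_high": p_hi,
                     "sga": rec.birthweight < p_lo, "lga": rec.birthweight > p_hi})
    out = pd.DataFrame(rows).set_index("index")
    out.attrs["model"] = reference.label
    out.attrs["excluded"] = excluded
    return out


# ------------------------------------------------------------------------
# 2x2 metrics
# ------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    odds_ratio: float
    or_ci: tuple
    c_statistic: float
    c_ci: tuple
    continuity_corrected: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0], "or_ci_high": self.or_ci[1],
            "c_statistic": self.c_statistic,
            "c_ci_low": self.c_ci[0], "c_ci_high": self.c_ci[1],
        }


def confusion_metrics(flags, outcome) -> ConfusionSummary:
    """All 2x2 screening metrics for a binary classifier.

    The odds ratio CI is Woolf's log-OR +/- 1.96 SE; a zero cell triggers
    a 0.5 continuity correction on every cell, with a warning.  The
    c-statistic of a binary classifier is (sens + spec)/2, with a
    Hanley-McNeil CI.
    """
    flags = np.asarray(flags, bool)
    outcome = np.asarray(outcome, bool)
    if flags.shape != outcome.shape:
        raise ValueError("flags and outcome must be aligned vectors")
    tp = int(np.sum(flags & outcome))
    fp = int(np.sum(flags & ~outcome))
    fn = int(np.sum(~flags & outcome))
    tn = int(np.sum(~flags & ~outcome))
    return _summary_from_cells(tp, fp, fn, tn)


def confusion_from_rates(sensitivity: float, specificity: float,
                         n_pos: int = 10_000, n_neg: int = 90_000) -> ConfusionSummary:
    """Reconstruct a 2x2 at given class sizes from sensitivity and
    specificity (the implied odds ratio does not depend on the sizes)."""
    tp = sensitivity * n_pos
    fn = n_pos - tp
    tn = specificity * n_neg
    fp = n_neg - tn
    return _summary_from_cells(tp, fp, fn, tn, integer_cells=False)


def _summary_from_cells(tp, fp, fn, tn, integer_cells: bool = True) -> ConfusionSummary:
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos == 0 or n_neg == 0:
        raise ValueError("outcome must contain both classes")
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    corrected = False
    a, b, c, d = tp, fp, fn, tn
    if min(a, b, c, d) == 0:
        corrected = True
        warnings.warn("zero cell in 2x2 table: odds ratio continuity-corrected by 0.5")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se_log = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    ci = (float(np.exp(np.log(or_value) - 1.96 * se_log)),
          float(np.exp(np.log(or_value) + 1.96 * se_log)))
    cstat = (sens + spec) / 2.0
    c_ci = _hanley_mcneil_ci(cstat, n_pos, n_neg)
    cells = (int(round(tp)), int(round(fp)), int(round(fn)), int(round(tn))) \
        if integer_cells else (round(tp), round(fp), round(fn), round(tn))
    return ConfusionSummary(
        tp=cells[0], fp=cells[1], fn=cells[2], tn=cells[3],
        sensitivity=float(sens), specificity=float(spec),
        ppv=float(ppv), npv=float(npv),
        odds_ratio=float(or_value), or_ci=ci,
        c_statistic=float(cstat), c_ci=c_ci,
        continuity_corrected=corrected,
    )


def _hanley_mcneil_ci(auc, n_pos, n_neg) -> tuple:
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    half = 1.96 * float(np.sqrt(max(var, 0.0)))
    return (max(0.0, auc - half), min(1.0, auc + half))


def c_statistic(score, outcome, with_ci: bool = False):
    """Probability a random case outscores a random non-case (ties 1/2).

    Rank (Mann-Whitney) formulation; works for continuous scores and for
    binary flags, where it reduces to (sensitivity + specificity)/2.
    """
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, bool)
    n_pos = int(outcome.sum())
    n_neg = int((~outcome).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("outcome must contain both classes")
    ranks = stats.rankdata(score)
    auc = (ranks[outcome].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if with_ci:
        return float(auc), _hanley_mcneil_ci(float(auc), n_pos, n_neg)
    return float(auc)


# ------------------------------------------------------------------------
# logistic regression
# ------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """Complete separation; names the offending column."""


def fit_logistic(outcome, design, tol: float = 1e-10, maxiter: int = 100):
    """Logistic regression by IRLS (Fisher scoring) for adjusted ORs.

    ``design`` is a DataFrame or 2-D array including its own intercept
    column.  Raises :class:`SeparationError` naming the most extreme
    column under complete or quasi-complete separation.
    """
    if isinstance(design, pd.DataFrame):
        X = design
    else:
        arr = np.asarray(design, float)
        X = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    y = np.asarray(outcome, float)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=maxiter)
        except (PerfectSeparationError, UserWarning, RuntimeWarning) as exc:
            raise SeparationError(_blame_separation(X, y)) from exc
    if np.max(np.abs(res.params)) > 30:
        raise SeparationError(_blame_separation(X, y))
    return res


def _blame_separation(X: pd.DataFrame, y: np.ndarray) -> str:
    # the column whose values best separate the classes
    best, best_col = -1.0, X.columns[0]
    for col in X.columns:
        v = X[col].to_numpy(float)
        if np.ptp(v) == 0:
            continue
        auc = abs(c_statistic(v, y.astype(bool)) - 0.5)
        if auc > best:
            best, best_col = auc, col
    return f"complete separation detected; separating column: {best_col!r}"


def evaluation_table(records: list[PregnancyRecord], fits: dict,
                     morbidity: pd.DataFrame, target: str = "SGA",
                     thresholds=(0.10, 0.90)) -> pd.DataFrame:
    """Screening-performance table across charts for one target.

    ``fits`` maps a label to a fitted engine; ``morbidity`` holds
    component flag columns.  The composite morbidity rate is reported
    against both candidate denominators: among classified-positive
    deliveries and in the whole cohort.
    """
    outcome = composite_morbidity(morbidity, target).to_numpy()
    rows = []
    for label, res in fits.items():
        cls = classify(records, res, thresholds, label=label)
        flag = cls["sga" if target.upper() == "SGA" else "lga"].to_numpy()
        out = outcome[cls.index.to_numpy()]
        m = confusion_metrics(flag, out)
        rows.append({
            "model": label, "target": target.upper(), "n_flagged": int(flag.sum()),
            "morbidity_pct_among_flagged": 100.0 * m.ppv,
            "morbidity_pct_overall": 100.0 * out.mean(),
            "ppv": m.ppv, "npv": m.npv,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "odds_ratio": m.odds_ratio, "or_ci_low": m.or_ci[0],
            "or_ci_high": m.or_ci[1], "c_statistic": m.c_statistic,
        })
    return pd.DataFrame(rows)
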