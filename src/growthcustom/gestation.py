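"""Gestational extrapolation of term percentiles and paired-week refits.

A customized term percentile is carried to earlier gestational ages by a
proportionality reference curve normalized to 1 at 280 days:
``P_q(ga) = P_q(term) * proportion(ga)``.  Estimated fetal weight (EFW)
comes from ultrasound biometry via a configurable log10-linear formula.
Both the reference curve and the biometry formula are configuration data
shipped as labelled JSON defaults, not hard-coded constants.

As a cross-sectional check of the variance model across gestation, the
heteroscedastic engine can be refitted on EFW within rolling pairs of
completed weeks (21-22, 22-23, ...), yielding per-pair coefficient
tables for trend inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_CONVENTION,
    CenteringConvention,
    PregnancyRecord,
    build_design_row,
    center_covariates,
)


def _load_data(name: str) -> dict:
    with resources.files("growthcustom").joinpath("data", name).open() as fh:
        return json.load(fh)


# ------------------------------------------------------------------------
# EFW from biometry
# ------------------------------------------------------------------------

@dataclass(frozen=True)
class BiometryFormula:
    """log10-linear EFW formula over HC, AC, FL (cm) with an AC*FL cross term.

    log10(EFW g) = b0 + b_hc*HC + b_ac*AC + b_fl*FL + b_acfl*AC*FL
    """

    intercept: float
    hc: float = 0.0
    ac: float = 0.0
    fl: float = 0.0
    ac_fl: float = 0.0
    label: str = "custom"

    @classmethod
    def default(cls) -> "BiometryFormula":
        payload = _load_data("hadlock_1985_hc_ac_fl.json")
        return cls(**payload["coefficients"], label=payload["label"])

    @classmethod
    def from_json(cls, path) -> "BiometryFormula":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload["coefficients"], label=payload.get("label", str(path)))


def efw_from_biometry(hc: float, ac: float, fl: float,
                      formula: BiometryFormula | None = None,
                      units: str = "mm") -> float:
    """Estimated fetal weight in grams from biometry.

    Inputs are millimetres by default (the cohort convention); the
    formula itself works in centimetres.
    """
    if formula is None:
        formula = BiometryFormula.default()
    if not (hc > 0 and ac > 0 and fl > 0):
        raise ValueError(f"biometry must be positive, got hc={hc}, ac={ac}, fl={fl}")
    if units == "mm":
        hc, ac, fl = hc / 10.0, ac / 10.0, fl / 10.0
    elif units != "cm":
        raise ValueError(f"unknown biometry units {units!r}")
    log10_efw = (formula.intercept + formula.hc * hc + formula.ac * ac
                 + formula.fl * fl + formula.ac_fl * ac * fl)
    return float(10.0 ** log10_efw)


# ------------------------------------------------------------------------
# proportionality reference curve
# ------------------------------------------------------------------------

class ReferenceCurve:
    """Fraction of term weight as a function of gestational age (days).

    The raw curve is a polynomial in gestational weeks on a
    percent-of-term scale; it is renormalized so ``proportion(280) == 1``
    exactly, making extrapolation at term the identity.
    """

    def __init__(self, coefficients, support_days=(168.0, 294.0),
                 label: str = "custom"):
        self.coefficients = np.asarray(coefficients, float)
        self.support = (float(support_days[0]), float(support_days[1]))
        self.label = label
        self._norm = float(np.polyval(self.coefficients[::-1], 280.0 / 7.0))
        if self._norm <= 0:
            raise ValueError("curve must be positive at term")

    @classmethod
    def default(cls) -> "ReferenceCurve":
        payload = _load_data("proportionality_curve.json")
        return cls(payload["coefficients"], payload["support_days"], payload["label"])

    @classmethod
    def from_json(cls, path) -> "ReferenceCurve":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(payload["coefficients"], payload.get("support_days", (168, 294)),
                   payload.get("label", str(path)))

    def proportion(self, ga_days: float) -> float:
        """Fraction of the term value at ``ga_days``; 1.0 at 280 days."""
        lo, hi = self.support
        if not lo <= ga_days <= hi:
            raise ValueError(f"ga {ga_days} d outside curve support [{lo}, {hi}]")
        return float(np.polyval(self.coefficients[::-1], ga_days / 7.0)) / self._norm


def extrapolate_percentile(term_percentile: float, ga_days: float,
                           curve: ReferenceCurve | None = None) -> float:
    """Scale a term percentile to another gestational age."""
    if curve is None:
        curve = ReferenceCurve.default()
    return term_percentile * curve.proportion(ga_days)


def percentile_chart(results, profile, ga_days, qs=(0.05, 0.10, 0.50, 0.90, 0.95),
                     curve: ReferenceCurve | None = None) -> pd.DataFrame:
    """GA-indexed table of extrapolated customized percentiles.

    ``results`` is any fitted engine exposing ``percentile(profile, q)``.
    """
    if curve is None:
        curve = ReferenceCurve.default()
    term = {q: results.percentile(profile, q, round_grams=False) for q in qs}
    rows = []
    for ga in ga_days:
        prop = curve.proportion(float(ga))
        rows.append({"ga": float(ga), **{f"p{int(q*100):02d}": term[q] * prop
                                         for q in qs}})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------
# rolling paired-week refits
# ------------------------------------------------------------------------

@dataclass
class PairedWeekFitTable:
    """Per week-pair heteroscedastic coefficient estimates for EFW."""

    frame: pd.DataFrame
    skipped: list = field(default_factory=list)

    def coefficient_trend(self, column: str, part: str = "mean") -> pd.DataFrame:
        prefix = {"mean": "beta_", "variance": "gamma_"}[part]
        cols = ["week_start", "n", prefix + column]
        se_col = "se_" + prefix + column
        if se_col in self.frame.columns:
            cols.append(se_col)
        return self.frame[cols]


def pair_windows(week_range=(21, 40)) -> list[tuple[int, float, float]]:
    """Half-open day windows [7w, 7(w+2)) for consecutive completed-week
    pairs w, w+1 in the range (inclusive of the final pair start)."""
    lo, hi = int(week_range[0]), int(week_range[1])
    return [(w, 7.0 * w, 7.0 * (w + 2)) for w in range(lo, hi)]


def rolling_pair_fits(records: list[PregnancyRecord], week_range=(21, 40),
                      convention: CenteringConvention = DEFAULT_CONVENTION,
                      tol: float = 1e-8, maxiter: int = 200) -> PairedWeekFitTable:
    """Refit the heteroscedastic model on EFW within each week-pair window.

    Every visit with an EFW falls in one or two overlapping windows.
    Within a window the gestational-age term is linear only, centred at
    the window midpoint (a 14-day window cannot identify the cubic GA
    polynomial), and pathologic adjusters are omitted; the remaining
    physiologic structure matches the term model.  Pairs with fewer
    usable visits than design columns are skipped with a log entry.
    """
    from .heteroscedastic import ConvergenceError, HeteroscedasticModel

    rows, skipped = [], []
    for w, lo, hi in pair_windows(week_range):
        mid = (lo + hi) / 2.0
        design_rows, ys = [], []
        for rec in records:
            dev = center_covariates(rec, convention)
            for v in rec.visits:
                if v.efw is not None and lo <= v.ga < hi:
                    row = build_design_row(
                        ga_dev=v.ga - mid,
                        height_dev=dev["height_dev"],
                        weight_dev=dev["weight_dev"],
                        sex=rec.infant_sex, race=rec.race, parity=int(rec.parity))
                    row = row.drop(["ga2", "ga3"])
                    design_rows.append(row)
                    ys.append(v.efw)
        if not design_rows:
            skipped.append((w, "no visits in window"))
            continue
        X = pd.DataFrame(design_rows).reset_index(drop=True)
        # drop constant dummy columns (window may lack a race/parity level)
        keep = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
        X = X[keep]
        y = np.asarray(ys, float)
        if len(y) <= X.shape[1] + 1:
            skipped.append((w, f"n={len(y)} below design width {X.shape[1]}"))
            continue
        model = HeteroscedasticModel.from_design(X, y, convention)
        try:
            res = model.fit(tol=tol, maxiter=maxiter)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            skipped.append((w, str(exc)))
            continue
        row = {"week_start": w, "week_end": w + 1, "ga_lo": lo, "ga_hi": hi,
               "n": len(y), "sigma0": res.sigma0, "se_sigma0": res.se_sigma0}
        for name in X.columns:
            row[f"beta_{name}"] = res.params[name]
            row[f"se_beta_{name}"] = res.bse[name]
        for name in model.variance_columns:
            row[f"gamma_{name}"] = res.gamma[name]
            row[f"se_gamma_{name}"] = res.se_gamma[name]
        rows.append(row)
    return PairedWeekFitTable(pd.DataFrame(rows), skipped)
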