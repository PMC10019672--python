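"""Constant-CV customization engine (Gardosi-style).

A linear mean model predicts birthweight at 280 days (term optimal weight,
TOW) from the six physiologic covariates plus fit-time pathologic
adjusters; percentiles then assume normality with a standard deviation
proportional to the customized mean, sigma = CV * TOW, so

    P_q(profile) = TOW(profile) * (1 + z_q * CV).

Only physiologic coefficients contribute at prediction time: the chart is
anchored at a "healthy" profile, so smoking, BMI, gestational diabetes,
hypertensive disease and bleeding adjust the fit but not the percentile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import (
    DEFAULT_CONVENTION,
    PATERNAL_COLUMNS,
    PATHOLOGIC_COLUMNS,
    PHYSIOLOGIC_COLUMNS,
    CenteringConvention,
    design_matrix,
)

#: multipliers as printed in published customization charts (two decimals);
#: "exact" switches to full-precision normal quantiles.
PRINTED_Z = {0.05: -1.645, 0.10: -1.28, 0.50: 0.0, 0.90: 1.28, 0.95: 1.645}


def zscore(q: float, mode: str = "printed") -> float:
    """Normal quantile multiplier for probability ``q``.

    ``mode='printed'`` uses the truncated two-decimal multipliers of the
    published worked examples (1.28 for the 10th/90th); ``mode='exact'``
    uses scipy's full-precision quantile.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile probability must be in (0,1), got {q}")
    if mode == "printed" and q in PRINTED_Z:
        return PRINTED_Z[q]
    return float(stats.norm.ppf(q))


@dataclass(frozen=True)
class PercentileSpec:
    """A target percentile: probability, z multiplier, gram rounding."""

    q: float
    z_mode: str = "printed"
    round_grams: bool = True

    @property
    def z(self) -> float:
        return zscore(self.q, self.z_mode)


def cv_from_components(residual_sd: float, mean_tow: float) -> float:
    """Population CV: pooled residual SD over mean predicted TOW."""
    if mean_tow == 0:
        raise ZeroDivisionError("degenerate cohort: mean predicted TOW is zero")
    return residual_sd / mean_tow


def gardosi_percentile(tow: float, cv: float, spec: PercentileSpec | float) -> float:
    """Constant-CV percentile: ``tow * (1 + z_q * cv)``.

    The median returns the TOW exactly and symmetric pairs (q, 1-q)
    average back to the TOW.
    """
    if np.any(np.asarray(tow) <= 0):
        raise ValueError("term optimal weight must be positive")
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec(q=float(spec))
    value = tow * (1.0 + spec.z * cv)
    return float(np.round(value)) if spec.round_grams and np.isscalar(value) else value


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is singular; carries the suspect column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


def _check_rank(X: pd.DataFrame) -> None:
    from scipy import linalg as sla

    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: columns pivoted beyond the numerical rank are the
        # (approximately) collinear ones
        _, _, piv = sla.qr(arr, pivoting=True, mode="economic")
        raise RankDeficiencyError(X.columns[piv[rank:]])


def drop_empty_adjusters(X: pd.DataFrame) -> pd.DataFrame:
    """Drop pathologic/paternal columns with no variation in the cohort
    (e.g. no smokers in a small sample); physiologic columns are kept so
    genuine rank problems still surface."""
    droppable = [c for c in X.columns
                 if c in PATHOLOGIC_COLUMNS + PATERNAL_COLUMNS
                 and X[c].nunique() <= 1]
    if droppable:
        import warnings
        warnings.warn(f"dropping constant adjustment columns: {droppable}")
        X = X.drop(columns=droppable)
    return X


class GardosiModel:
    """OLS model for term optimal weight with constant-CV percentiles.

    Parameters
    ----------
    records : list of PregnancyRecord
    convention : CenteringConvention, optional
    include_pathologic, include_paternal : bool
        Extra fit-time adjustment columns; their coefficients are always
        excluded from chart prediction.
    """

    def __init__(self, records, convention: CenteringConvention = DEFAULT_CONVENTION,
                 *, include_pathologic: bool = True, include_paternal: bool = False):
        self.records = list(records)
        self.convention = convention
        self.include_pathologic = include_pathologic
        self.include_paternal = include_paternal
        self.exog = drop_empty_adjusters(design_matrix(
            self.records, convention,
            include_pathologic=include_pathologic,
            include_paternal=include_paternal))
        self.endog = np.array([r.birthweight for r in self.records], float)

    def fit(self) -> "GardosiResults":
        X = self.exog
        _check_rank(X)
        ols = sm.OLS(self.endog, X).fit()
        resid_sd = float(np.sqrt(ols.ssr / ols.df_resid))
        return GardosiResults(
            params=ols.params.astype(float),
            bse=ols.bse.astype(float),
            residual_sd=resid_sd,
            nobs=int(ols.nobs),
            convention=self.convention,
            model=self,
            resid=np.asarray(ols.resid, float),
        )


class GardosiResults:
    """Fitted constant-CV customization chart.

    ``params`` spans the full fit-time design; ``physiologic_params`` is
    the restriction used for every chart prediction.
    """

    def __init__(self, params: pd.Series, bse: pd.Series | None,
                 residual_sd: float | None, nobs: int | None,
                 convention: CenteringConvention = DEFAULT_CONVENTION,
                 cv: float | None = None, model: GardosiModel | None = None,
                 resid: np.ndarray | None = None):
        self.params = params
        self.bse = bse
        self.residual_sd = residual_sd
        self.nobs = nobs
        self.convention = convention
        self.model = model
        self.resid = resid
        self._cv_override = cv

    # -- prediction -----------------------------------------------------
    @property
    def physiologic_params(self) -> pd.Series:
        return self.params.reindex(
            [c for c in PHYSIOLOGIC_COLUMNS if c in self.params.index])

    def _profile_product(self, profile, params: pd.Series) -> float:
        if isinstance(profile, pd.DataFrame):
            aligned = profile.reindex(columns=params.index, fill_value=0.0)
            return aligned.to_numpy() @ params.to_numpy()
        extra = set(profile.index) - set(self.params.index) \
            - set(PHYSIOLOGIC_COLUMNS) - set(PATHOLOGIC_COLUMNS) \
            - set(PATERNAL_COLUMNS)
        if extra:
            raise ValueError(f"profile has columns unknown to the fit: {sorted(extra)}")
        aligned = profile.reindex(params.index, fill_value=0.0)
        return float(aligned.to_numpy() @ params.to_numpy())

    def predict_tow(self, profile) -> float:
        """Term optimal weight at a profile: physiologic columns only.

        Pathologic columns in the profile contribute zero regardless of
        their values.
        """
        return self._profile_product(profile, self.physiologic_params)

    @property
    def cv(self) -> float:
        """Coefficient of variation: residual SD over mean predicted TOW.

        Returns the override when one was supplied (0.129 reproduces the
        published study population).
        """
        if self._cv_override is not None:
            return self._cv_override
        return self.estimate_cv()

    def estimate_cv(self) -> float:
        if self.model is None or self.residual_sd is None:
            raise ValueError("CV estimation needs the training cohort; supply cv=")
        mean_tow = float(np.mean(self.predict_tow(self.model.exog)))
        return cv_from_components(self.residual_sd, mean_tow)

    def percentile(self, profile, q: float, *, z_mode: str = "printed",
                   round_grams: bool = True) -> float:
        """Customized percentile at a profile under the constant-CV rule."""
        spec = PercentileSpec(q, z_mode, round_grams)
        return self.percentile_at_tow(self.predict_tow(profile), spec)

    def percentile_at_tow(self, tow: float, spec: PercentileSpec | float):
        cv = self.cv
        if cv == 0:
            import warnings as _w
            _w.warn("CV is zero: all percentiles collapse onto the TOW")
        if not isinstance(spec, PercentileSpec):
            spec = PercentileSpec(float(spec))
        if np.isscalar(tow):
            return gardosi_percentile(tow, cv, spec)
        out = np.asarray(tow) * (1.0 + spec.z * cv)
        return np.round(out) if spec.round_grams else out

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        lines = ["Constant-CV customization model (term optimal weight)",
                 f"n = {self.nobs}, residual SD = "
                 f"{self.residual_sd:.1f} g" if self.residual_sd else f"n = {self.nobs}",
                 f"CV = {self.cv:.4f}", "-" * 48,
                 f"{'term':<16}{'coef':>12}{'se':>12}"]
        for name, val in self.params.items():
            se = "" if self.bse is None else f"{self.bse.get(name, float('nan')):>12.3f}"
            lines.append(f"{name:<16}{val:>12.3f}{se}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "model": "gardosi",
            "params": self.params.to_dict(),
            "bse": None if self.bse is None else self.bse.to_dict(),
            "residual_sd": self.residual_sd,
            "cv": self.cv,
            "nobs": self.nobs,
            "convention": {
                "ga_center": self.convention.ga_center,
                "height_center": self.convention.height_center,
                "weight_center": self.convention.weight_center,
            },
        }
        return json.dumps(payload, indent=2)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_params(cls, params: dict | pd.Series, cv: float,
                    convention: CenteringConvention = DEFAULT_CONVENTION,
                    **kw) -> "GardosiResults":
        """Build a prediction-ready chart from externally supplied
        coefficients (e.g. a published coefficient table)."""
        return cls(params=pd.Series(params, dtype=float), bse=None,
                   residual_sd=None, nobs=kw.get("nobs"), convention=convention,
                   cv=cv)

    @classmethod
    def from_json(cls, text_or_path) -> "GardosiResults":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                payload = json.load(fh)
        conv = CenteringConvention.from_mapping(payload.get("convention", {}))
        res = cls.from_params(payload["params"], payload["cv"], conv,
                              nobs=payload.get("nobs"))
        res.residual_sd = payload.get("residual_sd")
        if payload.get("bse"):
            res.bse = pd.Series(payload["bse"], dtype=float)
        return res


def fit_mean_model(records, **kw) -> GardosiResults:
    """Convenience wrapper: construct and fit :class:`GardosiModel`."""
    return GardosiModel(records, **kw).fit()
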