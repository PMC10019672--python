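"""Direct percentile customization by linear quantile regression.

For each target probability tau the coefficient vector minimizes the
check loss sum_i rho_tau(y_i - x_i' beta) with rho_tau(r) = r (tau -
1{r<0}).  Each fit is the standard linear-programming primal

    min  tau 1'u + (1-tau) 1'v   s.t.  X beta + u - v = y,  u, v >= 0,

solved with scipy's HiGHS interior-point/simplex solver, which is
deterministic for a fixed row order.  Separately fitted quantile planes
may cross at extreme profiles; predictions are made monotone in tau by
monotone rearrangement (sorting the predicted values and reassigning
them to the ascending taus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .cohort import (
    DEFAULT_CONVENTION,
    PHYSIOLOGIC_COLUMNS,
    CenteringConvention,
    design_matrix,
)
from .gardosi import _check_rank, drop_empty_adjusters


def check_loss(resid: np.ndarray, tau: float) -> float:
    """Asymmetric absolute (pinball) loss summed over residuals."""
    r = np.asarray(resid, float)
    return float(np.sum(r * (tau - (r < 0))))


def solve_quantile_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Minimize the check loss by LP; returns the coefficient vector."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sparse.hstack([sparse.csr_matrix(X), sparse.eye(n), -sparse.eye(n)],
                      format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    return res.x[:p]


def enforce_noncrossing(values_by_tau: dict[float, float]) -> dict[float, float]:
    """Monotone rearrangement: sorted values reassigned to ascending taus.

    Idempotent; leaves already-monotone predictions unchanged.
    """
    taus = sorted(values_by_tau)
    ordered = np.sort([values_by_tau[t] for t in taus])
    return dict(zip(taus, (float(v) for v in ordered)))


class GrowthQuantileModel:
    """Linear quantile-regression customization over the shared design."""

    def __init__(self, records, taus=(0.10, 0.50, 0.90),
                 convention: CenteringConvention = DEFAULT_CONVENTION,
                 *, include_pathologic: bool = True, include_paternal: bool = False):
        taus = tuple(sorted(float(t) for t in taus))
        if len(set(taus)) != len(taus) or not all(0 < t < 1 for t in taus):
            raise ValueError("taus must be distinct probabilities in (0,1)")
        self.taus = taus
        self.records = list(records)
        self.convention = convention
        self.exog = drop_empty_adjusters(design_matrix(
            self.records, convention,
            include_pathologic=include_pathologic,
            include_paternal=include_paternal))
        self.endog = np.array([r.birthweight for r in self.records], float)

    def fit(self) -> "QuantileResults":
        Xf, y = self.exog, self.endog
        _check_rank(Xf)
        X = Xf.to_numpy(float)
        beta_by_tau = {}
        for tau in self.taus:
            beta_by_tau[tau] = pd.Series(solve_quantile_lp(X, y, tau),
                                         index=Xf.columns)
        se_median = None
        if 0.50 in beta_by_tau:
            se_median = pd.Series(
                _sparsity_se(X, y - X @ beta_by_tau[0.50].to_numpy(), 0.50),
                index=Xf.columns)
        return QuantileResults(taus=self.taus, beta_by_tau=beta_by_tau,
                               se_median=se_median, nobs=len(y),
                               convention=self.convention, model=self)


def _sparsity_se(X: np.ndarray, resid: np.ndarray, tau: float) -> np.ndarray:
    # Koenker-style sparsity (difference quotient of the residual quantile
    # function at a Hall-Sheather bandwidth) under iid errors
    n = len(resid)
    z = stats.norm.ppf(tau)
    h = n ** (-1 / 3) * stats.norm.ppf(0.975) ** (2 / 3) \
        * ((1.5 * stats.norm.pdf(z) ** 2) / (2 * z ** 2 + 1)) ** (1 / 3)
    lo, hi = max(tau - h, 1e-4), min(tau + h, 1 - 1e-4)
    s = (np.quantile(resid, hi) - np.quantile(resid, lo)) / (hi - lo)
    cov = tau * (1 - tau) * s ** 2 * np.linalg.inv(X.T @ X)
    return np.sqrt(np.diag(cov))


@dataclass
class QuantileResults:
    """Per-tau coefficient vectors for direct percentile prediction."""

    taus: tuple
    beta_by_tau: dict
    se_median: pd.Series | None = None
    nobs: int | None = None
    convention: CenteringConvention = DEFAULT_CONVENTION
    model: GrowthQuantileModel | None = None

    def __post_init__(self):
        self.taus = tuple(sorted(self.taus))
        self.beta_by_tau = {float(t): pd.Series(b, dtype=float)
                            for t, b in self.beta_by_tau.items()}

    def _physiologic(self, tau: float) -> pd.Series:
        b = self.beta_by_tau[tau]
        return b.reindex([c for c in PHYSIOLOGIC_COLUMNS if c in b.index])

    def _raw_predict(self, profile, tau: float):
        params = self._physiologic(tau)
        if isinstance(profile, pd.DataFrame):
            aligned = profile.reindex(columns=params.index, fill_value=0.0)
            return aligned.to_numpy() @ params.to_numpy()
        aligned = profile.reindex(params.index, fill_value=0.0)
        return float(aligned.to_numpy() @ params.to_numpy())

    def predict_quantile(self, profile, tau: float, *, noncrossing: bool = True,
                         round_grams: bool = False) -> float:
        """Customized percentile x'beta(tau), physiologic columns only.

        With ``noncrossing`` (default) the prediction is taken after
        monotone rearrangement across all fitted taus at this profile.
        """
        tau = float(tau)
        if tau not in self.beta_by_tau:
            raise ValueError(f"tau {tau} was not fitted; available: {self.taus}")
        if noncrossing and len(self.taus) > 1:
            value = self.predict_quantiles(profile)[tau]
        else:
            value = self._raw_predict(profile, tau)
        if not round_grams:
            return value
        return float(np.round(value)) if np.isscalar(value) else np.round(value)

    def predict_quantiles(self, profile) -> dict[float, float]:
        """All fitted percentiles at a profile, monotone in tau.

        ``profile`` may be a design row (scalars returned) or a design
        DataFrame (vectors returned, rearranged row by row).
        """
        raw = {t: self._raw_predict(profile, t) for t in self.taus}
        if isinstance(profile, pd.DataFrame):
            stacked = np.sort(np.column_stack([raw[t] for t in self.taus]), axis=1)
            return {t: stacked[:, j] for j, t in enumerate(self.taus)}
        return enforce_noncrossing(raw)

    def predict_tow(self, profile) -> float:
        """Median prediction (the quantile engine's term optimal weight)."""
        if 0.50 not in self.beta_by_tau:
            raise ValueError("median requires tau=0.5 among the fitted taus")
        return self.predict_quantile(profile, 0.50)

    def percentile(self, profile, q: float, *, round_grams: bool = True, **_):
        """Uniform percentile interface shared with the other engines."""
        return self.predict_quantile(profile, q, round_grams=round_grams)

    def summary(self) -> str:
        lines = [f"Quantile-regression customization model, n = {self.nobs}",
                 "-" * 60,
                 "term".ljust(16) + "".join(f"tau={t:<10.2f}" for t in self.taus)]
        index = self.beta_by_tau[self.taus[0]].index
        for name in index:
            lines.append(name.ljust(16) + "".join(
                f"{self.beta_by_tau[t][name]:<14.3f}" for t in self.taus))
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "model": "quantile",
            "taus": list(self.taus),
            "beta_by_tau": {str(t): b.to_dict() for t, b in self.beta_by_tau.items()},
            "se_median": None if self.se_median is None else self.se_median.to_dict(),
            "nobs": self.nobs,
            "convention": {
                "ga_center": self.convention.ga_center,
                "height_center": self.convention.height_center,
                "weight_center": self.convention.weight_center,
            },
        }, indent=2)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_params(cls, beta_by_tau: dict,
                    convention: CenteringConvention = DEFAULT_CONVENTION,
                    **kw) -> "QuantileResults":
        """Prediction-ready fit from externally supplied tau-coefficients."""
        beta_by_tau = {float(t): pd.Series(b, dtype=float)
                       for t, b in beta_by_tau.items()}
        return cls(taus=tuple(beta_by_tau), beta_by_tau=beta_by_tau,
                   convention=convention, nobs=kw.get("nobs"))

    @classmethod
    def from_json(cls, text_or_path) -> "QuantileResults":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                payload = json.load(fh)
        conv = CenteringConvention.from_mapping(payload.get("convention", {}))
        res = cls.from_params(payload["beta_by_tau"], conv, nobs=payload.get("nobs"))
        if payload.get("se_median"):
            res.se_median = pd.Series(payload["se_median"], dtype=float)
        return res


def fit_quantile(records, taus=(0.10, 0.50, 0.90), **kw) -> QuantileResults:
    """Convenience wrapper: construct and fit :class:`GrowthQuantileModel`."""
    return GrowthQuantileModel(records, taus, **kw).fit()
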