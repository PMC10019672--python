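"""Joint customization of mean and standard deviation.

The model is a normal regression with a log-linear variance:

    y_i ~ Normal(x_i' beta,  sigma_i^2),
    sigma_i = sigma0 * exp(0.5 * z_i' gamma),

where ``x`` is the shared customization design and ``z`` is the same
design without the intercept (the variance intercept is carried by
``sigma0``).  Equivalently log sigma_i^2 = alpha + z_i' gamma with
alpha = 2 log sigma0.  The constant-CV chart is the special case
gamma = 0 with sigma0 tied to the mean; here the dispersion is free to
depend on every customization covariate.

Fitting is maximum likelihood by alternating
(i)  weighted least squares for beta at weights 1/sigma_i^2, and
(ii) a Fisher-scoring update for (alpha, gamma) given the residuals,
     with step-halving so the log-likelihood never decreases.

Percentiles use the normal quantile formula with the customized sigma:
P_q = TOW + z_q * sigma(profile); as for the constant-CV engine, only
physiologic coefficients enter chart prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_CONVENTION,
    PATERNAL_COLUMNS,
    PATHOLOGIC_COLUMNS,
    PHYSIOLOGIC_COLUMNS,
    CenteringConvention,
    design_matrix,
)
from .gardosi import PercentileSpec, _check_rank, zscore

_LOG2PI = float(np.log(2.0 * np.pi))


def normal_loglik(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                  beta: np.ndarray, alpha: float, gamma: np.ndarray) -> float:
    """Exact normal log-likelihood under the log-linear variance model."""
    logvar = alpha + Z @ gamma
    resid = y - X @ beta
    return float(-0.5 * np.sum(_LOG2PI + logvar + resid ** 2 * np.exp(-logvar)))


class ConvergenceError(RuntimeError):
    """Alternating ML did not converge; carries the log-likelihood trace."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(
            f"no convergence after {len(self.trace)} iterations; "
            f"final loglik {self.trace[-1]:.6f}")


class HeteroscedasticModel:
    """Normal model with customized mean and log-linear customized variance.

    The variance design mirrors the mean design column-for-column
    (without the intercept); ``variance_pathologic=False`` drops the
    pathologic adjusters from the variance part only.
    """

    def __init__(self, records, convention: CenteringConvention = DEFAULT_CONVENTION,
                 *, include_pathologic: bool = True, include_paternal: bool = False,
                 variance_pathologic: bool = True, min_variance_group: int = 10):
        self.records = list(records)
        self.convention = convention
        self.include_pathologic = include_pathologic
        from .gardosi import drop_empty_adjusters
        self.exog = drop_empty_adjusters(design_matrix(
            self.records, convention,
            include_pathologic=include_pathologic,
            include_paternal=include_paternal))
        var_cols = [c for c in self.exog.columns if c != "intercept"]
        if not variance_pathologic:
            var_cols = [c for c in var_cols
                        if c not in PATHOLOGIC_COLUMNS + PATERNAL_COLUMNS]
        # a binary column with a handful of members in one group makes the
        # likelihood unbounded (that group's sigma can be driven to zero);
        # variance effects need a minimum group size to be estimable
        guarded = []
        for c in var_cols:
            col = self.exog[c]
            if col.nunique() <= 2:
                minor = int(min((col == col.min()).sum(), (col == col.max()).sum()))
                if minor < min_variance_group:
                    guarded.append(c)
        if guarded:
            warnings.warn("excluding sparse indicator columns from the "
                          f"variance design: {guarded}")
            var_cols = [c for c in var_cols if c not in guarded]
        self.variance_columns = var_cols
        self.endog = np.array([r.birthweight for r in self.records], float)

    @classmethod
    def from_design(cls, exog: pd.DataFrame, endog,
                    convention: CenteringConvention = DEFAULT_CONVENTION,
                    variance_columns: list[str] | None = None) -> "HeteroscedasticModel":
        """Build directly from a design matrix (e.g. paired-week EFW fits)."""
        model = cls.__new__(cls)
        model.records = []
        model.convention = convention
        model.include_pathologic = False
        model.exog = exog
        model.variance_columns = (variance_columns if variance_columns is not None
                                  else [c for c in exog.columns if c != "intercept"])
        model.endog = np.asarray(endog, float)
        return model

    def fit(self, tol: float = 1e-8, maxiter: int = 200,
            freeze_gamma: bool = False) -> "HeteroscedasticResults":
        """Alternating WLS / Fisher-scoring maximum likelihood.

        Stops when the relative log-likelihood change falls below ``tol``.
        ``freeze_gamma=True`` keeps (alpha fitted, gamma = 0), reducing the
        mean fit to homoscedastic ML.
        """
        Xf, y = self.exog, self.endog
        _check_rank(Xf)
        X = Xf.to_numpy(float)
        Z = Xf[self.variance_columns].to_numpy(float)
        n, p = X.shape
        q = Z.shape[1]

        # init: OLS mean, homoscedastic variance, flat gamma
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        alpha = float(np.log(max(np.mean(resid ** 2), _VAR_FLOOR)))
        logvar_floor = alpha - 16.0   # sigma floor ~ sigma_init * 3e-4
        gamma = np.zeros(q)
        Z1 = np.column_stack([np.ones(n), Z])
        ZtZ_inv = np.linalg.pinv(Z1.T @ Z1)

        trace = [normal_loglik(y, X, Z, beta, alpha, gamma)]
        converged = False
        for it in range(1, maxiter + 1):
            # (i) weighted least squares for the mean
            logvar = np.clip(alpha + Z @ gamma, logvar_floor, 700.0)
            w = np.exp(-logvar)
            XtW = X.T * w
            beta = np.linalg.solve(XtW @ X, XtW @ y)
            resid = y - X @ beta

            # (ii) one scoring step for the variance parameters, with
            # step-halving to keep the likelihood monotone
            if not freeze_gamma:
                u = resid ** 2 * np.exp(-logvar) - 1.0
                step = ZtZ_inv @ (Z1.T @ u)
            else:
                # gamma frozen at 0: alpha has a closed-form ML update
                step = np.zeros(q + 1)
                step[0] = float(np.log(max(np.mean(resid ** 2), _VAR_FLOOR))) - alpha
            ll_before = normal_loglik(y, X, Z, beta, alpha, gamma)
            scale = 1.0
            for _ in range(30):
                a_new = alpha + scale * step[0]
                g_new = gamma + scale * step[1:]
                ll_new = normal_loglik(y, X, Z, beta, a_new, g_new)
                if ll_new >= ll_before - 1e-10 * max(1.0, abs(ll_before)):
                    alpha, gamma = a_new, g_new
                    break
                scale *= 0.5
            ll = normal_loglik(y, X, Z, beta, alpha, gamma)
            trace.append(ll)
            if abs(ll - trace[-2]) <= tol * max(1.0, abs(ll)):
                converged = True
                break
        if not converged:
            raise ConvergenceError(trace)

        if np.any(alpha + Z @ gamma <= logvar_floor + 1e-12):
            warnings.warn("variance floor active for some observations")

        # observed/expected information, block-diagonal in (beta) x (alpha,gamma)
        logvar = alpha + Z @ gamma
        w = np.exp(-logvar)
        XtW = X.T * w
        cov_beta = np.linalg.inv(XtW @ X)
        cov_theta = 2.0 * ZtZ_inv
        sigma0 = float(np.exp(alpha / 2.0))
        se_alpha = float(np.sqrt(cov_theta[0, 0]))
        return HeteroscedasticResults(
            params=pd.Series(beta, index=Xf.columns),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=Xf.columns),
            sigma0=sigma0,
            gamma=pd.Series(gamma, index=self.variance_columns),
            se_sigma0=sigma0 * se_alpha / 2.0,  # delta method from alpha
            se_gamma=pd.Series(np.sqrt(np.diag(cov_theta)[1:]),
                               index=self.variance_columns),
            loglik_trace=trace,
            converged=converged,
            n_iter=it,
            nobs=n,
            convention=self.convention,
            model=self,
            resid=resid,
        )


_VAR_FLOOR = 1e-8


@dataclass
class HeteroscedasticResults:
    """Fitted mean + variance customization chart.

    ``sigma0`` is the baseline SD at the reference profile in grams;
    ``gamma`` are log-variance-scale slopes per unit of each variance
    design column (the hybrid SD-intercept / log-variance-slope
    parameterization used in published worked examples).
    """

    params: pd.Series
    sigma0: float
    gamma: pd.Series
    bse: pd.Series | None = None
    se_sigma0: float | None = None
    se_gamma: pd.Series | None = None
    loglik_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    nobs: int | None = None
    convention: CenteringConvention = DEFAULT_CONVENTION
    model: HeteroscedasticModel | None = None
    resid: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    @property
    def loglik(self) -> float | None:
        return self.loglik_trace[-1] if self.loglik_trace else None

    # -- prediction -----------------------------------------------------
    @property
    def physiologic_params(self) -> pd.Series:
        return self.params.reindex(
            [c for c in PHYSIOLOGIC_COLUMNS if c in self.params.index])

    @property
    def physiologic_gamma(self) -> pd.Series:
        return self.gamma.reindex(
            [c for c in PHYSIOLOGIC_COLUMNS
             if c in self.gamma.index and c != "intercept"])

    def _product(self, profile, params: pd.Series):
        if isinstance(profile, pd.DataFrame):
            aligned = profile.reindex(columns=params.index, fill_value=0.0)
            return aligned.to_numpy() @ params.to_numpy()
        aligned = profile.reindex(params.index, fill_value=0.0)
        return float(aligned.to_numpy() @ params.to_numpy())

    def predict_tow(self, profile):
        """Customized mean (TOW) at a profile, physiologic columns only."""
        return self._product(profile, self.physiologic_params)

    def customized_sigma(self, profile):
        """Customized SD: sigma0 * exp(0.5 * <gamma, physiologic columns>).

        Pathologic profile columns are zeroed at prediction, matching the
        treatment of the mean.
        """
        lin = self._product(profile, self.physiologic_gamma)
        return self.sigma0 * np.exp(0.5 * lin)

    def percentile(self, profile, q: float, *, z_mode: str = "printed",
                   round_grams: bool = True):
        """Customized percentile: TOW + z_q * customized sigma."""
        spec = PercentileSpec(q, z_mode, round_grams)
        value = self.predict_tow(profile) + spec.z * self.customized_sigma(profile)
        return float(np.round(value)) if round_grams and np.isscalar(value) else value

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        lines = ["Heteroscedastic customization model (mean + SD)",
                 f"n = {self.nobs}, iterations = {self.n_iter}, "
                 f"loglik = {self.loglik:.3f}" if self.loglik is not None
                 else f"n = {self.nobs}",
                 "-" * 48, "Mean model (g per unit):",
                 f"{'term':<16}{'coef':>12}{'se':>12}"]
        for name, val in self.params.items():
            se = float("nan") if self.bse is None else self.bse.get(name, float("nan"))
            lines.append(f"{name:<16}{val:>12.3f}{se:>12.3f}")
        lines += ["Variance model (log-variance scale; intercept as SD):",
                  f"{'sigma0':<16}{self.sigma0:>12.4f}"
                  + ("" if self.se_sigma0 is None else f"{self.se_sigma0:>12.4f}")]
        for name, val in self.gamma.items():
            se = float("nan") if self.se_gamma is None else self.se_gamma.get(name, float("nan"))
            lines.append(f"{name:<16}{val:>12.6f}{se:>12.6f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "model": "heteroscedastic",
            "params": self.params.to_dict(),
            "bse": None if self.bse is None else self.bse.to_dict(),
            "variance": {
                "sigma0": self.sigma0,
                "gamma": self.gamma.to_dict(),
                "se_sigma0": self.se_sigma0,
                "se_gamma": None if self.se_gamma is None else self.se_gamma.to_dict(),
            },
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
    def from_params(cls, params, sigma0: float, gamma,
                    convention: CenteringConvention = DEFAULT_CONVENTION,
                    **kw) -> "HeteroscedasticResults":
        """Prediction-ready chart from externally supplied coefficients."""
        return cls(params=pd.Series(params, dtype=float), sigma0=float(sigma0),
                   gamma=pd.Series(gamma, dtype=float), convention=convention,
                   nobs=kw.get("nobs"))

    @classmethod
    def from_json(cls, text_or_path) -> "HeteroscedasticResults":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                payload = json.load(fh)
        conv = CenteringConvention.from_mapping(payload.get("convention", {}))
        var = payload["variance"]
        res = cls.from_params(payload["params"], var["sigma0"], var["gamma"],
                              conv, nobs=payload.get("nobs"))
        if payload.get("bse"):
            res.bse = pd.Series(payload["bse"], dtype=float)
        return res


def fit_heteroscedastic(records, *, tol: float = 1e-8, maxiter: int = 200,
                        **kw) -> HeteroscedasticResults:
    """Convenience wrapper: construct and fit :class:`HeteroscedasticModel`."""
    return HeteroscedasticModel(records, **kw).fit(tol=tol, maxiter=maxiter)
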