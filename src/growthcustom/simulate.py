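"""Synthetic cohort generator.

Emulates the covariate structure of the NICHD Fetal Growth Studies -
Singletons term cohort (marginal means/SDs and category frequencies) and
generates birthweight from the heteroscedastic truth model

    bw ~ Normal(x' beta,  [sigma0 exp(0.5 z' gamma)]^2),

with the published customization coefficients as the default truth.
Covariates are drawn independently (only marginals are emulated; real
joint correlations, site effects and selection are not).  All randomness
flows from one seeded generator, so a config is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    DEFAULT_CONVENTION,
    CenteringConvention,
    PregnancyRecord,
    UltrasoundVisit,
    design_matrix,
)
from .gestation import ReferenceCurve
from .published import NICHD_GAMMA, NICHD_HETERO_MEAN, NICHD_SIGMA0
from .screening import morbidity_components


def _default_mean():
    return dict(NICHD_HETERO_MEAN)


def _default_gamma():
    return dict(NICHD_GAMMA)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Covariate defaults follow the published cohort summary: height
    162.8 (7.0) cm, pre-pregnancy weight 67.4 (14.9) kg, race
    NH-White/NH-Black/Hispanic/Asian-PI 28.1/26.5/29.1/16.3%, parity
    0/1/2+ 46.4/34.6/19.0%, 50.8% male, delivery GA 39.5 (1.1) weeks
    truncated to 37-41 completed weeks.  The outcome truth is the
    published heteroscedastic fit.
    """

    n: int = 2288
    seed: int = 0
    height_mean: float = 162.8
    height_sd: float = 7.0
    weight_mean: float = 67.4
    weight_sd: float = 14.9
    race_probs: tuple = (0.281, 0.265, 0.291, 0.163)  # W, B, H, A/PI
    parity_probs: tuple = (0.464, 0.346, 0.190)       # 0, 1, 2+
    male_prob: float = 0.508
    ga_mean_wk: float = 39.5
    ga_sd_wk: float = 1.1
    ga_range_wk: tuple = (37.0, 42.0)
    # pathologic covariate prevalences (cohort frequencies)
    smoking_rate: float = 0.004
    gdm_rate: float = 0.042
    hypertension_rate: float = 0.062
    bleeding_rate: float = 0.271
    # outcome truth
    mean_params: dict = field(default_factory=_default_mean)
    sigma0: float = NICHD_SIGMA0
    gamma: dict = field(default_factory=_default_gamma)
    pathologic_effects: dict = field(default_factory=dict)  # g per unit, default 0
    homoscedastic: bool = False     # force gamma = 0 (constant SD sigma0)
    # morbidity generation
    morbidity_base_rate: float = 0.04
    sga_morbidity_or: float = 2.05
    lga_morbidity_or: float = 1.80
    # longitudinal visits
    visit_weeks: tuple = (12.0, 19.0, 26.0, 31.0, 35.0, 39.0)
    efw_noise_scale: float = 1.0    # multiplies the proportional truth SD
    effect_switch_week: float | None = None  # height effect off before this week

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("race_probs", "parity_probs"):
            p = np.asarray(getattr(self, name), float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")


_RACES = ("NH-White", "NH-Black", "Hispanic", "Asian/PI")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def true_moments(records, config: SyntheticConfig,
                 conv: CenteringConvention = DEFAULT_CONVENTION):
    """Per-record true mean and SD under the config's generating model."""
    X = design_matrix(records, conv, include_pathologic=False)
    beta = pd.Series(config.mean_params, dtype=float).reindex(X.columns,
                                                              fill_value=0.0)
    mean = X.to_numpy() @ beta.to_numpy()
    if config.pathologic_effects:
        Xp = design_matrix(records, conv, include_pathologic=True)
        for col, eff in config.pathologic_effects.items():
            mean = mean + eff * Xp[col].to_numpy()
    if config.homoscedastic:
        sigma = np.full(len(records), config.sigma0)
    else:
        gamma = pd.Series(config.gamma, dtype=float).reindex(
            [c for c in X.columns if c != "intercept"], fill_value=0.0)
        Z = X[[c for c in X.columns if c != "intercept"]].to_numpy()
        sigma = config.sigma0 * np.exp(0.5 * (Z @ gamma.to_numpy()))
    return mean, sigma


def generate_cohort(config: SyntheticConfig) -> list[PregnancyRecord]:
    """Draw a synthetic delivery cohort; same config -> identical cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    height = np.round(_truncnorm(rng, config.height_mean, config.height_sd,
                                 140.0, 200.0, n), 1)
    weight = np.round(_truncnorm(rng, config.weight_mean, config.weight_sd,
                                 40.0, 130.0, n), 1)
    race = rng.choice(len(_RACES), size=n, p=config.race_probs)
    parity_cat = rng.choice(3, size=n, p=config.parity_probs)
    # the 2+ category carries real parities 2 and 3 so dummy collapsing
    # is exercised
    parity = np.where(parity_cat < 2, parity_cat,
                      2 + (rng.random(n) < 0.3).astype(int))
    sex = np.where(rng.random(n) < config.male_prob, "male", "female")
    ga_wk = _truncnorm(rng, config.ga_mean_wk, config.ga_sd_wk,
                       config.ga_range_wk[0], config.ga_range_wk[1] - 1e-9, n)
    ga_days = np.floor(ga_wk * 7.0)
    smoking = rng.random(n) < config.smoking_rate
    gdm = rng.random(n) < config.gdm_rate
    hyper = rng.random(n) < config.hypertension_rate
    bleeding = rng.random(n) < config.bleeding_rate

    records = []
    for i in range(n):
        records.append(PregnancyRecord(
            maternal_height=float(height[i]),
            maternal_weight_prepreg=float(weight[i]),
            parity=int(parity[i]),
            race=_RACES[race[i]],
            infant_sex=str(sex[i]),
            ga_delivery=float(ga_days[i]),
            birthweight=1.0,  # placeholder until the outcome draw below
            smoking=bool(smoking[i]),
            gestational_diabetes=bool(gdm[i]),
            hypertensive_disease="gestational hypertension" if hyper[i] else "none",
            antepartum_bleeding=bool(bleeding[i]),
        ))
    mean, sigma = true_moments(records, config)
    bw = rng.normal(mean, sigma)
    for rec, w in zip(records, bw):
        rec.birthweight = float(max(w, 250.0))
    return records


def true_size_status(records, config: SyntheticConfig,
                     thresholds=(0.10, 0.90)):
    """True SGA/LGA indicators under the generating model (exact normal
    quantiles of each record's own true distribution)."""
    mean, sigma = true_moments(records, config)
    bw = np.array([r.birthweight for r in records])
    z_lo, z_hi = stats.norm.ppf(thresholds[0]), stats.norm.ppf(thresholds[1])
    return bw < mean + z_lo * sigma, bw > mean + z_hi * sigma


def generate_morbidity(records, config: SyntheticConfig,
                       seed: int | None = None) -> pd.DataFrame:
    """Bernoulli morbidity component flags tied to true SGA/LGA status.

    Composite risk follows logit(p) = logit(base) + log(OR_sga)*SGA +
    log(OR_lga)*LGA; a morbid delivery gets one or two random component
    flags from the relevant list, so component-level aggregation is
    exercised.  Also stores the composites on each record.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    sga, lga = true_size_status(records, config)
    base = np.log(config.morbidity_base_rate / (1 - config.morbidity_base_rate))
    logit = base + np.log(config.sga_morbidity_or) * sga \
        + np.log(config.lga_morbidity_or) * lga
    p = 1.0 / (1.0 + np.exp(-logit))
    morbid = rng.random(len(records)) < p

    all_cols = sorted(set(morbidity_components("SGA")) | set(morbidity_components("LGA")))
    flags = pd.DataFrame(False, index=range(len(records)), columns=all_cols)
    shared = [c for c in all_cols if c in morbidity_components("SGA")
              and c in morbidity_components("LGA")]
    for i, m in enumerate(morbid):
        if not m:
            continue
        k = 1 + int(rng.random() < 0.25)
        for c in rng.choice(shared, size=k, replace=False):
            flags.loc[i, c] = True
    from .screening import composite_morbidity
    comp_sga = composite_morbidity(flags, "SGA")
    comp_lga = composite_morbidity(flags, "LGA")
    for i, rec in enumerate(records):
        rec.morbidity_sga = bool(comp_sga.iloc[i])
        rec.morbidity_lga = bool(comp_lga.iloc[i])
    return flags


def generate_visits(records, config: SyntheticConfig,
                    curve: ReferenceCurve | None = None,
                    seed: int | None = None) -> None:
    """Attach longitudinal EFW visits following the study schedule.

    EFW at GA t is proportion(t) times the record's true term mean plus
    proportional noise.  With ``effect_switch_week`` set, the maternal
    height contribution to the mean is zeroed for visits before that
    week (a built-in oracle for trend detection across gestation).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    if curve is None:
        curve = ReferenceCurve.default()
    mean, sigma = true_moments(records, config)
    if config.effect_switch_week is not None:
        cfg_off = replace(config, mean_params={
            **config.mean_params, "height": 0.0, "height2": 0.0, "height3": 0.0})
        mean_off, _ = true_moments(records, cfg_off)
    else:
        mean_off = mean
    lo, hi = curve.support
    for i, rec in enumerate(records):
        rec.visits = []
        for wk in config.visit_weeks:
            ga = (wk + rng.uniform(-1.0, 1.0)) * 7.0
            if not (lo <= ga < min(hi, rec.ga_delivery)):
                continue
            prop = curve.proportion(ga)
            m = mean[i] if (config.effect_switch_week is None
                            or ga >= config.effect_switch_week * 7.0) else mean_off[i]
            efw = prop * m + rng.normal(0.0, config.efw_noise_scale * prop * sigma[i])
            rec.visits.append(UltrasoundVisit(ga=float(ga),
                                              efw=float(max(efw, 50.0))))
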