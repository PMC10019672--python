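"""Published customization coefficients from the NICHD Fetal Growth
Studies - Singletons cohort (N = 2,288; term deliveries, 37-41 weeks).

These are the printed coefficient tables of the source study's three
customization models over the shared design (centred at 280 days,
163 cm, 64 kg, nulliparous, NH-White; sex effect-coded).  They serve two
roles here: prediction-ready charts for worked examples, and the default
truth for the synthetic cohort generator.  Printed values are rounded
(mostly 3 decimals; the variance coefficients carry the extra precision
given in the published worked-example footnote where available), so
chart values reproduce the published worked examples to within a gram
or two.

Pathologic adjustment coefficients were not published and are therefore
absent: charts built from these sets predict from physiologic columns
only, which is also how every engine predicts by design.
"""

from __future__ import annotations

from .gardosi import GardosiResults
from .heteroscedastic import HeteroscedasticResults
from .quantile import QuantileResults

#: constant-CV (Gardosi-style) mean model, g per unit of each column
NICHD_GARDOSI_MEAN = {
    "intercept": 3509.722,
    "ga": 14.944, "ga2": -0.282, "ga3": 0.026,
    "sex": 67.048,
    "height": 5.864, "height2": 0.041, "height3": -0.001,
    "weight": 7.720, "weight2": -0.114, "weight3": 0.000,
    "race_nh_black": -189.435, "race_hispanic": -54.454, "race_asian_pi": -49.903,
    "parity_1": 92.614, "parity_2plus": 101.536,
}

#: study-population coefficient of variation for the constant-CV chart
NICHD_CV = 0.129

#: heteroscedastic mean model
NICHD_HETERO_MEAN = {
    "intercept": 3510.000,
    "ga": 14.944, "ga2": -0.293, "ga3": 0.025,
    "sex": 67.048,
    "height": 5.861, "height2": 0.034, "height3": 0.000,
    "weight": 7.721, "weight2": -0.119, "weight3": 0.000,
    "race_nh_black": -189.435, "race_hispanic": -54.454, "race_asian_pi": -49.903,
    "parity_1": 92.614, "parity_2plus": 101.536,
}

#: baseline SD at the reference profile, grams (worked-example precision)
NICHD_SIGMA0 = 374.5975

#: log-variance-scale slopes; worked-example precision where published,
#: otherwise the 3-decimal table values.  The published worked example
#: also contains one extra "+0.0236*(0)" term that cannot be matched to
#: any printed variance row (its covariate is zero at every published
#: profile); it is not represented here.
NICHD_GAMMA = {
    "ga": -0.003582, "ga2": -0.000112, "ga3": -0.000003257,
    "sex": 0.025,
    "height": -0.0123, "height2": -0.000357, "height3": 0.0000472,
    "weight": 0.0145, "weight2": -0.000103, "weight3": -0.0000028,
    "race_nh_black": -0.1109, "race_hispanic": -0.0107, "race_asian_pi": -0.0407,
    "parity_1": 0.0394, "parity_2plus": 0.0403,
}

#: quantile-regression coefficients per target percentile
NICHD_QUANTILE = {
    0.10: {
        "intercept": 3069.076,
        "ga": 13.366, "ga2": -0.389, "ga3": 0.027,
        "sex": 55.752,
        "height": 9.412, "height2": 0.173, "height3": -0.018,
        "weight": 4.751, "weight2": -0.086, "weight3": -0.001,
        "race_nh_black": -182.776, "race_hispanic": -77.925, "race_asian_pi": -9.154,
        "parity_1": 72.759, "parity_2plus": 117.866,
    },
    0.50: {
        "intercept": 3486.616,
        "ga": 17.147, "ga2": -0.403, "ga3": 0.008,
        "sex": 66.499,
        "height": 5.306, "height2": 0.130, "height3": 0.002,
        "weight": 7.395, "weight2": -0.157, "weight3": 0.001,
        "race_nh_black": -193.922, "race_hispanic": -65.586, "race_asian_pi": -69.425,
        "parity_1": 97.666, "parity_2plus": 102.512,
    },
    0.90: {
        "intercept": 4041.833,
        "ga": 8.282, "ga2": -0.269, "ga3": 0.042,
        "sex": 71.076,
        "height": -4.789, "height2": -0.081, "height3": 0.020,
        "weight": 13.533, "weight2": -0.203, "weight3": -0.001,
        "race_nh_black": -225.116, "race_hispanic": -74.850, "race_asian_pi": -79.243,
        "parity_1": 59.634, "parity_2plus": 45.780,
    },
}

NICHD_N = 2288


def nichd_gardosi_results() -> GardosiResults:
    """Prediction-ready constant-CV chart at the published coefficients."""
    return GardosiResults.from_params(NICHD_GARDOSI_MEAN, cv=NICHD_CV, nobs=NICHD_N)


def nichd_heteroscedastic_results() -> HeteroscedasticResults:
    """Prediction-ready heteroscedastic chart at the published coefficients."""
    return HeteroscedasticResults.from_params(
        NICHD_HETERO_MEAN, sigma0=NICHD_SIGMA0, gamma=NICHD_GAMMA, nobs=NICHD_N)


def nichd_quantile_results() -> QuantileResults:
    """Prediction-ready quantile-regression chart at the published
    tau = 0.10 / 0.50 / 0.90 coefficients."""
    return QuantileResults.from_params(NICHD_QUANTILE, nobs=NICHD_N)
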