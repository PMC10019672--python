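import numpy as np
import pytest

import growthcustom as gc
from growthcustom.cohort import build_design_row
from growthcustom.published import (
    nichd_gardosi_results,
    nichd_heteroscedastic_results,
    nichd_quantile_results,
)


@pytest.fixture(scope="session")
def small_cohort():
    """600 synthetic deliveries at the published truth (fast fits)."""
    return gc.generate_cohort(gc.SyntheticConfig(n=600, seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """3000 synthetic deliveries at the published truth."""
    return gc.generate_cohort(gc.SyntheticConfig(n=3000, seed=7))


@pytest.fixture(scope="session")
def gardosi_chart():
    return nichd_gardosi_results()


@pytest.fixture(scope="session")
def hetero_chart():
    return nichd_heteroscedastic_results()


@pytest.fixture(scope="session")
def quantile_chart():
    return nichd_quantile_results()


@pytest.fixture(scope="session")
def weight_profiles():
    """The three worked maternal-weight profiles (25th/50th/75th weight
    percentile), all other covariates at reference, sex-averaged; keyed by
    the centred weight deviation used in the published worked example."""
    return {
        56.7: build_design_row(weight_dev=-7.301),
        63.5: build_design_row(weight_dev=-0.5),
        74.8: build_design_row(weight_dev=10.8),
    }
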