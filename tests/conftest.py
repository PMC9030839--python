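import numpy as np
import pytest

import finvuln as fv


@pytest.fixture(scope="session")
def urban_panel():
    """A medium synthetic urban panel with its ground-truth sidecar."""
    spec = fv.urban_spec(n_households=500, seed=20260923)
    panel, truth = fv.generate_panel(spec)
    return spec, panel, truth


@pytest.fixture(scope="session")
def fitted_models(urban_panel):
    """FGLS margins and Gaussian copula fitted on the session panel."""
    spec, panel, _ = urban_panel
    income = fv.fit_fgls(panel, "income", fv.INCOME_COVARIATES)
    medical = fv.fit_fgls(panel, "medical", fv.MEDICAL_COVARIATES)
    pairs = fv.pseudo_observations(income, medical, panel)
    copula = fv.fit_copula_mle("gaussian", pairs)
    return income, medical, copula


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
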