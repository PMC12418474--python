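import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from npxfactor.simulate import SimConfig, gen_matched_cohort
from npxfactor.tiered import fit_ols


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic matched cohort (19 subjects, 200 proteins)."""
    return gen_matched_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort without outliers or low-variance proteins (expected R2 ~0.8)."""
    config = SimConfig(n_proteins=150, outlier_fraction=0.0,
                       low_variance_fraction=0.0, seed=11)
    return gen_matched_cohort(config)


def brute_force_cooks(x, y):
    """Leave-one-out Cook's distances: scaled sum of squared changes in all
    fitted values when each sample is deleted in turn."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    full = fit_ols(x, y)
    base = full.intercept + full.slope * x
    n, p = x.size, 2
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        sub = fit_ols(x[mask], y[mask])
        pred = sub.intercept + sub.slope * x
        out[i] = ((base - pred) ** 2).sum() / (p * full.sigma2)
    return out
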