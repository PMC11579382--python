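import numpy as np
import pandas as pd
import pytest

from growthgwas import ModelSpec, SplineSpec, fit_lmm
from growthgwas.simulate import default_config, simulate_cohort

EQ1_SPEC = ModelSpec(
    fixed=SplineSpec("cubic_spline", (1.0, 8.0, 12.0)),
    random=SplineSpec("cubic_slope"),
    correlation="none",
)


def cohort_table(records):
    """Modelling table straight from simulator truth (no QC noise)."""
    out = records.copy()
    out["log_bmi"] = np.log(out["weight"] / out["height"] ** 2)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    cfg = default_config(n_subjects=200, seed=3)
    records, truth = simulate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def fitted_male(small_cohort):
    cfg, records, truth = small_cohort
    table = cohort_table(records)
    male = table[table["sex"] == "male"]
    fit = fit_lmm(male, EQ1_SPEC)
    assert fit.ok
    return fit, male
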