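import numpy as np
import pandas as pd
import pytest

from absrisk import Covariate, ModelSpec, RateTable, SnpInfo


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_spec():
    """Binary family history + 3-level categorical BMI group with an
    interaction between them."""
    return ModelSpec(
        covariates=[
            Covariate("famhist", "continuous"),
            Covariate("bmi", "categorical", ("low", "mid", "high")),
        ],
        interactions=[("famhist", "bmi")],
        log_relative_risks={
            "famhist": 0.5,
            "bmi[mid]": 0.1,
            "bmi[high]": 0.3,
            "famhist:bmi[mid]": -0.05,
            "famhist:bmi[high]": 0.12,
        },
        family_history="famhist",
    )


@pytest.fixture
def toy_reference(rng):
    n = 2000
    return pd.DataFrame(
        {
            "famhist": rng.integers(0, 2, n),
            "bmi": rng.choice(["low", "mid", "high"], n, p=[0.4, 0.35, 0.25]),
        }
    )


@pytest.fixture
def flat_incidence():
    return RateTable([1], [90], [0.003])


@pytest.fixture
def flat_mortality():
    return RateTable([1], [90], [0.01])


@pytest.fixture
def toy_snps():
    return SnpInfo(("rs1", "rs2", "rs3"), [1.3, 0.8, 1.1], [0.2, 0.5, 0.35])
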