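import numpy as np
import pandas as pd
import pytest

from vitdmr import CausalModel, GeneratorConfig, add_pgs, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default cohort (n = 1,426), PGS attached."""
    return add_pgs(generate_cohort(default_config))


@pytest.fixture(scope="session")
def linear_cohort():
    """Large cohort with a linear causal effect of 0.05 log-odds per ng/mL."""
    cfg = GeneratorConfig(
        n_participants=8000, seed=12,
        causal_model=CausalModel("linear", slope=0.05),
    )
    return add_pgs(generate_cohort(cfg))


@pytest.fixture()
def toy_waves():
    """Hand-enumerable 12-row table of SI wave patterns.

    Rows (w1, w2, w3):  yes/no/missing coded 1/0/NA.
      0: (0,0,0)  1: (0,1,0)  2: (0,0,1)  3: (0,1,1)
      4: (1,0,0)  5: (1,1,1)  6: (0,NA,0) 7: (0,NA,1)
      8: (0,0,NA) 9: (0,1,NA) 10:(NA,0,0) 11:(1,NA,NA)
    """
    w1 = pd.array([0, 0, 0, 0, 1, 1, 0, 0, 0, 0, pd.NA, 1], dtype="Int64")
    w2 = pd.array([0, 1, 0, 1, 0, 1, pd.NA, pd.NA, 0, 1, 0, pd.NA], dtype="Int64")
    w3 = pd.array([0, 0, 1, 1, 0, 1, 0, 1, pd.NA, pd.NA, 0, pd.NA], dtype="Int64")
    return pd.DataFrame({"si_w1": w1, "si_w2": w2, "si_w3": w3,
                         "sp_w1": w1, "sp_w2": w2, "sp_w3": w3,
                         "sa_w1": w1, "sa_w2": w2, "sa_w3": w3})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
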