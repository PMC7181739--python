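import numpy as np
import pandas as pd
import pytest

import methcorr as mc


@pytest.fixture()
def small_beta():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(rng.uniform(0, 1, size=(6, 5)),
                        index=[f"cg{i}" for i in range(6)],
                        columns=[f"S{i}" for i in range(5)])
    return mc.BetaMatrix(data)


@pytest.fixture(scope="session")
def sim_cohort():
    """A small synthetic cohort shared by integration-style tests."""
    ref = mc.simulate_reference(4, 400, 20, seed=5, n_genes=30)
    beta, expr, truth = mc.simulate_cohort(ref, 120, 30, 30, seed=5)
    return beta, expr, truth


@pytest.fixture(scope="session")
def sim_pipeline(sim_cohort):
    beta, expr, truth = sim_cohort
    config = mc.RunConfig(seed=5, cv_repeats=2)
    return mc.run_pipeline_arrays(expr, beta, config), truth
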