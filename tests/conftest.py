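import numpy as np
import pytest

import explirt as ex


@pytest.fixture(scope="session")
def null_dataset():
    """Covariate-free generating conditions at modest size."""
    return ex.simulate_dataset(ex.null_config(n_persons=400, seed=7))


@pytest.fixture(scope="session")
def paper_like_dataset():
    """Default (fully parameterised) study conditions at n=573."""
    return ex.simulate_dataset(ex.GenerationConfig(seed=42))


@pytest.fixture(scope="session")
def rasch_fit(null_dataset):
    return ex.RaschModel(null_dataset.responses).fit()


@pytest.fixture(scope="session")
def filtered_paper_tables(paper_like_dataset):
    ds = paper_like_dataset
    responses, covariates, _ = ex.filter_complete_cases(ds.responses, ds.covariates)
    return responses, covariates
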