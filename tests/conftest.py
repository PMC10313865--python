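import numpy as np
import pandas as pd
import pytest

from stratcrt import SimScenario, generate_trial

TOY_SEED = 20230314


@pytest.fixture(scope="session")
def toy_scenario() -> SimScenario:
    """8 clusters (2 strata x 2 arms x 2 clusters) of 4 observations each."""
    return SimScenario(
        clusters_per_stratum=4, cluster_size=4, icc=0.3, beta1=0.5, beta2=0.3
    )


@pytest.fixture(scope="session")
def toy_trial(toy_scenario) -> pd.DataFrame:
    """Frozen small trial used for all reference-implementation checks."""
    return generate_trial(toy_scenario, np.random.default_rng(TOY_SEED))
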