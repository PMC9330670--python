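import numpy as np
import pytest

import erpstrat as es


@pytest.fixture(scope="session")
def inventory():
    return es.build_feature_inventory()


@pytest.fixture(scope="session")
def null_cohort():
    """Mid-size cohort with no planted effects."""
    cfg = es.GeneratorConfig(n_per_group={"TL": 60, "EL-noASD": 60, "EL-ASD": 60},
                             effects=[], outcome_beta={}, seed=11)
    return es.generate_feature_table(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort at the study's group composition with the default effects."""
    cfg = es.GeneratorConfig(seed=2)
    return es.generate_feature_table(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
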