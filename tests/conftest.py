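import numpy as np
import pytest

from faerspv import SMQDefinition, build_cohort, deduplicate
from faerspv import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.default_config(n_reports=4000, seed=11)


@pytest.fixture(scope="session")
def small_records(small_config):
    return syn.generate(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_records):
    smq = SMQDefinition("renal", frozenset(syn.renal_pt_list(small_config)))
    return build_cohort(deduplicate(small_records), small_config.lexicon(), smq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
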