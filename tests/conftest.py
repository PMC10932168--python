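import numpy as np
import pytest

from dsbrepair import study_data


def reconstruct_rank_data():
    """The 90 subjects implied by the published 2 x 4 repair-group table,
    as (X, y) with the single rank feature coded 0..3 (3 = no repair)."""
    x1, y = [], []
    for code in range(4):
        x1 += [code] * study_data.REPAIR_GROUP_COUNTS["control"][code]
        y += [0] * study_data.REPAIR_GROUP_COUNTS["control"][code]
        x1 += [code] * study_data.REPAIR_GROUP_COUNTS["case"][code]
        y += [1] * study_data.REPAIR_GROUP_COUNTS["case"][code]
    return np.array(x1)[:, None], np.array(y)


@pytest.fixture(scope="session")
def rank_data():
    return reconstruct_rank_data()


@pytest.fixture(scope="session")
def small_config():
    from dsbrepair import default_config
    return default_config(n_cases=45, n_controls=45, seed=7)
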