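import numpy as np
import pandas as pd
import pytest

import oddrsa as od
from oddrsa.preprocess import EpochsArray


@pytest.fixture(scope="session")
def table():
    return od.make_default_character_table(1)


@pytest.fixture(scope="session")
def montage():
    return od.default_montage()


@pytest.fixture(scope="session")
def small_session(table):
    """A small session design: 24-trial equal block + 24-trial oddball blocks."""
    return od.generate_session(
        table, n_trials_oddball=24, n_trials_equal=24, p_target=0.0, seed=7
    )


def make_epochs(
    data: np.ndarray,
    channel_names,
    roles=None,
    categories=None,
    characters=None,
    blocks=None,
    srate=1000.0,
    window_ms=(-300.0, 700.0),
) -> EpochsArray:
    """Hand-built EpochsArray with minimal metadata for unit tests."""
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "sample": np.arange(n) * 1000 + 1000,
            "block": blocks if blocks is not None else ["equal_probability"] * n,
            "index": np.arange(n),
            "character_id": characters if characters is not None else ["x"] * n,
            "category": categories if categories is not None else ["CC"] * n,
            "role": roles if roles is not None else ["equiprobable"] * n,
            "is_target": [False] * n,
        }
    )
    return EpochsArray(
        data=np.asarray(data, dtype=float),
        srate=srate,
        window_ms=window_ms,
        channel_names=tuple(channel_names),
        meta=meta,
        retained_mask=np.ones(n, dtype=bool),
    )
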