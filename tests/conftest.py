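import numpy as np
import pytest

from hsisort import library_for_pair, make_seed_stream


def balanced_pair_table(pair, lib_seed=1, stream_seed=2, n=200, **stream_kwargs):
    """Roughly balanced legume/contaminant spectrum table for one pair."""
    lib = library_for_pair(*pair, rng_seed=lib_seed)
    table = make_seed_stream(
        n, {pair[1]: 0.99}, lib, orientation_noise=0.0,
        rng_seed=stream_seed, legume_class=pair[0], **stream_kwargs,
    )
    return lib, table


@pytest.fixture(scope="session")
def bw_library():
    """Two-class broad-bean/wheat library (planted bands 810 and 1455 nm)."""
    return library_for_pair("broad_bean", "wheat", rng_seed=1)


@pytest.fixture(scope="session")
def bw_table(bw_library):
    return make_seed_stream(
        200, {"wheat": 0.99}, bw_library, orientation_noise=0.0,
        rng_seed=2, legume_class="broad_bean",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
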