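import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from deltat1.lookup import build_lookup
from deltat1.phantom import (
    PhantomConfig,
    apply_gadolinium,
    build_phantom,
    default_tissues,
    simulate_acquisition,
)
from deltat1.pipeline import compute_delta_t1, reconstruct_t1_map
from deltat1.protocol import SequenceProtocol


@pytest.fixture(scope="session")
def protocol():
    return SequenceProtocol()


@pytest.fixture(scope="session")
def lookup(protocol):
    return build_lookup(protocol)


@pytest.fixture(scope="session")
def noiseless_phantom(protocol, lookup):
    """One noiseless 64^3 phantom pushed through the full chain.

    Ground truth uses the cohort-median tissue T1 values and gadolinium
    shifts; shared across tests that only read from it.
    """
    config = PhantomConfig(
        shape=(64, 64, 64),
        lesion_count=5,
        lesion_radius_range=(2.5, 4.0),
        el_fraction=0.2,
        seed=1,
    )
    gt = apply_gadolinium(build_phantom(config, default_tissues(nawm_delta=-0.004)))
    rec_pre = reconstruct_t1_map(
        *simulate_acquisition(gt, protocol, phase="pre"), protocol, lookup
    )
    rec_post = reconstruct_t1_map(
        *simulate_acquisition(gt, protocol, phase="post"), protocol, lookup
    )
    delta = compute_delta_t1(
        rec_pre.t1, rec_post.t1, rec_pre.qc_exclude, rec_post.qc_exclude
    )
    return {
        "gt": gt,
        "pre": rec_pre,
        "post": rec_post,
        "delta": delta,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
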