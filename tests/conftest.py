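import numpy as np
import pytest

from telemeg import synth


@pytest.fixture(scope="session")
def array64():
    """64-channel triaxial synthetic sensor array."""
    return synth.gen_sensor_array(64)


@pytest.fixture(scope="session")
def small_block_session():
    """A short block-design telemetry session (3 trials/condition, 1 block)."""
    truth = synth.GroundTruth(n_trials_per_block=3, n_blocks=1)
    return synth.gen_block_telemetry(truth, seed=7)


def random_hmm_params(rng, k, d):
    """Random valid HMM parameters for oracle comparisons."""
    from telemeg.hmm import HmmParams
    trans = rng.dirichlet(np.ones(k), size=k)
    init = rng.dirichlet(np.ones(k))
    means = rng.normal(scale=2.0, size=(k, d))
    covs = np.stack([np.diag(rng.uniform(0.5, 2.0, size=d)) for _ in range(k)])
    return HmmParams(init, trans, means, covs)
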