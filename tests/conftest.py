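import numpy as np
import pytest

from compfit import AlleleTrajectory, predict_frequency


@pytest.fixture
def noiseless_trajectories():
    """Three replicates generated exactly by the selection model closed form
    (p0=0.5, w=1.3), measured at the odd generations of the protocol."""
    gens = (1, 3, 5, 7)
    props = tuple(predict_frequency(0.5, 1.3, t) for t in gens)
    return [
        AlleleTrajectory(pair_label="noiseless", replicate_id=f"rep{i}",
                         generations=gens, proportions=props)
        for i in range(1, 4)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
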