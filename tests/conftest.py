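import numpy as np
import pytest

from ionspike import synapses, synthetic
from ionspike.cable import MembraneParams
from ionspike.morphology import Morphology, Segment


@pytest.fixture(scope="session")
def soma_morph() -> Morphology:
    """Single cylindrical soma, 20 um high and wide."""
    return Morphology(
        [Segment(0, -1, np.zeros(3), np.array([0.0, 20.0, 0.0]), 20.0, 20.0, "soma")]
    )


@pytest.fixture(scope="session")
def tree_morph() -> Morphology:
    return synthetic.make_random_tree(synthetic.SyntheticTreeSpec(), seed=1)


@pytest.fixture(scope="session")
def membrane_params() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def calibrated_weight(tree_morph, membrane_params) -> float:
    """Threshold-baseline synaptic weight on the session tree (uncorrelated
    10 Hz, 1 s protocol, fixed protocol seed)."""
    return synapses.calibrate_baseline_weight(
        tree_morph, membrane_params, duration=1000.0, seed=3
    )
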