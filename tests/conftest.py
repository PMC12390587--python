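import numpy as np
import pytest

from handvein.segmentation import extract_fingers, reorder_fingers
from handvein.synth import make_identity, render_hand


@pytest.fixture(scope="session")
def rendered_hand():
    """One deterministic right-hand render with full ground truth."""
    identity = make_identity(123, "RH")
    return render_hand(identity, sample_seed=1)


@pytest.fixture(scope="session")
def segmented_hand(rendered_hand):
    """Complete, anatomically ordered segmentation of the shared render."""
    result = extract_fingers(rendered_hand.image)
    assert result.complete
    return reorder_fingers(result, "RH")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
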