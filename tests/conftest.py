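import numpy as np
import pytest

# Independent hand-arithmetic of the ten-layer formula at the canonical
# wild-type landmarks (on=0.40, divider=0.60, off=0.77), frozen before the
# implementation was written:
#   u = 0.40/7; layers 1-3 end at 2u, 4u, 6u
#   layer 4 ends at 0.40 + (0.60-0.40)/4            = 0.45
#   layer 5 ends at 0.45 + (0.60-0.40)/2            = 0.55
#   layer 6 ends at 0.60 + (0.77-0.60)/4            = 0.6425
#   layer 7 ends at 0.6425 + (0.77-0.60)/2          = 0.7275
#   layer 8 ends at 0.77 + (1-0.77)/5               = 0.816
#   layer 9 ends at 0.816 + 2*(1-0.816)/... -> 0.77 + 3*(1-0.77)/5 = 0.908
CANONICAL_BOUNDARIES = np.array([
    0.0, 0.8 / 7, 1.6 / 7, 2.4 / 7,
    0.45, 0.55, 0.6425, 0.7275, 0.816, 0.908, 1.0,
])


@pytest.fixture
def canonical_boundaries():
    return CANONICAL_BOUNDARIES.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
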