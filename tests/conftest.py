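import numpy as np
import pytest

import liftqc as lq


@pytest.fixture
def grid_design():
    """The screening layout: a 4×4 droplet grid at 500 µm spacing."""
    return lq.PatternDesign.grid(4, 4, 500.0)


@pytest.fixture
def noiseless_print(grid_design):
    """A perfect print: every target occupied by an identical disk."""
    params = lq.SynthPrintParams(
        design=grid_design,
        transfer_prob=1.0,
        diameter_cv=0.0,
        placement_jitter_sd=0.0,
        satellite_rate=0.0,
        ellipticity=0.0,
        pixel_size=2.0,
        seed=11,
    )
    return lq.generate_print(params)


@pytest.fixture
def disk_mask():
    """Single solid disk of radius 35 px in a labelled mask."""
    from skimage.draw import disk

    mask = np.zeros((100, 100), dtype=np.uint16)
    rr, cc = disk((50, 50), 35)
    mask[rr, cc] = 1
    return mask
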