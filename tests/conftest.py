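import numpy as np
import pytest

from echoseg import phantom


@pytest.fixture(scope="session")
def default_scene():
    return phantom.generate_scene(seed=0)


@pytest.fixture(scope="session")
def default_frame_labels(default_scene):
    return phantom.render(default_scene)


@pytest.fixture(scope="session")
def leaked_maps():
    """Label maps with an injected right-ventricle leak crossing the
    right atrium's top row by >= 20 rows, plus the clean originals."""
    out = []
    for seed in range(30):
        scene = phantom.generate_scene(seed=seed)
        _, labels = phantom.render(scene)
        rv_rows = np.flatnonzero((labels == 3).any(axis=1))
        ra_rows = np.flatnonzero((labels == 4).any(axis=1))
        extent = int(ra_rows[0] - rv_rows[-1] + 25)
        leaked = phantom.inject_leak(labels, from_class=3, extent=extent, seed=seed)
        out.append((labels, leaked))
    return out
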