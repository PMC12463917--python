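import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import fruitdefect as fd


@pytest.fixture(scope="session")
def sound_scene():
    return fd.render_scene(fd.SceneParams(seed=101), label="sound")


@pytest.fixture(scope="session")
def one_defect_scene():
    """A single 12-px point defect wholly inside the interior pass-1 window (1, 1)."""
    params = fd.SceneParams(
        defect_specs=(fd.DefectSpec(kind="point_like", center=(150.0, 150.0), radii=(12.0, 12.0)),),
        seed=102,
    )
    return fd.render_scene(params, label="point")


@pytest.fixture(scope="session")
def stem_only_scene():
    params = fd.SceneParams(
        stem_spec=fd.StemSpec(center=(200.0, 120.0), radii=(30.0, 20.0), angle=15.0, hue=30),
        seed=103,
    )
    return fd.render_scene(params, label="stem")


@pytest.fixture(scope="session")
def three_defect_scene():
    """Three well-separated high-contrast point defects."""
    mk = lambda c: fd.DefectSpec(kind="point_like", center=c, radii=(15.0, 13.0))
    params = fd.SceneParams(
        defect_specs=(mk((140.0, 130.0)), mk((270.0, 160.0)), mk((190.0, 290.0))),
        seed=104,
    )
    return fd.render_scene(params, label="point")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
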