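import numpy as np
import pytest

import regcdi
from regcdi.pipeline import default_index


def make_series(values, start=(2001, 1), variable="var", **kw):
    """Small GriddedSeries helper; values may be 1-D (one pixel) or 3-D."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None, None]
    y0, m0 = start
    ts = [((y0 + (m0 - 1 + t) // 12), (m0 - 1 + t) % 12 + 1)
          for t in range(values.shape[0])]
    return regcdi.GriddedSeries(values=values, timestamps=ts,
                                variable=variable, **kw)


@pytest.fixture(scope="session")
def scene():
    """Default synthetic scene (seed 1): two imposed episodes, 19 years."""
    return regcdi.generate_scene(regcdi.SceneConfig(seed=1))


@pytest.fixture(scope="session")
def index_result(scene):
    """Combined index from the default SMCI/TCI/SIWSI-1 triple."""
    return default_index(scene.ssm, scene.lst, scene.swir1, scene.nir)
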