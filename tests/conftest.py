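import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon, box

from denscape import (
    FEATURES,
    LandscapeMap,
    default_truth,
    generate_choice_data,
)


@pytest.fixture(scope="session")
def toy_landscape() -> LandscapeMap:
    """Small hand-built mosaic: every class present, two roads.

    Laid out on a 100 x 100 m square; grassland is the 40x100 west strip,
    the rest tile the east side.
    """
    return LandscapeMap(
        class_layers={
            "grassland": [box(0, 0, 40, 100)],
            "plantation": [box(40, 0, 70, 50)],
            "agricultural": [box(40, 50, 70, 100)],
            "fallow": [box(70, 0, 100, 40)],
            "ploughed": [box(70, 40, 100, 70)],
            "built_up": [box(70, 70, 100, 100)],
        },
        roads=[LineString([(0, 5), (100, 5)]), LineString([(95, 0), (95, 100)])],
    )


@pytest.fixture(scope="session")
def choice_df() -> pd.DataFrame:
    return generate_choice_data(80, 4, default_truth(), seed=42)


@pytest.fixture(scope="session")
def ratio_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        np.abs(rng.normal(1.0, 0.3, size=(26, 7))), columns=list(FEATURES)
    )
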