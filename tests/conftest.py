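import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phenofish.trajio import ArenaSpec, behavior_tank_arena


@pytest.fixture
def arena():
    """Trapezoid behavior tank at 10 fps (fast test rate)."""
    return behavior_tank_arena(fps=10.0)


@pytest.fixture
def big_arena():
    """Large open square arena: negligible boundary effects at 10 fps."""
    return ArenaSpec(polygon_cm=((0, 0), (100, 0), (100, 100), (0, 100)),
                     water_level_cm=100.0, px_per_cm=1.0,
                     y_axis="physical-up", fps=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
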