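import numpy as np
import pytest

from aacscore import PhantomConfig, generate_cohort, generate_phantom
from aacscore.landmarks import CORNER_KEYS, Landmark, Vertebra, VertebraSet


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def mixed_phantom(default_config):
    """One phantom with a known mixed grade pattern."""
    return generate_phantom(default_config,
                            {("L3", "anterior"): 2, ("L4", "posterior"): 1})


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(12, "paper_like", seed=11)


def make_axis_aligned_vertebrae(x_left=10.0, x_right=52.0, y_top=20.0,
                                length=60.0, gap=10.0):
    """Hand-buildable axis-aligned L1-L5 column for geometry oracles."""
    vertebrae = []
    for i, level in enumerate(("L1", "L2", "L3", "L4", "L5")):
        yt = y_top + i * (length + gap)
        yb = yt + length
        corners = {
            "upper_left": Landmark(x_left, yt),
            "upper_right": Landmark(x_right, yt),
            "lower_left": Landmark(x_left, yb),
            "lower_right": Landmark(x_right, yb),
        }
        vertebrae.append(Vertebra(level=level, corners=corners))
    return VertebraSet(vertebrae)


def transform_vertebrae(vs: VertebraSet, rotation_deg=0.0, dx=0.0, dy=0.0,
                        center=(0.0, 0.0)):
    """Apply a rigid motion to every corner landmark."""
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    cx, cy = center
    out = []
    for v in vs:
        corners = {}
        for k in CORNER_KEYS:
            p = v.corners[k].as_array() - (cx, cy)
            q = rot @ p + (cx + dx, cy + dy)
            corners[k] = Landmark(float(q[0]), float(q[1]))
        out.append(Vertebra(level=v.level, corners=corners))
    return VertebraSet(out)
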