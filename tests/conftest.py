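import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cutoutfactor import fit_curve

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def six_cm_curve():
    """Rising curve over the standard 1-6 cm protocol, plateauing at 1.0."""
    return fit_curve([1, 2, 3, 4, 5, 6], [0.5, 0.8, 0.95, 1.0, 1.0, 1.0])


@pytest.fixture
def three_annulus_curve():
    """Tiny curve whose kernel is fully enumerable by hand:

    OF(0)=0, OF(1 mm)=0.10, OF(2 mm)=0.15, constant after -> annular output
    factors 0.10, 0.05, 0 at 1 mm annuli.
    """
    return fit_curve([0.1, 0.2, 0.3], [0.10, 0.15, 0.15])


def random_star_polygon(rng: np.random.Generator, n_min=5, n_max=20) -> np.ndarray:
    """Random simple polygon, star-shaped about the origin.

    Angular gaps between consecutive vertices are kept below pi so the origin
    lies in the polygon's kernel, which guarantees simplicity for any radii.
    """
    n = int(rng.integers(n_min, n_max + 1))
    gaps = rng.uniform(0.5, 1.0, size=n)
    theta = 2.0 * np.pi * np.cumsum(gaps) / gaps.sum()
    r = rng.uniform(0.5, 3.0, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
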