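import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from invasionscope.geo_profile import GridSpec, OccurrenceRecord  # noqa: E402


@pytest.fixture
def small_grid():
    """5x5 grid around (14.4E, 40.7N), 0.01 degree cells."""
    return GridSpec(14.40, 14.45, 40.70, 40.75, 0.01)


@pytest.fixture
def three_occurrences():
    return [
        OccurrenceRecord("a", 14.41, 40.71, 50.0),
        OccurrenceRecord("b", 14.43, 40.72, 80.0),
        OccurrenceRecord("c", 14.44, 40.74, 120.0),
    ]


def brute_force_dragnet(occurrences, grid, beta=1.0, sigma=None):
    """Independent direct double-loop Dragnet oracle (no vectorisation)."""
    import math

    R = 6371.0088

    def hav(lon1, lat1, lon2, lat2):
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dl = math.radians(lon2 - lon1)
        dp = p2 - p1
        a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
        return 2 * R * math.asin(math.sqrt(a))

    if sigma is None:
        pts = [(o.longitude, o.latitude) for o in occurrences]
        dists = [
            hav(*pts[i], *pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        sigma = sum(dists) / len(dists)
    out = np.zeros(grid.shape)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            lon, lat = grid.cell_center(r, c)
            total = 0.0
            for o in occurrences:
                d = hav(lon, lat, o.longitude, o.latitude)
                total += math.exp(-beta * d / sigma)
            out[r, c] = total / len(occurrences)
    return out
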