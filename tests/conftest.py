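import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sssltools.genetic_map import CMInterval, GeneticMap, Marker, SubstitutedSegment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_map() -> GeneticMap:
    """Six markers on chromosome 1 at hand-chosen positions."""
    return GeneticMap(
        [
            Marker("F0", 1, 8.0),
            Marker("M1", 1, 10.0),
            Marker("M2", 1, 14.0),
            Marker("M3", 1, 20.0),
            Marker("F1", 1, 24.0),
            Marker("END", 1, 30.0),
        ]
    )


def interval_library(
    intervals: dict[str, tuple[float, float]], chromosome: int = 1
) -> tuple[GeneticMap, dict[str, SubstitutedSegment]]:
    """Build a map and segments whose cM intervals are exactly the given
    (start, end) pairs: inner markers at both endpoints, no flanks."""
    markers = []
    segments = {}
    for line, (a, b) in intervals.items():
        if b < a:
            raise ValueError("need start <= end")
        if a == b:
            names = (f"{line}_a",)
            markers.append((a, names[0]))
        else:
            names = (f"{line}_a", f"{line}_b")
            markers.extend([(a, names[0]), (b, names[1])])
        segments[line] = SubstitutedSegment(chromosome=chromosome, inner_markers=names)
    markers.sort()
    gmap = GeneticMap([Marker(n, chromosome, p) for p, n in markers])
    return gmap, segments


def grid_membership(
    interval_list: list[CMInterval], lo: float, hi: float, step: float = 0.01
) -> np.ndarray:
    """Boolean membership of grid points in the union of closed intervals."""
    grid = np.arange(lo, hi + step / 2, step)
    member = np.zeros_like(grid, dtype=bool)
    for iv in interval_list:
        member |= (grid >= iv.start) & (grid <= iv.end)
    return member
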