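import numpy as np
import pytest

from spatialtme.io import CellRecord, CellTypeHierarchy, RegionPattern, Window


def make_pattern(
    pts_by_type: dict[str, list[tuple[float, float]]],
    window: Window,
    region_id: str = "r0",
    region_class: str = "tumor",
    patient_id: str = "p0",
) -> RegionPattern:
    """Pattern with identity marks (one analysis type per cell)."""
    cells, marks = [], []
    for t, pts in pts_by_type.items():
        for x, y in pts:
            cells.append(
                CellRecord(float(x), float(y), t, region_id, region_class, patient_id)
            )
            marks.append(frozenset({t}) if t != "other" else frozenset())
    return RegionPattern(
        window=window,
        cells=cells,
        marks=marks,
        region_id=region_id,
        region_class=region_class,
        patient_id=patient_id,
        types=tuple(t for t in pts_by_type if t != "other"),
    )


def random_pattern(
    rng: np.random.Generator,
    window: Window,
    counts: dict[str, int],
) -> RegionPattern:
    pts = {
        t: [
            (
                window.xmin + x * window.width,
                window.ymin + y * window.height,
            )
            for x, y in rng.random((n, 2))
        ]
        for t, n in counts.items()
    }
    return make_pattern(pts, window)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_type_hierarchy():
    return CellTypeHierarchy.identity(
        ("A", "B"), pair_list=[("A", "B"), ("B", "A")]
    )


@pytest.fixture
def unit_window():
    return Window(0.0, 100.0, 0.0, 100.0)
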