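import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nichekit as nk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_slide() -> nk.SpatialSlide:
    """A deterministic 12-cell slide on a grid with two types and 2 positives."""
    rows = []
    for i in range(12):
        rows.append(
            {
                "cell_id": f"c{i}",
                "x": float(i % 4),
                "y": float(i // 4),
                "cell_type": "A" if i % 3 else "B",
                "marker": 1.0 if i in (5, 7) else 0.0,
                "positive": i in (5, 7),
            }
        )
    return nk.SpatialSlide(pd.DataFrame(rows))


@pytest.fixture
def null_slide_1k() -> nk.SpatialSlide:
    cfg = nk.SlideConfig(
        n_cells=1000,
        type_proportions={"A": 0.5, "B": 0.3, "C": 0.2},
        m_positive=13,
        seed=42,
    )
    return nk.generate_null_slide(cfg)


def brute_force_knn(coords: np.ndarray, query: int, k: int):
    """All-pairs oracle: sort every other cell by (distance, index)."""
    d = np.hypot(coords[:, 0] - coords[query, 0], coords[:, 1] - coords[query, 1])
    d[query] = np.inf
    order = np.lexsort((np.arange(len(coords)), d))[:k]
    return order, d[order]
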