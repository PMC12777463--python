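"""Exact k-nearest-neighbor queries and cell-type composition statistics.

Neighborhoods are defined over 2D Euclidean distance on the slide
coordinates. A cell is never its own neighbor; its neighborhood composition
is the vector of cell-type fractions among its ``k`` nearest neighbors,
which lies on the probability simplex. Queries run through a k-d tree with
an explicit deterministic tie-resolution layer: equal distances are broken
by ascending cell index, so results are reproducible across platforms even
on degenerate (gridded or duplicated) geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._exceptions import ParameterError, ValidationError
from .io import SpatialSlide

__all__ = [
    "NeighborGraph",
    "knn_query",
    "radius_query",
    "composition",
    "mean_composition",
    "select_positive",
    "positive_fraction_by_type",
]


@dataclass
class NeighborGraph:
    """k nearest neighbors for each query cell.

    ``indices`` and ``distances`` are (n_queries, k) arrays; within each row
    distances are non-decreasing and equal distances are ordered by
    ascending cell index. The query cell itself is never included.
    """

    query_indices: np.ndarray
    indices: np.ndarray
    distances: np.ndarray
    k: int


def _as_coords(slide_or_coords) -> np.ndarray:
    if isinstance(slide_or_coords, SpatialSlide):
        return slide_or_coords.coords
    coords = np.asarray(slide_or_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ParameterError("coordinates must be an (n, 2) array")
    return coords


def knn_query(slide_or_coords, query_indices=None, k: int = 20) -> NeighborGraph:
    """Exact k nearest neighbors (self excluded) of each query cell.

    Parameters
    ----------
    slide_or_coords
        A :class:`SpatialSlide` or an (n, 2) coordinate array.
    query_indices
        Row indices of the cells to query; all cells when None.
    k
        Number of neighbors; must satisfy ``k < n_cells``.
    """
    coords = _as_coords(slide_or_coords)
    n = len(coords)
    if not (0 < k < n):
        raise ParameterError(f"k must satisfy 0 < k < n_cells (k={k}, n={n})")
    q = np.arange(n) if query_indices is None else np.asarray(query_indices, dtype=np.intp)
    if q.size and (q.min() < 0 or q.max() >= n):
        raise ParameterError("query index out of range")

    tree = cKDTree(coords)
    kq = min(k + 2, n)  # room for self + one boundary sentinel
    dist, idx = tree.query(coords[q], k=kq)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    self_mask = idx == q[:, None]
    self_found = self_mask.any(axis=1)
    dist = np.where(self_mask, np.inf, dist)

    # sort by index first, then stable-sort by distance: equal distances end
    # up ordered by ascending cell index
    order = np.argsort(idx, axis=1, kind="stable")
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    order = np.argsort(dist, axis=1, kind="stable")
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)

    out_idx = idx[:, :k].copy()
    out_dist = dist[:, :k].copy()

    # a row is decided iff self was seen and the k-th neighbor is strictly
    # closer than the next candidate (no truncated tie group at the boundary)
    if kq < n:
        unsafe = ~self_found | ~(out_dist[:, k - 1] < dist[:, k])
    else:
        # all cells were candidates: the global lexsort above is already exact
        unsafe = np.zeros(len(q), dtype=bool)
    for row in np.flatnonzero(unsafe):
        qi = q[row]
        d = np.hypot(coords[:, 0] - coords[qi, 0], coords[:, 1] - coords[qi, 1])
        d[qi] = np.inf
        full = np.lexsort((np.arange(n), d))[:k]
        out_idx[row] = full
        out_dist[row] = d[full]

    return NeighborGraph(q, out_idx, out_dist, k)


def radius_query(slide_or_coords, query_indices=None, radius: float = 1.0):
    """All neighbors within ``radius`` (self excluded), as variable-length lists.

    Labelled alternative neighborhood definition ("within a defined radius");
    the fixed-k definition is the primary one used by the enrichment test.
    """
    coords = _as_coords(slide_or_coords)
    n = len(coords)
    if radius <= 0:
        raise ParameterError("radius must be positive")
    q = np.arange(n) if query_indices is None else np.asarray(query_indices, dtype=np.intp)
    tree = cKDTree(coords)
    hits = tree.query_ball_point(coords[q], r=radius)
    out = []
    for qi, cand in zip(q, hits):
        cand = np.asarray(sorted(set(cand) - {int(qi)}), dtype=np.intp)
        d = np.hypot(coords[cand, 0] - coords[qi, 0], coords[cand, 1] - coords[qi, 1])
        order = np.lexsort((cand, d))
        out.append((cand[order], d[order]))
    return out


def composition(
    slide: SpatialSlide,
    graph: NeighborGraph,
    type_universe=None,
) -> pd.DataFrame:
    """Per-query cell-type composition of the k-neighbor sets.

    Returns a DataFrame (rows = query cells, columns = type universe) whose
    rows are fractions summing to 1; types absent from a neighborhood get 0.
    """
    universe = tuple(type_universe) if type_universe is not None else slide.type_universe
    mapping = {t: i for i, t in enumerate(universe)}
    labels = slide.cell_types
    unknown = set(labels) - set(universe)
    if unknown:
        raise ValidationError(
            f"cell_type {sorted(unknown)[0]!r} outside the supplied type universe"
        )
    codes = np.array([mapping[t] for t in labels], dtype=np.intp)
    T = len(universe)
    m, k = graph.indices.shape
    neigh_codes = codes[graph.indices]
    flat = neigh_codes + (np.arange(m)[:, None] * T)
    counts = np.bincount(flat.ravel(), minlength=m * T).reshape(m, T)
    frac = counts / float(k)
    return pd.DataFrame(frac, index=graph.query_indices, columns=list(universe))


def mean_composition(compositions: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Arithmetic mean and sample SD (ddof=1; 0 when n=1) per cell type."""
    if len(compositions) == 0:
        raise ParameterError("mean_composition requires at least one composition")
    mean = compositions.mean(axis=0)
    if len(compositions) == 1:
        sd = pd.Series(0.0, index=compositions.columns)
    else:
        sd = compositions.std(axis=0, ddof=1)
    return mean, sd


def select_positive(
    slide: SpatialSlide,
    expression_column: str | None = None,
    threshold: float = 0.0,
    prefer_flag: bool = False,
) -> np.ndarray:
    """Indices of marker-positive cells.

    A cell is positive when its expression strictly exceeds ``threshold``
    (default 0, the detectability rule). When ``prefer_flag`` is set — or no
    expression column is named — a ``positive`` flag column carried by the
    slide takes precedence.
    """
    flags = slide.positive_indices
    if (prefer_flag or expression_column is None) and flags is not None:
        return flags
    if expression_column is None:
        raise ParameterError(
            "no expression column named and the slide carries no positive flag"
        )
    if expression_column not in slide.cells.columns:
        raise ParameterError(f"expression column {expression_column!r} not present")
    values = slide.expression(expression_column)
    return np.flatnonzero(values > threshold)


def positive_fraction_by_type(slide: SpatialSlide, positive_indices) -> pd.Series:
    """Percentage of cells of each type that are marker-positive.

    Types with zero cells on the slide are absent from the result.
    """
    pos = np.asarray(positive_indices, dtype=np.intp)
    if pos.size and (pos.min() < 0 or pos.max() >= slide.n_cells):
        raise ParameterError("positive index out of range")
    labels = slide.cell_types
    totals = pd.Series(labels).value_counts()
    pos_counts = pd.Series(labels[pos]).value_counts() if pos.size else pd.Series(dtype=int)
    observed = [t for t in slide.type_universe if t in totals.index]
    out = pd.Series(
        {t: 100.0 * pos_counts.get(t, 0) / totals[t] for t in observed},
        name="positive_pct",
    )
    return out
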