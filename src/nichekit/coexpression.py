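"""Marker-restricted co-expression correlation between two genes.

Cells are first restricted to those with detectable marker expression
(strictly greater than a threshold, default 0); optionally cells with zero
target expression are excluded as a sensitivity analysis. Pearson or
Spearman correlation is then computed on the retained cells, with a
two-sided p-value from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom (for Spearman the same approximation on average ranks).

Because upstream data are expected as log-normalized expression, the
module itself performs no normalization; a ``log_transform`` switch is
provided for raw-scale inputs and applies a natural log after the
restriction (all retained values must then be strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator

from ._exceptions import InsufficientDataError, ParameterError

__all__ = ["CorrelationResult", "ExpressionCorrelation", "correlate"]

_METHODS = ("pearson", "spearman")


@dataclass
class CorrelationResult:
    """A correlation estimate with its t-based two-sided p-value."""

    method: str
    r: float
    p: float
    n_used: int
    restriction: str
    used_indices: np.ndarray | None = None


def _corr_with_p(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """Product-moment (or rank) correlation with the two-sided t p-value."""
    if method == "spearman":
        x = scipy.stats.rankdata(x, method="average")
        y = scipy.stats.rankdata(y, method="average")
    n = len(x)
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise InsufficientDataError(
            "correlation undefined: one vector is constant after restriction", n
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return r, p


class ExpressionCorrelation(BaseEstimator):
    """Marker-restricted two-gene correlation as an estimator.

    Parameters
    ----------
    method : {"pearson", "spearman", "both"}
        Correlation method; "both" computes and stores both.
    exclude_zero_target : bool, default False
        Additionally drop cells whose target expression is exactly 0.
    marker_threshold : float, default 0.0
        Detectability cut: keep cells with marker strictly above it.
    log_transform : bool, default False
        Natural-log the retained values before correlating (raw-scale
        inputs); requires all retained values to be strictly positive.

    Attributes (after :meth:`fit`)
    ------------------------------
    r_, p_, n_used_ : statistics for ``method`` (first of the two for "both")
    results_ : dict mapping method name to :class:`CorrelationResult`
    """

    def __init__(
        self,
        method: str = "pearson",
        exclude_zero_target: bool = False,
        marker_threshold: float = 0.0,
        log_transform: bool = False,
    ):
        self.method = method
        self.exclude_zero_target = exclude_zero_target
        self.marker_threshold = marker_threshold
        self.log_transform = log_transform

    def fit(self, marker_values, target_values):
        marker = np.asarray(marker_values, dtype=float)
        target = np.asarray(target_values, dtype=float)
        if marker.shape != target.shape or marker.ndim != 1:
            raise ParameterError("marker and target must be paired 1-D vectors")
        if self.method not in _METHODS + ("both",):
            raise ParameterError(f"unknown method {self.method!r}")

        mask = marker > self.marker_threshold
        restriction = f"marker > {self.marker_threshold:g}"
        if self.exclude_zero_target:
            mask &= target > 0
            restriction += " and target > 0"
        used = np.flatnonzero(mask)
        n_used = len(used)
        if n_used < 3:
            raise InsufficientDataError(
                f"only {n_used} cells remain after restriction ({restriction}); "
                "need at least 3",
                n_used,
            )
        x, y = marker[used], target[used]
        if self.log_transform:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ParameterError(
                    "log_transform requires strictly positive retained values "
                    "(use exclude_zero_target for zero-inflated targets)"
                )
            x, y = np.log(x), np.log(y)

        methods = _METHODS if self.method == "both" else (self.method,)
        self.results_ = {}
        for m in methods:
            r, p = _corr_with_p(x, y, m)
            self.results_[m] = CorrelationResult(m, r, p, n_used, restriction, used)
        first = self.results_[methods[0]]
        self.r_, self.p_, self.n_used_ = first.r, first.p, first.n_used
        self.used_indices_ = used
        return self


def correlate(
    marker_values,
    target_values,
    method: str = "pearson",
    exclude_zero_target: bool = False,
    marker_threshold: float = 0.0,
    log_transform: bool = False,
):
    """Functional wrapper around :class:`ExpressionCorrelation`.

    Returns a single :class:`CorrelationResult`, or a dict of both results
    when ``method="both"``.
    """
    est = ExpressionCorrelation(
        method=method,
        exclude_zero_target=exclude_zero_target,
        marker_threshold=marker_threshold,
        log_transform=log_transform,
    )
    est.fit(marker_values, target_values)
    if method == "both":
        return est.results_
    return est.results_[method]
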