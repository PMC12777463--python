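"""Peak-to-gene assignment, acetylation/expression concordance, DEG filtering
and gene-set overlap significance.

Each gene is assigned the nearest peak on its chromosome whose distance to
the TSS is at most a fixed window (default 5,000 bp, inclusive). Distance
is 0 when the TSS falls inside the half-open peak interval, otherwise base
pairs from the TSS to the nearest covered base of the peak; equidistant
peaks are broken by smaller start coordinate. Concordance correlates the
differential acetylation (peak logFC) against differential expression
(gene logFC) over assigned pairs. DEG filtering applies strict
|logFC| and significance cuts; overlap significance is the hypergeometric
upper tail (one-sided Fisher equivalent), accumulated in log space so
extreme tails do not underflow prematurely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._exceptions import InsufficientDataError, ParameterError, ValidationError
from .coexpression import CorrelationResult, _corr_with_p
from .io import DegTable, GenomicInterval, TssRecord

__all__ = [
    "PeakGeneAssignment",
    "OverlapTestInput",
    "NearestPeakAssigner",
    "assign_nearest_peak",
    "concordance",
    "filter_degs",
    "overlap_test",
]


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A gene's nearest in-window peak (or no assignment)."""

    gene_id: str
    peak_index: int | None
    distance: int | None

    @property
    def assigned(self) -> bool:
        return self.peak_index is not None


@dataclass(frozen=True)
class OverlapTestInput:
    """Sizes for a two-set overlap test within a finite gene universe."""

    n_a: int
    n_b: int
    k_overlap: int
    universe: int

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.k_overlap, self.universe) < 0:
            raise ValidationError("overlap counts must be non-negative")
        if max(self.n_a, self.n_b) > self.universe:
            raise ValidationError("set sizes cannot exceed the universe")
        if self.k_overlap > min(self.n_a, self.n_b):
            raise ValidationError("overlap cannot exceed the smaller set")
        if self.k_overlap < max(0, self.n_a + self.n_b - self.universe):
            raise ValidationError("overlap below the minimum forced by the margins")


def _tss_peak_distance(tss: int, start: int, end: int) -> int:
    """bp from a TSS to the nearest covered base of [start, end); 0 inside."""
    if tss < start:
        return start - tss
    if tss >= end:
        return tss - (end - 1)
    return 0


def _tss_midpoint_distance(tss: int, start: int, end: int) -> int:
    """Distance to the peak midpoint (optional alternative metric)."""
    return abs(tss - (start + end - 1) // 2)


class NearestPeakAssigner(BaseEstimator):
    """Nearest-in-window peak assignment as a fitted transformer.

    ``fit`` indexes the peak list; ``transform`` maps TSS records to
    :class:`PeakGeneAssignment` objects. ``window`` is inclusive: a peak at
    exactly ``window`` bp is assigned, one at ``window + 1`` is not.
    ``distance_mode`` selects TSS-to-nearest-edge (default) or
    TSS-to-midpoint distance.
    """

    def __init__(self, window: int = 5000, distance_mode: str = "edge"):
        self.window = window
        self.distance_mode = distance_mode

    def fit(self, peaks: Sequence[GenomicInterval], y=None):
        if self.window < 0:
            raise ParameterError("window must be non-negative")
        if self.distance_mode not in ("edge", "midpoint"):
            raise ParameterError(f"unknown distance_mode {self.distance_mode!r}")
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, p in enumerate(peaks):
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
        # sort by start so the argmin tie-break below lands on the smaller start
        self.peaks_by_chrom_ = {
            c: tuple(np.array(col) for col in zip(*sorted(v)))
            for c, v in by_chrom.items()
        }
        self.n_peaks_ = len(peaks)
        return self

    def transform(self, tss_list: Sequence[TssRecord]) -> list[PeakGeneAssignment]:
        dist_fn = _tss_peak_distance if self.distance_mode == "edge" else _tss_midpoint_distance
        out = []
        for rec in tss_list:
            entry = self.peaks_by_chrom_.get(rec.chrom)
            if entry is None:
                out.append(PeakGeneAssignment(rec.gene_id, None, None))
                continue
            starts, ends, orig = entry
            if dist_fn is _tss_peak_distance:
                d = np.where(
                    rec.tss < starts,
                    starts - rec.tss,
                    np.where(rec.tss >= ends, rec.tss - (ends - 1), 0),
                )
            else:
                d = np.abs(rec.tss - (starts + ends - 1) // 2)
            best = int(np.argmin(d))  # first minimum = smallest start (sorted)
            if d[best] <= self.window:
                out.append(PeakGeneAssignment(rec.gene_id, int(orig[best]), int(d[best])))
            else:
                out.append(PeakGeneAssignment(rec.gene_id, None, None))
        return out

    def fit_transform(self, peaks, tss_list):
        return self.fit(peaks).transform(tss_list)


def assign_nearest_peak(
    tss_list: Sequence[TssRecord],
    peaks: Sequence[GenomicInterval],
    window: int = 5000,
    distance_mode: str = "edge",
) -> list[PeakGeneAssignment]:
    """Assign each gene its nearest peak within ``window`` bp of the TSS."""
    return NearestPeakAssigner(window=window, distance_mode=distance_mode).fit_transform(
        peaks, tss_list
    )


def concordance(
    assignments: Sequence[PeakGeneAssignment],
    peak_logfc: Sequence[float] | Mapping[int, float],
    gene_logfc: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between peak and gene logFC over assigned pairs.

    ``peak_logfc`` is indexed by peak index (sequence or mapping);
    ``gene_logfc`` maps gene ids to expression logFC. Genes without an
    assignment or without a logFC are skipped.
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown method {method!r}")
    if isinstance(gene_logfc, pd.Series):
        gene_logfc = gene_logfc.to_dict()
    xs, ys = [], []
    for a in assignments:
        if not a.assigned or a.gene_id not in gene_logfc:
            continue
        xs.append(float(peak_logfc[a.peak_index]))
        ys.append(float(gene_logfc[a.gene_id]))
    n = len(xs)
    if n < 3:
        raise InsufficientDataError(
            f"only {n} assigned gene/peak pairs with logFC; need at least 3", n
        )
    r, p = _corr_with_p(np.asarray(xs), np.asarray(ys), method)
    return CorrelationResult(method, r, p, n, restriction="assigned gene/peak pairs")


def filter_degs(
    table: DegTable,
    lfc_cut: float,
    stat: str = "fdr",
    stat_cut: float = 0.01,
) -> set[str]:
    """Genes with |logFC| strictly above ``lfc_cut`` AND ``stat`` strictly
    below ``stat_cut`` (both cuts exclusive, e.g. |logFC| > 0.5, FDR < 0.01)."""
    if stat not in ("fdr", "pvalue"):
        raise ParameterError(f"stat must be 'fdr' or 'pvalue', got {stat!r}")
    df = table.frame
    mask = (df["logFC"].abs() > lfc_cut) & (df[stat] < stat_cut)
    return set(df.loc[mask, "gene_id"])


def overlap_test(
    n_a: int | OverlapTestInput,
    n_b: int | None = None,
    k_overlap: int | None = None,
    universe: int | None = None,
) -> float:
    """Upper-tail hypergeometric probability of the observed set overlap.

    P(X >= k_overlap) when drawing n_b elements from a universe containing
    n_a marked elements — the one-sided Fisher exact test for enrichment.
    The tail is accumulated from log-pmf terms so values far below float
    precision of a naive sum remain accurate.
    """
    if isinstance(n_a, OverlapTestInput):
        inp = n_a
    else:
        if None in (n_b, k_overlap, universe):
            raise ParameterError("overlap_test needs n_a, n_b, k_overlap and universe")
        inp = OverlapTestInput(n_a, n_b, k_overlap, universe)
    upper = min(inp.n_a, inp.n_b)
    ks = np.arange(inp.k_overlap, upper + 1)
    if len(ks) == 0:
        return 0.0
    logpmf = scipy.stats.hypergeom.logpmf(ks, inp.universe, inp.n_a, inp.n_b)
    return float(min(1.0, np.exp(logsumexp(logpmf))))
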