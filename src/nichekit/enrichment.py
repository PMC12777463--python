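"""Permutation-based spatial neighborhood enrichment test.

The question: do the m marker-positive cells on a slide sit in
neighborhoods whose cell-type composition differs from what m randomly
placed cells would see? The observed statistic is the mean k-neighbor
composition over the positive cells. The null is built by resampling m
cells uniformly without replacement from *all* cells B times and recording
each resample's mean composition. The empirical p-value for a type is the
proportion of null means greater than or equal to the observed mean
(one-sided, enrichment direction; ties count). Types with p below alpha
(strict) are called enriched.

The test is exposed both as the scikit-learn-style estimator
:class:`NeighborhoodEnrichment` and as the plain functions
:func:`sample_null`, :func:`empirical_p` and :func:`run_enrichment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from ._exceptions import ParameterError, ValidationError
from .io import SpatialSlide
from .neighborhood import composition, knn_query, mean_composition

__all__ = [
    "NullDistribution",
    "EnrichmentResult",
    "NeighborhoodEnrichment",
    "sample_null",
    "empirical_p",
    "run_enrichment",
    "t_test_variant",
]


@dataclass
class NullDistribution:
    """B resampled mean compositions (rows) over the type universe (columns)."""

    means: pd.DataFrame
    m: int
    k: int
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.means) < 1:
            raise ValidationError("null distribution needs at least one resample")
        sums = self.means.to_numpy().sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("null mean compositions must sum to 1")

    @property
    def B(self) -> int:
        return len(self.means)


@dataclass
class EnrichmentResult:
    """Observed composition, null, per-type empirical p-values and calls."""

    observed_mean: pd.Series
    observed_sd: pd.Series
    null: NullDistribution
    p_values: pd.Series
    enriched: pd.Series
    alpha: float
    m: int
    k: int
    B: int
    seed: int | None
    add_one: bool = False
    p_adjusted: pd.Series | None = None
    t_test: pd.DataFrame | None = None
    per_cell_compositions: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per cell type: observed mean/SD, null mean, p, call."""
        out = pd.DataFrame(
            {
                "observed_mean": self.observed_mean,
                "observed_sd": self.observed_sd,
                "null_mean": self.null.means.mean(axis=0),
                "p_value": self.p_values,
                "enriched": self.enriched,
            }
        )
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        if self.t_test is not None:
            out = out.join(self.t_test)
        out.index.name = "cell_type"
        return out


def _all_cell_compositions(slide: SpatialSlide, k: int) -> pd.DataFrame:
    graph = knn_query(slide, None, k=k)
    return composition(slide, graph)


def sample_null(
    slide: SpatialSlide,
    m: int,
    B: int = 1000,
    k: int = 20,
    seed: int | None = None,
    with_replacement: bool = False,
    cell_compositions: pd.DataFrame | None = None,
) -> NullDistribution:
    """Null distribution of mean k-neighbor compositions of m random cells.

    Each of the B resamples draws m distinct cells uniformly from all cells
    (``with_replacement=True`` relaxes distinctness) and stores the mean of
    their neighborhood compositions. ``cell_compositions`` may carry the
    precomputed per-cell composition matrix to avoid repeating the kNN pass.
    """
    n = slide.n_cells
    if not (1 <= m <= n):
        raise ParameterError(f"resample size m={m} must lie in [1, n_cells={n}]")
    if B < 1:
        raise ParameterError("B must be >= 1")
    comp = cell_compositions if cell_compositions is not None else _all_cell_compositions(slide, k)
    values = comp.to_numpy()
    rng = np.random.default_rng(seed)
    rows = np.empty((B, values.shape[1]))
    for b in range(B):
        take = rng.choice(n, size=m, replace=with_replacement)
        rows[b] = values[take].mean(axis=0)
    means = pd.DataFrame(rows, columns=comp.columns)
    return NullDistribution(means, m=m, k=k, seed=seed)


def empirical_p(observed_mean: pd.Series, null: NullDistribution, add_one: bool = False) -> pd.Series:
    """Per-type empirical p: the proportion of null means >= the observed mean.

    Ties count as extreme ("greater than or equal"), so a degenerate type
    whose null equals the observed value gets p = 1. With ``add_one`` the
    estimator becomes (count + 1) / (B + 1), which never reports exactly 0.
    """
    null_cols = list(null.means.columns)
    if set(observed_mean.index) != set(null_cols):
        raise ValidationError("observed and null type universes differ")
    obs = observed_mean.reindex(null_cols)
    counts = (null.means.to_numpy() >= obs.to_numpy()[None, :]).sum(axis=0)
    B = null.B
    if add_one:
        p = (counts + 1) / (B + 1)
    else:
        p = counts / B
    return pd.Series(p, index=null_cols, name="p_value")


def t_test_variant(
    positive_compositions: pd.DataFrame,
    null: NullDistribution,
    cell_type: str,
) -> tuple[float, float]:
    """One-sample two-sided t of the positives' per-cell fractions of one type
    against the null grand mean for that type.

    A labelled alternative to the permutation p (figure-legend style), not
    the primary inference.
    """
    if cell_type not in positive_compositions.columns:
        raise ParameterError(f"unknown cell type {cell_type!r}")
    x = positive_compositions[cell_type].to_numpy(dtype=float)
    if len(x) < 2:
        raise ParameterError("t-test needs at least 2 positive cells")
    popmean = float(null.means[cell_type].mean())
    if np.ptp(x) == 0:  # constant fractions: closed-form degenerate t
        if x[0] == popmean:
            return 0.0, 1.0
        return float(np.sign(x[0] - popmean) * np.inf), 0.0
    res = scipy.stats.ttest_1samp(x, popmean=popmean)
    return float(res.statistic), float(res.pvalue)


class NeighborhoodEnrichment(BaseEstimator):
    """Permutation-based neighborhood enrichment test as an estimator.

    Parameters
    ----------
    k : int, default 20
        Neighborhood size (number of nearest neighbors).
    n_permutations : int, default 1000
        Number of null resamples B.
    alpha : float, default 0.05
        Significance level; a type is called enriched iff p < alpha (strict).
    seed : int or None
        Seed for the null resampling stream.
    add_one : bool, default False
        Use the (count+1)/(B+1) p-value estimator.
    with_replacement : bool, default False
        Allow duplicate cells within a null resample.
    bh_correct : bool, default False
        Also compute Benjamini-Hochberg adjusted p-values across types and
        base the enrichment calls on them.
    compute_t_test : bool, default True
        Report the one-sample t-test alternative per type alongside the
        permutation p.

    Attributes (after :meth:`fit`)
    ------------------------------
    observed_mean_, observed_sd_ : per-type observed statistics
    null_ : :class:`NullDistribution`
    p_values_, enriched_ : per-type empirical p and boolean call
    result_ : the full :class:`EnrichmentResult`
    """

    def __init__(
        self,
        k: int = 20,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
        add_one: bool = False,
        with_replacement: bool = False,
        bh_correct: bool = False,
        compute_t_test: bool = True,
    ):
        self.k = k
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.seed = seed
        self.add_one = add_one
        self.with_replacement = with_replacement
        self.bh_correct = bh_correct
        self.compute_t_test = compute_t_test

    def fit(self, slide: SpatialSlide, positive_indices=None):
        """Run the test on a slide given the positive cell indices."""
        if positive_indices is None:
            positive_indices = slide.positive_indices
            if positive_indices is None:
                raise ParameterError(
                    "no positive_indices given and the slide carries no positive flag"
                )
        pos = np.asarray(positive_indices, dtype=np.intp)
        if pos.size == 0:
            raise ParameterError("enrichment test requires at least one positive cell")
        if pos.min() < 0 or pos.max() >= slide.n_cells:
            raise ParameterError("positive index out of range")

        comp = _all_cell_compositions(slide, self.k)
        pos_comp = comp.loc[pos]
        observed_mean, observed_sd = mean_composition(pos_comp)
        null = sample_null(
            slide,
            m=len(pos),
            B=self.n_permutations,
            k=self.k,
            seed=self.seed,
            with_replacement=self.with_replacement,
            cell_compositions=comp,
        )
        p = empirical_p(observed_mean, null, add_one=self.add_one)
        p_adj = None
        if self.bh_correct:
            p_adj = pd.Series(
                scipy.stats.false_discovery_control(p.to_numpy(), method="bh"),
                index=p.index,
                name="p_adjusted",
            )
        calls = (p_adj if p_adj is not None else p) < self.alpha
        calls.name = "enriched"

        t_frame = None
        if self.compute_t_test and len(pos) >= 2:
            rows = {}
            for t in comp.columns:
                stat, pval = t_test_variant(pos_comp, null, t)
                rows[t] = {"t_statistic": stat, "t_p_value": pval}
            t_frame = pd.DataFrame.from_dict(rows, orient="index")

        self.observed_mean_ = observed_mean
        self.observed_sd_ = observed_sd
        self.null_ = null
        self.p_values_ = p
        self.enriched_ = calls
        self.result_ = EnrichmentResult(
            observed_mean=observed_mean,
            observed_sd=observed_sd,
            null=null,
            p_values=p,
            enriched=calls,
            alpha=self.alpha,
            m=len(pos),
            k=self.k,
            B=self.n_permutations,
            seed=self.seed,
            add_one=self.add_one,
            p_adjusted=p_adj,
            t_test=t_frame,
            per_cell_compositions=pos_comp,
        )
        return self


def run_enrichment(
    slide: SpatialSlide,
    positive_indices,
    k: int = 20,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    add_one: bool = False,
    **kwargs,
) -> EnrichmentResult:
    """Functional wrapper around :class:`NeighborhoodEnrichment`."""
    est = NeighborhoodEnrichment(
        k=k, n_permutations=B, alpha=alpha, seed=seed, add_one=add_one, **kwargs
    )
    est.fit(slide, positive_indices)
    return est.result_
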