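"""Synthetic data with known ground truth for every downstream analysis.

Slides emulate the statistical structure of a sectioned tumor profiled at
cellular resolution: tens of thousands of cells of a handful of types on a
square field, with a rare marker-positive subpopulation (13 positives
among ~50,000 cells at study scale, k = 20 neighborhoods). The null
generator places everything uniformly at random; the enriched generator
clusters the focal cell type into Gaussian patches and draws the positives
with selection weights that increase with the local focal-type fraction,
so the neighborhood effect is planted without changing the marginal
spatial or type distributions.

Co-expression fixtures draw a latent bivariate normal pair with a chosen
correlation, exponentiate to an expression scale, and apply independent
dropout — returning the latents as an oracle. Genomic fixtures lay genes
and peaks on a synthetic chromosome so every gene's true
nearest-peak-within-window assignment is known by construction.

All randomness in a call flows through a single seeded NumPy generator
stream; identical configs reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from ._exceptions import ParameterError, ValidationError
from .io import (
    DegTable,
    GenomicInterval,
    SpatialSlide,
    TssRecord,
    write_bed_intervals,
    write_cell_table,
    write_deg_table,
    write_tss_bed,
)
from .neighborhood import knn_query

__all__ = [
    "SlideConfig",
    "CoexprConfig",
    "generate_null_slide",
    "generate_enriched_slide",
    "generate_coexpression",
    "generate_logfc_fixture",
    "write_slide_fixture",
    "write_logfc_fixture",
]

#: Study-scale default cell-type mix: six types dominated by tumor epithelium,
#: loosely mirroring an ER+ breast tumor section.
DEFAULT_TYPE_PROPORTIONS = {
    "Cancer Epithelial": 0.40,
    "Stromal": 0.20,
    "T-cells": 0.15,
    "Myeloid": 0.10,
    "B-cells": 0.08,
    "Endothelial": 0.07,
}


@dataclass
class SlideConfig:
    """Parameters of a synthetic spatial slide.

    Defaults reproduce the study-scale conditions: ~50,000 cells of 6
    types with 13 marker-positive cells and k = 20 neighborhoods on a
    square field of side 1,000 length units.
    """

    n_cells: int = 50_000
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    m_positive: int = 13
    focal_type: str | None = None
    enrichment_rho: float = 0.0
    n_clusters: int = 5
    cluster_sd: float = 50.0
    field_size: float = 1000.0
    k_local: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be positive")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"type_proportions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.type_proportions.values()):
            raise ValidationError("type_proportions must be non-negative")
        if not (0 <= self.m_positive <= self.n_cells):
            raise ValidationError("m_positive must lie in [0, n_cells]")
        if self.enrichment_rho < 0:
            raise ValidationError("enrichment_rho must be non-negative")
        if self.enrichment_rho > 0 and self.focal_type is not None:
            if self.focal_type not in self.type_proportions:
                raise ValidationError(
                    f"focal_type {self.focal_type!r} absent from type_proportions"
                )
        if self.n_clusters <= 0 or self.cluster_sd <= 0 or self.field_size <= 0:
            raise ValidationError("n_clusters, cluster_sd and field_size must be positive")
        if self.k_local <= 0:
            raise ValidationError("k_local must be positive")


@dataclass
class CoexprConfig:
    """Parameters of a zero-inflated correlated two-gene expression draw."""

    n_cells: int = 2000
    r_true: float = 0.65
    dropout_prob: float = 0.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be positive")
        if abs(self.r_true) > 1:
            raise ValidationError("r_true must lie in [-1, 1]")
        if not (0 <= self.dropout_prob < 1):
            raise ValidationError("dropout_prob must lie in [0, 1)")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")


def _build_slide(
    config: SlideConfig,
    coords: np.ndarray,
    labels: np.ndarray,
    positives: np.ndarray,
    rng: np.random.Generator,
) -> SpatialSlide:
    n = config.n_cells
    marker = np.zeros(n)
    # positives carry detectable marker expression on a log-normal scale
    marker[positives] = np.exp(rng.normal(0.0, 0.5, size=len(positives)))
    flags = np.zeros(n, dtype=bool)
    flags[positives] = True
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "cell_type": labels,
            "marker": marker,
            "positive": flags,
        }
    )
    return SpatialSlide(df, tuple(config.type_proportions))


def generate_null_slide(config: SlideConfig) -> SpatialSlide:
    """A fully random slide: uniform coordinates, i.i.d. type labels, and a
    uniformly random positive subset of size ``m_positive``."""
    if config.enrichment_rho > 0 and config.focal_type is not None:
        raise ParameterError(
            "null slide requested with enrichment_rho > 0 and a focal type; "
            "use generate_enriched_slide"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    coords = rng.uniform(0.0, config.field_size, size=(n, 2))
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    labels = rng.choice(types, size=n, p=probs)
    positives = rng.choice(n, size=config.m_positive, replace=False)
    return _build_slide(config, coords, labels, np.sort(positives), rng)


def _sample_truncated_clusters(
    rng: np.random.Generator,
    n_points: int,
    centers: np.ndarray,
    sd: float,
    field: float,
) -> np.ndarray:
    """Gaussian-mixture points rejection-sampled into the [0, field]^2 square."""
    assignments = rng.integers(0, len(centers), size=n_points)
    pts = centers[assignments] + rng.normal(0.0, sd, size=(n_points, 2))
    bad = np.flatnonzero(~np.all((pts >= 0) & (pts <= field), axis=1))
    while bad.size:
        pts[bad] = centers[assignments[bad]] + rng.normal(0.0, sd, size=(bad.size, 2))
        bad = bad[~np.all((pts[bad] >= 0) & (pts[bad] <= field), axis=1)]
    return pts


def generate_enriched_slide(config: SlideConfig) -> tuple[SpatialSlide, np.ndarray]:
    """A slide with planted co-location of positives and a focal cell type.

    Focal-type cells are placed in ``n_clusters`` truncated isotropic
    Gaussian clusters; all other cells are uniform. Positives are drawn
    without replacement with weight ``1 + enrichment_rho * f_i`` where
    ``f_i`` is the focal-type fraction among cell i's ``k_local`` nearest
    neighbors. Returns the slide together with the ground-truth selection
    weights.
    """
    if config.focal_type is None:
        raise ParameterError("generate_enriched_slide requires a focal_type")
    if config.focal_type not in config.type_proportions:
        raise ValidationError(
            f"focal_type {config.focal_type!r} absent from type_proportions"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    labels = rng.choice(types, size=n, p=probs)
    focal_mask = labels == config.focal_type

    coords = rng.uniform(0.0, config.field_size, size=(n, 2))
    n_focal = int(focal_mask.sum())
    if n_focal:
        centers = rng.uniform(0.0, config.field_size, size=(config.n_clusters, 2))
        coords[focal_mask] = _sample_truncated_clusters(
            rng, n_focal, centers, config.cluster_sd, config.field_size
        )

    graph = knn_query(coords, None, k=min(config.k_local, n - 1))
    f = focal_mask[graph.indices].mean(axis=1)
    weights = 1.0 + config.enrichment_rho * f
    positives = rng.choice(
        n, size=config.m_positive, replace=False, p=weights / weights.sum()
    )
    slide = _build_slide(config, coords, labels, np.sort(positives), rng)
    return slide, weights


def generate_coexpression(
    config: CoexprConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlated zero-inflated expression for a marker/target gene pair.

    Latent pairs are standard bivariate normal with correlation ``r_true``;
    observed values are ``scale * exp(latent)`` independently zeroed with
    probability ``dropout_prob``. Returns (marker, target, latents) where
    ``latents`` is the (n, 2) oracle.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    r = config.r_true
    z1 = rng.normal(size=n)
    z_ind = rng.normal(size=n)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z_ind
    latents = np.column_stack([z1, z2])
    marker = config.scale * np.exp(z1)
    target = config.scale * np.exp(z2)
    if config.dropout_prob > 0:
        marker[rng.random(n) < config.dropout_prob] = 0.0
        target[rng.random(n) < config.dropout_prob] = 0.0
    return marker, target, latents


def generate_logfc_fixture(
    n_genes: int,
    n_peaks: int,
    r_true: float,
    window: int = 5000,
    seed: int = 0,
) -> tuple[list[TssRecord], list[GenomicInterval], DegTable, dict[str, int | None]]:
    """Genes and peaks on a synthetic chromosome with a known assignment map.

    Gene territories are spaced 10 windows apart so assignments cannot leak
    across genes. Each gene falls into one scenario — a peak containing its
    TSS, a peak at a known distance within the window (sometimes shadowed
    by a farther in-window decoy, occasionally an exact equidistant tie), a
    peak strictly beyond the window, or no peak at all — so the ground-truth
    map is known by construction. Gene and assigned-peak logFCs are drawn
    bivariate normal with correlation ``r_true``; unassigned logFCs are
    independent. Leftover peaks land in intergenic deserts.
    """
    if n_peaks < 1:
        raise ParameterError("n_peaks must be >= 1")
    if abs(r_true) > 1:
        raise ParameterError("r_true must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    spacing = 10 * window
    tss_list: list[TssRecord] = []
    peaks: list[GenomicInterval] = []
    truth: dict[str, int | None] = {}
    gene_lfc: dict[str, float] = {}

    def new_peak(start: int, end: int, score: float) -> int:
        peaks.append(GenomicInterval(chrom, start, end, float(score), f"peak{len(peaks)}"))
        return len(peaks) - 1

    rho = float(np.clip(r_true, -1.0, 1.0))
    for g in range(n_genes):
        gene = f"gene{g}"
        anchor = (g + 1) * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        tss_list.append(TssRecord(chrom, anchor, strand, gene))
        z1 = rng.normal()
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()
        scenario = rng.choice(
            ["contain", "near", "decoy", "tie", "far", "none"],
            p=[0.25, 0.25, 0.15, 0.10, 0.15, 0.10],
        )
        if len(peaks) >= n_peaks:
            scenario = "none"
        width = int(rng.integers(200, 1000))
        if scenario == "contain":
            offset = int(rng.integers(1, width - 1))
            idx = new_peak(anchor - offset, anchor - offset + width, z2)
            truth[gene] = idx
        elif scenario in ("near", "decoy", "tie"):
            d = int(rng.integers(1, window + 1))
            idx = new_peak(anchor + d, anchor + d + width, z2)
            truth[gene] = idx
            if scenario == "decoy" and d + 1 <= window and len(peaks) < n_peaks:
                d2 = int(rng.integers(d + 1, window + 1)) if d + 1 <= window else None
                if d2 is not None:
                    new_peak(anchor + d2, anchor + d2 + width, rng.normal())
            elif scenario == "tie" and len(peaks) < n_peaks:
                # equidistant flanking peak on the left; the right peak above
                # has the larger start, so truth is the left one
                left_end = anchor - d + 1  # last covered base at anchor - d
                if left_end - width > 0:
                    idx_left = new_peak(left_end - width, left_end, rng.normal())
                    truth[gene] = idx_left
        elif scenario == "far":
            d = int(rng.integers(window + 1, 2 * window))
            new_peak(anchor + d, anchor + d + width, rng.normal())
            truth[gene] = None
            z2 = rng.normal()  # no assigned peak: gene logFC independent
        else:
            truth[gene] = None
            z2 = rng.normal()
        gene_lfc[gene] = float(z1)

    # park any remaining peaks in deserts beyond every gene territory
    desert = (n_genes + 2) * spacing
    while len(peaks) < n_peaks:
        width = int(rng.integers(200, 1000))
        new_peak(desert, desert + width, rng.normal())
        desert += spacing
    peaks = peaks[:n_peaks]
    truth = {g: (i if (i is not None and i < n_peaks) else None) for g, i in truth.items()}

    pvals = rng.uniform(1e-6, 1.0, size=n_genes)
    fdr = scipy.stats.false_discovery_control(pvals, method="bh")
    deg = DegTable(
        pd.DataFrame(
            {
                "gene_id": [f"gene{g}" for g in range(n_genes)],
                "logFC": [gene_lfc[f"gene{g}"] for g in range(n_genes)],
                "pvalue": pvals,
                "fdr": np.clip(fdr, 1e-12, 1.0),
            }
        )
    )
    return tss_list, peaks, deg, truth


# ---------------------------------------------------------------------------
# fixture writers (cell-table TSV / BED / TSV + JSON manifest)
# ---------------------------------------------------------------------------

def write_slide_fixture(
    config: SlideConfig, out_dir: str | Path, enriched: bool | None = None
) -> dict:
    """Generate a slide, write it as TSV plus a JSON manifest, and return the
    manifest dict. ``enriched`` defaults to whether a focal type is set with
    a positive enrichment_rho."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if enriched is None:
        enriched = config.focal_type is not None and config.enrichment_rho > 0
    if enriched:
        slide, weights = generate_enriched_slide(config)
    else:
        slide = generate_null_slide(config)
        weights = np.ones(config.n_cells)
    write_cell_table(slide, out / "cells.tsv")
    np.savetxt(out / "selection_weights.tsv", weights, fmt="%.10g")
    manifest = {
        "generator": "enriched" if enriched else "null",
        "config": dataclasses.asdict(config),
        "n_cells": slide.n_cells,
        "n_positive": int(len(slide.positive_indices)),
        "files": ["cells.tsv", "selection_weights.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_logfc_fixture(
    n_genes: int,
    n_peaks: int,
    r_true: float,
    out_dir: str | Path,
    window: int = 5000,
    seed: int = 0,
) -> dict:
    """Write a peak/TSS/DEG fixture (BED + TSV) with its ground-truth map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tss, peaks, deg, truth = generate_logfc_fixture(n_genes, n_peaks, r_true, window, seed)
    write_tss_bed(tss, out / "tss.bed")
    write_bed_intervals(peaks, out / "peaks.bed")
    write_deg_table(deg, out / "degs.tsv")
    manifest = {
        "generator": "logfc_fixture",
        "n_genes": n_genes,
        "n_peaks": n_peaks,
        "r_true": r_true,
        "window": window,
        "seed": seed,
        "truth": truth,
        "files": ["tss.bed", "peaks.bed", "degs.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
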