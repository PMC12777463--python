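import json

import numpy as np
import pytest

import nichekit as nk
from nichekit._exceptions import ParameterError, ValidationError


class TestSlideConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            nk.SlideConfig(n_cells=10, type_proportions={"A": 0.5, "B": 0.4})

    def test_m_positive_cannot_exceed_n(self):
        with pytest.raises(ValidationError, match="m_positive"):
            nk.SlideConfig(n_cells=10, type_proportions={"A": 1.0}, m_positive=11)

    def test_focal_type_must_exist_when_rho_positive(self):
        with pytest.raises(ValidationError, match="focal_type"):
            nk.SlideConfig(
                n_cells=10, type_proportions={"A": 1.0}, m_positive=1,
                focal_type="Z", enrichment_rho=1.0,
            )


class TestNullSlide:
    def test_degenerate_proportions_give_single_label(self):
        cfg = nk.SlideConfig(n_cells=100, type_proportions={"A": 1.0}, m_positive=5, seed=0)
        slide = nk.generate_null_slide(cfg)
        assert (slide.cell_types == "A").all()

    def test_study_scale_positive_count(self):
        """The study-scale defaults: 50,000 cells with exactly 13 positives."""
        cfg = nk.SlideConfig(seed=1)
        assert cfg.n_cells == 50_000 and cfg.m_positive == 13
        slide = nk.generate_null_slide(cfg)
        assert slide.n_cells == 50_000
        assert len(slide.positive_indices) == 13
        marker = slide.expression("marker")
        assert (marker[slide.positive_indices] > 0).all()
        assert np.count_nonzero(marker) == 13

    def test_label_fractions_within_binomial_bounds(self):
        n = 20_000
        cfg = nk.SlideConfig(
            n_cells=n, type_proportions={"A": 0.3, "B": 0.7}, m_positive=0, seed=5
        )
        slide = nk.generate_null_slide(cfg)
        for label, p in (("A", 0.3), ("B", 0.7)):
            frac = (slide.cell_types == label).mean()
            bound = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(frac - p) < bound

    def test_reproducible_and_seed_sensitive(self):
        cfg = lambda s: nk.SlideConfig(
            n_cells=500, type_proportions={"A": 0.6, "B": 0.4}, m_positive=5, seed=s
        )
        a = nk.generate_null_slide(cfg(3))
        b = nk.generate_null_slide(cfg(3))
        assert a.cells.equals(b.cells)
        positive_sets = {
            tuple(nk.generate_null_slide(cfg(s)).positive_indices) for s in range(10)
        }
        assert len(positive_sets) > 1

    def test_coordinates_within_field(self):
        cfg = nk.SlideConfig(
            n_cells=200, type_proportions={"A": 1.0}, m_positive=1,
            field_size=42.0, seed=0,
        )
        coords = nk.generate_null_slide(cfg).coords
        assert coords.min() >= 0 and coords.max() <= 42.0


def _enriched_cfg(rho, seed, n=2000, m=13):
    return nk.SlideConfig(
        n_cells=n, type_proportions={"A": 0.3, "B": 0.4, "C": 0.3},
        m_positive=m, focal_type="A", enrichment_rho=rho, n_clusters=3,
        cluster_sd=30.0, field_size=500.0, seed=seed,
    )


def _mean_focal_fraction(slide, indices):
    graph = nk.knn_query(slide, np.asarray(indices), k=20)
    return (slide.cell_types[graph.indices] == "A").mean(axis=1).mean()


class TestEnrichedSlide:
    def test_rho_zero_gives_uniform_weights(self):
        slide, weights = nk.generate_enriched_slide(_enriched_cfg(0.0, seed=1))
        np.testing.assert_allclose(weights, 1.0)

    def test_positives_see_more_focal_neighbors(self):
        cfg = _enriched_cfg(5.0, seed=2, n=5000)
        slide, _ = nk.generate_enriched_slide(cfg)
        pos = slide.positive_indices
        assert _mean_focal_fraction(slide, pos) > _mean_focal_fraction(
            slide, np.arange(slide.n_cells)
        )

    def test_focal_enrichment_monotone_in_rho(self):
        """Mean positive-neighborhood focal fraction is non-decreasing in rho
        (Monte-Carlo over replicate slides)."""
        means = []
        for rho in (0.0, 1.0, 5.0, 20.0):
            vals = []
            for seed in range(50):
                slide, _ = nk.generate_enriched_slide(_enriched_cfg(rho, seed))
                vals.append(_mean_focal_fraction(slide, slide.positive_indices))
            means.append(np.mean(vals))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_extreme_rho_concentrates_on_max_focal_cells(self):
        cfg = _enriched_cfg(1e6, seed=4, n=2000, m=10)
        slide, weights = nk.generate_enriched_slide(cfg)
        f = (weights - 1.0) / 1e6
        pos = slide.positive_indices
        # in the rho->inf limit selection mass is ~ proportional to f: cells
        # with zero local focal fraction are never picked and the positives'
        # mean local focal fraction sits far above the slide-wide mean
        assert f[pos].min() > 0
        assert f[pos].mean() >= 2 * f.mean()
        assert f[pos].mean() >= 0.5 * f.max()

    def test_weights_match_definition(self):
        cfg = _enriched_cfg(7.0, seed=6)
        slide, weights = nk.generate_enriched_slide(cfg)
        graph = nk.knn_query(slide, None, k=cfg.k_local)
        f = (slide.cell_types[graph.indices] == "A").mean(axis=1)
        np.testing.assert_allclose(weights, 1.0 + 7.0 * f)

    def test_requires_focal_type(self):
        cfg = nk.SlideConfig(n_cells=100, type_proportions={"A": 1.0}, m_positive=1)
        with pytest.raises(ParameterError, match="focal_type"):
            nk.generate_enriched_slide(cfg)


class TestCoexpression:
    def test_perfect_dependence(self):
        cfg = nk.CoexprConfig(n_cells=100, r_true=1.0, dropout_prob=0.0, seed=0)
        marker, target, latents = nk.generate_coexpression(cfg)
        r = np.corrcoef(np.log(marker), np.log(target))[0, 1]
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_null_correlation_below_fisher_bound(self):
        n = 2000
        cfg = nk.CoexprConfig(n_cells=n, r_true=0.0, dropout_prob=0.0, seed=1)
        marker, target, _ = nk.generate_coexpression(cfg)
        r = np.corrcoef(np.log(marker), np.log(target))[0, 1]
        assert abs(r) < 3.29 / np.sqrt(n - 3)

    def test_recovery_matches_latent_oracle(self):
        cfg = nk.CoexprConfig(n_cells=2000, r_true=0.65, dropout_prob=0.0, seed=2)
        marker, target, latents = nk.generate_coexpression(cfg)
        oracle = np.corrcoef(latents[:, 0], latents[:, 1])[0, 1]
        r = np.corrcoef(np.log(marker), np.log(target))[0, 1]
        assert abs(r - oracle) < 0.1

    def test_dropout_zeroes_expected_share(self):
        cfg = nk.CoexprConfig(n_cells=5000, r_true=0.3, dropout_prob=0.4, seed=3)
        marker, target, _ = nk.generate_coexpression(cfg)
        assert abs((marker == 0).mean() - 0.4) < 0.03
        assert abs((target == 0).mean() - 0.4) < 0.03

    def test_invalid_r_rejected(self):
        with pytest.raises(ValidationError, match="r_true"):
            nk.CoexprConfig(n_cells=10, r_true=1.5)


class TestLogfcFixture:
    def test_truth_map_consistent_with_window(self):
        for seed in range(5):
            tss, peaks, deg, truth = nk.generate_logfc_fixture(
                40, 60, r_true=0.9, window=5000, seed=seed
            )
            assert len(peaks) == 60 and len(tss) == 40
            by_gene = {t.gene_id: t for t in tss}
            for gene, idx in truth.items():
                if idx is None:
                    continue
                p = peaks[idx]
                rec = by_gene[gene]
                if rec.tss < p.start:
                    d = p.start - rec.tss
                elif rec.tss >= p.end:
                    d = rec.tss - (p.end - 1)
                else:
                    d = 0
                assert d <= 5000

    def test_unassigned_genes_have_no_in_window_peak(self):
        tss, peaks, _, truth = nk.generate_logfc_fixture(50, 80, 0.5, seed=7)
        by_gene = {t.gene_id: t for t in tss}
        for gene, idx in truth.items():
            if idx is not None:
                continue
            rec = by_gene[gene]
            for p in peaks:
                if p.chrom != rec.chrom:
                    continue
                if rec.tss < p.start:
                    d = p.start - rec.tss
                elif rec.tss >= p.end:
                    d = rec.tss - (p.end - 1)
                else:
                    d = 0
                assert d > 5000

    def test_assigned_pair_logfc_correlated(self):
        tss, peaks, deg, truth = nk.generate_logfc_fixture(300, 400, 0.9, seed=1)
        gene_lfc = dict(zip(deg.frame["gene_id"], deg.frame["logFC"]))
        pairs = [(peaks[i].score, gene_lfc[g]) for g, i in truth.items() if i is not None]
        x, y = np.array(pairs).T
        assert np.corrcoef(x, y)[0, 1] > 0.6

    def test_deg_table_valid_and_reproducible(self):
        _, _, deg1, t1 = nk.generate_logfc_fixture(30, 30, 0.5, seed=9)
        _, _, deg2, t2 = nk.generate_logfc_fixture(30, 30, 0.5, seed=9)
        assert deg1.frame.equals(deg2.frame) and t1 == t2


class TestFixtureWriters:
    def test_slide_fixture_round_trip(self, tmp_path):
        cfg = nk.SlideConfig(
            n_cells=300, type_proportions={"A": 0.5, "B": 0.5}, m_positive=4, seed=0
        )
        from nichekit.synthetic import write_slide_fixture

        manifest = write_slide_fixture(cfg, tmp_path / "fix")
        slide = nk.read_cell_table(tmp_path / "fix" / "cells.tsv")
        assert slide.n_cells == 300
        assert manifest["n_positive"] == 4
        assert json.loads((tmp_path / "fix" / "manifest.json").read_text())["config"]["seed"] == 0

    def test_logfc_fixture_files(self, tmp_path):
        from nichekit.synthetic import write_logfc_fixture

        manifest = write_logfc_fixture(20, 25, 0.8, tmp_path / "fix", seed=2)
        tss = nk.read_tss_bed(tmp_path / "fix" / "tss.bed")
        peaks = nk.read_bed_intervals(tmp_path / "fix" / "peaks.bed")
        deg = nk.read_deg_table(tmp_path / "fix" / "degs.tsv")
        assert len(tss) == 20 and len(peaks) == 25 and len(deg) == 20
        assert set(manifest["truth"]) == {t.gene_id for t in tss}
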