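"""Generator contracts: marker structure, sampling semantics, artifacts."""

import numpy as np
import pytest

from spotdecon.data_io import SpotExpressionMatrix
from spotdecon.simulator import (PseudoSpotConfig, apply_artifact,
                                 downsample_counts, generate_synthetic_scrna,
                                 generate_synthetic_slide,
                                 simulate_pseudospots, simulate_slide_dataset)


class TestReference:
    def test_single_type_means_uniform_labels(self):
        ref = generate_synthetic_scrna(n_cells=50, n_genes=10, n_types=1,
                                       marker_fold=5, seed=0)
        assert set(ref.cell_types) == {0}

    def test_same_seed_is_bit_identical(self):
        a = generate_synthetic_scrna(seed=9)
        b = generate_synthetic_scrna(seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.cell_types, b.cell_types)

    def test_marker_fold_recovered_empirically(self):
        ref = generate_synthetic_scrna(n_cells=2000, n_genes=40, n_types=4,
                                       marker_fold=10, base_rate=1.0, seed=1)
        gene = ref.marker_map[0][0]
        in_type = ref.counts[ref.cell_types == 0, gene].mean()
        out_type = ref.counts[ref.cell_types != 0, gene].mean()
        assert 7 <= in_type / out_type <= 13

    def test_more_types_than_genes_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_scrna(n_genes=3, n_types=5)

    def test_every_type_has_cells_and_markers(self, small_reference):
        counts = np.bincount(small_reference.cell_types)
        assert counts.min() >= 1
        assert all(len(v) >= 1 for v in small_reference.marker_map.values())


class TestPseudoSpots:
    def test_single_type_reference_gives_unit_proportions(self):
        ref = generate_synthetic_scrna(n_cells=30, n_genes=8, n_types=1, seed=2)
        _, props = simulate_pseudospots(ref, PseudoSpotConfig(n_spots=20, seed=5))
        np.testing.assert_array_equal(props.values, np.ones((20, 1)))

    def test_types_per_spot_truncated_to_type_count(self):
        ref = generate_synthetic_scrna(n_cells=60, n_genes=10, n_types=2, seed=2)
        cfg = PseudoSpotConfig(n_spots=100, mu_types=5, sigma_types=3, seed=4)
        _, props = simulate_pseudospots(ref, cfg)
        n_present = (props.values > 0).sum(axis=1)
        assert np.all((n_present >= 1) & (n_present <= 2))

    def test_replay_of_recorded_cells_reproduces_expression(self, small_reference):
        cfg = PseudoSpotConfig(n_spots=25, seed=11)
        expr, _ = simulate_pseudospots(small_reference, cfg, record_cells=True)
        for s, cells in enumerate(expr.sampled_cells):
            replayed = small_reference.counts[cells].sum(axis=0)
            np.testing.assert_array_equal(expr.values[s], replayed)

    def test_proportions_are_exact_cell_count_ratios(self, small_reference):
        cfg = PseudoSpotConfig(n_spots=40, seed=8)
        expr, props = simulate_pseudospots(small_reference, cfg,
                                           record_cells=True)
        np.testing.assert_allclose(props.values.sum(axis=1), 1.0, atol=1e-9)
        for s, cells in enumerate(expr.sampled_cells):
            counts = np.bincount(small_reference.cell_types[cells],
                                 minlength=small_reference.n_types)
            np.testing.assert_allclose(props.values[s], counts / len(cells))

    def test_total_counts_conserved_from_sampled_cells(self, small_reference):
        cfg = PseudoSpotConfig(n_spots=15, seed=13)
        expr, _ = simulate_pseudospots(small_reference, cfg, record_cells=True)
        for s, cells in enumerate(expr.sampled_cells):
            assert expr.values[s].sum() == small_reference.counts[cells].sum()

    def test_deterministic_in_seed(self, small_reference):
        cfg = PseudoSpotConfig(n_spots=10, seed=21)
        e1, p1 = simulate_pseudospots(small_reference, cfg)
        e2, p2 = simulate_pseudospots(small_reference, cfg)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PseudoSpotConfig(n_spots=0)
        with pytest.raises(ValueError):
            PseudoSpotConfig(mu_cells=0.2)
        with pytest.raises(ValueError):
            PseudoSpotConfig(downsample_fraction=0)


class TestDownsampling:
    def test_fraction_one_is_identity(self, counts_matrix):
        out = downsample_counts(counts_matrix, 1.0, seed=0)
        np.testing.assert_array_equal(out.values, counts_matrix.values)

    def test_never_exceeds_input(self, counts_matrix):
        out = downsample_counts(counts_matrix, 0.3, seed=1)
        assert np.all(out.values <= counts_matrix.values)
        assert np.all(out.values >= 0)

    def test_tiny_fraction_zeroes_small_counts(self):
        m = SpotExpressionMatrix([[3, 1], [2, 0]], ["a", "b"], ["g1", "g2"])
        out = downsample_counts(m, 1e-300, seed=2)
        assert np.all(out.values == 0)

    def test_binomial_mean_at_half(self):
        m = SpotExpressionMatrix(np.full((10_000, 1), 100),
                                 [f"s{i}" for i in range(10_000)], ["g"])
        out = downsample_counts(m, 0.5, seed=3)
        assert 48 <= out.values.mean() <= 52

    def test_unbiased_within_four_percent(self):
        count, frac = 40, 0.37
        m = SpotExpressionMatrix(np.full((10_000, 1), count),
                                 [f"s{i}" for i in range(10_000)], ["g"])
        out = downsample_counts(m, frac, seed=4)
        assert abs(out.values.mean() / frac - count) / count < 0.04

    def test_fraction_bounds(self, counts_matrix):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                downsample_counts(counts_matrix, bad)


class TestSlide:
    def test_single_region_labels_uniform(self):
        slide = generate_synthetic_slide(n_rows=5, n_cols=5, n_regions=1, seed=0)
        assert np.all(slide.regions.class_indices == 0)

    def test_patches_of_scale_50_fit_with_margin(self):
        slide = generate_synthetic_slide(n_rows=4, n_cols=4, spacing_px=40,
                                         image_margin_px=30, seed=1)
        h, w = slide.image.shape[:2]
        for x, y in slide.coords.xy:
            assert 25 <= x <= w - 25 and 25 <= y <= h - 25

    def test_labels_match_region_geometry(self):
        slide = generate_synthetic_slide(n_rows=6, n_cols=6, n_regions=3, seed=2)
        # geometric oracle: each spot must fall inside its region's hull box
        for (x, y), reg in zip(slide.coords.xy, slide.regions.class_indices):
            poly = slide.region_geometry[reg]
            x0, y0 = poly.min(axis=0)
            x1, y1 = poly.max(axis=0)
            assert x0 <= x <= x1 and y0 <= y <= y1

    def test_regions_are_contiguous(self):
        slide = generate_synthetic_slide(n_rows=8, n_cols=8, n_regions=4, seed=3)
        lab = slide.regions.class_indices.reshape(8, 8)
        for reg in range(4):
            cells = {tuple(c) for c in np.argwhere(lab == reg)}
            start = next(iter(cells))
            frontier, seen = [start], {start}
            while frontier:
                r, c = frontier.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    if (r + dr, c + dc) in cells and (r + dr, c + dc) not in seen:
                        seen.add((r + dr, c + dc))
                        frontier.append((r + dr, c + dc))
            assert seen == cells

    def test_region_tints_are_discriminative(self):
        slide = generate_synthetic_slide(n_rows=6, n_cols=6, n_regions=2, seed=4)
        lab = slide.regions.class_indices
        means = []
        for reg in range(2):
            pts = slide.coords.xy[lab == reg].astype(int)
            means.append(np.mean([slide.image[y, x] for x, y in pts], axis=0))
        assert np.abs(means[0] - means[1]).max() > 20


class TestArtifacts:
    @pytest.fixture
    def image(self):
        return generate_synthetic_slide(n_rows=6, n_cols=6, seed=5).image

    @pytest.mark.parametrize("kind", ["crack", "fold", "stain",
                                      "crack_fold_stain"])
    def test_deterministic_and_shape_preserving(self, image, kind):
        a = apply_artifact(image, kind, 0.4, seed=7)
        b = apply_artifact(image, kind, 0.4, seed=7)
        np.testing.assert_array_equal(a, b)
        assert a.shape == image.shape

    def test_crack_modifies_small_pixel_fraction(self, image):
        out = apply_artifact(image, "crack", 0.2, seed=8)
        frac = np.mean(np.any(out != image, axis=2))
        assert 0.001 <= frac <= 0.05

    def test_unknown_kind_rejected(self, image):
        with pytest.raises(ValueError, match="unknown artifact"):
            apply_artifact(image, "blur", 0.5)

    def test_severity_bounds(self, image):
        with pytest.raises(ValueError):
            apply_artifact(image, "crack", 0.0)


class TestSlideDataset:
    def test_dominant_type_enriched_in_proportions(self, small_reference):
        slide = generate_synthetic_slide(n_rows=6, n_cols=6, n_regions=3, seed=6)
        cfg = PseudoSpotConfig(n_spots=36, seed=9)
        _, props = simulate_slide_dataset(small_reference, slide, cfg,
                                          dominant_weight=0.7)
        dominant = slide.regions.class_indices % small_reference.n_types
        match = props.values.argmax(axis=1) == dominant
        assert match.mean() > 0.8
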