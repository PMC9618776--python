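import math

import numpy as np
import pandas as pd
import pytest

from embryoquant.io import max_intensity_projection
from embryoquant.masses import MassDetectionParams, detect_masses
from embryoquant.synthetic import (
    DensityError,
    ResolutionError,
    SyntheticConfig,
    axis_ratio_for_circularity,
    ellipse_circularity,
    generate_embryo_stack,
    generate_mass_field,
    generate_nucleus_cohort,
    generate_nucleus_population,
    ramanujan_perimeter,
    render_ellipse,
)


class TestEllipseOracle:
    def test_circle_circularity_exactly_one(self):
        assert ellipse_circularity(5.0, 5.0) == pytest.approx(1.0)

    def test_two_to_one_value(self):
        """8*pi^2*ab/p^2 with Ramanujan p for a=2b gives ~0.8413."""
        assert ellipse_circularity(2.0, 1.0) == pytest.approx(0.8413, abs=5e-4)

    def test_ratio_inversion_round_trips(self):
        for c in (0.99, 0.94, 0.83, 0.6, 0.3):
            r = axis_ratio_for_circularity(c)
            assert ellipse_circularity(r, 1.0) == pytest.approx(c, abs=1e-8)
        assert axis_ratio_for_circularity(1.0) == 1.0


class TestNucleusPopulation:
    def test_circles_have_unit_circularity(self):
        _, gt = generate_nucleus_population(5, 1.0, 5.0, 0.5, seed=3)
        assert np.allclose(gt["circularity"], 1.0)

    def test_axis_ratio_two_ground_truth(self):
        _, gt = generate_nucleus_population(5, 2.0, 5.0, 0.5, seed=3)
        assert np.allclose(gt["circularity"], 0.8413, atol=5e-4)

    def test_seeded_determinism(self):
        m1, g1 = generate_nucleus_population(6, 1.5, 5.0, 0.5, seed=11)
        m2, g2 = generate_nucleus_population(6, 1.5, 5.0, 0.5, seed=11)
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))
        pd.testing.assert_frame_equal(g1, g2)

    def test_resolution_floor_enforced(self):
        """Nuclei whose minor axis would be < 3 px are refused, not rendered."""
        with pytest.raises(ResolutionError):
            generate_nucleus_population(3, 4.0, 2.0, 1.0, seed=0)

    def test_raster_matches_analytic_area(self):
        """Rasterized pixel area agrees with pi*a*b within 5% for minor
        axes of >= 5 px."""
        masks, gt = generate_nucleus_population(8, 2.0, 6.0, 1.0, seed=5)
        for mask, (_, row) in zip(masks, gt.iterrows()):
            raster_area = mask.sum() * 1.0**2
            assert raster_area == pytest.approx(row["area_um2"], rel=0.05)

    def test_cohort_hits_target_distribution(self):
        _, gt = generate_nucleus_cohort(200, 0.83, 0.05, 5.5, 0.5, seed=9)
        assert gt["circularity"].mean() == pytest.approx(0.83, abs=0.015)


class TestMassField:
    def test_planted_mass_true_area(self):
        """A 35 um-radius disc has true area pi*r^2 ~ 0.00385 mm^2."""
        _, gt = generate_mass_field([35.0], (512, 512), 1.0, seed=2)
        assert gt["area_mm2"].iloc[0] == pytest.approx(math.pi * 0.035**2)
        assert gt["area_mm2"].iloc[0] == pytest.approx(0.00385, abs=1e-4)

    def test_empty_field_has_no_masses(self):
        img, gt = generate_mass_field([], (512, 512), 1.0, seed=2)
        assert len(gt) == 0
        assert detect_masses(img, 1.0) == []

    def test_determinism(self):
        i1, _ = generate_mass_field([30, 40], (256, 256), 1.0, seed=8)
        i2, _ = generate_mass_field([30, 40], (256, 256), 1.0, seed=8)
        np.testing.assert_array_equal(i1, i2)

    def test_overcrowding_raises(self):
        with pytest.raises(DensityError):
            generate_mass_field([60] * 30, (256, 256), 1.0, seed=1)


@pytest.fixture(scope="module")
def small_config():
    # field kept several times larger than any mass so whole-MIP threshold
    # statistics remain in their working regime
    return SyntheticConfig(
        shape_zyx=(56, 320, 320), n_surface=8, n_invaded=8, mass_probability=1.0
    )


@pytest.fixture(scope="module")
def stack_and_gt(small_config):
    return generate_embryo_stack(small_config, "emb0", seed=21)


class TestEmbryoStack:

    def test_determinism_bit_for_bit(self, small_config):
        s1, g1 = generate_embryo_stack(small_config, "emb0", seed=21)
        s2, g2 = generate_embryo_stack(small_config, "emb0", seed=21)
        np.testing.assert_array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(g1, g2)

    def test_every_object_has_one_ground_truth_row(self, stack_and_gt, small_config):
        _, gt = stack_and_gt
        assert (gt["kind"] == "nucleus").sum() == 16
        assert (gt["kind"] == "cell").sum() == 16
        assert (gt["kind"] == "surface").sum() == 1
        assert gt.loc[gt["kind"] == "nucleus", "object_id"].is_unique

    def test_populations_straddle_surface(self, stack_and_gt):
        _, gt = stack_and_gt
        surface_z = gt.loc[gt["kind"] == "surface", "surface_z_um"].iloc[0]
        cells = gt[gt["kind"] == "cell"]
        inv = cells[cells["population"] == "invaded"]["center_z_um"]
        surf = cells[cells["population"] == "surface"]["center_z_um"]
        assert (inv > surface_z).all()
        assert (surf <= surface_z).all()

    def test_ground_truth_circularity_in_unit_interval(self, stack_and_gt):
        _, gt = stack_and_gt
        c = gt.loc[gt["kind"] == "nucleus", "circularity"]
        assert ((c > 0) & (c <= 1.0 + 1e-9)).all()

    def test_mass_planting_contract(self, stack_and_gt):
        """Planted mass peaks exceed the reporter MIP's mean + 4 SD even
        after noise, so the detection threshold must recover them."""
        stack, gt = stack_and_gt
        mip = max_intensity_projection(stack, "reporter").astype(float)
        tau = mip.mean() + 4 * mip.std()
        for _, row in gt[gt["kind"] == "mass"].iterrows():
            cy, cx = int(row["center_y_px"]), int(row["center_x_px"])
            peak = mip[cy - 2 : cy + 3, cx - 2 : cx + 3].max()
            assert peak > tau

    def test_no_masses_when_none_planted(self):
        cfg = SyntheticConfig(shape_zyx=(40, 192, 192), n_surface=6, n_invaded=6,
                              mass_probability=0.0)
        stack, gt = generate_embryo_stack(cfg, "emb1", seed=4)
        assert (gt["kind"] == "mass").sum() == 0
        mip = max_intensity_projection(stack, "reporter")
        assert detect_masses(mip, cfg.pixel_size_um, MassDetectionParams()) == []

    def test_fixed_mass_count_and_true_area(self):
        """Requesting 3 masses of ~35 um radius yields 3 ground-truth rows of
        true area ~0.00385 mm^2 each."""
        cfg = SyntheticConfig(shape_zyx=(40, 320, 320), n_surface=4, n_invaded=4,
                              mass_count=3, mass_radius_um=(35.0, 35.0))
        _, gt = generate_embryo_stack(cfg, "emb2", seed=6)
        m = gt[gt["kind"] == "mass"]
        assert len(m) == 3
        assert np.allclose(m["area_mm2"], 0.00385, atol=1e-4)

    def test_positivity_fraction_binomial(self):
        """With positivity fraction 0.3 the positive count concentrates
        around n*p (within 4 binomial SDs at n=300)."""
        cfg = SyntheticConfig(
            shape_zyx=(32, 512, 512), n_surface=0, n_invaded=300,
            nucleus_radius_um=4.0, nucleus_radius_sd_um=0.0,
            invasion_depth_um=(8.0, 12.0),
            marker_positive_fraction={"invaded": 0.3}, mass_probability=0.0,
        )
        _, gt = generate_embryo_stack(cfg, "emb3", seed=17)
        cells = gt[gt["kind"] == "cell"]
        k = int(cells["marker_positive"].sum())
        sd = math.sqrt(300 * 0.3 * 0.7)
        assert abs(k - 90) < 4 * sd

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(marker_positive_fraction={"invaded": 1.4})

    def test_overcrowded_field_raises(self):
        cfg = SyntheticConfig(shape_zyx=(40, 96, 96), n_surface=200, n_invaded=0)
        with pytest.raises(DensityError):
            generate_embryo_stack(cfg, "emb4", seed=0)


class TestRenderEllipse:
    def test_subpixel_area_accuracy(self):
        """Anti-aliased coverage sums to the analytic area within 0.5%."""
        canvas = np.zeros((100, 100))
        render_ellipse(canvas, (50, 50), (30, 15), 0.7)
        assert canvas.sum() == pytest.approx(math.pi * 30 * 15, rel=0.005)

    def test_ramanujan_perimeter_sanity(self):
        assert ramanujan_perimeter(1, 1) == pytest.approx(2 * math.pi)
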