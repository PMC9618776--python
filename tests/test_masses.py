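import math

import numpy as np
import pytest

from embryoquant.masses import (
    DegenerateThresholdWarning,
    MassDetectionParams,
    MassRecord,
    confirm_below_epithelium,
    detect_masses,
    embryo_lateral_area,
    masses_per_embryo,
)
from embryoquant.io import max_intensity_projection
from embryoquant.synthetic import (
    SyntheticConfig,
    generate_embryo_silhouette,
    generate_embryo_stack,
    generate_mass_field,
)


class TestDetection:
    def test_pure_noise_yields_no_masses(self):
        img, _ = generate_mass_field([], (1024, 1024), 1.0, seed=0)
        assert detect_masses(img, 1.0) == []

    def test_planted_disc_found_with_area(self):
        """A 35 um-radius disc well above threshold is found once, with
        measured area within 5% of pi*r^2 ~ 0.00385 mm^2."""
        img, _ = generate_mass_field([35.0], (1024, 1024), 1.0, seed=1)
        recs = detect_masses(img, 1.0)
        assert len(recs) == 1
        assert recs[0].area_mm2 == pytest.approx(math.pi * 0.035**2, rel=0.05)

    def test_subminimum_disc_ignored(self):
        """An object of 0.002 mm^2 falls below the 0.0025 mm^2 floor."""
        r_um = 1000 * math.sqrt(0.002 / math.pi)  # ~25.2 um
        img, _ = generate_mass_field([r_um], (1024, 1024), 1.0, seed=2)
        assert detect_masses(img, 1.0) == []

    def test_boundary_area_exactly_at_minimum_is_kept(self):
        """Only objects strictly smaller than the minimum are dropped."""
        img = np.zeros((250, 250))
        img[50:100, 50:100] = 100.0  # 2500 px = 0.0025 mm^2 at 1 um/px
        recs = detect_masses(img, 1.0)
        assert len(recs) == 1
        assert recs[0].area_mm2 == pytest.approx(0.0025)

    def test_exclusion_mask_removes_object(self):
        img, gt = generate_mass_field([40.0], (512, 512), 1.0, seed=3)
        excl = np.zeros((512, 512), bool)
        cy, cx = int(gt["center_y_px"][0]), int(gt["center_x_px"][0])
        yy, xx = np.mgrid[0:512, 0:512]
        excl[(yy - cy) ** 2 + (xx - cx) ** 2 <= 60**2] = True
        assert detect_masses(img, 1.0, exclusion_mask=excl) == []

    def test_exclusion_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="exclusion"):
            detect_masses(np.zeros((10, 10)), 1.0,
                          exclusion_mask=np.zeros((5, 5), bool))

    def test_constant_image_degenerate_warning(self):
        with pytest.warns(DegenerateThresholdWarning):
            assert detect_masses(np.full((64, 64), 9.0), 1.0) == []


@pytest.fixture(scope="module")
def field():
    return generate_mass_field([35.0, 50.0], (768, 768), 1.0, seed=5)[0]


class TestThresholdProperties:
    def detected_mask_signature(self, img):
        return [(r.pixel_count, r.centroid_yx) for r in detect_masses(img, 1.0)]

    def test_shift_equivariance(self, field):
        """Adding a constant to every pixel leaves detections unchanged."""
        assert (self.detected_mask_signature(field)
                == self.detected_mask_signature(field + 137.0))

    def test_scale_invariance(self, field):
        """Multiplying intensities by k > 0 leaves detections unchanged."""
        assert (self.detected_mask_signature(field)
                == self.detected_mask_signature(field * 3.7))

    def test_min_area_monotonicity(self, field):
        """Raising the minimum area never increases the mass count."""
        counts = [
            len(detect_masses(field, 1.0, MassDetectionParams(min_area_mm2=m)))
            for m in (0.001, 0.0025, 0.004, 0.008, 0.02)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_connectivity_option(self, field):
        for conn in (4, 8):
            recs = detect_masses(field, 1.0, MassDetectionParams(connectivity=conn))
            assert len(recs) == 2


class TestPerEmbryo:
    def test_zero_mass_embryo(self):
        out = masses_per_embryo(
            [MassRecord("e1", 1, 3000, 0.003, (5.0, 5.0))]
        )
        assert out.loc[0, "mass_count"] == 1
        out2 = masses_per_embryo([])
        assert len(out2) == 0

    def test_duplicate_labels_rejected(self):
        recs = [MassRecord("e1", 1, 3000, 0.003, (5.0, 5.0)),
                MassRecord("e1", 1, 2800, 0.0028, (9.0, 9.0))]
        with pytest.raises(ValueError, match="duplicate"):
            masses_per_embryo(recs)

    def test_mean_mass_rate_recovered(self):
        """Planting ~1.4 masses per 'embryo' over 22 fields recovers the mean
        rate within +-0.2 after detection."""
        rng = np.random.default_rng(2024)
        counts = [1, 2, 1, 1, 2, 0, 2, 1, 3, 1, 2, 1, 0, 2, 1, 2, 3, 1, 2, 1, 1, 1]
        assert sum(counts) / 22 == pytest.approx(1.4, abs=0.01)
        detected = 0
        for e, n in enumerate(counts):
            radii = rng.uniform(32, 50, n)
            img, _ = generate_mass_field(radii, (1024, 1024), 1.0,
                                         seed=int(rng.integers(1 << 30)))
            detected += len(detect_masses(img, 1.0, embryo_id=f"e{e}"))
        assert detected / 22 == pytest.approx(1.4, abs=0.2)


@pytest.fixture(scope="module")
def stack_with_mass():
    cfg = SyntheticConfig(shape_zyx=(56, 320, 320), n_surface=6, n_invaded=6,
                          mass_count=1)
    return generate_embryo_stack(cfg, "e", seed=31)


class TestBelowEpithelium:

    def test_planted_internal_mass_confirmed(self, stack_with_mass):
        stack, gt = stack_with_mass
        surface_z = gt.loc[gt["kind"] == "surface", "surface_z_um"].iloc[0]
        mip = max_intensity_projection(stack, "reporter")
        recs = detect_masses(mip, stack.pixel_size_um, embryo_id="e")
        assert len(recs) == 1
        surface_map = np.full((320, 320), surface_z)
        assert confirm_below_epithelium(recs[0], stack, surface_map) is True

    def test_surface_bright_patch_not_confirmed(self):
        """Signal concentrated above the surface plane is rejected."""
        data = np.full((1, 20, 64, 64), 10.0)
        data[0, 2, 20:40, 20:40] = 500.0  # bright at 1 um depth
        from embryoquant.io import ImageStack

        stack = ImageStack(data, 1.0, 0.5, {"reporter": 0})
        rec = MassRecord("e", 1, 400, 4e-4, (29.5, 29.5))
        surface_map = np.full((64, 64), 5.0)  # surface at 5 um
        footprint = np.zeros((64, 64), bool)
        footprint[20:40, 20:40] = True
        assert confirm_below_epithelium(rec, stack, surface_map, footprint) is False

    def test_undefined_surface_unconfirmed_with_warning(self, stack_with_mass):
        stack, _ = stack_with_mass
        mip = max_intensity_projection(stack, "reporter")
        recs = detect_masses(mip, stack.pixel_size_um, embryo_id="e")
        nan_map = np.full((320, 320), np.nan)
        with pytest.warns(UserWarning, match="unconfirmed"):
            assert confirm_below_epithelium(recs[0], stack, nan_map) is False


class TestLateralArea:
    def test_filled_rectangle_exact_area(self):
        """A 1000x530 px bright rectangle at 1 um/px measures 0.53 mm^2.

        The field is several times the embryo so the whole-image threshold
        statistics stay in their working regime, as in 10x acquisitions."""
        img = np.zeros((1500, 2000))
        img[485:1015, 500:1500] = 500.0
        rng = np.random.default_rng(0)
        img += rng.normal(100, 5, img.shape)
        assert embryo_lateral_area(img, 1.0) == pytest.approx(0.53, rel=0.01)

    def test_synthetic_silhouette_within_two_percent(self):
        img, true_area = generate_embryo_silhouette((530, 1000), 1.0, seed=7)
        assert embryo_lateral_area(img, 1.0) == pytest.approx(true_area, rel=0.02)

    def test_manual_polygon_oracle(self):
        """A polygon outline integrates to its shoelace area."""
        # right triangle, legs 300 and 400 px -> area 60000 px^2 = 0.06 mm^2
        poly = np.array([[0, 0], [300, 0], [0, 400]])
        area = embryo_lateral_area(np.zeros((500, 500)), 1.0,
                                   outline_polygon_px=poly)
        assert area == pytest.approx(0.06)

    def test_blank_image_fails(self):
        with pytest.raises(ValueError, match="segmentation failure"):
            embryo_lateral_area(np.zeros((100, 100)), 1.0)
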