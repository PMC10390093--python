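"""Synthetic generators: analytic counts, determinism, cohort invariants."""

import numpy as np
import pytest

from fracmorph.fractal import box_count, estimate_fd
from fracmorph.structure import extract_boundary
from fracmorph.synthetic import (
    GenerationError,
    ShapeSpec,
    default_effect,
    gen_cohort,
    gen_reference_fractal,
    gen_textured_region,
    gen_tumor_mask,
    null_effect,
)
from fracmorph.types import BinaryMask, REGIONS


class TestReferenceFractals:
    def test_filled_square_pixel_and_box_counts(self):
        m = gen_reference_fractal(ShapeSpec(kind="filled_square", depth_or_size=64))
        assert m.n_set == 4096
        curve = box_count(m, scales=[1, 2, 4, 8, 16, 32, 64])
        for s, n in zip(curve.scales, curve.counts):
            assert n == (64 // s) ** 2

    def test_carpet_depth4_pixel_count(self):
        m = gen_reference_fractal(
            ShapeSpec(kind="sierpinski_carpet", depth_or_size=4))
        assert m.shape == (81, 81)
        assert m.n_set == 8 ** 4

    def test_carpet_self_similar_box_counts(self):
        k = 4
        m = gen_reference_fractal(
            ShapeSpec(kind="sierpinski_carpet", depth_or_size=k))
        curve = box_count(m, scales=[3 ** j for j in range(k + 1)])
        for j, n in enumerate(curve.counts):
            assert n == 8 ** (k - j)

    def test_triangle_depth5_pixel_count(self):
        m = gen_reference_fractal(
            ShapeSpec(kind="sierpinski_triangle", depth_or_size=5))
        assert m.shape == (32, 32)
        assert m.n_set == 3 ** 5

    def test_triangle_self_similar_box_counts(self):
        k = 5
        m = gen_reference_fractal(
            ShapeSpec(kind="sierpinski_triangle", depth_or_size=k))
        curve = box_count(m, scales=[2 ** j for j in range(k + 1)])
        for j, n in enumerate(curve.counts):
            assert n == 3 ** (k - j)

    def test_oversized_grid_rejected(self):
        with pytest.raises(GenerationError):
            gen_reference_fractal(
                ShapeSpec(kind="sierpinski_carpet", depth_or_size=9))

    def test_deterministic(self):
        a = gen_reference_fractal(ShapeSpec(kind="sierpinski_carpet",
                                            depth_or_size=3))
        b = gen_reference_fractal(ShapeSpec(kind="sierpinski_carpet",
                                            depth_or_size=3))
        np.testing.assert_array_equal(a.data, b.data)


class TestTumorMask:
    def spec(self, seed=1, **params):
        base = {"base_radius": 40, "roughness_amplitude": 0.0,
                "roughness_frequency": 8, "n_branches": 0,
                "branch_length": 20}
        base.update(params)
        return ShapeSpec(kind="tumor", depth_or_size=256, seed=seed, params=base)

    def test_smooth_disc_boundary_fd_near_one(self):
        m = gen_tumor_mask(self.spec())
        fd = estimate_fd(extract_boundary(m)).D
        assert fd == pytest.approx(1.0, abs=0.15)

    def test_roughness_raises_boundary_fd(self):
        smooth = gen_tumor_mask(ShapeSpec(
            kind="tumor", depth_or_size=256, seed=1,
            params={"base_radius": 40, "roughness_amplitude": 0.0}))
        rough = gen_tumor_mask(ShapeSpec(
            kind="tumor", depth_or_size=256, seed=1,
            params={"base_radius": 40, "roughness_amplitude": 0.6,
                    "roughness_frequency": 16}))
        fd_smooth = estimate_fd(extract_boundary(smooth)).D
        fd_rough = estimate_fd(extract_boundary(rough)).D
        assert fd_rough > fd_smooth

    def test_boundary_fd_monotone_in_roughness_over_seeds(self):
        """Averaged over 20 seeds the boundary FD strictly increases across
        roughness 0 -> 0.3 -> 0.6."""
        means = []
        for amp in (0.0, 0.3, 0.6):
            vals = []
            for seed in range(20):
                m = gen_tumor_mask(ShapeSpec(
                    kind="tumor", depth_or_size=256, seed=seed,
                    params={"base_radius": 40, "roughness_amplitude": amp,
                            "roughness_frequency": 12}))
                vals.append(estimate_fd(extract_boundary(m)).D)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_single_connected_component(self):
        from scipy import ndimage
        for seed in range(5):
            m = gen_tumor_mask(ShapeSpec(
                kind="tumor", depth_or_size=256, seed=seed,
                params={"base_radius": 35, "roughness_amplitude": 0.5,
                        "roughness_frequency": 14, "n_branches": 6,
                        "branch_length": 30}))
            assert ndimage.label(m.data)[1] == 1

    def test_deterministic_given_seed(self):
        spec = ShapeSpec(kind="tumor", depth_or_size=256, seed=42,
                         params={"base_radius": 30, "roughness_amplitude": 0.4,
                                 "n_branches": 3})
        a = gen_tumor_mask(spec)
        b = gen_tumor_mask(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShapeSpec(kind="tumor", depth_or_size=256,
                      params={"roughness_amplitude": 1.5})
        with pytest.raises(ValueError):
            ShapeSpec(kind="tumor", depth_or_size=256,
                      params={"base_radius": -3})


class TestTexturedRegion:
    def test_constant_when_no_contrast_no_noise(self, tumor_mask):
        img = gen_textured_region(tumor_mask, 0.0, 0.0, seed=3)
        inside = img.data[tumor_mask.data]
        assert np.ptp(inside) == 0
        assert (img.data[~tumor_mask.data] == 0).all()

    def test_deterministic(self, tumor_mask):
        a = gen_textured_region(tumor_mask, 2.0, 1.0, seed=9)
        b = gen_textured_region(tumor_mask, 2.0, 1.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_levels_rejected(self, tumor_mask):
        with pytest.raises(ValueError):
            gen_textured_region(tumor_mask, -1.0, 0.0, seed=0)


class TestCohort:
    def test_default_cohort_inventory(self):
        cohort = gen_cohort(n_lgg=4, n_hgg=3, seed=7)
        assert len(cohort) == 7
        for subj in cohort.subjects:
            assert set(subj.masks) == set(REGIONS)
            assert set(subj.images) == set(REGIONS)

    def test_region_containment_and_disjointness(self):
        cohort = gen_cohort(n_lgg=3, n_hgg=3, seed=11, with_images=False)
        for s in cohort.subjects:
            wt = s.masks["whole_tumor"].data
            assert not (s.masks["enhanced_tumor"].data & ~wt).any()
            assert not (s.masks["edema"].data & ~wt).any()
            assert not (s.masks["gm"].data & wt).any()
            assert not (s.masks["wm"].data & wt).any()
            assert all(m.n_set > 0 for m in s.masks.values())

    def test_minimal_cohort(self):
        cohort = gen_cohort(n_lgg=2, n_hgg=2, seed=1, with_images=False)
        assert len(cohort) == 4

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gen_cohort(n_lgg=1, n_hgg=5)

    def test_negative_sd_rejected(self):
        eff = default_effect()
        eff["LGG"]["radius_sd"] = -1.0
        with pytest.raises(ValueError):
            gen_cohort(n_lgg=3, n_hgg=3, effect=eff)

    def test_null_effect_uses_identical_groups(self):
        eff = null_effect()
        assert eff["LGG"] == eff["HGG"]

    def test_subject_reproducible_in_isolation(self):
        a = gen_cohort(n_lgg=3, n_hgg=2, seed=5, with_images=False)
        b = gen_cohort(n_lgg=3, n_hgg=2, seed=5, with_images=False)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.masks["whole_tumor"].data,
                                          sb.masks["whole_tumor"].data)
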