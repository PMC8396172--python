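"""Tumor augmentation, retexture, placement, insertion, and dataset assembly."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from murilung.core import BinaryMask, CTVolume
from murilung.phantom import generate_tumor_bank
from murilung.tumorsim import (
    ConeBeamGeometry,
    PlacementError,
    apply_affine_to_mask,
    augment_tumor,
    boundary_weights,
    compose_tumor_volumes,
    draw_target_volume,
    finalize_training_set,
    forward_project,
    generate_simulated_dataset,
    insert_tumors_in_projections,
    place_tumor,
    random_rotation,
    retexture_tumor,
    sample_tumor_location,
    simulate_tumor_scan,
)


@pytest.fixture(scope="module")
def template(small_bank):
    return small_bank[0]


class TestAugment:
    def test_identity_preserves_volume(self, template):
        out = apply_affine_to_mask(template.mask, np.eye(3))
        assert abs(out.volume_mm3 - template.volume_mm3) <= template.mask.voxel_volume_mm3

    def test_pure_scale_cubes_volume(self, template):
        s = 1.4
        out = apply_affine_to_mask(
            template.mask, s * np.eye(3), target_volume_mm3=template.volume_mm3 * s**3
        )
        assert out.volume_mm3 / template.volume_mm3 == pytest.approx(s**3, rel=0.05)

    def test_rotation_matrices_orthonormal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = random_rotation(rng)
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_volume_law_quantiles(self):
        """The default size law reproduces the configured median and q90."""
        rng = np.random.default_rng(0)
        v = np.array([draw_target_volume(rng) for _ in range(20000)])
        assert np.median(v) == pytest.approx(0.65, rel=0.05)
        assert (v < 10.0).mean() == pytest.approx(0.9, abs=0.01)
        assert v.min() >= 0.03 and v.max() <= 70.0

    def test_augmented_mask_volume_tracks_draw(self, template):
        rng = np.random.default_rng(4)
        for _ in range(10):
            mask, affine = augment_tumor(template, rng, size_range_mm3=(1.0, 30.0))
            assert 0.5 <= mask.volume_mm3 <= 40.0
            assert np.linalg.det(affine) > 0


class TestRetexture:
    def test_interior_statistics_match_targets(self):
        """Sample mean/std of a large retextured interior within 2 standard
        errors of the requested values."""
        m = np.zeros((50, 50, 50), dtype=np.uint8)
        m[2:48, 2:48, 2:48] = 1
        mask = BinaryMask(m, 300.0)
        tex, _ = retexture_tumor(mask, 30.0, 40.0, np.random.default_rng(0))
        inside = tex[mask.as_bool()]
        n = inside.size
        assert abs(inside.mean() - 30.0) < 2 * 40.0 / np.sqrt(n) * 3  # smoothed samples correlate
        assert abs(inside.std() - 40.0) / 40.0 < 0.05

    def test_zero_edge_sigma_returns_binary(self, template):
        _, soft = retexture_tumor(template.mask, 30.0, 40.0, np.random.default_rng(0), 0.0)
        assert np.array_equal(soft, template.mask.voxels.astype(soft.dtype))

    def test_soft_mask_compact_support(self, template):
        edge_sigma_mm = 0.3
        _, soft = retexture_tumor(
            template.mask, 30.0, 40.0, np.random.default_rng(0), edge_sigma_mm
        )
        r = int(np.ceil(4 * edge_sigma_mm / template.mask.spacing_mm)) + 1
        dil = ndi.binary_dilation(
            template.mask.as_bool(), structure=np.ones((3, 3, 3)), iterations=r
        )
        assert np.all(soft[~dil] == 0)

    def test_negative_std_rejected(self, template):
        with pytest.raises(ValueError):
            retexture_tumor(template.mask, 30.0, -1.0, np.random.default_rng(0))


class TestPlacement:
    def test_inverse_distance_weights(self):
        """Voxels at boundary distance 1 vs 2 get 2:1 selection odds."""
        m = np.zeros((5, 5, 7), dtype=np.uint8)
        m[1:4, 1:4, 1:6] = 1
        w = boundary_weights(m)
        # voxel (2,2,1) is 1 voxel from the boundary, (2,2,2) is 2 voxels
        assert w[2, 2, 1] / w[2, 2, 2] == pytest.approx(2.0)

    def test_mask_smaller_than_tumor_raises(self, template):
        tiny = BinaryMask(np.zeros((6, 6, 6), dtype=np.uint8), 300.0)
        tiny.voxels[2:4, 2:4, 2:4] = 1
        with pytest.raises(PlacementError):
            sample_tumor_location(tiny, template.mask, [], np.random.default_rng(0), max_trials=30)

    def test_boundary_bias_versus_uniform(self):
        """Monte-Carlo: accepted centers sit nearer the boundary than uniform
        samples from the same mask."""
        slab = np.zeros((20, 40, 40), np.uint8)
        slab[2:18, 4:36, 4:36] = 1
        lung = BinaryMask(slab, 300.0)
        small = BinaryMask(np.ones((2, 2, 2), dtype=np.uint8), 300.0)
        rng = np.random.default_rng(0)
        d = ndi.distance_transform_edt(slab)
        dists = []
        for _ in range(300):
            center, _, _ = sample_tumor_location(lung, small, [], rng)
            dists.append(d[tuple(center)])
        assert np.mean(dists) < d[slab > 0].mean()

    def test_constraints_hold_and_mask_carved(self, noisy_phantom, small_bank):
        rng = np.random.default_rng(1)
        placed = []
        for i in range(3):
            p = place_tumor(noisy_phantom.lung_mask_truth, small_bank[i % 3].mask, placed, rng)
            assert p.outside_fraction <= 0.10
            for q in placed:
                assert not (p.mask.as_bool() & q.mask.as_bool()).any()
            placed.append(p)


class TestInsertion:
    def test_identity_edit_bit_unchanged(self, small_phantom):
        geom = ConeBeamGeometry.for_volume(small_phantom.image, n_views=12)
        proj = forward_project(small_phantom.image, geom)
        same = small_phantom.image.like(small_phantom.image.voxels.copy())
        out = insert_tumors_in_projections(proj, same, same)
        assert np.array_equal(out.views, proj.views)

    def test_edit_is_additive_in_tumor_minus_parenchyma(self, small_phantom):
        """With zero tumor volume the edit reduces to subtracting the
        parenchyma projections (linearity)."""
        from murilung.tumorsim.projector import forward_project_attenuation
        from murilung.core import from_hounsfield

        geom = ConeBeamGeometry.for_volume(small_phantom.image, n_views=6)
        proj = forward_project(small_phantom.image, geom)
        img = small_phantom.image
        zero = img.like(np.full(img.shape, -1000.0, dtype=np.float32))
        paren = img.like(img.voxels.copy())
        out = insert_tumors_in_projections(proj, zero, paren)
        mu_diff = from_hounsfield(zero.voxels, clamp=False) - from_hounsfield(
            paren.voxels, clamp=False
        )
        expected = proj.views + forward_project_attenuation(mu_diff, img, geom).views
        assert np.allclose(out.views, expected, atol=1e-5)

    def test_compose_outside_support_is_air(self, small_phantom, small_bank):
        rng = np.random.default_rng(2)
        p = place_tumor(small_phantom.lung_mask_truth, small_bank[0].mask, [], rng)
        tex, soft = retexture_tumor(p.mask, 30.0, 40.0, rng)
        tumor, paren, blend = compose_tumor_volumes(small_phantom.image, [p], [tex], [soft])
        outside = blend == 0
        assert np.all(tumor.voxels[outside] == -1000.0)
        assert np.all(paren.voxels[outside] == -1000.0)
        inside = p.mask.as_bool()
        assert np.allclose(paren.voxels[inside], small_phantom.image.voxels[inside])


class TestFinalize:
    def test_crop_arithmetic_without_magnification(self):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(size=(200, 200, 200)).astype(np.float32), 300.0)
        lung = np.zeros((200, 200, 200), dtype=np.uint8)
        lung[40:91, 40:91, 40:91] = 1
        labels = np.zeros_like(lung)
        labels[60:63, 60:63, 60:63] = 1

        class _FixedRng:
            def uniform(self, lo, hi):
                return 1.0

        img, lab = finalize_training_set(
            vol, BinaryMask(labels, 300.0), BinaryMask(lung, 300.0), _FixedRng()
        )
        assert img.shape == (111, 111, 111)  # [10, 121) per axis
        assert lab.voxels.sum() == labels.sum()
        assert np.array_equal(img.voxels, vol.voxels[10:121, 10:121, 10:121])

    def test_magnification_keeps_labels_inside(self, noisy_phantom, small_bank):
        rng = np.random.default_rng(5)
        img, labels, _ = simulate_tumor_scan(
            noisy_phantom.image, noisy_phantom.lung_mask_truth, small_bank, rng,
            n_tumors=1, method="voxel", size_range_mm3=(6.0, 20.0), min_tumor_mm3=6.0,
        )
        out_img, out_lab = finalize_training_set(
            img, labels, noisy_phantom.lung_mask_truth, np.random.default_rng(9), pad_voxels=5
        )
        assert out_lab.voxels.sum() > 0
        assert out_img.shape == out_lab.shape


class TestDataset:
    def test_counts_split_and_determinism(self, noisy_phantom, small_bank):
        kwargs = dict(
            n_sets=6, tumors_per_set=2, n_validation=2, method="voxel",
            size_range_mm3=(6.0, 20.0), min_tumor_mm3=6.0,
        )
        sets, manifest = generate_simulated_dataset(
            [noisy_phantom], small_bank, np.random.default_rng(21), **kwargs
        )
        assert len(sets) == 6
        assert sum(s.is_validation for s in sets) == 2
        assert sum(len(s.tumors) for s in sets) == 12
        for s in sets:
            _, n = ndi.label(s.labels.as_bool(), structure=np.ones((3, 3, 3)))
            assert 1 <= n <= 2  # two tumors; adjacency can merge at most once
            for t in s.tumors:
                assert t["outside_fraction"] <= 0.10
        _, manifest2 = generate_simulated_dataset(
            [noisy_phantom], small_bank, np.random.default_rng(21), **kwargs
        )
        assert manifest == manifest2

    def test_default_counts_match_study_design(self, noisy_phantom, small_bank):
        """60 sets, 13 validation, two tumors each (120 total)."""
        sets, manifest = generate_simulated_dataset(
            [noisy_phantom], small_bank, np.random.default_rng(3),
            method="voxel", size_range_mm3=(6.0, 20.0), min_tumor_mm3=6.0,
        )
        assert manifest["n_sets"] == 60 and len(sets) == 60
        assert sum(s.is_validation for s in sets) == 13
        assert sum(len(s.tumors) for s in sets) == 120
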