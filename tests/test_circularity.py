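import numpy as np
import pytest
from scipy import ndimage

from chromodyn import (
    DynamicsParams,
    Image2D,
    ImageStack,
    INVIVO_SCHEME,
    SLICE_SCHEME,
    classify_ci,
    compute_ci,
    eigen3d,
    evolve_label,
    make_line_label,
    weighted_pca_2d,
)

from conftest import ci_of_mask


def brute_force_weighted_cov(px, threshold):
    """Explicit-summation oracle for the brightness-weighted 2D covariance."""
    wsum = 0.0
    cy = cx = 0.0
    pts = [
        (y, x, px[y, x])
        for y in range(px.shape[0])
        for x in range(px.shape[1])
        if px[y, x] > threshold
    ]
    wsum = sum(w for *_ , w in pts)
    cy = sum(y * w for y, _, w in pts) / wsum
    cx = sum(x * w for _, x, w in pts) / wsum
    syy = sxx = sxy = 0.0
    for y, x, w in pts:
        syy += w * (y - cy) ** 2
        sxx += w * (x - cx) ** 2
        sxy += w * (y - cy) * (x - cx)
    cov = np.array([[syy, sxy], [sxy, sxx]]) / wsum
    return np.sort(np.linalg.eigvalsh(cov))[::-1]


class TestWeightedPCA2D:
    def test_two_to_one_rectangle_ratio(self):
        px = np.zeros((64, 64))
        px[22:42, 12:52] = 1.0  # 20 x 40 uniform rectangle
        eig_major, eig_minor, _ = weighted_pca_2d(Image2D(px))
        assert eig_minor / eig_major == pytest.approx(0.25, abs=0.02)

    def test_uniform_square_has_equal_eigenvalues(self):
        px = np.zeros((40, 40))
        px[10:30, 10:30] = 1.0
        eig_major, eig_minor, _ = weighted_pca_2d(Image2D(px))
        assert eig_minor == pytest.approx(eig_major, rel=1e-12)

    def test_uniform_intensity_rescale_keeps_ratio(self):
        px = np.zeros((40, 40))
        px[10:20, 5:35] = 1.0
        full = weighted_pca_2d(Image2D(px))
        dimmed = weighted_pca_2d(Image2D(0.9 * px))
        assert dimmed[1] / dimmed[0] == pytest.approx(full[1] / full[0], rel=1e-12)

    def test_matches_brute_force_to_1e9(self):
        rng = np.random.default_rng(42)
        px = rng.uniform(0, 1, (64, 64))
        eig_major, eig_minor, _ = weighted_pca_2d(Image2D(px), threshold=0.25)
        oracle = brute_force_weighted_cov(px, 0.25)
        assert eig_major == pytest.approx(oracle[0], rel=1e-9)
        assert eig_minor == pytest.approx(oracle[1], rel=1e-9)

    def test_degenerate_labels_are_errors(self):
        lone = np.zeros((10, 10))
        lone[5, 5] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            weighted_pca_2d(Image2D(lone))
        with pytest.raises(ValueError, match="degenerate"):
            weighted_pca_2d(Image2D(np.zeros((10, 10))))


class TestComputeCI:
    def test_straight_line_is_near_zero(self):
        mask = np.zeros((64, 64))
        mask[32, 10:54] = 1.0
        assert ci_of_mask(mask) < 0.05

    def test_filled_disk_is_one(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 20**2).astype(float)
        assert ci_of_mask(disk) == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("angle_deg", [15, 45, 75, 120])
    def test_rotated_line_keeps_ci(self, circular_geometry, clean_render, angle_deg):
        base_mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        rot_mask, _ = make_line_label(
            circular_geometry, 1, np.deg2rad(angle_deg), clean_render
        )
        assert abs(ci_of_mask(rot_mask) - ci_of_mask(base_mask)) < 0.02

    def test_ci_in_unit_interval_for_noisy_labels(self, geometry, default_render):
        _, stack = make_line_label(geometry, 2, 0.7, default_render)
        res = compute_ci(stack)
        assert 0.0 <= res.ci <= 1.0
        assert res.eig_major >= res.eig_minor >= 0.0
        assert res.n_pixels >= 2


def planar_label_stack(n=48, radius=14, z_sigma=2.5, smooth=1.5):
    """Thin plane of label: axial extent ~2 um (a few voxels at 0.368 um),
    PSF-smoothed in-plane as a deconvolved confocal label would be."""
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2
    disk = (((yy[0] - c) ** 2 + (xx[0] - c) ** 2) <= radius**2).astype(float)
    disk = ndimage.gaussian_filter(disk, smooth)
    label = np.exp(-((zz - c) ** 2) / (2 * z_sigma**2)) * disk[None]
    return ImageStack(label, voxel_size=(0.368,) * 3)


class TestEigen3D:
    def test_isotropic_blob_has_equal_eigenvalues(self):
        n = 40
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2
        blob = np.exp(-((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) / (2 * 5.0**2))
        res = eigen3d(ImageStack(blob, voxel_size=(0.368,) * 3))
        assert res.eig2 == pytest.approx(res.eig1, rel=0.05)
        assert res.eig3 == pytest.approx(res.eig1, rel=0.05)

    def test_planar_label_flat_then_diffusion_raises_third_eigenvalue(self):
        stack = planar_label_stack()
        before = eigen3d(stack)
        assert before.eig3 < 0.2 * before.eig2
        evolved = evolve_label(
            stack.voxels,
            DynamicsParams(model="isotropic_diffusion", rate=0.5, seed=1),
            dt=30.0,
        )
        after = eigen3d(ImageStack(evolved, voxel_size=(0.368,) * 3))
        assert after.eig3 > before.eig3

    def test_rigid_rotation_preserves_eigenvalue_triple(self):
        stack = planar_label_stack()
        angle = np.deg2rad(30)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        center = (np.array(stack.shape) - 1) / 2.0
        rotated = ndimage.affine_transform(
            stack.voxels, rot, offset=center - rot @ center, order=3
        )
        res0 = eigen3d(stack)
        res1 = eigen3d(ImageStack(np.clip(rotated, 0, None), voxel_size=(0.368,) * 3))
        for a, b in zip(res0.eigs, res1.eigs):
            assert b == pytest.approx(a, rel=0.05)

    def test_zflat_label_top_two_match_mip_pca(self):
        n = 40
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        c = (n - 1) / 2
        plane = np.exp(-(((yy - c) / 8.0) ** 2 + ((xx - c) / 4.0) ** 2))
        vox = np.zeros((n, n, n))
        vox[18:21] = plane  # constant across three z planes
        stack = ImageStack(vox, voxel_size=(0.368,) * 3)
        res3d = eigen3d(stack, threshold=0.1)
        mip = Image2D(vox.max(axis=0))
        eig_major, eig_minor, _ = weighted_pca_2d(mip, threshold=0.1)
        assert res3d.eig1 == pytest.approx(eig_major, rel=0.05)
        assert res3d.eig2 == pytest.approx(eig_minor, rel=0.05)

    def test_too_few_voxels_is_error(self):
        vox = np.zeros((8, 8, 8))
        vox[4, 4, 4] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            eigen3d(ImageStack(vox, voxel_size=(0.368,) * 3))


class TestClassifyCI:
    @pytest.mark.parametrize(
        "ci,scheme,expected",
        [
            (0.04, SLICE_SCHEME, "low"),
            (0.30, SLICE_SCHEME, "high"),
            (0.10, SLICE_SCHEME, "medium"),
            (0.15, INVIVO_SCHEME, "medium"),
            (0.05, INVIVO_SCHEME, "low"),
            (0.25, INVIVO_SCHEME, "high"),
        ],
    )
    def test_examples(self, ci, scheme, expected):
        label, _ = classify_ci(ci, scheme)
        assert label == expected

    def test_slice_scheme_gap_is_flagged_medium(self):
        label, gap = classify_ci(0.20, SLICE_SCHEME)
        assert label == "medium" and gap
        label, gap = classify_ci(0.10, SLICE_SCHEME)
        assert label == "medium" and not gap

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            classify_ci(1.2, SLICE_SCHEME)
        with pytest.raises(ValueError):
            classify_ci(-0.1, INVIVO_SCHEME)

    def test_every_ci_maps_to_exactly_one_label(self):
        for ci in np.linspace(0, 1, 101):
            for scheme in (SLICE_SCHEME, INVIVO_SCHEME):
                label, _ = classify_ci(float(ci), scheme)
                assert label in ("low", "medium", "high")
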