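import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromodyn import (
    CohortConfig,
    CohortGroup,
    DynamicsParams,
    NucleusGeometry,
    RenderParams,
    evolve_label,
    make_line_label,
    make_pan_nucleus,
    simulate_behavior_video,
    simulate_cohort,
    score_freezing,
    weighted_pca_2d,
)
from chromodyn.stacks import Image2D
from chromodyn.synthetic import _deposit, _mask_to_quanta

from conftest import ci_of_mask


class TestMakePanNucleus:
    def test_zero_granularity_is_homogeneous_inside(self, geometry, clean_render):
        stack = make_pan_nucleus(geometry, 0.0, clean_render)
        plane = stack.voxels[stack.shape[0] // 2]
        inner = NucleusGeometry(geometry.center, tuple(a - 2 for a in geometry.semi_axes))
        yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
        pts = np.stack([yy, xx], axis=-1).reshape(-1, 2)
        vals = plane.reshape(-1)[inner.contains(pts)]
        assert vals.std() / vals.mean() == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, geometry):
        render = RenderParams(seed=9)
        a = make_pan_nucleus(geometry, 0.7, render)
        b = make_pan_nucleus(geometry, 0.7, render)
        assert np.array_equal(a.voxels, b.voxels)

    def test_background_only_outside_nucleus(self, geometry, clean_render):
        stack = make_pan_nucleus(geometry, 0.9, clean_render)
        corner = stack.voxels[:, :4, :4]
        assert np.allclose(corner, 0.0)

    def test_invalid_inputs(self, geometry, clean_render):
        with pytest.raises(ValueError, match="granularity"):
            make_pan_nucleus(geometry, 1.5, clean_render)
        huge = NucleusGeometry(center=(32, 32), semi_axes=(40, 40))
        with pytest.raises(ValueError, match="frame"):
            make_pan_nucleus(huge, 0.5, clean_render)


class TestMakeLineLabel:
    def test_width_one_horizontal_segment(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        ys, xs = np.nonzero(mask)
        assert set(ys) == {32}  # single row through the centre
        assert np.ptp(xs) >= 2 * 0.9 * circular_geometry.semi_axes[1] - 2

    def test_line_ci_below_paper_anchor(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        assert ci_of_mask(mask) < 0.05

    def test_default_noise_still_gives_thin_line_ci(self, circular_geometry):
        from chromodyn import compute_ci

        _, stack = make_line_label(circular_geometry, 1, 0.3, RenderParams(seed=2))
        assert compute_ci(stack).ci < 0.05

    def test_invalid_width(self, circular_geometry, clean_render):
        with pytest.raises(ValueError):
            make_line_label(circular_geometry, 0, 0.0, clean_render)


class TestEvolveLabel:
    def test_stable_is_identity(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        out = evolve_label(mask, DynamicsParams(model="stable"), dt=120.0)
        assert np.array_equal(out, mask)

    def test_quarter_turn_makes_vertical_line(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        out = evolve_label(
            mask, DynamicsParams(model="rigid_rotation", rate=np.pi / 2), dt=1.0
        )
        ys, xs = np.nonzero(out > 0.05)
        assert np.ptp(xs) <= 3 and np.ptp(ys) > 30
        assert abs(ci_of_mask(out) - ci_of_mask(mask)) < 0.02

    def test_rotations_compose(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 2, 0.4, clean_render)
        two_step = evolve_label(
            evolve_label(mask, DynamicsParams(model="rigid_rotation", rate=0.3), 1.0),
            DynamicsParams(model="rigid_rotation", rate=0.4),
            1.0,
        )
        one_step = evolve_label(
            mask, DynamicsParams(model="rigid_rotation", rate=0.7), 1.0
        )
        assert two_step.sum() == pytest.approx(one_step.sum(), rel=1e-9)
        ea = weighted_pca_2d(Image2D(two_step), threshold=0.05)
        eb = weighted_pca_2d(Image2D(one_step), threshold=0.05)
        assert ea[0] == pytest.approx(eb[0], rel=0.05)
        assert np.allclose(ea[2], eb[2], atol=0.2)  # centroids agree

    def test_mass_conserved_within_1pct(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 2, 1.1, clean_render)
        for model, rate in [
            ("rigid_rotation", 0.5),
            ("isotropic_diffusion", 0.3),
            ("directed_flow", 0.2),
        ]:
            out = evolve_label(
                mask,
                DynamicsParams(model=model, rate=rate, seed=3),
                dt=10.0,
                geometry=circular_geometry,
            )
            assert out.sum() == pytest.approx(mask.sum(), rel=0.01)

    def test_diffusion_converges_to_filled_disk_ci(self, circular_geometry, clean_render):
        mask, _ = make_line_label(circular_geometry, 1, 0.0, clean_render)
        dyn = DynamicsParams(model="isotropic_diffusion", rate=2.0, seed=5)
        rng = np.random.default_rng(11)
        m = mask
        for _ in range(20):
            m = evolve_label(m, dyn, dt=10.0, geometry=circular_geometry, rng=rng)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 20**2).astype(float)
        assert ci_of_mask(m) > 0.85
        assert ci_of_mask(m) == pytest.approx(ci_of_mask(disk), abs=0.1)

    def test_directed_flow_is_deterministic_and_moves_label(
        self, circular_geometry, clean_render
    ):
        mask, _ = make_line_label(circular_geometry, 2, 0.0, clean_render)
        dyn = DynamicsParams(model="directed_flow", rate=1.0)
        a = evolve_label(mask, dyn, 5.0, geometry=circular_geometry)
        b = evolve_label(mask, dyn, 5.0, geometry=circular_geometry)
        assert np.array_equal(a, b)
        assert np.abs(a - mask).sum() > 1.0

    def test_unknown_model_is_error(self):
        with pytest.raises(ValueError, match="unknown dynamics model"):
            DynamicsParams(model="levitation", rate=1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**16))
def test_quanta_deposition_conserves_mass(seed):
    """Splitting a mask into quanta and re-depositing conserves total mass."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((24, 24))
    n = rng.integers(3, 30)
    mask[rng.integers(4, 20, n), rng.integers(4, 20, n)] = rng.uniform(0.2, 1.0, n)
    pts, w = _mask_to_quanta(mask)
    jittered = pts + rng.uniform(-1.5, 1.5, pts.shape)  # stay inside the grid
    out = _deposit(np.clip(jittered, 0, 23), w, mask.shape)
    assert out.sum() == pytest.approx(mask.sum(), rel=1e-9)


class TestSimulateCohort:
    def test_static_control_cohort_is_flat(self):
        cfg = CohortConfig(
            groups={"control": CohortGroup(n_cells=10, fraction_dynamic=0.0)},
            times=(0.0, 30.0, 60.0, 90.0),
            render=RenderParams(shape=(5, 48, 48)),
            seed=4,
        )
        cohort = simulate_cohort(cfg)
        from chromodyn import build_series

        for s in build_series(cohort):
            vals = np.asarray(s.values)
            assert np.nanmax(np.abs(vals - vals[0])) < 0.05

    def test_reproducible_truth_and_stacks(self):
        cfg = CohortConfig(
            groups={"g": CohortGroup(n_cells=3, fraction_dynamic=0.5)},
            times=(0.0, 60.0),
            render=RenderParams(shape=(5, 48, 48)),
            seed=8,
        )
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for ca, cb in zip(a.truth.cells, b.truth.cells):
            assert ca.cell_id == cb.cell_id and ca.dynamics == cb.dynamics
            for ma, mb in zip(ca.masks, cb.masks):
                assert np.array_equal(ma, mb)
        for cell_id in a.stacks:
            for sa, sb in zip(a.stacks[cell_id], b.stacks[cell_id]):
                assert np.array_equal(sa.voxels, sb.voxels)

    def test_empty_groups_are_errors(self):
        with pytest.raises(ValueError):
            CohortConfig(groups={}, seed=0)
        with pytest.raises(ValueError):
            CohortGroup(n_cells=0)

    def test_time_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CohortConfig(
                groups={"g": CohortGroup(n_cells=1)}, times=(0.0, 0.0, 60.0), seed=0
            )


class TestSimulateBehaviorVideo:
    def test_all_still_and_all_moving(self):
        still, _ = simulate_behavior_video(20, 10, [], seed=0)
        assert score_freezing(still).fractions["all"] == 1.0
        moving, _ = simulate_behavior_video(20, 10, [(0, 20, True)], seed=0)
        assert score_freezing(moving).fractions["all"] == 0.0

    def test_baseline_window_only_still(self):
        video, _ = simulate_behavior_video(
            90,
            10,
            [(0, 30, True), (60, 90, True)],
            seed=1,
            periods=[("baseline", 30, 60), ("session", 0, 90)],
        )
        report = score_freezing(video)
        assert report.fractions["baseline"] == pytest.approx(1.0, abs=2 * (1 / 10) / 30)
        assert report.fractions["session"] < 1.0

    def test_invalid_schedules(self):
        with pytest.raises(ValueError):
            simulate_behavior_video(10, 0, [])
        with pytest.raises(ValueError, match="overlap"):
            simulate_behavior_video(10, 5, [(0, 5, True), (4, 8, True)])
        with pytest.raises(ValueError, match="duration"):
            simulate_behavior_video(10, 5, [(5, 15, True)])
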