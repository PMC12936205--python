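"""Tracer-transport model: stepping rules, run-duration distributions and
model-vs-reference comparison."""

import numpy as np
import pytest

from synaptrack.actin_flow import FlowField
from synaptrack.geometry import CellGeometry
from synaptrack.pipeline import _reference_distribution
from synaptrack.tracer import (
    DurationDistribution,
    _run_lengths,
    distribution_mse,
    init_tracers,
    mode2_threshold_sweep,
    outward_time_distribution,
    run_simulation,
    step_mode1,
    step_mode2,
)

GEOM = CellGeometry.disc((160, 160), (80.0, 80.0), 72.0, 18.0)
PX = 41.6
NO_EDGES = np.empty((0, 2), dtype=int)


def _radii(tracers):
    return np.array([GEOM.radii(t.x, t.y) for t in tracers])


class TestInitTracers:
    def test_hundred_tracers_inside_the_annulus(self):
        tracers = init_tracers(100, GEOM, seed=1)
        assert len(tracers) == 100
        r = _radii(tracers)
        assert np.all(r >= GEOM.csmac_radius) and np.all(r <= GEOM.cell_radius)

    def test_seed_reproducibility(self):
        a = init_tracers(20, GEOM, seed=5)
        b = init_tracers(20, GEOM, seed=5)
        assert all(t1.x == t2.x and t1.y == t2.y for t1, t2 in zip(a, b))

    def test_zero_tracers_is_an_error(self):
        with pytest.raises(ValueError):
            init_tracers(0, GEOM, seed=1)

    def test_degenerate_geometry_is_an_error(self):
        bad = CellGeometry.disc((40, 40), (20.0, 20.0), 10.0, 5.0)
        bad.csmac_radius = bad.cell_radius
        with pytest.raises(ValueError):
            init_tracers(5, bad, seed=1)


class TestStepMode1:
    def test_without_wavefronts_tracers_march_inward_until_the_csmac(self):
        tracers = init_tracers(30, GEOM, seed=2)
        r_prev = _radii(tracers)
        for _ in range(150):
            step_mode1(tracers, NO_EDGES, GEOM, dt=1.0, pixel_size=PX, wave_speed=40.0)
            r = _radii(tracers)
            assert np.all(r <= r_prev + 1e-9)
            r_prev = r
        assert np.all(np.abs(r_prev - GEOM.csmac_radius) < 1e-6)

    def test_edge_within_scan_radius_couples_the_tracer(self):
        # scan radius 300 nm: an edge 100 nm away captures, 400 nm does not
        tracers = [init_tracers(1, GEOM, seed=3)[0]]
        tracers[0].x, tracers[0].y = 120.0, 80.0
        near = np.array([[120 + round(100 / PX), 80]])  # ~100 nm away
        step_mode1(tracers, near, GEOM, dt=1.0, pixel_size=PX, wave_speed=40.0)
        assert tracers[0].state == "wave_coupled"
        assert GEOM.radii(tracers[0].x, tracers[0].y) > 40.0  # moved outward

        far_tracer = [init_tracers(1, GEOM, seed=3)[0]]
        far_tracer[0].x, far_tracer[0].y = 120.0, 80.0
        far = np.array([[120 + round(400 / PX), 80]])
        step_mode1(far_tracer, far, GEOM, dt=1.0, pixel_size=PX, wave_speed=40.0)
        assert far_tracer[0].state == "free"


class TestStepMode2:
    def _uniform_field(self, radial_speed):
        # radial vectors on a grid covering the whole annulus so every
        # tracer finds vectors inside its scan disc
        step = 8
        gx, gy = np.meshgrid(np.arange(8, 152, step), np.arange(8, 152, step))
        x, y = gx.ravel().astype(float), gy.ravel().astype(float)
        r = GEOM.radii(x, y)
        keep = (r > GEOM.csmac_radius) & (r < GEOM.cell_radius)
        x, y = x[keep], y[keep]
        ux, uy = GEOM.outward_unit(x, y)
        return FlowField((0, 1), x, y, radial_speed * ux, radial_speed * uy, 32, 16)

    def test_threshold_above_all_flow_reduces_to_pure_retrograde(self):
        field = self._uniform_field(40.0)
        a = run_simulation(2, [field] * 20, GEOM, 20, seed=4, pixel_size=PX,
                           frame_interval=1.0, n_tracers=25, speed_threshold=1e6)
        b = run_simulation(1, [NO_EDGES] * 20, GEOM, 20, seed=4, pixel_size=PX,
                           frame_interval=1.0, n_tracers=25, wave_speed=40.0)
        np.testing.assert_allclose(a, b)

    def test_outward_field_above_threshold_carries_all_tracers_outward(self):
        field = self._uniform_field(40.0)
        tracers = init_tracers(25, GEOM, seed=5)
        r0 = _radii(tracers)
        step_mode2(tracers, field, speed_threshold=13.0, geometry=GEOM, dt=1.0, pixel_size=PX)
        r1 = _radii(tracers)
        moved = r0 < GEOM.cell_radius - 1.0
        assert np.all(r1[moved] > r0[moved])
        assert all(t.state == "flow_coupled" for t in tracers)


class TestRunSimulation:
    def test_pure_retrograde_kinematics(self):
        traj = run_simulation(1, [NO_EDGES] * 10, GEOM, 10, seed=6, pixel_size=PX,
                              frame_interval=1.0, n_tracers=40, wave_speed=40.0,
                              default_speed=50.0)
        r0 = np.hypot(traj[:, 0, 0] - 80, traj[:, 0, 1] - 80)
        r1 = np.hypot(traj[:, -1, 0] - 80, traj[:, -1, 1] - 80)
        free_run = r0 - 10 * 50.0 / PX > GEOM.csmac_radius  # never hit the boundary
        assert np.allclose((r0 - r1)[free_run] * PX, 10 * 50.0, rtol=1e-6)

    def test_trajectories_deterministic_given_seed(self):
        a = run_simulation(1, [NO_EDGES] * 5, GEOM, 5, seed=7, pixel_size=PX,
                           frame_interval=1.0, n_tracers=10, wave_speed=40.0)
        b = run_simulation(1, [NO_EDGES] * 5, GEOM, 5, seed=7, pixel_size=PX,
                           frame_interval=1.0, n_tracers=10, wave_speed=40.0)
        np.testing.assert_array_equal(a, b)

    def test_tracer_count_and_bounds_conserved(self, primary_batch):
        gt = primary_batch[0]["ground_truth"]
        edge_sets = [gt.wavefront_edges_at(t) for t in range(60)]
        traj = run_simulation(1, edge_sets, gt.geometry, 59, seed=8,
                              pixel_size=PX, frame_interval=1.0, n_tracers=50,
                              wave_speed=gt.profile.wave_speed)
        assert traj.shape[0] == 50
        r = np.hypot(traj[..., 0] - gt.geometry.center[0], traj[..., 1] - gt.geometry.center[1])
        assert np.all(r <= gt.geometry.cell_radius + 1e-6)
        assert np.all(r >= gt.geometry.csmac_radius - 1e-6)

    def test_wavefronts_induce_outward_runs(self, primary_batch):
        gt = primary_batch[0]["ground_truth"]
        edge_sets = [gt.wavefront_edges_at(t) for t in range(gt.n_frames)]
        traj = run_simulation(1, edge_sets, gt.geometry, gt.n_frames - 1, seed=9,
                              pixel_size=PX, frame_interval=1.0, n_tracers=100,
                              wave_speed=gt.profile.wave_speed)
        outward, inward = outward_time_distribution(traj, gt.geometry, dt=1.0)
        assert outward is not None and len(outward.durations) > 0

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(1, [NO_EDGES] * 3, GEOM, 10, seed=0, pixel_size=PX,
                           frame_interval=1.0, wave_speed=40.0)


class TestRunLengths:
    def test_alternating_increments_give_unit_runs(self):
        inc = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        out, inw = _run_lengths(inc)
        assert out == [1, 1, 1] and inw == [1, 1]

    def test_zero_increments_break_runs_without_starting_new_ones(self):
        inc = np.array([1.0, 1.0, 0.0, 1.0, -1.0, 0.0, -1.0])
        out, inw = _run_lengths(inc)
        assert out == [2, 1] and inw == [1, 1]


class TestDurationDistribution:
    def test_pure_retrograde_run_is_a_single_inward_spike(self):
        traj = run_simulation(1, [NO_EDGES] * 8, GEOM, 8, seed=10, pixel_size=PX,
                              frame_interval=1.0, n_tracers=5, wave_speed=40.0)
        outward, inward = outward_time_distribution(traj, GEOM, dt=1.0)
        assert outward is None
        assert np.all(inward.durations == 8.0)

    def test_density_normalization_is_exact(self):
        dist = DurationDistribution.from_durations([1, 2, 2, 3, 5, 8, 8, 9], bins=5)
        widths = np.diff(dist.bin_edges)
        assert abs(np.sum(dist.densities * widths) - 1.0) < 1e-9

    def test_kde_curve_is_non_negative(self):
        dist = DurationDistribution.from_durations([1, 2, 3, 10, 12], bins=6)
        assert np.all(dist.kde_curve >= 0)

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            DurationDistribution.from_durations([])


class TestDistributionMse:
    def test_self_distance_is_zero_and_symmetric(self):
        a = DurationDistribution.from_durations([1, 2, 3, 4, 10], bins=4)
        b = DurationDistribution.from_durations([2, 3, 5, 9, 11], bins=4)
        assert distribution_mse(a, a) == 0.0
        assert distribution_mse(a, b) == pytest.approx(distribution_mse(b, a))

    def test_wave_coupled_model_beats_pure_retrograde_control(self, primary_batch):
        gt = primary_batch[0]["ground_truth"]
        ref_out, _ = _reference_distribution(gt)
        edge_sets = [gt.wavefront_edges_at(t) for t in range(gt.n_frames)]
        traj1 = run_simulation(1, edge_sets, gt.geometry, gt.n_frames - 1, seed=11,
                               pixel_size=PX, frame_interval=1.0, n_tracers=100,
                               wave_speed=gt.profile.wave_speed)
        out1, _ = outward_time_distribution(traj1, gt.geometry, dt=1.0)
        mse_model = distribution_mse(out1, ref_out)
        # control: no outward motion at all -> compare reference to silence
        mse_control = float(np.mean(ref_out.kde_at(ref_out.bin_centers) ** 2))
        assert mse_model < mse_control

    def test_none_rejected(self):
        a = DurationDistribution.from_durations([1, 2, 3], bins=3)
        with pytest.raises(ValueError):
            distribution_mse(a, None)


class TestThresholdSweep:
    def test_moderate_thresholds_beat_excessive_ones(self, primary_batch):
        # thresholds in the 13-33 nm/s range should match the reference
        # closely while a threshold above all real flow degrades sharply
        cell = primary_batch[0]
        gt = cell["ground_truth"]
        ref_out, _ = _reference_distribution(gt)
        sweep = mode2_threshold_sweep(
            cell["flow_fields"], gt.geometry, ref_out,
            thresholds=(13.0, 23.0, 33.0, 60.0),
            n_steps=gt.n_frames - 1, seed=12, pixel_size=PX, frame_interval=1.0,
            n_tracers=100,
        )
        mid = max(sweep[13.0], sweep[23.0], sweep[33.0])
        assert sweep[60.0] > 3 * mid
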