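"""Predictive linking, motility filtering, direction classification and
track statistics."""

import numpy as np
import pandas as pd
import pytest

from synaptrack.geometry import CellGeometry, radial_normalize
from synaptrack.tracking import (
    Track,
    classify_direction,
    directional_fraction,
    filter_motile,
    intensity_density,
    link,
    link_nearest_neighbor,
    track_speed,
    tracks_to_dataframe,
)

GEOM = CellGeometry.disc((160, 160), (80.0, 80.0), 72.0, 18.0)


def _features(rows):
    return pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"])


class TestLink:
    def test_two_stationary_particles_give_two_full_tracks(self):
        rows = []
        for t in range(10):
            rows.append((t, 10.0, 10.0, 1.0))
            rows.append((t, 40.0, 40.0, 1.0))
        tracks = link(_features(rows), search_range=5)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_predictive_linking_resolves_a_crossing_nearest_neighbor_swaps(self):
        # two particles with opposite velocities passing each other: after
        # the crossing, each is closer to the other's previous position, so
        # zero-velocity (nearest-neighbor) linking swaps identities while
        # velocity extrapolation keeps them
        rows = []
        for t in range(11):
            rows.append((t, 4.0 * t, 10.0, 1.0))          # rightward, 4 px/frame
            rows.append((t, 41.0 - 4.0 * t, 10.5, 1.0))   # leftward, 4 px/frame
        feats = _features(rows)

        predictive = link(feats, search_range=6)
        assert len(predictive) == 2
        for tr in predictive:
            dx = np.diff(tr.x)
            assert np.all(dx > 0) or np.all(dx < 0)  # monotone: no identity swap

        baseline = link_nearest_neighbor(feats, search_range=6)
        swapped = any(
            not (np.all(np.diff(tr.x) > 0) or np.all(np.diff(tr.x) < 0))
            for tr in baseline
        )
        assert swapped

    def test_noiseless_redetection_reproduces_ground_truth_paths(self, primary_batch):
        gt = primary_batch[1]["ground_truth"]
        rows = []
        for t in range(gt.n_frames):
            ids, xs, ys = gt.positions_at(t)
            for x, y in zip(xs, ys):
                rows.append((t, x, y, 1.0))
        tracks = link(_features(rows), search_range=5, memory=2)
        recovered = {
            (len(tr), round(tr.x[0], 6), round(tr.y[0], 6), round(tr.x[-1], 6))
            for tr in tracks
        }
        n_match = 0
        for c in gt.cluster_paths:
            if len(c.frames) < 2:
                continue
            key = (len(c.frames), round(c.x[0], 6), round(c.y[0], 6), round(c.x[-1], 6))
            if key in recovered:
                n_match += 1
        n_paths = sum(1 for c in gt.cluster_paths if len(c.frames) >= 2)
        assert n_match / n_paths > 0.95

    def test_linking_partitions_features(self):
        rng = np.random.default_rng(3)
        rows = []
        for t in range(15):
            for k in range(6):
                rows.append((t, 20.0 * k + rng.normal(0, 0.3), 50.0 + t, 1.0))
        feats = _features(rows)
        tracks = link(feats, search_range=5, min_length=1)
        assert sum(len(t) for t in tracks) == len(feats)

    def test_invalid_search_range(self):
        with pytest.raises(ValueError):
            link(_features([(0, 1.0, 1.0, 1.0)]), search_range=0)


class TestFilterMotile:
    def test_stationary_track_removed(self):
        tr = Track(0, [0, 1, 2], [5, 5, 5], [5, 5, 5], [1, 1, 1])
        assert filter_motile([tr]) == []

    def test_clearly_motile_track_kept(self):
        tr = Track(0, [0, 1], [0, 10], [0, 0], [1, 1])
        assert filter_motile([tr]) == [tr]

    def test_displacement_exactly_at_cutoff_is_kept(self):
        tr = Track(0, [0, 1], [0.0, 3.5], [0.0, 0.0], [1, 1])
        assert filter_motile([tr]) == [tr]
        tr2 = Track(1, [0, 1], [0.0, 3.499], [0.0, 0.0], [1, 1])
        assert filter_motile([tr2]) == []


class TestClassifyDirection:
    def test_outward_track_is_anterograde_and_reverse_is_retrograde(self):
        out = Track(0, [0, 1, 2], [100, 110, 120], [80, 80, 80], [1, 1, 1])
        assert classify_direction(out, GEOM) == "anterograde"
        back = Track(1, out.frame, out.x[::-1].copy(), out.y[::-1].copy(), out.intensity)
        assert classify_direction(back, GEOM) == "retrograde"

    def test_equal_radii_is_a_tie(self):
        tr = Track(0, [0, 1], [100.0, 60.0], [80.0, 80.0], [1, 1])  # r=20 both
        assert classify_direction(tr, GEOM) == "tie"

    def test_labels_invariant_under_global_rotation(self):
        rng = np.random.default_rng(4)
        theta = 1.1
        c, s = np.cos(theta), np.sin(theta)
        for _ in range(10):
            x = 80 + rng.uniform(20, 60, 5) * np.cos(rng.uniform(0, 2 * np.pi))
            y = 80 + rng.uniform(20, 60, 5) * np.sin(rng.uniform(0, 2 * np.pi))
            tr = Track(0, np.arange(5), x, y, np.ones(5))
            xr = 80 + c * (x - 80) - s * (y - 80)
            yr = 80 + s * (x - 80) + c * (y - 80)
            tr_rot = Track(1, np.arange(5), xr, yr, np.ones(5))
            assert classify_direction(tr, GEOM) == classify_direction(tr_rot, GEOM)


class TestTrackSpeed:
    def test_one_pixel_per_frame_is_pixel_size_per_second(self):
        tr = Track(0, np.arange(5), np.arange(5, dtype=float), np.zeros(5), np.ones(5))
        assert track_speed(tr, 41.6, 1.0) == pytest.approx(41.6)

    def test_stationary_track_has_zero_speed(self):
        tr = Track(0, [0, 1, 2], [3, 3, 3], [4, 4, 4], [1, 1, 1])
        assert track_speed(tr, 41.6, 1.0) == 0.0

    def test_speed_recovered_from_ground_truth_paths(self, jurkat_batch):
        gt = jurkat_batch[0]["ground_truth"]
        p = gt.profile
        speeds = []
        for c in gt.cluster_paths:
            if len(c.frames) < 10 or c.coupled.any():
                continue
            tr = Track(c.id, c.frames, c.x, c.y, np.ones(len(c.frames)))
            speeds.append(track_speed(tr, p.pixel_size, p.frame_interval))
        assert len(speeds) > 3
        # free clusters drift at N(retro_speed, retro_speed_sd) plus jitter
        assert abs(np.median(speeds) - p.retro_speed) < 2 * p.retro_speed_sd


class TestRadialNormalize:
    @pytest.mark.parametrize(
        "point,expected",
        [((98.0, 80.0), 0.0), ((152.0, 80.0), 1.0), ((125.0, 80.0), 0.5)],
    )
    def test_boundary_and_midpoint_values(self, point, expected):
        assert radial_normalize(point, GEOM) == pytest.approx(expected)

    def test_values_clipped_into_unit_interval(self):
        assert radial_normalize((80.0, 80.0), GEOM) == 0.0  # inside cSMAC
        assert radial_normalize((159.0, 159.0), GEOM) == 1.0  # outside cell

    def test_degenerate_geometry_is_an_error(self):
        bad = CellGeometry((10.0, 10.0), 5.0, 4.999999, np.ones((20, 20), bool))
        bad.csmac_radius = bad.cell_radius  # force degenerate span
        with pytest.raises(ValueError):
            radial_normalize((12.0, 10.0), bad)


class TestDirectionalSummary:
    def _tracks(self, n_antero, n_retro):
        tracks = []
        for k in range(n_antero):
            tracks.append(Track(k, [0, 1], [100, 110], [80 + k, 80 + k], [1, 1]))
        for k in range(n_retro):
            tracks.append(
                Track(100 + k, [0, 1], [110, 100], [80 + k, 80 + k], [2, 2])
            )
        return tracks

    def test_fraction_counts_only_directional_tracks(self):
        summary = directional_fraction(self._tracks(4, 6), GEOM, 41.6, 1.0)
        assert summary.anterograde_fraction == pytest.approx(0.4)
        assert summary.n_anterograde + summary.n_retrograde + summary.n_tie == summary.n_tracks

    def test_no_tracks_is_an_error(self):
        with pytest.raises(ValueError):
            directional_fraction([], GEOM, 41.6, 1.0)

    def test_intensity_densities_integrate_to_one_per_direction(self):
        hists = intensity_density(self._tracks(5, 7), GEOM, bins=5)
        for h in hists.values():
            widths = np.diff(h.bin_edges)
            assert np.sum(h.densities * widths) == pytest.approx(1.0)

    def test_pipeline_fraction_matches_ground_truth_labels(self, primary_batch):
        # full-chain check: detected-track fraction vs realized label fraction
        diffs = [
            cell["metrics"]["tcr_anterograde_fraction"]
            - cell["metrics"]["gt_anterograde_fraction"]
            for cell in primary_batch
        ]
        assert abs(np.mean(diffs)) < 0.05


def test_track_dataframe_round_trip():
    tr = Track(3, [0, 2, 3], [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
    df = tracks_to_dataframe([tr], frame_interval=0.5)
    assert list(df["track_id"]) == [3, 3, 3]
    assert list(df["t_s"]) == [0.0, 1.0, 1.5]
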