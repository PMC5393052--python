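"""Drift correction, filtering, and blink merging."""

import numpy as np
import pandas as pd
import pytest

from telostorm import preprocess, simulate
from telostorm.preprocess import (
    FilterParams,
    FiducialTrack,
    FovRejectedError,
    apply_drift,
    build_drift,
    filter_localizations,
    find_fiducials,
    fit_drift_spline,
    merge_localizations,
)


def make_table(frames, x, y, precision=5.0, sigma=150.0, loglike=50.0, photons=1000.0):
    n = len(frames)
    return pd.DataFrame(
        {
            "frame": np.asarray(frames, np.int64),
            "x_nm": np.asarray(x, float),
            "y_nm": np.asarray(y, float),
            "precision_nm": np.broadcast_to(precision, n).astype(float),
            "sigma_nm": np.broadcast_to(sigma, n).astype(float),
            "loglike": np.broadcast_to(loglike, n).astype(float),
            "photons": np.broadcast_to(photons, n).astype(float),
        }
    )


def linear_track(frames_total=2000, slope=(0.05, -0.02), origin=(2500.0, 2500.0), jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    f = np.arange(1, frames_total + 1)
    x = origin[0] + slope[0] * (f - 1) + jitter * rng.standard_normal(frames_total)
    y = origin[1] + slope[1] * (f - 1) + jitter * rng.standard_normal(frames_total)
    return FiducialTrack(
        bin_origin_nm=(2000.0, 2000.0),
        member_indices=np.arange(frames_total),
        frames=f,
        x_nm=x,
        y_nm=y,
    )


class TestFindFiducials:
    def test_always_on_emitter_becomes_one_track(self):
        f = np.arange(1, 20_001)
        table = make_table(f, np.full(len(f), 2500.0), np.full(len(f), 2500.0))
        tracks = find_fiducials(table, 20_000)
        assert len(tracks) == 1
        assert tracks[0].n_frames_covered == 20_000

    def test_blinking_emitters_fall_below_threshold(self):
        # 1% duty cycle: 200 localizations over 20,000 frames is far below 0.8x
        f = np.arange(1, 20_001, 100)
        table = make_table(f, np.full(len(f), 2500.0), np.full(len(f), 2500.0))
        assert find_fiducials(table, 20_000) == []

    def test_two_fiducials_give_two_tracks_with_correct_bins(self):
        f = np.arange(1, 1001)
        t1 = make_table(f, np.full(1000, 2500.0), np.full(1000, 2500.0))
        t2 = make_table(f, np.full(1000, 7500.0), np.full(1000, 2500.0))
        table = pd.concat([t1, t2], ignore_index=True)
        tracks = find_fiducials(table, 1000)
        assert len(tracks) == 2
        assert sorted(tr.bin_origin_nm for tr in tracks) == [(2000.0, 2000.0), (7000.0, 2000.0)]

    def test_overfull_bin_is_not_a_fiducial(self):
        # two co-located always-on emitters -> 2 locs/frame, above max_fraction
        f = np.repeat(np.arange(1, 1001), 2)
        table = make_table(f, np.full(2000, 2500.0), np.full(2000, 2500.0))
        assert find_fiducials(table, 1000) == []


class TestDriftSpline:
    def test_reproduces_noise_free_line(self):
        spline = fit_drift_spline(linear_track())
        f = np.arange(1, 2001, dtype=float)
        vals = spline(f)
        assert np.max(np.abs(vals[:, 0] - (2500.0 + 0.05 * (f - 1)))) < 0.1
        assert np.max(np.abs(vals[:, 1] - (2500.0 - 0.02 * (f - 1)))) < 0.1

    def test_recovers_line_under_jitter(self):
        spline = fit_drift_spline(linear_track(jitter=10.0, seed=3))
        f = np.arange(1, 2001, dtype=float)
        resid = spline(f)[:, 0] - (2500.0 + 0.05 * (f - 1))
        assert np.sqrt(np.mean(resid**2)) < 3.0

    def test_recovers_constant_under_jitter(self):
        spline = fit_drift_spline(linear_track(slope=(0.0, 0.0), jitter=10.0, seed=4))
        f = np.arange(1, 2001, dtype=float)
        assert np.sqrt(np.mean((spline(f)[:, 0] - 2500.0) ** 2)) < 3.0

    def test_short_track_rejected_with_coverage(self):
        with pytest.raises(ValueError, match="500 frames"):
            fit_drift_spline(linear_track(frames_total=500))


class TestBuildApplyDrift:
    def test_average_of_identical_tracks_is_the_common_drift(self):
        t1 = linear_track(origin=(2500.0, 2500.0))
        t2 = linear_track(origin=(7500.0, 7500.0))
        drift = build_drift([t1, t2], 2000)
        f = np.arange(2000)
        assert drift.n_fiducials_used == 2
        assert np.max(np.abs(drift.dxy_nm[:, 0] - 0.05 * f)) < 0.1
        assert np.max(np.abs(drift.dxy_nm[:, 1] + 0.02 * f)) < 0.1

    def test_no_fiducials_rejects_the_fov(self):
        with pytest.raises(FovRejectedError, match="no good fiducials"):
            build_drift([], 2000)

    def test_averaging_reduces_noise_versus_single_track(self):
        truth = 0.05 * np.arange(2000)
        errs = []
        for tracks in ([linear_track(jitter=10.0, seed=1)],
                       [linear_track(jitter=10.0, seed=i) for i in range(1, 5)]):
            drift = build_drift(tracks, 2000)
            errs.append(np.sqrt(np.mean((drift.dxy_nm[:, 0] - truth) ** 2)))
        assert errs[1] < errs[0]

    def test_zero_trajectory_is_identity(self):
        table = make_table([1, 2, 3], [10.0, 20.0, 30.0], [5.0, 5.0, 5.0])
        drift = preprocess.DriftTrajectory(dxy_nm=np.zeros((3, 2)), n_fiducials_used=1)
        pd.testing.assert_frame_equal(apply_drift(table, drift), table)

    def test_apply_then_unapply_roundtrips(self):
        table = make_table([1, 2, 3], [10.0, 20.0, 30.0], [5.0, 6.0, 7.0])
        rng = np.random.default_rng(0)
        drift = preprocess.DriftTrajectory(dxy_nm=rng.normal(size=(3, 2)), n_fiducials_used=1)
        back = preprocess.DriftTrajectory(dxy_nm=-drift.dxy_nm, n_fiducials_used=1)
        pd.testing.assert_frame_equal(apply_drift(apply_drift(table, drift), back), table)

    def test_frame_outside_trajectory_domain_errors(self):
        table = make_table([5], [1.0], [1.0])
        drift = preprocess.DriftTrajectory(dxy_nm=np.zeros((3, 2)), n_fiducials_used=1)
        with pytest.raises(ValueError, match="covers"):
            apply_drift(table, drift)

    def test_end_to_end_fiducial_spread_after_correction(self):
        # known smooth drift + 6-nm precision: corrected fiducial positions
        # scatter about their mean by roughly the localization precision
        truth = simulate.GroundTruth(
            emitter_positions=np.empty((0, 2)),
            emitter_cluster_id=np.empty(0, np.int64),
            cluster_centers=np.empty((0, 2)),
            cluster_rg_target_nm=np.empty(0),
            cluster_rg_realized_nm=np.empty(0),
            fiducial_positions=np.array([[2500.0, 2500.0], [7500.0, 5500.0]]),
            ddr_positive_indices=frozenset(),
        )
        blink = simulate.BlinkModel(frames_total=4000)
        drift_model = simulate.DriftModel(kind="smooth-random", magnitude_nm=150.0, seed=9)
        table, truth = simulate.simulate_localizations(
            truth, blink, drift_model, precision_mean_nm=6.0, seed=4
        )
        tracks = find_fiducials(table, 4000)
        drift = build_drift(tracks, 4000, weight_sigma_frames=40, window_frames=160)
        corrected = apply_drift(table, drift)
        for fid in (-1, -2):
            xy = corrected.loc[corrected["true_cluster_id"] == fid, ["x_nm", "y_nm"]].to_numpy()
            rms = np.sqrt(np.mean(np.sum((xy - xy.mean(axis=0)) ** 2, axis=1) / 2))
            assert rms < 10.0


class TestFilter:
    def test_threshold_semantics(self):
        table = make_table(
            [1, 2, 3, 4],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            precision=[35.0, 30.0, 5.0, 5.0],
            loglike=[50.0, 250.0, 300.0, 50.0],
            sigma=[150.0, 175.0, 150.0, 150.0],
        )
        kept, tally = filter_localizations(table, FilterParams())
        # 35-nm precision and loglike 300 are rejected; exact boundary values kept
        assert list(kept["frame"]) == [2, 4]
        assert tally == {
            "precision": 1, "loglike": 1, "sigma": 0, "rejected_total": 2, "retained": 2,
        }

    def test_loosening_thresholds_is_monotone(self):
        rng = np.random.default_rng(1)
        n = 500
        table = make_table(
            np.arange(1, n + 1), rng.normal(size=n), rng.normal(size=n),
            precision=rng.gamma(4, 2.5, n), loglike=rng.chisquare(45, n) * 4,
            sigma=rng.normal(150, 20, n),
        )
        kept_counts = [
            len(filter_localizations(table, FilterParams(max_precision_nm=p))[0])
            for p in (10.0, 20.0, 30.0, 60.0)
        ]
        assert kept_counts == sorted(kept_counts)

    def test_missing_column_named(self):
        table = make_table([1], [0.0], [0.0]).drop(columns=["loglike"])
        with pytest.raises(ValueError, match="loglike"):
            filter_localizations(table, FilterParams())


class TestMerge:
    def test_consecutive_blinks_collapse_and_conserve_photons(self):
        table = make_table(
            [1, 2, 3], [100.0, 102.0, 101.0], [50.0, 51.0, 49.0], photons=[10.0, 20.0, 30.0]
        )
        merged = merge_localizations(table, radius_nm=30.0, gap_frames=1)
        assert len(merged) == 1
        assert merged["photons"].iloc[0] == 60.0
        assert merged["frame"].iloc[0] == 1
        assert merged["n_merged"].iloc[0] == 3

    def test_long_dark_gaps_break_tracks(self):
        # two dark frames between events exceeds the one-frame gap tolerance
        table = make_table([1, 4, 7], [100.0, 100.0, 100.0], [50.0, 50.0, 50.0])
        merged = merge_localizations(table, radius_nm=30.0, gap_frames=1)
        assert len(merged) == 3

    def test_single_frame_gap_is_bridged(self):
        table = make_table([1, 3], [100.0, 100.0], [50.0, 50.0])
        assert len(merge_localizations(table, radius_nm=30.0, gap_frames=1)) == 1

    def test_singleton_passes_through(self):
        table = make_table([5], [123.0], [456.0])
        merged = merge_localizations(table)
        assert len(merged) == 1
        assert merged["x_nm"].iloc[0] == 123.0
        assert merged["n_merged"].iloc[0] == 1

    def test_zero_radius_is_identity_on_positions(self):
        rng = np.random.default_rng(2)
        table = make_table(
            np.sort(rng.integers(1, 50, 100)), rng.normal(size=100), rng.normal(size=100)
        )
        merged = merge_localizations(table, radius_nm=0.0)
        assert len(merged) == len(table)
        np.testing.assert_allclose(np.sort(merged["x_nm"]), np.sort(table["x_nm"]))

    def test_precision_combines_as_inverse_variance(self):
        table = make_table([1, 2], [0.0, 10.0], [0.0, 0.0], precision=[10.0, 5.0])
        merged = merge_localizations(table, radius_nm=30.0)
        w1, w2 = 1 / 100.0, 1 / 25.0
        assert merged["precision_nm"].iloc[0] == pytest.approx(np.sqrt(1 / (w1 + w2)))
        assert merged["x_nm"].iloc[0] == pytest.approx(10.0 * w2 / (w1 + w2))

    def test_photon_conservation_on_random_tables(self):
        rng = np.random.default_rng(3)
        n = 400
        table = make_table(
            np.sort(rng.integers(1, 100, n)),
            rng.uniform(0, 2000, n), rng.uniform(0, 2000, n),
            photons=rng.uniform(100, 5000, n),
        )
        merged = merge_localizations(table, radius_nm=50.0, gap_frames=1)
        assert merged["photons"].sum() == pytest.approx(table["photons"].sum())
        assert len(merged) <= len(table)

    def test_negative_parameters_rejected(self):
        table = make_table([1], [0.0], [0.0])
        with pytest.raises(ValueError):
            merge_localizations(table, radius_nm=-1.0)
        with pytest.raises(ValueError):
            merge_localizations(table, gap_frames=-1)
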