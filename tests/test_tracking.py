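"""Detection, linking (with exhaustive assignment oracle), profiles, curve fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magcap import (
    Trajectory,
    VelocityProfile,
    detect_capsules,
    fit_velocity_curve,
    link_trajectories,
    pooled_mean_speed,
    velocity_profile,
)
from magcap.errors import DomainError, InsufficientDataError
from magcap.tracking import approach_speeds, solve_frame_assignment


# --------------------------------------------------------------------------
# detection


class TestDetectCapsules:
    def test_uniform_image_empty(self):
        with pytest.warns(UserWarning):
            out = detect_capsules(np.full((32, 32), 7.0))
        assert out.shape == (0, 2)

    def test_single_gaussian_spot_center(self):
        ys, xs = np.mgrid[0:41, 0:41]
        img = 100 + 1000 * np.exp(-(((xs - 20.3) ** 2 + (ys - 17.8) ** 2) / (2 * 2.0**2)))
        det = detect_capsules(img)
        assert det.shape == (1, 2)
        assert det[0, 0] == pytest.approx(20.3, abs=0.05)
        assert det[0, 1] == pytest.approx(17.8, abs=0.05)

    def test_noisy_spots_recovered(self, rng):
        """10 spots under photon noise: all found, RMS error below the
        per-spot localization scale (~sigma/sqrt(photons))."""
        ys, xs = np.mgrid[0:60, 0:200]
        centers = np.column_stack([np.linspace(12, 188, 10), rng.uniform(15, 45, 10)])
        img = np.full((60, 200), 100.0)
        for cx, cy in centers:
            img += 2000 * np.exp(-(((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * 2.0**2)))
        noisy = rng.poisson(img).astype(float)
        det = detect_capsules(noisy)
        assert det.shape == (10, 2)
        err = det[np.argsort(det[:, 0])] - centers[np.argsort(centers[:, 0])]
        rms = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        assert rms < 0.2  # pixels


# --------------------------------------------------------------------------
# linking and the exhaustive oracle


def brute_force_assignment(prev_pts, new_pts, gate):
    """Enumerate every partial injective assignment; minimize total cost with
    gate^2 paid per unmatched point on either side (same objective as the
    padded linear assignment)."""
    t, d = len(prev_pts), len(new_pts)
    gate2 = gate * gate
    best_cost, best = np.inf, []
    for k in range(min(t, d) + 1):
        for rows in itertools.combinations(range(t), k):
            for cols in itertools.permutations(range(d), k):
                cost = (t - k + d - k) * gate2
                ok = True
                for r, c in zip(rows, cols):
                    d2 = float(np.sum((prev_pts[r] - new_pts[c]) ** 2))
                    if d2 > gate2:
                        ok = False
                        break
                    cost += d2
                if ok and cost < best_cost - 1e-12:
                    best_cost, best = cost, sorted(zip(rows, cols))
    return best_cost, best


class TestFrameAssignment:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t, d = rng.integers(1, 7, size=2)
        prev_pts = rng.uniform(0, 10, size=(t, 2))
        new_pts = rng.uniform(0, 10, size=(d, 2))
        gate = rng.uniform(1.0, 6.0)
        got = sorted(solve_frame_assignment(prev_pts, new_pts, gate))
        oracle_cost, _ = brute_force_assignment(prev_pts, new_pts, gate)
        got_cost = (t + d - 2 * len(got)) * gate**2 + sum(
            float(np.sum((prev_pts[r] - new_pts[c]) ** 2)) for r, c in got
        )
        # optimal assignments may be non-unique; costs must agree exactly
        assert got_cost == pytest.approx(oracle_cost, rel=1e-12)


class TestLinkTrajectories:
    @staticmethod
    def _detections(tracks_xy):
        """tracks_xy: dict track -> list of (frame, x, y)."""
        rows = [(f, x, y) for pts in tracks_xy.values() for (f, x, y) in pts]
        return pd.DataFrame(rows, columns=["frame", "x_m", "y_m"])

    def test_single_capsule_single_track(self):
        det = self._detections({0: [(f, 1e-3 - f * 1e-5, 5e-4) for f in range(10)]})
        tracks = link_trajectories(det, max_displacement=5e-5, frame_rate=24.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        assert not tracks[0].interpolated.any()

    def test_two_separated_capsules_pure_tracks(self):
        det = self._detections(
            {
                0: [(f, 1e-3 - f * 1e-5, 2e-4) for f in range(8)],
                1: [(f, 4e-3 - f * 1.5e-5, 8e-4) for f in range(8)],
            }
        )
        tracks = link_trajectories(det, max_displacement=5e-5, frame_rate=24.0)
        assert len(tracks) == 2
        xs = sorted(tr.positions[0, 0] for tr in tracks)
        assert xs == pytest.approx([1e-3, 4e-3])
        for tr in tracks:
            # pure: x decrement constant within a track
            steps = np.diff(tr.positions[:, 0])
            assert np.allclose(steps, steps[0])

    def test_gap_bridged_with_interpolated_point(self):
        pts = [(f, 1e-3 - f * 1e-5, 5e-4) for f in range(7) if f != 3]
        tracks = link_trajectories(
            self._detections({0: pts}), max_displacement=5e-5, max_gap=1, frame_rate=24.0
        )
        assert len(tracks) == 1
        tr = tracks[0]
        assert len(tr) == 7
        assert tr.interpolated.sum() == 1
        assert tr.frames[tr.interpolated][0] == 3
        assert tr.positions[3, 0] == pytest.approx(1e-3 - 3e-5, rel=1e-12)

    def test_gap_beyond_max_gap_splits_track(self):
        pts = [(f, 1e-3 - f * 1e-5, 5e-4) for f in list(range(3)) + list(range(7, 10))]
        tracks = link_trajectories(
            self._detections({0: pts}), max_displacement=5e-5, max_gap=2, frame_rate=24.0
        )
        assert len(tracks) == 2

    def test_displacement_gate_forbids_link(self):
        det = self._detections({0: [(0, 1e-3, 5e-4), (1, 2e-3, 5e-4), (2, 3e-3, 5e-4)]})
        tracks = link_trajectories(det, max_displacement=1e-4, frame_rate=24.0, min_length=1)
        # each jump exceeds the gate: no track reaches 2 detections
        assert all(len(t) < 2 for t in tracks) or not tracks

    def test_no_two_tracks_share_a_detection(self, capsule, fluid, field):
        from magcap import ExperimentDesign, generate_observations

        design = ExperimentDesign(
            n_tracks=6, duration=15.0, localization_noise_sd=5e-7, seed=5
        )
        det, _ = generate_observations(design, capsule, fluid, field, chi_eff=2e-5)
        tracks = link_trajectories(det, max_displacement=2e-4, frame_rate=24.0)
        used = set()
        for tr in tracks:
            for f, p in zip(tr.frames[~tr.interpolated], tr.positions[~tr.interpolated]):
                key = (int(f), round(p[0], 12), round(p[1], 12))
                assert key not in used
                used.add(key)

    def test_noiseless_generation_recovers_ground_truth_labels(
        self, small_design, capsule, fluid, field
    ):
        """Noiseless generate -> link reconstructs the ground-truth partition
        when capsules are farther apart than a per-frame displacement."""
        from magcap import generate_observations

        det, truth = generate_observations(small_design, capsule, fluid, field, chi_eff=2e-5)
        tracks = link_trajectories(det, max_displacement=2e-4, frame_rate=24.0)
        assert len(tracks) == small_design.n_tracks
        truth_by_y = {g["y_m"].iloc[0]: g for _, g in truth.groupby("track_id")}
        for tr in tracks:
            g = truth_by_y[tr.positions[0, 1]]
            np.testing.assert_array_equal(tr.frames, g["frame"].to_numpy())
            np.testing.assert_allclose(tr.positions[:, 0], g["x_m"].to_numpy(), rtol=0, atol=0)


# --------------------------------------------------------------------------
# velocity profiles


def _constant_speed_track(v=1e-4, x0=5e-3, n=50, dt=1 / 24, tid=0):
    t = np.arange(n) * dt
    x = x0 - v * t
    return Trajectory(tid, np.arange(n), t, np.column_stack([x, np.full(n, 1e-3)]))


class TestVelocityProfile:
    def test_constant_speed_exact(self):
        prof = velocity_profile([_constant_speed_track()], bin_width=2e-4)
        np.testing.assert_allclose(prof.mean_speed, 1e-4, rtol=1e-12)
        assert prof.n_obs.sum() == 50

    def test_empty_bins_omitted(self):
        prof = velocity_profile([_constant_speed_track(n=10)], bin_width=1e-5)
        # track spans ~37.5 um; far bins must be absent, none zero-filled
        assert np.all(prof.n_obs >= 1)
        assert prof.bin_centers.max() < 5.1e-3

    def test_total_obs_equals_speed_samples(self):
        tracks = [_constant_speed_track(tid=0), _constant_speed_track(v=2e-4, tid=1)]
        prof = velocity_profile(tracks, bin_width=1e-3)
        assert prof.n_obs.sum() == 100

    def test_profile_matches_model_speeds(self, capsule, fluid, field, small_design):
        """Noiseless end-to-end: generated tracks' binned speeds match the
        closed form at bin centers within finite-difference error (<1%)."""
        from magcap import generate_observations, terminal_velocity

        det, _ = generate_observations(small_design, capsule, fluid, field, chi_eff=2e-5)
        tracks = link_trajectories(det, max_displacement=2e-4, frame_rate=24.0)
        prof = velocity_profile(tracks, bin_width=1e-4)
        sel = prof.n_obs >= 10
        v_model = np.abs(
            terminal_velocity(
                capsule, fluid, field, prof.bin_centers[sel], chi_eff=2e-5, check_reynolds=False
            )
        )
        np.testing.assert_allclose(prof.mean_speed[sel], v_model, rtol=0.01)

    def test_mean_speed_decreases_with_distance(self, capsule, fluid, field, small_design):
        from magcap import generate_observations

        det, _ = generate_observations(small_design, capsule, fluid, field, chi_eff=2e-5)
        tracks = link_trajectories(det, max_displacement=2e-4, frame_rate=24.0)
        prof = velocity_profile(tracks, bin_width=3e-4)
        sel = prof.n_obs >= 10
        assert np.all(np.diff(prof.mean_speed[sel]) < 0)

    def test_per_track_pooling_differs(self):
        tracks = [_constant_speed_track(v=1e-4, tid=0), _constant_speed_track(v=3e-4, tid=1, n=10)]
        pooled = pooled_mean_speed(tracks, (0, 1))
        per_track = pooled_mean_speed(tracks, (0, 1), method="per_track")
        assert per_track == pytest.approx(2e-4, rel=1e-9)
        assert pooled < per_track  # slow track contributes more samples

    def test_central_difference_truncation_shrinks_with_dt(self, capsule, fluid, field):
        """Halving dt cuts the finite-difference error ~4x (2nd order)."""
        from magcap import terminal_velocity
        from magcap.dynamics import integrate_positions

        def max_err(dt):
            times = np.arange(1, int(10 / dt)) * dt
            x = integrate_positions(capsule, fluid, field, 3e-3, times, chi_eff=2e-5)
            sp = approach_speeds(times, x)
            v = np.abs(terminal_velocity(capsule, fluid, field, x, chi_eff=2e-5, check_reynolds=False))
            return np.max(np.abs(sp[1:-1] - v[1:-1]) / v[1:-1])

        e1, e2 = max_err(1 / 24), max_err(1 / 48)
        assert e1 < 0.01
        assert e2 < e1 / 2.5

    def test_short_track_rejected(self):
        with pytest.raises(DomainError):
            Trajectory(0, [0], [0.0], [[1e-3, 0.0]])


# --------------------------------------------------------------------------
# curve fit


def _profile_from_curve(a=2e-4, x0=3e-3, n=12, counts=None):
    x = np.linspace(5e-4, 5e-3, n)
    v = a * np.exp(-2 * x / x0)
    counts = np.full(n, 20) if counts is None else counts
    return VelocityProfile(x, v, np.full(n, 1e-6), counts, bin_width=x[1] - x[0])


class TestFitVelocityCurve:
    def test_exact_recovery(self):
        fit = fit_velocity_curve(_profile_from_curve())
        assert fit.amplitude == pytest.approx(2e-4, rel=1e-9)
        assert fit.decay_length == pytest.approx(3e-3, rel=1e-9)

    def test_fixed_decay_length(self):
        fit = fit_velocity_curve(_profile_from_curve(), field_decay_length=3e-3)
        assert fit.fixed_decay_length
        assert fit.amplitude == pytest.approx(2e-4, rel=1e-12)
        assert np.isnan(fit.se_decay_length)

    def test_insufficient_bins(self):
        with pytest.raises(InsufficientDataError):
            fit_velocity_curve(_profile_from_curve(n=2))

    def test_unbiased_on_noisy_profiles(self):
        """100 noisy profiles: decay-length estimates unbiased within
        Monte-Carlo error."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            prof = _profile_from_curve()
            noisy = VelocityProfile(
                prof.bin_centers,
                prof.mean_speed * (1 + 0.03 * rng.standard_normal(prof.n_points)),
                prof.speed_sd,
                prof.n_obs,
                bin_width=prof.bin_width,
            )
            estimates.append(fit_velocity_curve(noisy).decay_length)
        se = np.std(estimates) / 10
        assert np.mean(estimates) == pytest.approx(3e-3, abs=4 * se)
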