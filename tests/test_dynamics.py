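"""Time-averaged MSD, motion correction, and anomalous-diffusion fitting."""

import math

import numpy as np
import pytest

from nucleomech import dynamics, simkit
from nucleomech.dynamics import MsdCurve, Trajectory
from nucleomech.errors import DataError, InvalidGeometryError, ShapeError


def brute_force_msd(traj: Trajectory) -> MsdCurve:
    """Independent O(N^2) double-loop oracle with exact summation."""
    t, p = traj.valid_segment()
    n = len(t)
    dt = t[1] - t[0]
    lags, msds, counts = [], [], []
    for k in range(1, n):
        terms = []
        for i in range(n - k):
            d = p[i + k] - p[i]
            sq = 0.0
            for c in d:
                sq += c * c
            terms.append(sq)
        lags.append(k * dt)
        counts.append(n - k)
        msds.append(math.fsum(terms) / (n - k))
    return MsdCurve(lag=np.array(lags), msd=np.array(msds), n_pairs=np.array(counts))


class TestTimeAvgMsd:
    def test_static_particle_zero_msd(self):
        t = np.arange(10) * 120.0
        traj = Trajectory(id="s", time=t, position=np.tile([3.0, -1.0], (10, 1)))
        assert np.all(dynamics.time_avg_msd(traj).msd == 0)

    def test_ballistic_closed_form(self):
        v = np.array([0.02, -0.01])
        t = np.arange(20) * 120.0
        traj = Trajectory(id="b", time=t, position=t[:, None] * v[None, :])
        msd = dynamics.time_avg_msd(traj)
        assert np.allclose(msd.msd, (v @ v) * msd.lag**2, rtol=1e-12)

    def test_matches_brute_force_exactly_on_random_tracks(self, rng):
        for _ in range(100):
            n = 20
            pos = rng.normal(size=(n, 2))
            traj = Trajectory(id="r", time=np.arange(n) * 120.0, position=pos)
            fast = dynamics.time_avg_msd(traj)
            slow = brute_force_msd(traj)
            assert np.array_equal(fast.msd, slow.msd)
            assert np.array_equal(fast.n_pairs, slow.n_pairs)

    def test_bare_sum_convention(self):
        t = np.arange(6) * 1.0
        pos = np.arange(12, dtype=float).reshape(6, 2)
        mean = dynamics.time_avg_msd(Trajectory(id="a", time=t, position=pos))
        total = dynamics.time_avg_msd(
            Trajectory(id="a", time=t, position=pos), average=False
        )
        assert np.allclose(total.msd, mean.msd * mean.n_pairs)

    def test_short_track_rejected(self):
        t = np.arange(2) * 1.0
        traj = Trajectory(id="x", time=t, position=np.zeros((2, 2)))
        with pytest.raises(DataError):
            dynamics.time_avg_msd(traj)

    def test_off_center_rotation_closed_form(self):
        # static point at radius rho under pure rotation:
        # msd(tau) = 2 rho^2 (1 - cos(omega tau))
        rho, omega, dt = 2.0, math.radians(10), 120.0
        n = 20
        ang = omega * np.arange(n)
        pos = rho * np.column_stack([np.cos(ang), np.sin(ang)])
        traj = Trajectory(id="rot", time=np.arange(n) * dt, position=pos)
        msd = dynamics.time_avg_msd(traj)
        k = np.arange(1, n)
        expected = 2 * rho**2 * (1 - np.cos(omega * k))
        assert np.allclose(msd.msd, expected, atol=1e-10)


class TestRotationEstimation:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.normal(size=(6, 2))
        R = dynamics.estimate_rotation(pts, pts)
        assert np.allclose(R, np.eye(2), atol=1e-12)

    def test_constructed_rotation_recovered(self, rng):
        for d in (2, 3):
            pts = rng.normal(size=(8, d))
            theta = math.radians(30)
            if d == 2:
                R_true = np.array(
                    [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
                )
            else:
                c, s = math.cos(theta), math.sin(theta)
                R_true = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            rotated = (pts - pts.mean(0)) @ R_true.T + pts.mean(0)
            R = dynamics.estimate_rotation(rotated, pts)
            assert np.allclose(R, R_true, atol=1e-9)

    def test_noisy_fit_beats_grid_search(self, rng):
        # Kabsch minimizes RMSD: no angle on a fine grid does better
        pts = rng.normal(size=(10, 2)) * 3
        theta = 0.4
        R_true = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        noisy = (pts - pts.mean(0)) @ R_true.T + rng.normal(0, 0.05, size=pts.shape)

        def rmsd(angle):
            R = np.array(
                [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
            )
            diff = (noisy - noisy.mean(0)) - (pts - pts.mean(0)) @ R.T
            return np.sqrt((diff**2).sum())

        R_est = dynamics.estimate_rotation(noisy, pts)
        est_angle = math.atan2(R_est[1, 0], R_est[0, 0])
        grid = np.arange(-math.pi, math.pi, math.radians(0.01))
        best_grid = min(rmsd(a) for a in grid)
        assert rmsd(est_angle) <= best_grid + 1e-9

    def test_collinear_3d_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.arange(5.0)])
        with pytest.raises(InvalidGeometryError):
            dynamics.estimate_rotation(pts, pts)


class TestMeanRotation:
    @staticmethod
    def rot2(deg):
        a = math.radians(deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def test_all_identity(self):
        assert np.allclose(dynamics.mean_rotation([np.eye(2)] * 3), np.eye(2))

    def test_symmetric_angles_cancel(self):
        R = dynamics.mean_rotation([self.rot2(10), self.rot2(-10)])
        assert np.allclose(R, np.eye(2), atol=1e-12)

    def test_circular_mean_of_angles(self):
        R = dynamics.mean_rotation([self.rot2(0), self.rot2(10), self.rot2(20)])
        est = math.degrees(math.atan2(R[1, 0], R[0, 0]))
        assert est == pytest.approx(10.0, abs=1e-9)

    def test_antipodal_spread_fails(self):
        with pytest.raises(DataError):
            dynamics.mean_rotation([self.rot2(0), self.rot2(180)])


class TestCorrections:
    def test_track_equal_to_center_gives_zero(self):
        t = np.arange(10) * 120.0
        pos = np.cumsum(np.ones((10, 2)), axis=0)
        traj = Trajectory(id="a", time=t, position=pos)
        center = Trajectory(id="c", time=t, position=pos)
        out = dynamics.correct_drift(traj, center)
        assert np.all(out.position == 0)

    def test_drift_correction_restores_msd(self):
        tracks, _ = simkit.gen_tracks(3, 20, 120.0, 1.0, 0.02, seed=5)
        drift = np.arange(20)[:, None] * np.array([0.4, -0.3])[None, :]
        t = tracks[0].time
        center = Trajectory(id="c", time=t, position=drift)
        for tr in tracks:
            drifted = Trajectory(id=tr.id, time=t, position=tr.position + drift)
            corrected = dynamics.correct_drift(drifted, center)
            ref = dynamics.time_avg_msd(tr).msd
            got = dynamics.time_avg_msd(corrected).msd
            assert np.abs(got - ref).max() <= 1e-9

    def test_per_frame_rotation_correction_exact(self):
        # static particle off-center under pure rigid rotation -> zero MSD
        n = 20
        motion = simkit.gen_nucleus_motion(n, (0.0, 0.0), math.radians(12), n_landmarks=4, seed=1)
        static = Trajectory(
            id="s", time=np.arange(n) * 120.0, position=np.tile([2.0, 0.5], (n, 1))
        )
        obs = simkit.compose_observed_tracks([static], motion)[0]
        rec = dynamics.correct_rotation(obs, motion.rotations)
        assert dynamics.time_avg_msd(rec).msd.max() <= 1e-18

    def test_mean_rotation_mode_leaves_residual(self):
        # averaging the rotations cannot fully undo a steady rotation
        n = 20
        motion = simkit.gen_nucleus_motion(n, (0.0, 0.0), math.radians(12), n_landmarks=4, seed=1)
        static = Trajectory(
            id="s", time=np.arange(n) * 120.0, position=np.tile([2.0, 0.5], (n, 1))
        )
        obs = simkit.compose_observed_tracks([static], motion)[0]
        Rbar = dynamics.mean_rotation(motion.rotations)
        rec = dynamics.correct_rotation(obs, Rbar)
        assert dynamics.time_avg_msd(rec).msd.max() > 1e-3

    def test_grid_mismatch_rejected(self):
        a = Trajectory(id="a", time=np.arange(5) * 1.0, position=np.zeros((5, 2)))
        b = Trajectory(id="b", time=np.arange(6) * 1.0, position=np.zeros((6, 2)))
        with pytest.raises(ShapeError):
            dynamics.correct_drift(a, b)


class TestFitPowerlaw:
    def test_exact_power_law_recovered_to_machine_precision(self):
        lag = np.arange(1, 20) * 120.0
        msd = MsdCurve(lag=lag, msd=0.04 * lag**0.8, n_pairs=np.arange(19, 0, -1))
        fit = dynamics.fit_powerlaw(msd)
        assert fit.alpha == pytest.approx(0.8, abs=1e-12)
        assert fit.D == pytest.approx(0.04, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.accepted

    def test_per_track_alpha_median_recovery(self):
        tracks, _ = simkit.gen_tracks(200, 20, 120.0, 1.0, 0.01, seed=17)
        fits = [dynamics.fit_powerlaw(dynamics.time_avg_msd(t)) for t in tracks]
        med = np.median([f.alpha for f in fits])
        assert 0.9 <= med <= 1.1

    def test_per_track_short_track_D_bias_is_upward(self):
        # characterization: the slope bias of 20-frame per-track fits
        # extrapolates to an inflated intercept; ensemble fitting avoids it
        tracks, _ = simkit.gen_tracks(200, 20, 120.0, 1.0, 0.01, seed=21)
        curves = [dynamics.time_avg_msd(t) for t in tracks]
        per_track = np.median([dynamics.fit_powerlaw(c).D for c in curves])
        ens = dynamics.fit_powerlaw(dynamics.ensemble_msd(curves))
        assert per_track > 0.01  # biased up
        assert ens.D == pytest.approx(0.01, rel=0.3)
        assert ens.alpha == pytest.approx(1.0, abs=0.1)

    def test_noisy_curve_below_r2_gate_rejected(self, rng):
        lag = np.arange(1, 21) * 120.0
        msd_vals = np.exp(rng.normal(0, 1.5, size=20))  # no power-law structure
        msd = MsdCurve(lag=lag, msd=msd_vals, n_pairs=np.arange(20, 0, -1))
        fit = dynamics.fit_powerlaw(msd)
        assert fit.r_squared <= 0.8
        assert not fit.accepted
        assert fit.T is None

    def test_nonpositive_msd_rejected(self):
        lag = np.arange(1, 10) * 1.0
        msd = MsdCurve(lag=lag, msd=np.zeros(9), n_pairs=np.ones(9, dtype=int))
        with pytest.raises(DataError):
            dynamics.fit_powerlaw(msd)


class TestDiffusionTime:
    def make(self, alpha, D, accepted=True):
        return dynamics.PowerLawFit(
            alpha=alpha, D=D, r_squared=0.95 if accepted else 0.5,
            accepted=accepted, T=None,
        )

    def test_unit_prefactor_gives_one_second(self):
        for alpha in (0.5, 1.0, 1.7):
            assert dynamics.diffusion_time(self.make(alpha, 1.0)) == pytest.approx(1.0)

    def test_brownian_reduces_to_inverse_D(self):
        assert dynamics.diffusion_time(self.make(1.0, 0.04)) == pytest.approx(25.0)

    def test_subdiffusive_direct_evaluation(self):
        assert dynamics.diffusion_time(self.make(0.8, 0.04)) == pytest.approx(
            (1 / 0.04) ** (1 / 0.8), rel=1e-12
        )

    def test_rejected_fit_gives_none(self):
        assert dynamics.diffusion_time(self.make(1.0, 0.04, accepted=False)) is None


class TestEnsembleSummary:
    def test_identical_fits(self):
        f = dynamics.PowerLawFit(alpha=0.9, D=0.02, r_squared=0.95, accepted=True, T=70.0)
        out = dynamics.ensemble_summary([f, f, f])
        assert out.loc["alpha", "mean"] == pytest.approx(0.9)
        assert out.attrs["n_accepted"] == 3

    def test_rejected_fits_excluded(self):
        good = dynamics.PowerLawFit(alpha=1.0, D=0.01, r_squared=0.9, accepted=True, T=100.0)
        bad = dynamics.PowerLawFit(alpha=5.0, D=9.0, r_squared=0.1, accepted=False, T=None)
        out = dynamics.ensemble_summary([good, bad, good])
        assert out.loc["alpha", "mean"] == pytest.approx(1.0)
        assert out.attrs["n_rejected"] == 1

    def test_two_conditions_ordered_as_ground_truth(self):
        fits = {}
        for alpha in (0.6, 1.2):
            tracks, _ = simkit.gen_tracks(100, 20, 120.0, alpha, 0.01, seed=31)
            fits[alpha] = [
                dynamics.fit_powerlaw(dynamics.time_avg_msd(t)) for t in tracks
            ]
        s_low = dynamics.ensemble_summary(fits[0.6])
        s_high = dynamics.ensemble_summary(fits[1.2])
        assert s_low.loc["alpha", "median"] < s_high.loc["alpha", "median"]
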