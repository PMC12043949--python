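"""Seeded synthetic-data generators with known ground truth.

Each generator stands in for one of the instruments used in a
viscoelastic-substrate nuclear-mechanobiology study — the compression
rheometer (stress-relaxation curves), the confocal microscope (nucleus
z-stacks at a 0.3 um step, lamin images, FRAP traces with a 7-frame
740 ms prescan and 1 s post-bleach frames), and the particle tracker
(fractional-Brownian intranuclear tracks, 20 frames at 2-min intervals,
composited with rigid nucleus drift and rotation).  Every generator takes a
single integer seed, never touches global random state, and returns a
:class:`GroundTruth` carrying the analytic parameter values the analysis
stages are supposed to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dynamics import Trajectory
from .errors import InvalidGeometryError, InvalidParameterError, ShapeError
from .frap import FrapProtocol, FrapTrace
from .morphometry import ZStack
from .rheology import RelaxationCurve

__all__ = [
    "GroundTruth",
    "NucleusMotion",
    "gen_relaxation",
    "gen_nucleus_stack",
    "gen_lamin_image",
    "gen_frap_trace",
    "gen_tracks",
    "gen_nucleus_motion",
    "compose_observed_tracks",
]

DEFAULT_VOXEL_XY = 0.1  # um
DEFAULT_Z_STEP = 0.3  # um


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into the data."""

    kind: str
    params: dict

    def __post_init__(self):
        for k, v in self.params.items():
            if isinstance(v, (int, float)) and not math.isfinite(float(v)):
                raise InvalidParameterError(f"ground-truth parameter {k} is not finite")


@dataclass(frozen=True)
class NucleusMotion:
    """Rigid-body motion of a nucleus over time.

    center_track: (n_frames, d) positions of the nucleus center in um.
    rotations: (n_frames, d, d) proper rotation matrices about the center.
    landmarks: (n_frames, k, d) landmark coordinates rigidly co-moving.
    """

    center_track: np.ndarray
    rotations: np.ndarray
    landmarks: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center_track, dtype=float)
        R = np.asarray(self.rotations, dtype=float)
        L = np.asarray(self.landmarks, dtype=float)
        object.__setattr__(self, "center_track", c)
        object.__setattr__(self, "rotations", R)
        object.__setattr__(self, "landmarks", L)
        n, d = c.shape
        if R.shape != (n, d, d) or L.shape[0] != n or L.shape[2] != d:
            raise ShapeError("center_track, rotations and landmarks disagree in shape")
        for Rt in R:
            if not np.allclose(Rt @ Rt.T, np.eye(d), atol=1e-9) or np.linalg.det(Rt) < 0:
                raise InvalidGeometryError("rotations must be orthonormal with det +1")

    @property
    def n_frames(self) -> int:
        return self.center_track.shape[0]


# ---------------------------------------------------------------------------
# rheometer


def gen_relaxation(
    amplitudes,
    taus,
    sigma0: float = 2.0,
    t_max: float = 4000.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[RelaxationCurve, GroundTruth]:
    """Synthesize a stress-relaxation record under constant strain.

    stress(t) = sigma0 * (plateau + sum_i a_i exp(-t / tau_i)) + noise, with
    plateau = 1 - sum(a_i) the non-relaxing fraction.  The ground truth
    carries the analytic half time when the plateau is below 1/2.
    """
    a = np.asarray(amplitudes, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if a.shape != tau.shape:
        raise InvalidParameterError("amplitudes and taus must have equal length")
    if np.any(a < 0) or a.sum() > 1 + 1e-9:
        raise InvalidParameterError("weights must be nonnegative and sum to <= 1")
    if np.any(tau <= 0):
        raise InvalidParameterError("time constants must be positive")
    if dt <= 0 or t_max <= 0:
        raise InvalidParameterError("dt and t_max must be positive")
    plateau = 1.0 - float(a.sum())
    t = np.arange(0.0, t_max + dt / 2, dt)
    decay = plateau + (a[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1)
    stress = sigma0 * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=t.shape)
    truth = GroundTruth(
        kind="relaxation",
        params={
            "sigma0": sigma0,
            "plateau": plateau,
            "tau_half": _analytic_half_time(a, tau, plateau),
            **{f"a{i+1}": float(v) for i, v in enumerate(a)},
            **{f"tau{i+1}": float(v) for i, v in enumerate(tau)},
        },
    )
    return RelaxationCurve(time=t, stress=stress), truth


def _analytic_half_time(a, tau, plateau) -> float | None:
    if plateau >= 0.5 or a.sum() == 0:
        return None

    def f(t):
        return plateau + float(np.sum(a * np.exp(-t / tau))) - 0.5

    hi = 100.0 * float(tau.max())
    if f(hi) > 0:
        return None
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# confocal stacks and images


def gen_nucleus_stack(
    semi_axes=(5.0, 5.0, 3.0),
    voxel_xy: float = DEFAULT_VOXEL_XY,
    z_step: float = DEFAULT_Z_STEP,
    interior_intensity: float = 100.0,
    texture_strength: float = 0.0,
    texture_sigma_px: float = 3.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    centers=None,
) -> tuple[ZStack, GroundTruth]:
    """Render one (or several) ellipsoidal nuclei into a z-stack.

    ``semi_axes`` = (a, b, c) um with c along z.  The interior is uniform at
    ``interior_intensity``, optionally modulated by a smoothed multiplicative
    texture ("chromatin clumping") of relative strength ``texture_strength``,
    normalized to mean 1 inside the nucleus so the integrated intensity is
    preserved.  ``centers`` places additional nuclei (um offsets from the
    stack center); by default one nucleus sits at the center.  Ground truth
    records the analytic volume 4/3 pi a b c per nucleus.
    """
    ax, ay, az = (float(v) for v in semi_axes)
    if min(ax, ay, az) <= 0:
        raise InvalidParameterError("semi-axes must be positive")
    if voxel_xy <= 0 or z_step <= 0:
        raise InvalidParameterError("voxel spacings must be positive")
    if centers is None:
        centers = [(0.0, 0.0, 0.0)]
    centers = [np.asarray(c, dtype=float) for c in centers]
    if shape is None:
        span = 1.3 * max(abs(c).max() if c.size else 0.0 for c in centers)
        nz = 2 * math.ceil((1.25 * az + span) / z_step) + 1
        ny = 2 * math.ceil((1.25 * ay + span) / voxel_xy) + 1
        nx = 2 * math.ceil((1.25 * ax + span) / voxel_xy) + 1
        shape = (nz, ny, nx)
    nz, ny, nx = shape
    z = (np.arange(nz) - (nz - 1) / 2) * z_step
    y = (np.arange(ny) - (ny - 1) / 2) * voxel_xy
    x = (np.arange(nx) - (nx - 1) / 2) * voxel_xy
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")

    inside = np.zeros(shape, dtype=bool)
    for c in centers:
        cx, cy, cz = c
        if (
            abs(cx) + ax > abs(x[0]) + voxel_xy / 2
            or abs(cy) + ay > abs(y[0]) + voxel_xy / 2
            or abs(cz) + az > abs(z[0]) + z_step / 2
        ):
            raise InvalidGeometryError("ellipsoid exceeds the stack bounds")
        inside |= (
            ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
        ) <= 1.0

    rng = np.random.default_rng(seed)
    field = np.full(shape, float(background))
    interior = np.full(shape, float(interior_intensity))
    if texture_strength > 0 and inside.any():
        from scipy import ndimage as ndi

        raw = rng.standard_normal(shape)
        smooth = ndi.gaussian_filter(raw, texture_sigma_px)
        tex = 1.0 + texture_strength * smooth / max(smooth[inside].std(), 1e-12)
        tex = np.clip(tex, 0.0, None)
        tex /= tex[inside].mean()
        interior = interior * tex
    field[inside] = interior[inside]
    if noise_sd > 0:
        field = np.clip(field + rng.normal(0.0, noise_sd, size=shape), 0.0, None)

    volume = 4.0 / 3.0 * math.pi * ax * ay * az
    truth = GroundTruth(
        kind="nucleus_stack",
        params={
            "volume_um3": volume * len(centers),
            "volume_per_nucleus_um3": volume,
            "n_nuclei": len(centers),
            "interior_intensity": interior_intensity,
            "expected_compaction": interior_intensity / (voxel_xy**2 * z_step),
        },
    )
    return ZStack(voxels=field, voxel_xy=voxel_xy, z_step=z_step), truth


def gen_lamin_image(
    radius: float = 4.0,
    fold_amplitude: float = 1.0,
    n_folds: int = 4,
    pixel: float = DEFAULT_VOXEL_XY,
    noise_sd: float = 2.0,
    seed: int = 0,
    rim_intensity: float = 1000.0,
    interior_base: float = 300.0,
    ridge_gain: float = 150.0,
    fold_wavelength_px: float = 12.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a lamin-stained nucleus: bright rim plus interior fold ridges.

    The folds are ``n_folds`` smoothed sinusoidal ridge waves of fixed
    spatial wavelength (so fold density per unit area does not change with
    nucleus size) and random seeded orientations/phases; their contrast
    scales linearly with ``fold_amplitude``.  Returns (image, mask, truth).
    """
    if fold_amplitude < 0:
        raise InvalidParameterError("fold amplitude must be nonnegative")
    if radius <= 0 or pixel <= 0:
        raise InvalidParameterError("radius and pixel size must be positive")
    r_px = radius / pixel
    half = math.ceil(1.3 * r_px)
    n = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    dist = np.hypot(yy, xx)
    mask = dist <= r_px

    rng = np.random.default_rng(seed)
    image = np.zeros((n, n))
    image[mask] = interior_base
    if n_folds > 0:
        ridges = np.zeros((n, n))
        for _ in range(n_folds):
            theta = rng.uniform(0.0, np.pi)
            phase = rng.uniform(0.0, 2 * np.pi)
            u = xx * math.cos(theta) + yy * math.sin(theta)
            ridges += 0.5 * (1.0 + np.cos(2 * np.pi * u / fold_wavelength_px + phase))
        ridges /= n_folds
        image[mask] += fold_amplitude * ridge_gain * ridges[mask]
    rim = rim_intensity * np.exp(-((dist - r_px) ** 2) / (2 * 1.5**2))
    image += rim
    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, size=image.shape), 0.0, None)

    truth = GroundTruth(
        kind="lamin_image",
        params={
            "fold_amplitude": float(fold_amplitude),
            "n_folds": int(n_folds),
            "radius_um": float(radius),
            "radius_px": float(r_px),
        },
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# FRAP


def gen_frap_trace(
    I_pre: float = 100.0,
    I_bleach: float = 30.0,
    I_plateau: float = 90.0,
    tau_r: float = 14.427,
    protocol: FrapProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FrapTrace, GroundTruth]:
    """Synthesize a FRAP trace with single-exponential recovery.

    Prescan frames sit at ``I_pre``; post-bleach frames follow
    I(t) = I_plateau - (I_plateau - I_bleach) exp(-t / tau_r).  Ground
    truth half time is tau_r * ln 2.
    """
    if protocol is None:
        protocol = FrapProtocol()
    if tau_r <= 0:
        raise InvalidParameterError("tau_r must be positive")
    if I_plateau < I_bleach:
        raise InvalidParameterError("recovery plateau cannot be below the bleach level")
    if I_pre < I_plateau:
        raise InvalidParameterError("prescan intensity must be >= the recovery plateau")
    rng = np.random.default_rng(seed)
    pre = np.full(protocol.n_prescan, float(I_pre))
    t = np.arange(protocol.n_post) * protocol.post_interval
    y = I_plateau - (I_plateau - I_bleach) * np.exp(-t / tau_r)
    if noise_sd > 0:
        pre = np.clip(pre + rng.normal(0.0, noise_sd, pre.shape), 0.0, None)
        y = np.clip(y + rng.normal(0.0, noise_sd, y.shape), 0.0, None)
    truth = GroundTruth(
        kind="frap",
        params={
            "tau_r": float(tau_r),
            "t_half": float(tau_r * math.log(2.0)),
            "I_pre": float(I_pre),
            "I_bleach": float(I_bleach),
            "I_plateau": float(I_plateau),
            "mobile_fraction": float(
                (I_plateau - I_bleach) / (I_pre - I_bleach) if I_pre > I_bleach else 1.0
            ),
        },
    )
    return FrapTrace(time=t, intensity=y, prescan_intensity=pre, protocol=protocol), truth


# ---------------------------------------------------------------------------
# particle tracks


def _fgn_autocorr(n: int, alpha: float) -> np.ndarray:
    """Autocorrelation of fractional Gaussian noise at lags 0..n."""
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )


def _fgn_davies_harte(n: int, alpha: float, rng) -> np.ndarray | None:
    """Exact fGn sample via circulant embedding; None if the embedding fails."""
    rho = _fgn_autocorr(n, alpha)
    c = np.concatenate([rho, rho[-2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)
    m = c.size
    W = np.zeros(m, dtype=complex)
    W[0] = math.sqrt(lam[0] / m) * rng.standard_normal()
    W[m // 2] = math.sqrt(lam[m // 2] / m) * rng.standard_normal()
    k = np.arange(1, m // 2)
    re = rng.standard_normal(k.size)
    im = rng.standard_normal(k.size)
    W[k] = np.sqrt(lam[k] / (2 * m)) * (re + 1j * im)
    W[m - k] = np.conj(W[k])
    return np.fft.fft(W).real[:n]


def _fgn_cholesky(n: int, alpha: float, rng) -> np.ndarray:
    rho = _fgn_autocorr(n - 1, alpha)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = rho[idx] + 1e-12 * np.eye(n)
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(n)


def gen_tracks(
    n_tracks: int = 1,
    n_steps: int = 20,
    dt: float = 120.0,
    alpha: float = 1.0,
    D: float = 0.01,
    dim: int = 2,
    seed: int = 0,
) -> tuple[list[Trajectory], GroundTruth]:
    """Fractional-Brownian particle tracks with E[MSD(tau)] = D * tau^alpha.

    ``D`` is the full dim-summed MSD prefactor (um^2 s^-alpha); coordinates
    are independent, each carrying D/dim of it.  ``n_steps`` is the number
    of time points (frames), default 20 frames at 2-min intervals.
    alpha = 2 is the ballistic limit (random constant velocity per track).
    Fractional Gaussian increments are drawn exactly, by circulant
    embedding with a Cholesky fallback.
    """
    if not 0 < alpha <= 2:
        raise InvalidParameterError("alpha must be in (0, 2]")
    if D <= 0 or dt <= 0 or n_steps < 2 or dim not in (2, 3):
        raise InvalidParameterError("invalid track parameters")
    rng = np.random.default_rng(seed)
    sd_step = math.sqrt(D / dim) * dt ** (alpha / 2.0)
    t = np.arange(n_steps) * dt
    tracks = []
    for i in range(n_tracks):
        pos = np.zeros((n_steps, dim))
        for d in range(dim):
            if alpha == 2.0:
                v = rng.standard_normal()
                incr = np.full(n_steps - 1, v)
            else:
                incr = _fgn_davies_harte(n_steps - 1, alpha, rng)
                if incr is None:
                    incr = _fgn_cholesky(n_steps - 1, alpha, rng)
            pos[1:, d] = np.cumsum(sd_step * incr)
        tracks.append(Trajectory(id=f"track{i}", time=t, position=pos))
    truth = GroundTruth(
        kind="tracks",
        params={"alpha": float(alpha), "D": float(D), "dt": float(dt), "dim": dim},
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# nucleus rigid motion


def _rotation_matrix(angle: float, dim: int) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    if dim == 2:
        return np.array([[c, -s], [s, c]])
    R = np.eye(3)
    R[0, 0], R[0, 1], R[1, 0], R[1, 1] = c, -s, s, c  # rotation about z
    return R


def gen_nucleus_motion(
    n_frames: int = 20,
    drift_per_frame=(0.1, 0.05),
    rotation_per_frame: float = 0.0,
    n_landmarks: int = 6,
    seed: int = 0,
    landmark_spread: float = 5.0,
    jitter_sd: float = 0.0,
    center0=None,
) -> NucleusMotion:
    """Rigid nucleus motion: cumulative drift plus rotation about the moving
    center, with landmarks co-moving (optionally with seeded jitter)."""
    drift = np.asarray(drift_per_frame, dtype=float)
    dim = drift.size
    if dim not in (2, 3):
        raise InvalidGeometryError("drift vector must be 2-D or 3-D")
    if n_landmarks < (2 if dim == 2 else 3):
        raise InvalidGeometryError("need >= 2 landmarks in 2-D, >= 3 in 3-D")
    rng = np.random.default_rng(seed)
    c0 = np.zeros(dim) if center0 is None else np.asarray(center0, dtype=float)
    base = rng.uniform(-landmark_spread, landmark_spread, size=(n_landmarks, dim))
    if dim == 3 and np.linalg.matrix_rank(base - base.mean(axis=0)) < 2:
        raise InvalidGeometryError("landmark set is collinear")
    frames = np.arange(n_frames)
    centers = c0[None, :] + frames[:, None] * drift[None, :]
    rotations = np.stack([_rotation_matrix(rotation_per_frame * f, dim) for f in frames])
    landmarks = np.einsum("nij,kj->nki", rotations, base) + centers[:, None, :]
    if jitter_sd > 0:
        landmarks = landmarks + rng.normal(0.0, jitter_sd, size=landmarks.shape)
    return NucleusMotion(center_track=centers, rotations=rotations, landmarks=landmarks)


def compose_observed_tracks(
    tracks: list[Trajectory], motion: NucleusMotion
) -> list[Trajectory]:
    """Forward model of observation: each nucleus-frame position is rotated
    by the frame's rotation about the nucleus center and translated by the
    center track.  Exact inverse of drift + per-frame rotation correction."""
    out = []
    for traj in tracks:
        n, d = traj.position.shape
        if n != motion.n_frames:
            raise ShapeError("track and motion frame counts differ")
        if d != motion.center_track.shape[1]:
            raise ShapeError("track and motion dimensionality differ")
        obs = (
            np.einsum("nij,nj->ni", motion.rotations, traj.position)
            + motion.center_track
        )
        out.append(Trajectory(id=traj.id, time=traj.time, position=obs, valid=traj.valid))
    return out
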