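"""Intranuclear particle dynamics: motion correction, time-averaged MSD,
and anomalous-diffusion power-law fitting.

Fluorescently tagged fibrillarin marks the dense fibrillar component of the
nucleolus and serves as a traceable intranuclear landmark.  Raw trajectories
recorded by a tracker mix the particle's own motion with stage drift and
rigid-body drift and rotation of the whole nucleus.  The correction chain
here subtracts the nucleus center track (drift) and applies inverse rotation
matrices (rotation) before any MSD is computed.

For a corrected track r_i(t) the time-averaged mean squared displacement at
lag tau is the average of |r_i(t + tau) - r_i(t)|^2 over all ordered frame
pairs separated by tau.  Intranuclear motion is subdiffusive, so only the
first half of the MSD curve is fitted as log10(MSD) = alpha * log10(tau) +
log10(D), yielding the diffusion exponent alpha and generalized diffusion
coefficient D (um^2 s^-alpha); fits with R^2 <= 0.8 are rejected.  The
characteristic time to diffuse 1 um^2 is T = (1/D)^(1/alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InvalidGeometryError, ShapeError

__all__ = [
    "Trajectory",
    "MsdCurve",
    "PowerLawFit",
    "estimate_rotation",
    "mean_rotation",
    "correct_drift",
    "correct_rotation",
    "time_avg_msd",
    "fit_powerlaw",
    "diffusion_time",
    "ensemble_summary",
]


@dataclass(frozen=True)
class Trajectory:
    """A single particle track on a uniform time grid.

    ``valid`` flags frames belonging to the one contiguous tracked segment;
    concatenations of different loci are not represented (tracks with gaps
    joining distinct particles must be split upstream).
    """

    id: str
    time: np.ndarray
    position: np.ndarray  # (n_frames, dim) in um
    valid: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)
        if p.ndim != 2 or p.shape[0] != t.size:
            raise ShapeError("position must be (n_frames, dim) matching time")
        if p.shape[1] not in (2, 3):
            raise ShapeError("only 2-D or 3-D positions are supported")
        v = self.valid
        v = np.ones(t.size, dtype=bool) if v is None else np.asarray(v, dtype=bool)
        object.__setattr__(self, "valid", v)
        if v.shape != t.shape:
            raise ShapeError("valid flags must match the frame count")
        idx = np.flatnonzero(v)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise DataError("valid frames must form a single contiguous segment")

    @property
    def dim(self) -> int:
        return self.position.shape[1]

    def valid_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and positions of the contiguous valid segment."""
        return self.time[self.valid], self.position[self.valid]


@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged MSD of one track; msd(0) = 0 is implicit."""

    lag: np.ndarray  # s, positive multiples of the frame interval
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # pair count per lag


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log fit msd = D * tau^alpha with the R^2 > 0.8 acceptance gate."""

    alpha: float
    D: float
    r_squared: float
    accepted: bool
    T: float | None  # s, time to diffuse 1 um^2; None when rejected


def estimate_rotation(landmarks_t: np.ndarray, landmarks_ref: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) rotation mapping centered ``landmarks_ref``
    onto centered ``landmarks_t``; determinant +1 enforced."""
    P = np.asarray(landmarks_ref, dtype=float)
    Q = np.asarray(landmarks_t, dtype=float)
    if P.shape != Q.shape or P.ndim != 2:
        raise ShapeError("landmark sets must be matched (n_points, dim) arrays")
    n, d = P.shape
    if d not in (2, 3) or n < d - (1 if d == 2 else 0):
        raise InvalidGeometryError("need >= 2 points in 2-D or >= 3 in 3-D")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # a configuration spanning fewer than d-1 dimensions cannot pin a rotation
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < d - 1:
        raise InvalidGeometryError("degenerate (collinear/coincident) landmark set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(d)
    D[-1, -1] = sign
    return Vt.T @ D @ U.T


def mean_rotation(rotations) -> np.ndarray:
    """Chordal mean rotation: arithmetic average of the matrices projected
    back onto SO(d) by the orthogonal polar factor.  In 2-D this equals the
    circular mean of the rotation angles."""
    Rs = np.asarray(rotations, dtype=float)
    if Rs.ndim == 2:
        Rs = Rs[None]
    if Rs.ndim != 3 or Rs.shape[1] != Rs.shape[2] or Rs.shape[0] == 0:
        raise ShapeError("expected a nonempty list of square rotation matrices")
    M = Rs.mean(axis=0)
    U, s, Vt = np.linalg.svd(M)
    if s[-1] < 1e-12:
        raise DataError("rotation spread is antipodal; chordal mean undefined")
    d = M.shape[0]
    Dm = np.eye(d)
    Dm[-1, -1] = np.sign(np.linalg.det(U @ Vt))
    return U @ Dm @ Vt


def _check_rotation(R: np.ndarray) -> None:
    d = R.shape[0]
    if not np.allclose(R @ R.T, np.eye(d), atol=1e-8) or np.linalg.det(R) < 0:
        raise InvalidGeometryError("matrix is not a proper rotation")


def correct_drift(traj: Trajectory, center_track: Trajectory) -> Trajectory:
    """Subtract the nucleus mass-center track frame-wise."""
    if traj.time.shape != center_track.time.shape or not np.allclose(
        traj.time, center_track.time
    ):
        raise ShapeError("trajectory and center track must share the frame grid")
    if traj.position.shape != center_track.position.shape:
        raise ShapeError("trajectory and center track must share dimensionality")
    return Trajectory(
        id=traj.id,
        time=traj.time,
        position=traj.position - center_track.position,
        valid=traj.valid,
    )


def correct_rotation(traj: Trajectory, rotations, center=None) -> Trajectory:
    """Undo nucleus rotation: position <- R(t)^-1 (position - c(t)) + c(t).

    ``rotations`` is either a per-frame (n, d, d) stack or a single (d, d)
    matrix (the per-trajectory mean rotation, applied to every frame, as in
    averaging-based correction).  With ``center=None`` the rotation is
    undone about the origin — the natural choice after drift correction,
    when positions are already relative to the nucleus center.
    """
    n, d = traj.position.shape
    Rs = np.asarray(rotations, dtype=float)
    if Rs.ndim == 2:
        Rs = np.broadcast_to(Rs, (n, d, d))
    if Rs.shape != (n, d, d):
        raise ShapeError("rotations must be (d, d) or (n_frames, d, d)")
    for R in Rs[:: max(1, n - 1)]:  # cheap spot check: first and last frame
        _check_rotation(R)
    if center is None:
        c = np.zeros((n, d))
    elif isinstance(center, Trajectory):
        c = center.position
    else:
        c = np.asarray(center, dtype=float)
    if c.shape != (n, d):
        raise ShapeError("center must be per-frame (n_frames, dim)")
    rel = traj.position - c
    # R^-1 = R^T for proper rotations
    corrected = np.einsum("nij,nj->ni", Rs.transpose(0, 2, 1), rel) + c
    return Trajectory(id=traj.id, time=traj.time, position=corrected, valid=traj.valid)


def time_avg_msd(
    traj: Trajectory, max_lag_fraction: float = 1.0, average: bool = True
) -> MsdCurve:
    """Time-averaged MSD over all ordered frame pairs of the valid segment.

    For lag tau = k * dt the estimate is mean_t |r(t + k dt) - r(t)|^2 over
    the n - k available pairs.  ``average=False`` keeps the bare sum over
    pairs instead of the mean (a convention some trackers report); the
    log-log exponent fit is only lag-consistent under the mean.  Sums are
    accumulated with exact (fsum) summation so results do not depend on
    accumulation order.
    """
    t, p = traj.valid_segment()
    n = t.size
    if n < 3:
        raise DataError("need at least 3 valid frames for an MSD")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt):
        raise DataError("trajectory time grid must be uniform")
    max_k = max(1, int(math.floor(max_lag_fraction * (n - 1))))
    lags = np.empty(max_k)
    msd = np.empty(max_k)
    n_pairs = np.empty(max_k, dtype=int)
    for k in range(1, max_k + 1):
        disp = p[k:] - p[:-k]
        sq = np.einsum("ij,ij->i", disp, disp)
        total = math.fsum(sq.tolist())
        lags[k - 1] = k * dt
        n_pairs[k - 1] = n - k
        msd[k - 1] = total / (n - k) if average else total
    return MsdCurve(lag=lags, msd=msd, n_pairs=n_pairs)


def ensemble_msd(curves: list[MsdCurve]) -> MsdCurve:
    """Average per-track MSD curves into one ensemble curve.

    Lags present in every curve are kept; each lag's MSD is the unweighted
    mean over tracks (every track contributes equally, as when tracks come
    from different cells).  For short tracks the per-track log-log fit is
    biased — fitting this ensemble curve instead is the low-noise route to
    (alpha, D) when many tracks of one condition are available.
    """
    if not curves:
        raise DataError("empty curve list")
    n_common = min(c.lag.size for c in curves)
    lag = curves[0].lag[:n_common]
    for c in curves:
        if not np.allclose(c.lag[:n_common], lag):
            raise DataError("MSD curves have incompatible lag grids")
    msd = np.mean([c.msd[:n_common] for c in curves], axis=0)
    n_pairs = np.sum([c.n_pairs[:n_common] for c in curves], axis=0)
    return MsdCurve(lag=lag, msd=msd, n_pairs=n_pairs)


def fit_powerlaw(
    msd: MsdCurve, fit_fraction: float = 0.5, r2_min: float = 0.8
) -> PowerLawFit:
    """Fit log10(msd) vs log10(tau) over the first ``fit_fraction`` of lags.

    The fit window is the first floor(fit_fraction * n_lags) lag values,
    never fewer than 3.  alpha is the slope, D = 10^intercept, and the fit
    is accepted only when R^2 exceeds ``r2_min``; T is computed from the
    accepted fit as (1/D)^(1/alpha).
    """
    n_lags = msd.lag.size
    n_fit = max(3, int(math.floor(fit_fraction * n_lags)))
    if n_lags < 3:
        raise DataError("need at least 3 lags to fit a power law")
    n_fit = min(n_fit, n_lags)
    tau = msd.lag[:n_fit]
    y = msd.msd[:n_fit]
    if np.any(y <= 0):
        raise DataError("MSD must be positive on the fit window")
    lx, ly = np.log10(tau), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-30 else 0.0)
    alpha = float(slope)
    D = float(10.0**intercept)
    accepted = bool(r2 > r2_min)
    T = float((1.0 / D) ** (1.0 / alpha)) if accepted and D > 0 and alpha > 0 else None
    return PowerLawFit(alpha=alpha, D=D, r_squared=float(r2), accepted=accepted, T=T)


def diffusion_time(fit: PowerLawFit) -> float | None:
    """Time for the fitted MSD to reach 1 um^2: T = (1/D)^(1/alpha).

    Returns None for rejected fits (the gate excludes them from summaries).
    """
    if not fit.accepted or fit.D <= 0 or fit.alpha <= 0:
        return None
    return float((1.0 / fit.D) ** (1.0 / fit.alpha))


def ensemble_summary(fits: list[PowerLawFit]) -> pd.DataFrame:
    """Mean/median/SD of alpha, D and T over accepted fits.

    The returned frame carries ``n_accepted`` / ``n_rejected`` in ``attrs``.
    """
    if not fits:
        raise DataError("empty fit list")
    acc = [f for f in fits if f.accepted]
    rows = {}
    for name, values in (
        ("alpha", [f.alpha for f in acc]),
        ("D", [f.D for f in acc]),
        ("T", [f.T for f in acc if f.T is not None]),
    ):
        if values:
            arr = np.asarray(values, dtype=float)
            rows[name] = {
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
            }
        else:
            rows[name] = {"mean": np.nan, "median": np.nan, "sd": np.nan, "n": 0}
    out = pd.DataFrame(rows).T
    out.attrs["n_accepted"] = len(acc)
    out.attrs["n_rejected"] = len(fits) - len(acc)
    return out
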