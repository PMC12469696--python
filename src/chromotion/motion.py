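"""Per-trajectory mobility statistics.

For a gap-filled track p(m*dt), m = 0..n (n = last frame, zero-based),
the time-averaged mean square displacement at lag k is

    MSD(k*dt) = 1/(n-k+1) * sum_{m=0}^{n-k} |p((m+k)*dt) - p(m*dt)|^2 .

The short-lag portion of the curve is fitted with the anomalous
diffusion law MSD(t) = 4 * D_app * t**alpha by ordinary least squares
in log-log space; D_app (μm²/sᵅ) is rescaled to a time-referenced
coefficient D(t) = D_app * t**(alpha-1), which at t = 1 s equals D_app
numerically and carries μm²/s.  Mean displacement per frame and the
gyration radius (RMS distance of positions from the trajectory centre)
complete the parameter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectories import Trajectory

__all__ = [
    "MSDCurve",
    "MotionParams",
    "compute_msd",
    "fit_anomalous",
    "rescale_diffusion",
    "mean_displacement",
    "gyration_radius",
    "summarize_track",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``lags`` are in frames (k = 1..n), ``times`` in seconds, ``values``
    in μm²; ``n_pairs[k-1] = n - k + 1`` displacement pairs averaged.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return self.lags * self.dt


@dataclass
class MotionParams:
    """Mobility parameters of one track."""

    alpha: float
    d_app: float              # μm²/s^alpha
    d_1s: float               # μm²/s, = d_app at t_ref = 1 s
    mean_displacement: float  # μm per frame
    gyration_radius: float    # μm
    fit_fraction: float
    fit_r2: float
    track_id: object = None
    cell_id: object = None


def _contiguous_xy(traj: Trajectory) -> np.ndarray:
    if traj.n_frames < 2:
        raise ValueError("trajectory needs at least 2 frames")
    if traj.n_spanned != traj.n_frames:
        raise ValueError("trajectory has unfilled gaps; interpolate first")
    if not np.all(np.isfinite(traj.xy)):
        raise ValueError("trajectory has non-finite positions")
    return traj.xy


def compute_msd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD at every lag k = 1..n (or up to ``max_lag``).

    Interpolated points participate identically to observed ones.
    """
    xy = _contiguous_xy(traj)
    n = xy.shape[0] - 1  # last frame index, zero-based
    kmax = n if max_lag is None else min(int(max_lag), n)
    values = np.empty(kmax)
    n_pairs = np.empty(kmax, dtype=np.int64)
    for k in range(1, kmax + 1):
        d = xy[k:] - xy[:-k]
        values[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k - 1] = n - k + 1
    return MSDCurve(np.arange(1, kmax + 1), values, n_pairs, traj.dt)


def fit_window_length(n_lags: int, fit_fraction: float) -> int:
    """Number of leading MSD lags entering the power-law fit."""
    return int(np.floor(fit_fraction * n_lags))


def fit_anomalous(msd: MSDCurve, fit_fraction: float = 0.20):
    """Fit MSD(t) = 4 * D_app * t**alpha over the leading lag window.

    Ordinary least squares of log(MSD) on log(t) over lags
    k = 1..floor(fit_fraction * n_lags).  Zero MSD values in the window
    are excluded with a warning.  Returns (d_app, alpha, r2).
    """
    if not (0.0 < fit_fraction <= 1.0):
        raise ValueError("fit_fraction must be in (0, 1]")
    k = fit_window_length(msd.lags.size, fit_fraction)
    t = msd.times[:k]
    y = msd.values[:k]
    keep = y > 0
    if np.count_nonzero(~keep):
        warnings.warn(f"excluding {np.count_nonzero(~keep)} zero MSD values "
                      "from the power-law fit", stacklevel=2)
        t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError(f"need at least 3 usable MSD points, got {t.size}")
    logt, logy = np.log(t), np.log(y)
    slope, intercept = np.polyfit(logt, logy, 1)
    resid = logy - (slope * logt + intercept)
    ss_tot = np.sum((logy - logy.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(intercept) / 4.0), float(slope), float(r2)


def rescale_diffusion(d_app: float, alpha: float, t_ref: float = 1.0) -> float:
    """Time-referenced diffusion coefficient D(t) = D_app * t**(alpha-1).

    At t_ref = 1 s the value equals D_app numerically and carries μm²/s,
    making tracks with different alpha comparable.
    """
    if not d_app > 0:
        raise ValueError("d_app must be positive")
    if not t_ref > 0:
        raise ValueError("t_ref must be positive")
    return float(d_app * t_ref ** (alpha - 1.0))


def mean_displacement(traj: Trajectory) -> float:
    """Arithmetic mean of consecutive-frame Euclidean displacements (μm)."""
    xy = _contiguous_xy(traj)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return float(steps.mean())


def gyration_radius(traj: Trajectory, first_n_frames: int | None = None) -> float:
    """RMS distance of positions from the trajectory centre (μm).

    ``first_n_frames`` truncates the track to its leading frames first,
    e.g. to compare acquisitions of different duration on equal footing.
    """
    xy = traj.xy
    if first_n_frames is not None:
        if first_n_frames < 1:
            raise ValueError("first_n_frames must be >= 1")
        xy = xy[:first_n_frames]
    if xy.shape[0] < 1:
        raise ValueError("trajectory is empty")
    if not np.all(np.isfinite(xy)):
        raise ValueError("trajectory has non-finite positions")
    centre = xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((xy - centre) ** 2, axis=1))))


def summarize_track(traj: Trajectory, fit_fraction: float = 0.20,
                    rg_first_n_frames: int | None = None,
                    cell_id=None, max_lag: int | None = None) -> MotionParams:
    """All mobility parameters of one QC-passed track.

    ``max_lag`` may limit the MSD computation to the lags the fit
    consumes (the fit window is determined from the full lag count, so
    the fitted window is identical either way).
    """
    n_lags = traj.n_frames - 1
    k_fit = fit_window_length(n_lags, fit_fraction)
    if max_lag is not None:
        max_lag = max(max_lag, k_fit)
    msd = compute_msd(traj, max_lag=max_lag)
    d_app, alpha, r2 = _fit_with_window(msd, k_fit)
    return MotionParams(
        alpha=alpha,
        d_app=d_app,
        d_1s=rescale_diffusion(d_app, alpha, 1.0),
        mean_displacement=mean_displacement(traj),
        gyration_radius=gyration_radius(traj, rg_first_n_frames),
        fit_fraction=fit_fraction,
        fit_r2=r2,
        track_id=traj.track_id,
        cell_id=cell_id,
    )


def _fit_with_window(msd: MSDCurve, k_fit: int):
    """Fit over an explicit leading window of k_fit lags."""
    if k_fit > msd.lags.size:
        raise ValueError("fit window exceeds available lags")
    sub = MSDCurve(msd.lags[:k_fit], msd.values[:k_fit],
                   msd.n_pairs[:k_fit], msd.dt)
    return fit_anomalous(sub, fit_fraction=1.0)
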