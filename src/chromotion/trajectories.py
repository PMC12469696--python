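"""Core trajectory containers and nucleus-frame preparation.

Positions are 2-D, in micrometres, on a fixed frame grid with spacing
``dt`` seconds.  A trajectory may contain missing frames (``observed``
False, positions NaN) until :func:`interpolate_gaps` fills them; after
filling, ``observed`` False marks interpolated points.

The preparation stage mirrors a live-cell locus/focus tracking workflow:
signal coordinates are first expressed in the coordinate system of the
nucleus centre (translation only), gaps are closed by per-axis linear
interpolation, and per-experiment quality-control rules drop short or
gap-heavy tracks and under-populated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "CellRecord",
    "QCOutcome",
    "compensate_nucleus",
    "interpolate_gaps",
    "qc_filter_locus",
    "qc_filter_foci",
]


@dataclass
class Trajectory:
    """Ordered per-frame 2-D positions of one tracked object.

    Parameters
    ----------
    frames : array of int
        Strictly increasing 0-based frame indices.
    xy : array, shape (n, 2)
        Positions in μm; NaN where the frame is missing.
    observed : bool array
        True where the position is a detection, False where it is
        missing (NaN) or was filled by interpolation.
    dt : float
        Frame interval in seconds.
    track_id : int or str, optional
        Identifier used for deterministic selection and table output.
    """

    frames: np.ndarray
    xy: np.ndarray
    observed: np.ndarray
    dt: float
    track_id: object = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.frames.ndim != 1:
            raise ValueError("frames must be 1-D")
        if self.xy.shape != (self.frames.size, 2):
            raise ValueError("xy must have shape (n_frames, 2)")
        if self.observed.shape != self.frames.shape:
            raise ValueError("observed must match frames")
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def n_spanned(self) -> int:
        """Frames spanned from first to last, inclusive (gaps count)."""
        if self.frames.size == 0:
            return 0
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(~self.observed))

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.dt

    def copy(self) -> "Trajectory":
        return Trajectory(self.frames.copy(), self.xy.copy(),
                          self.observed.copy(), self.dt, self.track_id)


ReplicationState = Literal["replicated", "unreplicated", "unknown"]
SignalKind = Literal["locus", "focus"]


@dataclass
class CellRecord:
    """One cell: its nucleus track and the signal tracks inside it."""

    cell_id: object
    condition: str
    nucleus: Trajectory
    signals: list = field(default_factory=list)
    replication_state: ReplicationState = "unknown"
    signal_kind: SignalKind = "locus"
    #: optional map track_id -> generating ground truth (synthetic cohorts)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.signals:
            if not np.isclose(s.dt, self.nucleus.dt):
                raise ValueError("all trajectories in a cell must share dt")


@dataclass
class QCOutcome:
    """Filtered cohort plus an audit trail of rejections."""

    cells: list
    n_tracks_in: int
    n_tracks_kept: int
    rejected: list  # (cell_id, track_id, reason)

    @property
    def n_tracks_rejected(self) -> int:
        return self.n_tracks_in - self.n_tracks_kept


def compensate_nucleus(signal: Trajectory, nucleus: Trajectory) -> Trajectory:
    """Express a signal trajectory in the nucleus-centre coordinate system.

    Output position at frame m is ``signal(m) - nucleus(m)``; gap flags
    and dt are preserved.  Raises if the nucleus lacks any signal frame.
    """
    idx = np.searchsorted(nucleus.frames, signal.frames)
    bad = (idx >= nucleus.frames.size) | (
        nucleus.frames[np.minimum(idx, nucleus.frames.size - 1)] != signal.frames
    )
    if np.any(bad):
        missing = signal.frames[bad][0]
        raise ValueError(
            f"nucleus trajectory has no position at signal frame {missing}"
        )
    out = signal.copy()
    out.xy = signal.xy - nucleus.xy[idx]
    return out


def interpolate_gaps(traj: Trajectory, max_total_gaps: int | None = None) -> Trajectory:
    """Fill missing frames by per-axis linear interpolation.

    The trajectory must start and end on an observed frame.  Missing
    interior frames (absent from ``frames`` or flagged unobserved) are
    filled between the nearest observed neighbours and flagged as
    interpolated.  If ``max_total_gaps`` is given and the number of
    missing frames exceeds it, a :class:`QCRejection` is raised — the
    caller treats this as a QC failure, not a programming error.
    """
    if traj.n_frames < 2:
        return traj.copy()
    if not (traj.observed[0] and traj.observed[-1]):
        raise ValueError("first and last frames must be observed")

    full = np.arange(traj.frames[0], traj.frames[-1] + 1, dtype=np.int64)
    obs_mask_in = traj.observed & np.all(np.isfinite(traj.xy), axis=1)
    obs_frames = traj.frames[obs_mask_in]
    obs_xy = traj.xy[obs_mask_in]

    n_missing = full.size - obs_frames.size
    if max_total_gaps is not None and n_missing > max_total_gaps:
        raise QCRejection(
            f"track has {n_missing} missing frames (> {max_total_gaps})"
        )

    xy = np.column_stack([
        np.interp(full, obs_frames, obs_xy[:, 0]),
        np.interp(full, obs_frames, obs_xy[:, 1]),
    ])
    observed = np.isin(full, obs_frames)
    # keep observed positions bit-exact; np.interp at a node returns the
    # node value but we assign explicitly to guarantee it
    pos_idx = np.searchsorted(full, obs_frames)
    xy[pos_idx] = obs_xy
    return Trajectory(full, xy, observed, traj.dt, traj.track_id)


class QCRejection(Exception):
    """A track failed a quality-control rule (not a usage error)."""


def _try_interp(traj: Trajectory, max_total_gaps: int):
    try:
        return interpolate_gaps(traj, max_total_gaps), None
    except QCRejection as e:
        return None, str(e)


def qc_filter_locus(
    cells: Iterable[CellRecord],
    min_frames: int = 180,
    max_total_gaps: int = 5,
    one_per_cell: bool = True,
    rng: np.random.Generator | None = None,
) -> QCOutcome:
    """Locus-experiment QC: length and gap rules, one signal per cell.

    Tracks spanning fewer than ``min_frames`` frames or carrying more
    than ``max_total_gaps`` missing points are dropped; cells with no
    surviving track are dropped.  When a cell retains several signals
    and ``one_per_cell`` is set, the signal with the lowest track id
    among the longest tracks is kept (pass ``rng`` for a seeded random
    choice among the longest instead).
    """
    kept_cells: list[CellRecord] = []
    rejected: list = []
    n_in = n_kept = 0
    for cell in cells:
        survivors = []
        for sig in cell.signals:
            n_in += 1
            if sig.n_spanned < min_frames:
                rejected.append((cell.cell_id, sig.track_id,
                                 f"spans {sig.n_spanned} < {min_frames} frames"))
                continue
            filled, reason = _try_interp(sig, max_total_gaps)
            if filled is None:
                rejected.append((cell.cell_id, sig.track_id, reason))
                continue
            survivors.append(filled)
        if not survivors:
            continue
        if one_per_cell and len(survivors) > 1:
            longest = max(s.n_spanned for s in survivors)
            candidates = [s for s in survivors if s.n_spanned == longest]
            if rng is not None:
                chosen = candidates[int(rng.integers(len(candidates)))]
            else:
                chosen = min(candidates, key=lambda s: str(s.track_id))
            for s in survivors:
                if s is not chosen:
                    rejected.append((cell.cell_id, s.track_id,
                                     "cell already contributes one signal"))
            survivors = [chosen]
        n_kept += len(survivors)
        kept_cells.append(replace(cell, signals=survivors))
    return QCOutcome(kept_cells, n_in, n_kept, rejected)


def qc_filter_foci(
    cells: Iterable[CellRecord],
    min_points: int = 110,
    max_total_gaps: int = 5,
    min_tracks_per_cell: int = 5,
) -> QCOutcome:
    """Focus-experiment QC: point count, gap total, tracks-per-cell rules.

    A focus track is valid when it carries at least ``min_points``
    observed points and at most ``max_total_gaps`` missing frames; a
    cell enters the cohort only with at least ``min_tracks_per_cell``
    valid tracks.
    """
    kept_cells: list[CellRecord] = []
    rejected: list = []
    n_in = n_kept = 0
    for cell in cells:
        survivors = []
        for sig in cell.signals:
            n_in += 1
            n_obs = int(np.count_nonzero(sig.observed))
            if n_obs < min_points:
                rejected.append((cell.cell_id, sig.track_id,
                                 f"{n_obs} observed points < {min_points}"))
                continue
            filled, reason = _try_interp(sig, max_total_gaps)
            if filled is None:
                rejected.append((cell.cell_id, sig.track_id, reason))
                continue
            survivors.append(filled)
        if len(survivors) < min_tracks_per_cell:
            for s in survivors:
                rejected.append((cell.cell_id, s.track_id,
                                 f"cell has {len(survivors)} valid tracks "
                                 f"< {min_tracks_per_cell}"))
            continue
        n_kept += len(survivors)
        kept_cells.append(replace(cell, signals=survivors))
    return QCOutcome(kept_cells, n_in, n_kept, rejected)
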