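"""Frame-to-frame linking and gap closing of spot detections.

A two-step linear-assignment scheme in the spirit of simple LAP
trackers: consecutive frames are linked by an exact minimum-total-cost
one-to-one assignment on squared distance, with links beyond a distance
gate forbidden (unmatched detections start new tracklets); tracklet
ends are then matched to later tracklet starts under frame-gap and
distance gates, again by exact assignment.  No splitting or merging
events and no motion-model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import SpotDetection
from .trajectories import Trajectory

__all__ = ["LinkConfig", "link_frames", "close_gaps"]

# cost of leaving a detection / tracklet end unmatched, relative to the
# squared gate: any admissible link is preferred to starting a new track
_NO_LINK_FACTOR = 1.0 + 1e-9
_FORBIDDEN = 1e30


@dataclass
class LinkConfig:
    """Distance/gap gates of the two linking steps.

    Defaults are a locus-tracking configuration (0.5 μm link and
    gap-close gates, up to 5 missing frames); a focus configuration
    would use 0.2 / 0.4 μm, 3 frames and 110 minimum points.
    """

    max_link_distance: float = 0.5   # μm
    max_gap_frames: int = 5          # missing frames bridgeable
    max_gap_distance: float = 0.5    # μm
    min_track_points: int = 1

    def __post_init__(self) -> None:
        if not (self.max_link_distance > 0 and self.max_gap_distance > 0):
            raise ValueError("distance gates must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


def _gated_assignment(cost: np.ndarray, no_link_cost: float):
    """One-to-one assignment allowing unmatched rows/cols.

    ``cost`` holds admissible costs and ``_FORBIDDEN`` elsewhere.  The
    matrix is augmented with per-row/per-column opt-out entries at
    ``no_link_cost`` so the solver can leave any item unmatched.
    Returns the list of matched (row, col) pairs.
    """
    na, nb = cost.shape
    if na == 0 or nb == 0:
        return []
    full = np.full((na + nb, na + nb), _FORBIDDEN)
    full[:na, :nb] = cost
    full[na:, nb:] = 0.0
    np.fill_diagonal(full[:na, nb:], no_link_cost)
    np.fill_diagonal(full[na:, :nb], no_link_cost)
    rows, cols = linear_sum_assignment(full)
    return [(r, c) for r, c in zip(rows, cols)
            if r < na and c < nb and cost[r, c] < _FORBIDDEN]


def link_frames(detections: Sequence[SpotDetection],
                cfg: LinkConfig) -> list[list[SpotDetection]]:
    """Assemble detections into tracklets by per-frame-pair assignment."""
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []
    gate2 = cfg.max_link_distance ** 2
    tracklets: list[list[SpotDetection]] = []
    active: dict[int, list[SpotDetection]] = {}  # index in current frame -> tracklet
    frames = sorted(by_frame)
    for i, d in enumerate(by_frame[frames[0]]):
        t = [d]
        tracklets.append(t)
        active[i] = t
    for prev_f, cur_f in zip(frames[:-1], frames[1:]):
        cur = by_frame[cur_f]
        new_active: dict[int, list[SpotDetection]] = {}
        if cur_f == prev_f + 1 and active:
            prev = by_frame[prev_f]
            pa = np.array([[d.x, d.y] for d in prev])
            ca = np.array([[d.x, d.y] for d in cur])
            cost = np.sum((pa[:, None, :] - ca[None, :, :]) ** 2, axis=2)
            cost[cost > gate2] = _FORBIDDEN
            matched_cols = set()
            for r, c in _gated_assignment(cost, gate2 * _NO_LINK_FACTOR):
                if r in active:
                    active[r].append(cur[c])
                    new_active[c] = active[r]
                    matched_cols.add(c)
            for c, d in enumerate(cur):
                if c not in matched_cols:
                    t = [d]
                    tracklets.append(t)
                    new_active[c] = t
        else:  # empty frame in between (or first frame): everything restarts
            for c, d in enumerate(cur):
                t = [d]
                tracklets.append(t)
                new_active[c] = t
        active = new_active
    return tracklets


def close_gaps(tracklets: Sequence[Sequence[SpotDetection]], cfg: LinkConfig,
               dt: float) -> list[Trajectory]:
    """Bridge tracklets across missing frames and build trajectories.

    Tracklet ends are matched one-to-one to later tracklet starts when
    the number of missing frames between them is at most
    ``max_gap_frames`` and the jump at most ``max_gap_distance``; cost
    is squared distance.  Merged tracks shorter than
    ``min_track_points`` detections are discarded.  Track ids are
    assigned by (first frame, x, y) of the first detection.
    """
    segs = [list(t) for t in tracklets if t]
    n = len(segs)
    gate2 = cfg.max_gap_distance ** 2
    cost = np.full((n, n), _FORBIDDEN)
    for i, a in enumerate(segs):
        for j, b in enumerate(segs):
            if i == j:
                continue
            gap = b[0].frame - a[-1].frame - 1
            if gap < 0 or gap > cfg.max_gap_frames:
                continue
            d2 = (a[-1].x - b[0].x) ** 2 + (a[-1].y - b[0].y) ** 2
            if d2 <= gate2:
                cost[i, j] = d2
    succ: dict[int, int] = {}
    has_pred = set()
    if n:
        for i, j in _gated_assignment(cost, gate2 * _NO_LINK_FACTOR):
            succ[i] = j
            has_pred.add(j)
    merged: list[list[SpotDetection]] = []
    for i in range(n):
        if i in has_pred:
            continue
        chain = list(segs[i])
        k = i
        while k in succ:
            k = succ[k]
            chain.extend(segs[k])
        merged.append(chain)
    merged = [c for c in merged if len(c) >= cfg.min_track_points]
    merged.sort(key=lambda c: (c[0].frame, c[0].x, c[0].y))
    out = []
    for tid, chain in enumerate(merged):
        frames = np.array([d.frame for d in chain])
        xy = np.array([[d.x, d.y] for d in chain])
        out.append(Trajectory(frames, xy, np.ones(len(chain), bool), dt,
                              track_id=tid))
    return out
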