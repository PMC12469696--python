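"""Delimited-text table formats and pipeline configuration.

All tables are comma-separated UTF-8 with a header row.  The native
track-table schema has one row per localization:

    cell_id, track_id, frame, x_um, y_um, observed, role,
    condition, replication_state, signal_kind, dt_s

``role`` is ``signal`` or ``nucleus``; frames are 0-based; coordinates
in μm.  A column-mapping dialect allows importing exports of external
tracking software (e.g. TrackMate spot tables) so real data can bypass
the detection and linking stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import PARAMETER_LABELS, PARAMETER_ORDER, ComparisonResult
from .trajectories import CellRecord, Trajectory

__all__ = [
    "TRACK_COLUMNS",
    "DIALECTS",
    "FormatError",
    "read_track_table",
    "write_track_table",
    "write_ground_truth",
    "comparisons_to_frame",
    "PipelineConfig",
]

TRACK_COLUMNS = ["cell_id", "track_id", "frame", "x_um", "y_um", "observed",
                 "role", "condition", "replication_state", "signal_kind",
                 "dt_s"]

_REQUIRED = ["cell_id", "track_id", "frame", "x_um", "y_um"]

#: column-name mappings from external export formats onto the native schema
DIALECTS: dict[str, dict[str, str]] = {
    "native": {},
    "trackmate": {
        "TRACK_ID": "track_id",
        "FRAME": "frame",
        "POSITION_X": "x_um",
        "POSITION_Y": "y_um",
    },
}


class FormatError(ValueError):
    """A table violates the expected schema."""


def write_track_table(cells: Iterable[CellRecord], path) -> None:
    """Write cells (nucleus + signals) in the native track-table schema."""
    rows = []
    for cell in cells:
        for role, trajs in (("nucleus", [cell.nucleus]),
                            ("signal", cell.signals)):
            for t in trajs:
                for i, f in enumerate(t.frames):
                    x, y = t.xy[i]
                    rows.append((cell.cell_id, t.track_id, int(f),
                                 x, y, bool(t.observed[i]), role,
                                 cell.condition, cell.replication_state,
                                 cell.signal_kind, t.dt))
    # %.17g guarantees float64 round-trip through the text format
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.17g")


def read_track_table(path, dialect: str | dict = "native",
                     dt: float | None = None, **defaults) -> list[CellRecord]:
    """Read a track table into CellRecords.

    ``dialect`` maps external column names onto the native schema;
    columns the external format lacks (condition, role, ...) can be
    supplied through ``defaults`` (e.g. ``condition="control"``).
    Malformed rows and duplicate (cell, track, frame) keys raise
    :class:`FormatError` with line numbers.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns=mapping)
    for col, value in defaults.items():
        if col not in df.columns:
            df[col] = value
    if "cell_id" not in df.columns:
        df["cell_id"] = "cell0"
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    for col in ("frame",):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # header is line 1
            raise FormatError(f"non-numeric {col!r} at line(s) {lines[:5]}")
    dup = df.duplicated(subset=["cell_id", "track_id", "frame"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise FormatError(
            f"duplicate (cell_id, track_id, frame) at line(s) {lines[:5]}")
    if "observed" not in df.columns:
        df["observed"] = True
    if "role" not in df.columns:
        df["role"] = "signal"
    if "dt_s" not in df.columns:
        df["dt_s"] = 0.412 if dt is None else dt
    if dt is not None:
        df["dt_s"] = dt
    for col, dv in (("condition", "unknown"),
                    ("replication_state", "unknown"),
                    ("signal_kind", "locus")):
        if col not in df.columns:
            df[col] = dv

    cells = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        nucleus = None
        signals = []
        for (track_id, role), tg in g.groupby(["track_id", "role"], sort=True):
            tg = tg.sort_values("frame")
            traj = Trajectory(
                tg["frame"].to_numpy(dtype=np.int64),
                tg[["x_um", "y_um"]].to_numpy(dtype=np.float64),
                tg["observed"].to_numpy(dtype=bool),
                float(tg["dt_s"].iloc[0]),
                track_id=track_id,
            )
            if role == "nucleus":
                nucleus = traj
            else:
                signals.append(traj)
        if nucleus is None:
            # external exports often have no nucleus track; use a static one
            frames = np.arange(int(g["frame"].min()), int(g["frame"].max()) + 1)
            nucleus = Trajectory(frames, np.zeros((frames.size, 2)),
                                 np.ones(frames.size, bool),
                                 float(g["dt_s"].iloc[0]), track_id="nucleus")
        cells.append(CellRecord(
            cell_id=cell_id,
            condition=str(g["condition"].iloc[0]),
            nucleus=nucleus,
            signals=signals,
            replication_state=str(g["replication_state"].iloc[0]),
            signal_kind=str(g["signal_kind"].iloc[0]),
        ))
    return cells


def write_ground_truth(cells: Iterable[CellRecord], path) -> None:
    """Sidecar table of generating parameters, keyed by cell and track."""
    rows = []
    for cell in cells:
        for tid, gt in cell.ground_truth.items():
            rows.append((cell.cell_id, tid, gt.alpha, gt.d_app,
                         gt.noise_sigma, int(gt.gap_mask.sum())))
    pd.DataFrame(rows, columns=["cell_id", "track_id", "true_alpha",
                                "true_d_app", "noise_sigma", "n_gaps"]
                 ).to_csv(path, index=False)


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Results table mirroring a median-parameters comparison layout."""
    rows = []
    for r in results:
        rows.append({
            "parameter": PARAMETER_LABELS.get(r.parameter, r.parameter),
            "median_control": r.median_a,
            "median_treated": r.median_b,
            "median_fold_change": r.median_fold_change,
            "u_statistic": r.u_statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "n_control": r.n_a,
            "n_treated": r.n_b,
            "family_size": r.family_size,
        })
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Experiment-level parameters; defaults are the study's settings.

    ``kind`` selects the locus or focus parameter set: fit fraction
    0.20 vs 0.30, QC rules (>= 180 spanned frames vs >= 110 points with
    >= 5 tracks per nucleus, both with <= 5 gaps), and the linking
    gates (0.5/0.5 μm, 5 frames vs 0.2/0.4 μm, 3 frames, 110 points).
    """

    kind: str = "locus"
    dt: float = 0.412
    fit_fraction: float | None = None
    min_frames: int = 180            # locus QC
    min_points: int = 110            # focus QC
    max_total_gaps: int = 5
    min_tracks_per_cell: int = 5     # focus QC
    max_link_distance: float | None = None
    max_gap_distance: float | None = None
    max_gap_frames: int | None = None
    family_size: int = 8
    rg_truncation: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("locus", "focus"):
            raise ValueError("kind must be 'locus' or 'focus'")
        if self.fit_fraction is None:
            self.fit_fraction = 0.20 if self.kind == "locus" else 0.30
        if self.max_link_distance is None:
            self.max_link_distance = 0.5 if self.kind == "locus" else 0.2
        if self.max_gap_distance is None:
            self.max_gap_distance = 0.5 if self.kind == "locus" else 0.4
        if self.max_gap_frames is None:
            self.max_gap_frames = 5 if self.kind == "locus" else 3

    @property
    def min_track_points(self) -> int:
        return 1 if self.kind == "locus" else self.min_points

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from a plain-text key-value (YAML) file; an empty file
        reproduces the default experiment settings."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise FormatError("config must be a mapping of keys to values")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
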