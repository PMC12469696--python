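"""Model/Results interface over the mobility analysis.

:class:`MobilityModel` is built from cell records (or a track table)
and holds the experiment design: locus or focus analysis, fit window,
QC thresholds, comparison family.  ``fit()`` runs nucleus
compensation, gap interpolation, QC, per-track MSD and power-law
fitting, per-cell aggregation and the two-condition nonparametric
comparison, returning a :class:`MobilityResults` with the per-track
and per-cell parameter tables, the comparison results, median MSD
curves with confidence bands, and a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import motion as _motion
from .cohort import PARAMETER_LABELS, PARAMETER_ORDER
from .io import PipelineConfig, comparisons_to_frame, read_track_table
from .trajectories import (CellRecord, compensate_nucleus, qc_filter_foci,
                           qc_filter_locus)

__all__ = ["MobilityModel", "MobilityResults"]

_PARAM_COLUMNS = {
    "alpha": "alpha",
    "d_app": "d_app_um2_per_s_alpha",
    "d_1s": "d_1s_um2_per_s",
    "mean_displacement": "mean_disp_um",
    "gyration_radius": "rg_um",
    "fit_r2": "fit_r2",
}


class MobilityModel:
    """Chromatin-mobility analysis of a two-condition cohort.

    Parameters
    ----------
    cells : list of CellRecord
        Cohort(s) of cells with nucleus and signal trajectories.
    config : PipelineConfig, optional
        Experiment settings; a locus-default config is used if omitted.
    control_label : str, optional
        Condition treated as the comparison baseline; defaults to the
        condition of the first cell.
    """

    def __init__(self, cells, config: PipelineConfig | None = None,
                 control_label: str | None = None):
        self.cells = list(cells)
        if not self.cells:
            raise ValueError("model needs at least one cell")
        self.config = config or PipelineConfig()
        self.control_label = control_label

    @classmethod
    def from_track_table(cls, path, config: PipelineConfig | None = None,
                         dialect="native", control_label=None, **defaults):
        cfg = config or PipelineConfig()
        cells = read_track_table(path, dialect=dialect, dt=cfg.dt, **defaults)
        return cls(cells, cfg, control_label)

    # -- fitting ---------------------------------------------------------

    def fit(self, compute_msd_curves: bool = True) -> "MobilityResults":
        cfg = self.config
        compensated = []
        for cell in self.cells:
            signals = [compensate_nucleus(s, cell.nucleus)
                       for s in cell.signals]
            compensated.append(CellRecord(
                cell.cell_id, cell.condition, cell.nucleus, signals,
                cell.replication_state, cell.signal_kind, cell.ground_truth))
        if cfg.kind == "locus":
            qc = qc_filter_locus(compensated, min_frames=cfg.min_frames,
                                 max_total_gaps=cfg.max_total_gaps)
        else:
            qc = qc_filter_foci(compensated, min_points=cfg.min_points,
                                max_total_gaps=cfg.max_total_gaps,
                                min_tracks_per_cell=cfg.min_tracks_per_cell)

        track_rows, cell_rows = [], []
        msd_by_condition: dict[str, list] = {}
        condition_order: list[str] = []
        for cell in qc.cells:
            if cell.condition not in condition_order:
                condition_order.append(cell.condition)
            params = []
            for sig in cell.signals:
                # without curve output, only the fit window's lags are needed
                max_lag = None if compute_msd_curves else 1
                p = _motion.summarize_track(
                    sig, fit_fraction=cfg.fit_fraction,
                    rg_first_n_frames=cfg.rg_truncation,
                    cell_id=cell.cell_id, max_lag=max_lag)
                params.append(p)
                track_rows.append(self._row(p, cell, sig.track_id))
                if compute_msd_curves:
                    msd_by_condition.setdefault(cell.condition, []).append(
                        _motion.compute_msd(sig))
            agg = params[0] if len(params) == 1 else _cohort.per_cell_median(params)
            cell_rows.append(self._row(agg, cell, None))

        track_params = pd.DataFrame(track_rows)
        cell_params = pd.DataFrame(cell_rows)

        comparisons = []
        if not cell_params.empty:
            labels = condition_order
            if self.control_label is not None and self.control_label in labels:
                labels = ([self.control_label]
                          + [l for l in labels if l != self.control_label])
            if len(labels) == 2:
                samples = {}
                for param in PARAMETER_ORDER:
                    col = _PARAM_COLUMNS[param]
                    samples[param] = {
                        lab: cell_params.loc[cell_params.condition == lab,
                                             col].to_numpy()
                        for lab in labels
                    }
                comparisons = _cohort.compare_conditions(
                    samples, family_size=cfg.family_size)

        msd_curves = {}
        for label, curves in msd_by_condition.items():
            lags, times, med, lo, hi, n, rel = _cohort.median_msd_curve(curves)
            msd_curves[label] = {"lags": lags, "times": times, "median": med,
                                 "ci_low": lo, "ci_high": hi,
                                 "n_curves": n, "reliable": rel}

        return MobilityResults(model=self, qc=qc, track_params=track_params,
                               cell_params=cell_params,
                               comparisons=comparisons, msd_curves=msd_curves)

    @staticmethod
    def _row(p, cell, track_id):
        row = {"cell_id": cell.cell_id, "track_id": track_id,
               "condition": cell.condition,
               "replication_state": cell.replication_state}
        for attr, col in _PARAM_COLUMNS.items():
            row[col] = getattr(p, attr)
        return row


@dataclass
class MobilityResults:
    """Fitted mobility analysis: tables, comparisons, MSD bands."""

    model: MobilityModel
    qc: object
    track_params: pd.DataFrame
    cell_params: pd.DataFrame
    comparisons: list
    msd_curves: dict

    def comparison_table(self) -> pd.DataFrame:
        return comparisons_to_frame(self.comparisons)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Chromatin mobility analysis",
            "=" * 64,
            f"experiment kind:    {cfg.kind}",
            f"frame interval:     {cfg.dt} s",
            f"fit fraction:       {cfg.fit_fraction:.2f}",
            f"comparison family:  {cfg.family_size}",
            f"tracks in / kept:   {self.qc.n_tracks_in} / {self.qc.n_tracks_kept}",
            f"cells analysed:     {self.cell_params['cell_id'].nunique() if not self.cell_params.empty else 0}",
            "",
        ]
        if self.comparisons:
            a, b = self.comparisons[0].label_a, self.comparisons[0].label_b
            lines.append(f"{'parameter':<30}{a:>12}{b:>12}{'fold':>8}{'p(adj)':>12}")
            lines.append("-" * 74)
            for r in self.comparisons:
                lines.append(
                    f"{PARAMETER_LABELS.get(r.parameter, r.parameter):<30}"
                    f"{r.median_a:>12.4g}{r.median_b:>12.4g}"
                    f"{r.median_fold_change:>8.3f}{r.p_adjusted:>12.3g}")
        else:
            for label, g in self.cell_params.groupby("condition"):
                lines.append(f"condition {label!r}: n = {g.shape[0]} cells")
        return "\n".join(lines)

    def save_tables(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.track_params.to_csv(outdir / "track_params.csv", index=False)
        self.cell_params.to_csv(outdir / "cell_params.csv", index=False)
        if self.comparisons:
            self.comparison_table().to_csv(outdir / "comparisons.csv",
                                           index=False)
        for label, c in self.msd_curves.items():
            pd.DataFrame({k: c[k] for k in ("lags", "times", "median",
                                            "ci_low", "ci_high", "n_curves")}
                         ).to_csv(outdir / f"msd_{label}.csv", index=False)

    def plot_msd(self, ax=None):
        """Median MSD per condition with its confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, c in self.msd_curves.items():
            ax.plot(c["times"], c["median"], label=label)
            ax.fill_between(c["times"], c["ci_low"], c["ci_high"], alpha=0.25)
        ax.set_xlabel("time lag (s)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.legend()
        return ax
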