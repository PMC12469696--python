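"""Cohort-level aggregation and nonparametric condition comparison.

The analysis unit is the cell: for focus experiments each nucleus
contributes the median of its (>= 5) track parameters, for locus
experiments each cell contributes its single retained track.  Condition
samples are compared with the two-sided Mann-Whitney U test and Holm's
step-down correction over an explicitly declared comparison family
(which may be larger than the number of tests run here, when the
experiment includes further contrasts).  Median MSD curves carry
distribution-free 95% confidence bands from binomial order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .motion import MSDCurve, MotionParams

__all__ = [
    "CohortSample",
    "ComparisonResult",
    "PARAMETER_ORDER",
    "per_cell_median",
    "median_msd_curve",
    "mann_whitney",
    "holm_adjust",
    "compare_conditions",
]

#: fixed reporting order of mobility parameters
PARAMETER_ORDER = ("alpha", "d_1s", "mean_displacement", "gyration_radius")

PARAMETER_LABELS = {
    "alpha": "Anomalous exponent",
    "d_1s": "Diffusion coefficient, um^2/s",
    "mean_displacement": "Mean displacement, um",
    "gyration_radius": "Gyration radius, um",
}


@dataclass
class CohortSample:
    """One condition's per-cell values for a named parameter."""

    label: str
    parameter: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 1:
            raise ValueError("sample must contain at least one cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class ComparisonResult:
    """Two-condition comparison of one mobility parameter."""

    parameter: str
    label_a: str
    label_b: str
    median_a: float
    median_b: float
    median_fold_change: float  # b / a (treated / control)
    u_statistic: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int
    family_size: int


def per_cell_median(cell_params: Sequence[MotionParams]) -> MotionParams:
    """Componentwise median of one cell's track parameters.

    Even sample sizes use the mean-of-central-order-statistics median.
    """
    if len(cell_params) == 0:
        raise ValueError("cell has no track parameters")
    med = lambda attr: float(np.median([getattr(p, attr) for p in cell_params]))
    first = cell_params[0]
    return MotionParams(
        alpha=med("alpha"), d_app=med("d_app"), d_1s=med("d_1s"),
        mean_displacement=med("mean_displacement"),
        gyration_radius=med("gyration_radius"),
        fit_fraction=first.fit_fraction, fit_r2=med("fit_r2"),
        track_id=None, cell_id=first.cell_id,
    )


def _median_ci_ranks(n: int, confidence: float = 0.95):
    """1-based order-statistic ranks (lo, hi) of a distribution-free
    median CI with coverage >= confidence, or None if unattainable."""
    alpha = 1.0 - confidence
    cdf = stats.binom.cdf(np.arange(n + 1), n, 0.5)
    ok = np.nonzero(cdf <= alpha / 2)[0]  # candidate values of l - 1
    if ok.size == 0:
        return None  # even (x_(1), x_(n)) cannot reach the coverage
    lo = int(ok[-1]) + 1
    hi = n + 1 - lo
    if hi < lo:
        return None
    return lo, hi


def median_msd_curve(curves: Sequence[MSDCurve], confidence: float = 0.95,
                     min_curves: int = 6, method: str = "order",
                     n_boot: int = 10_000, seed: int = 0):
    """Per-lag median MSD with a 95% confidence band.

    Curves may have unequal lengths; each lag is summarized over the
    curves that reach it.  ``method='order'`` (default) uses
    distribution-free binomial order statistics; ``method='bootstrap'``
    uses a seeded percentile bootstrap of the median with ``n_boot``
    resamples.  Returns (lags, times, median, ci_low, ci_high,
    n_curves, reliable); ``reliable`` is False where fewer than
    ``min_curves`` curves contribute or the band is undefined.
    """
    if len(curves) == 0:
        raise ValueError("no MSD curves given")
    if method not in ("order", "bootstrap"):
        raise ValueError("method must be 'order' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    dt = curves[0].dt
    if any(not np.isclose(c.dt, dt) for c in curves):
        raise ValueError("curves must share one frame interval")
    kmax = max(c.lags.size for c in curves)
    lags = np.arange(1, kmax + 1)
    median = np.full(kmax, np.nan)
    lo = np.full(kmax, np.nan)
    hi = np.full(kmax, np.nan)
    n_curves = np.zeros(kmax, dtype=np.int64)
    reliable = np.zeros(kmax, dtype=bool)
    for k in range(1, kmax + 1):
        vals = np.sort([c.values[k - 1] for c in curves if c.lags.size >= k])
        n = vals.size
        n_curves[k - 1] = n
        median[k - 1] = np.median(vals)
        if method == "bootstrap":
            if n >= 2:
                boots = np.median(
                    vals[rng.integers(0, n, size=(n_boot, n))], axis=1)
                alpha = 1.0 - confidence
                lo[k - 1], hi[k - 1] = np.quantile(
                    boots, [alpha / 2, 1 - alpha / 2])
                reliable[k - 1] = n >= min_curves
            continue
        ranks = _median_ci_ranks(n, confidence)
        if ranks is not None:
            lo[k - 1] = vals[ranks[0] - 1]
            hi[k - 1] = vals[ranks[1] - 1]
            reliable[k - 1] = n >= min_curves
    return lags, lags * dt, median, lo, hi, n_curves, reliable


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U test; returns (U_a, p).

    U is the rank-method statistic of the first sample (midranks for
    ties).  The p-value is exact for small untied samples
    (n_a + n_b <= 16) and otherwise uses the normal approximation with
    tie and continuity corrections.  Identical constant samples yield
    p = 1 with a warning.
    """
    a = np.asarray(getattr(a, "values", a), dtype=np.float64)
    b = np.asarray(getattr(b, "values", b), dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; degenerate test",
                      stacklevel=2)
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= 16
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: Iterable[float], family_size: int | None = None):
    """Holm step-down adjusted p-values, in input order.

    ``family_size`` m defaults to the number of p-values but may be
    declared larger when the experiment's comparison family includes
    tests not passed here; each adjusted value is
    max_{j <= i} min(1, (m - j + 1) * p_(j)) along the sorted order.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValueError("family_size must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(p.size)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def compare_conditions(samples, family_size: int,
                       parameters: Sequence[str] = PARAMETER_ORDER):
    """Compare two conditions for each mobility parameter.

    ``samples`` maps parameter name -> {condition label -> CohortSample
    or array}; exactly two conditions per parameter, the first taken as
    control (fold change = treated / control).  Raw Mann-Whitney
    p-values are Holm-adjusted over the declared ``family_size``.
    """
    tests = []
    for param in parameters:
        if param not in samples:
            raise ValueError(f"missing samples for parameter {param!r}")
        conds = samples[param]
        if len(conds) != 2:
            raise ValueError(f"parameter {param!r} needs exactly two conditions")
        (la, va), (lb, vb) = conds.items()
        va = np.asarray(getattr(va, "values", va), dtype=np.float64)
        vb = np.asarray(getattr(vb, "values", vb), dtype=np.float64)
        u, p = mann_whitney(va, vb)
        tests.append((param, la, lb, va, vb, u, p))
    if family_size < len(tests):
        raise ValueError("family_size must cover all tests")
    adj = holm_adjust([t[6] for t in tests], family_size)
    results = []
    for (param, la, lb, va, vb, u, p), pa in zip(tests, adj):
        ma, mb = float(np.median(va)), float(np.median(vb))
        results.append(ComparisonResult(
            parameter=param, label_a=la, label_b=lb,
            median_a=ma, median_b=mb,
            median_fold_change=mb / ma,
            u_statistic=u, p_raw=p, p_adjusted=float(pa),
            n_a=va.size, n_b=vb.size, family_size=family_size,
        ))
    return results
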