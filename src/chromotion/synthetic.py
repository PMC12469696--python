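"""Synthetic trajectory and image-stack generation with known ground truth.

The generator emulates live-cell single-particle tracking of chromatin
loci and repair foci: 2-D subdiffusive motion following the ensemble law

    MSD(t) = 4 * D_app * t**alpha,

realised as fractional Brownian motion (each axis an independent
fractional Gaussian process with Var[x(t) - x(0)] = 2 * D_app * t**alpha),
plus shared per-cell nucleus drift, static Gaussian localization error,
missing frames, optionally doubled (replicated) signal pairs, and
rendered fluorescence image stacks with photobleaching.

All emitted positions are quantized to a dyadic grid of 2**-20 μm
(~1 pm).  The grid is far below any physical scale in the problem and
makes drift injection followed by nucleus compensation an exact
floating-point round trip, so compensation correctness can be asserted
bit-for-bit.

fBm increments are sampled exactly by Cholesky factorization of the
fractional-Gaussian-noise covariance; the factor depends only on
(alpha, n_frames) and is cached, so cohorts of identically configured
tracks reuse one factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .detection import ImageStack
from .trajectories import CellRecord, Trajectory

__all__ = [
    "SimulationConfig",
    "ImageSimulationConfig",
    "DriftModel",
    "GroundTruth",
    "sample_fbm_track",
    "add_localization_noise",
    "add_drift",
    "introduce_gaps",
    "simulate_cohort",
    "render_image_stack",
]

#: dyadic position grid (μm); see module docstring
POSITION_QUANTUM = 2.0 ** -20


def _quantize(a: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(a, dtype=np.float64) / POSITION_QUANTUM) * POSITION_QUANTUM


@dataclass(frozen=True)
class DriftModel:
    """Nucleus drift specification shared by all signals of a cell."""

    kind: str = "none"              # none | linear | random_walk
    velocity: tuple = (0.0, 0.0)    # μm/s, linear drift
    step_sigma: float = 0.0         # μm per frame per axis, random walk

    @classmethod
    def none(cls) -> "DriftModel":
        return cls("none")

    @classmethod
    def linear(cls, vx: float, vy: float) -> "DriftModel":
        return cls("linear", velocity=(float(vx), float(vy)))

    @classmethod
    def random_walk(cls, step_sigma: float) -> "DriftModel":
        if step_sigma < 0:
            raise ValueError("step_sigma must be >= 0")
        return cls("random_walk", step_sigma=float(step_sigma))

    def realize(self, n_frames: int, dt: float,
                rng: np.random.Generator) -> np.ndarray:
        """Drift path (n_frames, 2) in μm, starting at the origin."""
        if self.kind == "none":
            return np.zeros((n_frames, 2))
        if self.kind == "linear":
            t = np.arange(n_frames)[:, None] * dt
            return _quantize(t * np.asarray(self.velocity))
        if self.kind == "random_walk":
            steps = rng.normal(0.0, self.step_sigma, size=(n_frames, 2))
            steps[0] = 0.0
            return _quantize(np.cumsum(steps, axis=0))
        raise ValueError(f"unknown drift kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Study-scale defaults for one condition's trajectory ensemble.

    Defaults reproduce a chromatin-locus acquisition: 189 frames at
    0.412 s with subdiffusive motion (alpha 0.27, D_app 0.0051 μm²/sᵅ —
    untreated-cell medians), ~20 nm static localization error, a slow
    random-walk nucleus drift, and sparse trackable gaps.
    """

    alpha: float = 0.27
    d_app: float = 0.0051          # μm²/s^alpha
    n_frames: int = 189
    dt: float = 0.412              # s
    loc_noise_sigma: float = 0.02  # μm per axis
    drift_model: DriftModel = field(default_factory=lambda: DriftModel.random_walk(0.01))
    gap_rate: float = 0.01
    max_gap_run: int = 5
    n_signals_per_cell: int = 1
    replicated_fraction: float = 0.0
    pair_distance: float = 0.5     # μm
    placement_radius: float = 0.0  # μm; spread of signal start positions
    min_separation: float = 0.8    # μm between start positions, if spread
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not self.d_app > 0:
            raise ValueError("d_app must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("gap_rate", "replicated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be >= 0")
        if self.n_signals_per_cell < 1:
            raise ValueError("n_signals_per_cell must be >= 1")


@dataclass
class GroundTruth:
    """Generating parameters and realizations for one emitted trajectory."""

    alpha: float
    d_app: float
    noise_sigma: float
    true_xy: np.ndarray            # drift-free, noise-free positions (μm)
    drift: np.ndarray              # shared cell drift path (μm)
    gap_mask: np.ndarray           # True where the frame was removed


@lru_cache(maxsize=64)
def _fgn_cholesky(alpha: float, n_increments: int) -> np.ndarray:
    """Cholesky factor of the unit fGn covariance for given alpha.

    The increment process of fBm with Var[x(t)-x(0)] = t**alpha has
    autocovariance gamma(k) = (|k+1|^a - 2|k|^a + |k-1|^a) / 2 in units
    of the one-step variance.
    """
    k = np.arange(n_increments, dtype=np.float64)
    gamma = 0.5 * (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha
                   + np.abs(k - 1) ** alpha)
    cov = gamma[np.abs(np.subtract.outer(k, k)).astype(np.int64)]
    return np.linalg.cholesky(cov)


def _fbm_displacements(alpha: float, d_app: float, n_frames: int, dt: float,
                       rng: np.random.Generator, n_tracks: int = 1) -> np.ndarray:
    """(n_tracks, n_frames, 2) fBm paths starting at the origin."""
    n_inc = n_frames - 1
    L = _fgn_cholesky(float(alpha), n_inc)
    scale = np.sqrt(2.0 * d_app * dt ** alpha)  # per-axis one-step std
    z = rng.standard_normal((n_tracks, n_inc, 2))
    incs = scale * np.einsum("ij,njk->nik", L, z)
    paths = np.zeros((n_tracks, n_frames, 2))
    np.cumsum(incs, axis=1, out=paths[:, 1:, :])
    return paths


def sample_fbm_track(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> Trajectory:
    """Draw one 2-D fBm trajectory at the configured (alpha, D_app).

    The ensemble satisfies MSD(t) = 4 * D_app * t**alpha exactly (each
    axis contributes 2 * D_app * t**alpha).  Deterministic for a given
    ``config.seed`` when no generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    path = _fbm_displacements(config.alpha, config.d_app, config.n_frames,
                              config.dt, rng)[0]
    xy = _quantize(path)
    frames = np.arange(config.n_frames)
    return Trajectory(frames, xy, np.ones(config.n_frames, bool), config.dt)


def add_localization_noise(traj: Trajectory, sigma: float,
                           rng: np.random.Generator | int | None = None) -> Trajectory:
    """Add independent zero-mean Gaussian localization error per frame."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = traj.copy()
    if sigma == 0:
        return out
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out.xy = _quantize(traj.xy + rng.normal(0.0, sigma, size=traj.xy.shape))
    return out


def add_drift(cell_trajs: Sequence[Trajectory], drift_model: DriftModel,
              rng: np.random.Generator | int | None = None,
              centroid_noise: float = 0.0):
    """Add one shared drift path to every signal of a cell.

    Returns the drifted signals and the nucleus trajectory, which is
    the drift path itself plus optional centroid-detection noise.  With
    ``centroid_noise=0`` nucleus compensation inverts this operation
    exactly (positions live on a dyadic grid).
    """
    if not cell_trajs:
        raise ValueError("need at least one trajectory")
    frames0 = cell_trajs[0].frames
    for t in cell_trajs[1:]:
        if not np.array_equal(t.frames, frames0):
            raise ValueError("all trajectories must share one frame grid")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = frames0.size
    drift = drift_model.realize(n, cell_trajs[0].dt, rng)
    out = []
    for t in cell_trajs:
        d = t.copy()
        d.xy = t.xy + drift  # exact: both operands on the dyadic grid
        out.append(d)
    nuc_xy = drift.copy()
    if centroid_noise > 0:
        nuc_xy = _quantize(nuc_xy + rng.normal(0.0, centroid_noise, size=nuc_xy.shape))
    nucleus = Trajectory(frames0, nuc_xy, np.ones(n, bool), cell_trajs[0].dt,
                         track_id="nucleus")
    return out, nucleus


def introduce_gaps(traj: Trajectory, gap_rate: float, max_gap_run: int,
                   rng: np.random.Generator | int | None = None) -> Trajectory:
    """Flag random interior frames as missing detections.

    Endpoints are never removed and no missing run exceeds
    ``max_gap_run`` (surplus frames of a too-long run are restored,
    earliest first).
    """
    if not (0.0 <= gap_rate < 1.0):
        raise ValueError("gap_rate must be in [0, 1)")
    out = traj.copy()
    if gap_rate == 0 or traj.n_frames <= 2:
        return out
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    missing = rng.random(traj.n_frames) < gap_rate
    missing[0] = missing[-1] = False
    # clip runs longer than max_gap_run
    run_start = None
    for i in range(traj.n_frames):
        if missing[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len > max_gap_run:
                missing[run_start:run_start + run_len - max_gap_run] = False
            run_start = None
    out.observed = ~missing
    out.xy = out.xy.copy()
    out.xy[missing] = np.nan
    return out


def _start_positions(config: SimulationConfig, n_signals: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Start positions spread in a disk of ``placement_radius`` with
    pairwise separation >= ``min_separation`` (all at the origin when
    the radius is zero, the single-locus case)."""
    if config.placement_radius <= 0 or n_signals == 1:
        return np.zeros((n_signals, 2))
    starts: list[np.ndarray] = []
    for _ in range(10_000):
        r = config.placement_radius * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        cand = np.array([r * np.cos(phi), r * np.sin(phi)])
        if all(np.linalg.norm(cand - s) >= config.min_separation
               for s in starts):
            starts.append(cand)
            if len(starts) == n_signals:
                return _quantize(np.array(starts))
    raise ValueError("could not place signals with the requested separation")


def _simulate_cell(config: SimulationConfig, cell_id, condition: str,
                   replicated: bool, seed: np.random.SeedSequence,
                   signal_kind: str = "locus",
                   centroid_noise: float = 0.01) -> CellRecord:
    rng = np.random.default_rng(seed)
    n_signals = config.n_signals_per_cell * (2 if replicated else 1)
    starts = _start_positions(config, n_signals, rng)
    base = []
    for j in range(n_signals):
        t = sample_fbm_track(config, rng)
        t.xy = t.xy + starts[j]  # exact: both on the dyadic grid
        if replicated and j % 2 == 1:
            # second member of a replicated pair starts pair_distance away
            t.xy = t.xy + _quantize(np.array([config.pair_distance, 0.0]))
        t.track_id = f"{cell_id}-s{j}"
        base.append(t)
    drifted, nucleus = add_drift(base, config.drift_model, rng,
                                 centroid_noise=centroid_noise)
    signals, gts = [], {}
    for t, clean in zip(drifted, base):
        noised = add_localization_noise(t, config.loc_noise_sigma, rng)
        gapped = introduce_gaps(noised, config.gap_rate, config.max_gap_run, rng)
        signals.append(gapped)
        gts[t.track_id] = GroundTruth(
            alpha=config.alpha, d_app=config.d_app,
            noise_sigma=config.loc_noise_sigma,
            true_xy=clean.xy, drift=nucleus.xy,
            gap_mask=~gapped.observed,
        )
    return CellRecord(cell_id=cell_id, condition=condition, nucleus=nucleus,
                      signals=signals,
                      replication_state="replicated" if replicated else "unreplicated",
                      signal_kind=signal_kind, ground_truth=gts)


def simulate_cohort(config_a: SimulationConfig, config_b: SimulationConfig,
                    n_cells_a: int, n_cells_b: int, seed: int,
                    condition_a: str = "control", condition_b: str = "treated",
                    signal_kind: str = "locus",
                    nucleus_centroid_noise: float = 0.01):
    """Simulate two labelled cohorts with per-cell deterministic seeding.

    Every cell's randomness flows from a child of the master seed, so a
    cohort is reproducible and independent of generation order.
    """
    if n_cells_a < 1 or n_cells_b < 1:
        raise ValueError("cohorts need at least one cell each")
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_cells_a + n_cells_b)
    cohorts = []
    offset = 0
    for cfg, n_cells, label, prefix in ((config_a, n_cells_a, condition_a, "a"),
                                        (config_b, n_cells_b, condition_b, "b")):
        cells = []
        for i in range(n_cells):
            ss = seeds[offset + i]
            replicated = (np.random.default_rng(ss.spawn(1)[0]).random()
                          < cfg.replicated_fraction)
            cells.append(_simulate_cell(cfg, f"{prefix}{i:03d}", label,
                                        replicated, ss, signal_kind,
                                        nucleus_centroid_noise))
        cohorts.append(cells)
        offset += n_cells
    return tuple(cohorts)


@dataclass
class ImageSimulationConfig:
    """Rendering parameters for synthetic fluorescence stacks.

    Defaults follow a confocal locus acquisition: 103 nm pixels, a
    ~200 nm Gaussian spot, and mild per-frame photobleaching.
    """

    pixel_size: float = 0.103      # μm / pixel
    image_shape: tuple = (128, 128)
    psf_sigma: float = 0.2         # μm
    spot_photons: float = 1000.0   # expected photons per spot per frame
    background: float = 10.0       # counts / pixel
    bleach_rate: float = 0.997     # per-frame intensity decay factor
    nucleus_radius: float = 4.5    # μm
    nucleus_intensity: float = 20.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not (0.0 < self.bleach_rate <= 1.0):
            raise ValueError("bleach_rate must be in (0, 1]")


def render_image_stack(cell: CellRecord, img_config: ImageSimulationConfig,
                       rng: np.random.Generator | int | None = None,
                       poisson_noise: bool = True) -> ImageStack:
    """Render a cell as a time-lapse: nucleus disk + Gaussian spots.

    Frame m has expected intensity (background + nucleus disk + spots)
    scaled by ``bleach_rate**m``, with Poisson photon noise.  The μm
    origin is chosen so the nucleus mean position maps to the image
    centre; it is stored as ``origin_um`` on the returned stack so
    detections can be compared with lab-frame ground truth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = img_config
    h, w = cfg.image_shape
    px = cfg.pixel_size
    n_frames = cell.nucleus.n_frames
    centre_um = np.array([(w - 1) / 2 * px, (h - 1) / 2 * px])
    origin = cell.nucleus.xy.mean(axis=0) - centre_um  # lab μm of pixel grid origin

    yy, xx = np.mgrid[0:h, 0:w]
    xum = xx * px
    yum = yy * px
    sig2 = cfg.psf_sigma ** 2
    amp = cfg.spot_photons / (2 * np.pi * sig2 / px ** 2)  # peak counts/pixel

    frames = np.empty((n_frames, h, w), dtype=np.float64)
    for m in range(n_frames):
        nx, ny = cell.nucleus.xy[m] - origin
        disk = ((xum - nx) ** 2 + (yum - ny) ** 2) <= cfg.nucleus_radius ** 2
        expected = cfg.background + cfg.nucleus_intensity * disk
        for sig in cell.signals:
            pos = sig.xy[sig.frames == m]
            if pos.size == 0 or not np.all(np.isfinite(pos)):
                continue
            sx, sy = pos[0] - origin
            if not (0 <= sx <= (w - 1) * px and 0 <= sy <= (h - 1) * px):
                raise ValueError(
                    f"spot at ({sx:.2f}, {sy:.2f}) μm outside image at frame {m}"
                )
            expected = expected + amp * np.exp(
                -((xum - sx) ** 2 + (yum - sy) ** 2) / (2 * sig2))
        expected *= cfg.bleach_rate ** m
        frames[m] = rng.poisson(expected) if poisson_noise else expected
    return ImageStack(frames=frames, pixel_size=px, dt=cell.nucleus.dt,
                      origin_um=tuple(origin))
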