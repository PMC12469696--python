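"""Spot and nucleus detection on fluorescence time-lapse stacks.

Two detection styles are provided, matching common live-cell workflows:

* locus detection — difference-of-Gaussians (DoG) band-pass filtering
  with sub-pixel localization by quadratic interpolation of the filter
  response around each local maximum;
* focus detection — DoG filtering, automatic intermeans (isodata)
  thresholding, and centroid extraction of connected mask components,
  with an area-based quality cut.

Bleach correction remaps every frame's intensity histogram onto the
first frame's by monotone quantile mapping.  The nucleus is tracked as
the centroid of the largest above-threshold component per frame.

Coordinate convention: pixel centres sit at integer coordinates with
the origin at the corner pixel centre; x runs along columns, y along
rows; positions are reported in μm as pixel * pixel_size.  All
convolutions use reflective boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms

__all__ = [
    "ImageStack",
    "SpotDetection",
    "bleach_correct_histogram_match",
    "difference_of_gaussians",
    "auto_threshold_isodata",
    "extract_mask_spots",
    "detect_dog_spots",
    "count_local_maxima",
    "track_nucleus",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class ImageStack:
    """T x H x W grayscale time-lapse with physical calibration."""

    frames: np.ndarray
    pixel_size: float  # μm / pixel
    dt: float          # s / frame
    origin_um: tuple = (0.0, 0.0)  # lab-frame μm of pixel (0, 0) centre

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty T x H x W array")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class SpotDetection:
    """One localized spot in one frame (positions in μm)."""

    frame: int
    x: float
    y: float
    quality: float
    area: int | None = None  # pixels, mask detections only


def bleach_correct_histogram_match(stack: ImageStack) -> ImageStack:
    """Remap each frame's histogram onto frame 0's (bleach correction).

    Monotone empirical quantile mapping; frame 0 is unchanged.  After
    correction all frames share frame 0's intensity distribution up to
    quantization, removing the global intensity decay of bleaching.
    """
    ref = stack.frames[0]
    out = np.empty_like(stack.frames)
    out[0] = ref
    for m in range(1, stack.n_frames):
        out[m] = match_histograms(stack.frames[m], ref)
    return ImageStack(out, stack.pixel_size, stack.dt, stack.origin_um)


def difference_of_gaussians(frame: np.ndarray, sigma_small: float,
                            sigma_large: float) -> np.ndarray:
    """Band-pass DoG response G(σs)*I - G(σl)*I, clipped at zero."""
    if not sigma_small < sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    frame = np.asarray(frame, dtype=np.float64)
    lo = ndimage.gaussian_filter(frame, sigma_small, mode="reflect")
    hi = ndimage.gaussian_filter(frame, sigma_large, mode="reflect")
    return np.clip(lo - hi, 0.0, None)


def auto_threshold_isodata(frame: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 500) -> np.ndarray:
    """Binarize by the iterated-intermeans (isodata) threshold.

    Iterates t <- (mean of values <= t + mean of values > t) / 2 from
    the global mean until convergence; the mask is ``frame > t``.
    Raises on constant input, where no threshold separates anything.
    """
    frame = np.asarray(frame, dtype=np.float64)
    vals = frame.ravel()
    if np.unique(vals).size < 2:
        raise ValueError("constant image: isodata threshold undefined")
    t = vals.mean()
    for _ in range(max_iter):
        below = vals[vals <= t]
        above = vals[vals > t]
        if above.size == 0:  # t at or above max; step back inside the range
            t = vals[vals < vals.max()].mean()
            continue
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) <= tol:
            t = t_new
            break
        t = t_new
    return frame > t


def extract_mask_spots(mask: np.ndarray, min_quality: float,
                       pixel_size: float = 1.0,
                       frame: int = 0) -> list[SpotDetection]:
    """Centroids of 8-connected mask components above a size cut.

    Quality is the component pixel area, so a fractional ``min_quality``
    like 3.9 acts as an at-least-4-pixels rule.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    spots = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        area = ys.size
        if area < min_quality:
            continue
        spots.append(SpotDetection(
            frame=frame,
            x=float(xs.mean() * pixel_size),
            y=float(ys.mean() * pixel_size),
            quality=float(area),
            area=int(area),
        ))
    spots.sort(key=lambda s: (s.x, s.y))
    return spots


def dog_sigmas_from_radius(radius_px: float) -> tuple[float, float]:
    """Map a spot radius (pixels) to the DoG σ pair used for detection."""
    sigma_small = radius_px / (1.0 + np.sqrt(2.0))
    return sigma_small, np.sqrt(2.0) * sigma_small


def detect_dog_spots(frame: np.ndarray, radius: float,
                     quality_threshold: float, pixel_size: float = 1.0,
                     frame_index: int = 0) -> list[SpotDetection]:
    """DoG spot detection with sub-pixel quadratic localization.

    ``radius`` is the expected spot radius in μm; the DoG σ pair is
    σ_small = radius_px / (1 + √2), σ_large = √2 σ_small.  Local maxima
    of the filtered image above ``quality_threshold`` are refined by a
    separable quadratic fit to the 3 x 3 neighbourhood; quality is the
    filter response at the maximum.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    radius_px = radius / pixel_size
    if radius_px < 1.0:
        raise ValueError("radius must be at least one pixel")
    resp = difference_of_gaussians(np.asarray(frame, dtype=np.float64),
                                   *dog_sigmas_from_radius(radius_px))
    footprint = ndimage.maximum_filter(resp, size=3, mode="reflect")
    peaks = (resp == footprint) & (resp > quality_threshold)
    peaks[0, :] = peaks[-1, :] = peaks[:, 0] = peaks[:, -1] = False
    # a plateau maximum spans several pixels; keep one centre per plateau
    labels, n_peaks = ndimage.label(peaks, structure=_EIGHT_CONNECTED)
    reps = []
    for lab in range(1, n_peaks + 1):
        ys, xs = np.nonzero(labels == lab)
        reps.append((int(round(ys.mean())), int(round(xs.mean()))))
    spots = []
    for y, x in reps:
        c = resp[y, x]
        dx = _parabolic_offset(resp[y, x - 1], c, resp[y, x + 1])
        dy = _parabolic_offset(resp[y - 1, x], c, resp[y + 1, x])
        spots.append(SpotDetection(
            frame=frame_index,
            x=float((x + dx) * pixel_size),
            y=float((y + dy) * pixel_size),
            quality=float(c),
        ))
    spots.sort(key=lambda s: (s.x, s.y))
    return spots


def _parabolic_offset(left: float, centre: float, right: float) -> float:
    denom = left - 2.0 * centre + right
    if denom >= 0:  # flat or non-concave; no refinement
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def count_local_maxima(frame: np.ndarray, prominence: float) -> int:
    """Count local maxima with topographic prominence above a cutoff.

    A maximum's prominence is its height above the highest saddle that
    connects it to higher terrain; the global maximum's prominence is
    the full image range.  Computed by union-find over pixels in
    descending intensity order (persistence of superlevel-set
    components), with 8-connectivity.  Equal-height maxima whose
    connecting saddle lies within the prominence cutoff merge into one
    count (flood-merge semantics; the plateau earlier in row-major
    order survives).
    """
    if not prominence > 0:
        raise ValueError("prominence must be positive")
    img = np.asarray(frame, dtype=np.float64)
    h, w = img.shape
    flat = img.ravel()
    order = np.argsort(-flat, kind="stable")
    parent = np.full(flat.size, -1, dtype=np.int64)  # -1: not yet processed
    peak_height: dict[int, float] = {}
    count = 0

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for idx in order:
        y, x = divmod(int(idx), w)
        neigh_roots = set()
        for dy2 in (-1, 0, 1):
            for dx2 in (-1, 0, 1):
                if dy2 == 0 and dx2 == 0:
                    continue
                ny, nx = y + dy2, x + dx2
                if 0 <= ny < h and 0 <= nx < w and parent[ny * w + nx] != -1:
                    neigh_roots.add(find(ny * w + nx))
        parent[idx] = idx
        if not neigh_roots:
            peak_height[int(idx)] = float(flat[idx])
            continue
        roots = sorted(neigh_roots, key=lambda r: (-peak_height[r], r))
        main = roots[0]
        for r in roots[1:]:
            # component r dies at the current level (saddle)
            if peak_height[r] - flat[idx] > prominence:
                count += 1
            parent[r] = main
            del peak_height[r]
        parent[idx] = main
    # surviving components: prominence is height above the global minimum
    lo = float(flat.min())
    for r, hgt in peak_height.items():
        if hgt - lo > prominence:
            count += 1
    return count


def track_nucleus(stack: ImageStack, intensity_threshold: float):
    """Centroid trajectory of the largest above-threshold component.

    Returns a gap-free :class:`~chromotion.trajectories.Trajectory` in
    μm; raises naming the frame if any frame has no pixel above the
    threshold.
    """
    from .trajectories import Trajectory  # local import: avoid cycle

    n = stack.n_frames
    xy = np.empty((n, 2))
    for m in range(n):
        mask = stack.frames[m] > intensity_threshold
        labels, nlab = ndimage.label(mask, structure=_EIGHT_CONNECTED)
        if nlab == 0:
            raise ValueError(f"no region above threshold in frame {m}")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, nlab + 1))
        largest = int(np.argmax(sizes)) + 1
        ys, xs = np.nonzero(labels == largest)
        xy[m] = (xs.mean() * stack.pixel_size, ys.mean() * stack.pixel_size)
    return Trajectory(np.arange(n), xy, np.ones(n, bool), stack.dt,
                      track_id="nucleus")
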