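# Methods

## Scope and pipeline

`chromotion` quantifies the mobility of sub-diffraction fluorescent
signals (a tagged chromatin locus, DNA-repair foci) inside moving cell
nuclei from 2-D time-lapse data. The pipeline is

1. **detection** — per-frame spot localization on image stacks;
2. **linking** — assembly of detections into trajectories with gap
   closing;
3. **preparation** — conversion of signal coordinates into the
   nucleus-centre frame, linear interpolation of missing frames,
   quality control;
4. **motion statistics** — per-track time-averaged MSD,
   anomalous-diffusion fit, D(1 s), mean displacement, gyration radius;
5. **cohort statistics** — per-cell aggregation, median MSD curves with
   confidence bands, Mann–Whitney comparisons with Holm correction.

Track tables (CSV) can enter at stage 3, so exports of external
tracking software bypass the imaging front-end. The
`MobilityModel`/`MobilityResults` pair wraps stages 3–5 in a fit/results
interface; `run_pipeline` and the CLI bind all stages together.

## Motion model and estimators

Each axis of a trajectory is modelled as fractional Brownian motion:
a zero-mean Gaussian process with stationary, negatively correlated
increments and Var[x(t) − x(0)] = 2·D_app·t^α, so the 2-D ensemble obeys
MSD(t) = 4·D_app·t^α. The time-averaged MSD of a track with frames
m = 0..n (n the last zero-based frame index) is

MSD(kΔt) = (1/(n−k+1)) Σ_{m=0}^{n−k} |p((m+k)Δt) − p(mΔt)|², k = 1..n.

(α, D_app) are estimated by ordinary least squares of log MSD on
log t over the leading `floor(fit_fraction · n_lags)` lags starting at
k = 1. The fit fraction is 0.20 for 189-frame locus acquisitions
(lags 1..37) and 0.30 for 122-frame focus acquisitions (lags 1..36),
which covers the same absolute time-lag range in both designs. The
log-log OLS is exact on noiseless power laws and deterministic; a
nonlinear least-squares alternative would weight lags differently but
requires initialization and is not used. Zero MSD values in the window
(possible for a numerically frozen track) are excluded with a warning;
fewer than 3 usable points is an error.

Because D_app carries μm²/sᵅ, tracks with different α are compared via
D(t) = D_app·t^(α−1) evaluated at t = 1 s, where the value equals D_app
numerically and has units μm²/s.

Mean displacement is the arithmetic mean of consecutive-frame Euclidean
steps. The gyration radius is the RMS distance of positions from the
trajectory centroid; an optional truncation to the first N frames (122
by convention) puts acquisitions of different duration on equal
footing. Interpolated points participate in all statistics exactly
like observed ones, since QC guarantees they are few (≤ 5 per track).

## Preparation and quality control

Nucleus compensation is translation-only: position(m) − nucleus(m),
with an error naming the frame if the nucleus track lacks it. Whether
nuclear rotation should also be removed is an open question of the
workflow this reimplements; rotation is not compensated here.

Gap interpolation is per-axis linear between nearest observed
neighbours; tracks must start and end on a detection (the tracker
guarantees this), and observed positions are preserved bit-exactly.

QC rules (defaults, per experiment kind):

* locus — track must span ≥ 180 frames (gaps count toward the span,
  consistent with a 189-frame acquisition carrying ≤ 5 interpolated
  points), carry ≤ 5 missing frames, and each cell contributes exactly
  one signal. Selection among several surviving signals is
  deterministic — lowest track id among the longest — rather than
  random; a seeded random mode is available. Determinism was preferred
  so identical inputs give identical cohorts.
* focus — track must carry ≥ 110 observed points and ≤ 5 missing
  frames; a nucleus enters the cohort only with ≥ 5 valid tracks, and
  contributes the per-parameter median of its tracks.

Both filters are idempotent and report every rejection with a reason.

## Cohort statistics

The analysis unit is the cell. Condition samples are compared with the
two-sided Mann–Whitney U test: the U statistic uses midranks; the
p-value is the exact permutation distribution for untied samples with
n_a + n_b ≤ 16 and otherwise a normal approximation with tie and
continuity corrections (scipy's implementation serves as backend; the
test suite checks it against an independent full enumeration). Two
identical constant samples yield p = 1 with a warning.

Holm's step-down adjustment is computed in-package because the declared
comparison family (8 for a locus experiment, 16 for the locus-vs-foci
table) can exceed the number of tests actually run here — the
experiment's remaining contrasts belong to the same family, so the
first factor must be m = family_size, not the local test count.

Median MSD curves carry distribution-free 95% confidence bands from
binomial order statistics: the band at each lag is (x(l), x(n+1−l))
with l the largest rank satisfying P(Bin(n, ½) ≤ l−1) ≤ 0.025. Fewer
than 6 curves cannot reach 95% coverage and are flagged unreliable.
The even-n sample median is the mean of the two central order
statistics.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes, at the studied scales: Δt = 0.412 s; 189-frame locus and
122-frame focus acquisitions; α ≈ 0.17–0.32 and D_app ≈
0.0019–0.0072 μm²/sᵅ (cohort medians of the studied conditions);
shared per-cell nucleus drift (random walk, 0.01 μm/frame/axis by
default); static Gaussian localization error (default 0.02 μm per
axis — the imaging's true localization error is not published, so this
is a typical confocal value, exposed as a free parameter, not an
estimate of the experiment); missing frames with bounded run length
and protected endpoints; doubled signal pairs for replicated loci;
optional rendering to image stacks (103 nm/pixel, Gaussian PSF spots,
nucleus disk, Poisson noise, geometric per-frame bleaching).

fBm is sampled exactly by Cholesky factorization of the
fractional-Gaussian-noise covariance. The factor depends only on
(α, n) and is cached, so cohorts reuse one factorization; track lengths
here (≤ 256 frames) make the exact method cheap, and it avoids the
spectral leakage of approximate FFT samplers.

All generator outputs are quantized to a dyadic grid of 2⁻²⁰ μm
(~1 pm). The grid is ~4 orders of magnitude below the localization
noise and has no physical effect; it makes drift injection followed by
nucleus compensation an exact floating-point round trip, so
compensation correctness is asserted bit-for-bit rather than to a
tolerance.

Not emulated: confined/corralled diffusion (motion is pure fBm, so
plateauing MSD curves are out of scope), 3-D motion and defocus, camera
gain/EMCCD noise, signal blinking beyond random missing frames, and
nuclear rotation or deformation. Passing recovery tests therefore
demonstrates correctness of the estimators under the model's
assumptions — not robustness to every artefact of real microscopy.
For focus-style renders the nucleus fluorescence can be set flat
(`nucleus_intensity=0`), emulating the common preprocessing step of
filling everything outside the nucleus with the background level
before thresholding.

## Detection and linking

* Bleach correction: monotone empirical quantile mapping of each
  frame's histogram onto frame 0's (scikit-image `match_histograms`).
* Locus detection: DoG band-pass with σ_small = radius_px/(1+√2),
  σ_large = √2·σ_small — a fixed, documented mapping from the specified
  spot radius (0.6 μm) to σ values; local maxima above a per-image
  quality threshold; sub-pixel refinement by separable quadratic fit to
  the 3×3 neighbourhood (offsets clamped to ±0.5 px); plateau maxima
  contribute one detection. Detection thresholds are per-image inputs,
  as in the interactive workflow, because signal brightness varies
  between cells.
* Focus detection: DoG with σ = 2/4 px, intermeans (isodata)
  auto-threshold iterated on the pixel values from the global mean,
  8-connected components, centroid extraction. Component "quality" is
  its pixel area, so the conventional cut of 3.9 acts as an
  at-least-4-pixels rule — area is the only size-like score a binary
  mask offers.
* Maxima counting: topographic prominence via union-find persistence
  over descending pixel order; equal-height maxima merge at their
  connecting saddle (flood-merge semantics).
* Linking: exact minimum-cost one-to-one assignment
  (`linear_sum_assignment`) on squared distance per consecutive frame
  pair, links beyond the gate forbidden; gap closing matches tracklet
  ends to later starts under frame-gap and distance gates, cost again
  squared distance with no frame-gap penalty (the simplest
  deterministic choice consistent with the stated gates). Track ids
  are assigned by (first frame, x, y). Exact equivalence with any
  specific interactive tracker is not claimed — internal penalty terms
  of such tools are not documented.
* All convolutions use reflective boundaries (no spurious edge
  responses on small synthetic frames); pixel centres sit at integer
  coordinates, origin at the corner pixel centre, positions in μm are
  pixel × pixel_size.

## Validation problem sizes

The test suite validates at these scales, chosen to exercise the study
conditions while keeping a full run in tens of seconds: parameter
recovery on 200-track noise-free ensembles (189 frames); familywise
error on 200 null replicate experiments of 40 cells/arm; power on 100
replicate experiments at the replicated-chromatin effect sizes
(α 0.23 vs 0.31, D 0.0046 vs 0.0072 μm²/s); detection metrics on six
rendered 189-frame locus stacks and three 122-frame seven-focus stacks
at 128×128 px. `scripts/acceptance.py` re-runs the same computations
from scratch under a caller-supplied seed.

## Known limitations

* The power-law fit window convention (lags starting at k = 1, `floor`
  of the fraction) pins an off-by-one that interactive workflows leave
  unstated; both conventions differ by at most one lag.
* Static localization error biases the short-lag fit — D_app upward and
  α downward (a directionality the test suite asserts on simulation);
  no MSD-offset correction term is fitted, matching the reimplemented
  workflow.
* Median-MSD confidence bands use order statistics by default;
  notch-style or bootstrap intervals would differ slightly. A seeded
  percentile bootstrap (10⁴ resamples) is selectable via
  `median_msd_curve(..., method="bootstrap")`.
* No splitting/merging in linking, no Kalman prediction, no 3-D.
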