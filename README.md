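# chromotion

Live-cell chromatin mobility analysis for single-particle tracking
experiments: from time-lapse spot data (or rendered synthetic image
stacks) through trajectory building, nucleus-motion compensation,
MSD-based anomalous-diffusion quantification, and nonparametric
comparison of mobility parameters between experimental conditions —
e.g. a fluorescently tagged genomic locus, or DNA-repair foci, in
control versus perturbed cells.

## Who this is for

Groups tracking sub-diffraction fluorescent signals (CRISPR-based locus
tags, repair-factor foci) in nuclei over seconds-to-minutes time-lapses
who want a reproducible, scriptable version of the common
Fiji/TrackMate-style workflow: difference-of-Gaussians spot detection,
LAP-style linking with gap closing, per-cell quality control, and
cohort statistics — with a synthetic-data generator that provides
ground truth for validating every stage.

## The model

Each trajectory p(mΔt), m = 0..n, is summarized by its time-averaged
mean square displacement

    MSD(kΔt) = 1/(n−k+1) · Σ_{m=0}^{n−k} |p((m+k)Δt) − p(mΔt)|² ,

and the leading portion of the curve is fitted with the anomalous
diffusion law

    MSD(t) = 4 · D_app · t^α ,

giving the anomalous exponent α (α < 1: subdiffusion) and the
generalized diffusion coefficient D_app (μm²/sᵅ). Because D_app's unit
depends on α, it is reported on a fixed time scale via
D(t) = D_app · t^(α−1); at t = 1 s, D(1 s) equals D_app numerically and
carries μm²/s. The mean displacement per frame and the gyration radius
R_g (RMS distance of positions from the trajectory centroid, a measure
of confinement) complete the parameter set. Conditions are compared
per cell with the two-sided Mann–Whitney U test and Holm's step-down
correction over the experiment's declared comparison family, reporting
the fold change of sample medians.

Synthetic trajectories are fractional Brownian motion sampled exactly
(Cholesky factorization of the increment covariance), so the generated
ensemble obeys MSD(t) = 4·D_app·t^α by construction — the generator is
the ground truth against which parameter recovery is tested.

## Worked example

```python
from chromotion import (SimulationConfig, simulate_cohort,
                        MobilityModel, PipelineConfig)

# two-condition cohort at the studied cohort-median scales
cfg_ctrl = SimulationConfig(alpha=0.23, d_app=0.0046, seed=0)
cfg_aux  = SimulationConfig(alpha=0.31, d_app=0.0072, seed=0)
control, treated = simulate_cohort(cfg_ctrl, cfg_aux, 40, 40, seed=7)

model = MobilityModel(control + treated, PipelineConfig(kind="locus"),
                      control_label="control")
results = model.fit()
print(results.summary())
```

```
Chromatin mobility analysis
================================================================
experiment kind:    locus
frame interval:     0.412 s
fit fraction:       0.20
comparison family:  8
tracks in / kept:   80 / 80
cells analysed:     80

parameter                          control     treated    fold      p(adj)
--------------------------------------------------------------------------
Anomalous exponent                  0.1944      0.2812   1.447    1.78e-08
Diffusion coefficient, um^2/s     0.005053     0.00759   1.502    1.15e-13
Mean displacement, um               0.1141      0.1367   1.199    1.15e-13
Gyration radius, um                  0.133      0.1952   1.468    1.45e-13
```

Each row compares the per-cell parameter between the two cohorts: the
medians, the fold change of the medians (treated/control), and the
Mann–Whitney p-value Holm-adjusted over the declared family of 8
comparisons. The fitted α values sit below the generating ones because
static localization noise (20 nm per axis, on by default in the
generator) flattens the short-lag MSD — the same bias real tracking
data carries. `results.track_params`, `results.cell_params` and
`results.msd_curves` hold the per-track table, per-cell table and
median MSD curves with distribution-free 95% confidence bands;
`results.plot_msd()` draws them.

The same analysis is available from the shell:

```
chromotion simulate --n-cells 40 --seed 7 --out tracks.csv
chromotion run tracks.csv --kind locus --seed 7 --outdir results/
```

plus `detect`, `link`, `prep`, `motion` and `compare` subcommands for
stage-by-stage runs, including TIFF stacks through the DoG / mask
detection front-ends.

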