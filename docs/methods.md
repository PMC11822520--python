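# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `sersquant`, in the spirit of a methods appendix.

## The measurement model the generator emulates

A raster-scanned SERS map of a dried plasma/nanoparticle well is modeled
per spectrum as

    I(w) = f * B(w) + A * S(w) + e(w)

* `B(w)` — a deterministic plasma background: a sum of broad Gaussian
  humps plus one narrow Gaussian at 807 cm^-1 representing a
  glutathione-like interferent that partially overlaps the 792 cm^-1
  analysis window.  `f` is a per-spectrum lognormal scaling factor with
  mean 1 and relative sd `background_variability` (default 0.2),
  emulating matrix heterogeneity across the dried surface.
* `S(w)` — the unit analyte signature: Lorentzian bands at 792 cm^-1
  (ring breathing, height 1), 1586 cm^-1 (NH2 bending, 0.45) and
  1672 cm^-1 (C=C/C=N/C=O stretching, 0.30).
* `A` — the hotspot amplitude: zero with probability `1 - pi`
  (`hotspot_fraction`, default 0.35), otherwise drawn from an exponential
  law with mean

      mu(c) = beta * log10(c / c_ref),  clipped at 0

  with `beta = amplitude_scale` (default 10 counts per decade) and
  `c_ref = 39 ng/mL` (one twofold step below the lowest standard, so every
  standard has positive mean).  An optional clipped-normal mixture
  component (`exponential_plus_normal`) represents the pseudo-normal
  population that interfering species with similar surface affinity can
  contribute; its weight/mean/sd are exposed but default to an inactive
  role (the default law is purely exponential).  A third law, `constant`,
  draws no randomness and returns `mu(c)` exactly; it exists for
  ground-truth parameter-recovery tests.
* `e(w)` — i.i.d. Gaussian detector noise, sd 8 counts.

The linear-in-log10(c) mean ties the generator's ground truth to the
response-vs-log(concentration) form of all three calibration methods, so
noise-free recovery tests have closed-form expectations.

Default geometry is the study's: 42 x 43 raster (1806 spectra/well),
8 x 5 plate, seven twofold standards 5000 -> 78 ng/mL (integer-truncated)
plus a matrix blank, five replicate wells per sample.  Blank wells carry
the full background, interferent and noise — only the analyte term is
absent.

**Parameter rationale.**  The acquisition axis (400-1800 cm^-1 at
1 cm^-1) and band shapes (Lorentzian lines on Gaussian humps) are
conventional Raman choices.  `pi = 0.35` encodes that the majority of map
spectra carry little or no analyte signal.  `beta = 10` with noise sd 8
puts single-hotspot-spectrum S/N at ~2.6 for the top standard — a
weak-signal regime in which the three methods differentiate the way the
method comparison reports: the top-20 selection inflates the Q_i-sample
slope by roughly the order-statistics factor `ln(pi*N/k)+1` over the
total-population slope (which is damped by `pi`), while the CDF response
lives on a log10(Q_i) axis and its slope is nearly independent of `beta`.
The default regime was verified over many seeds, and is a *model
calibration* to the qualitative regime of the underlying study, not a fit
to its instrument numbers.  `background_variability = 0.2` is what makes
raw-intensity CDFs visibly worse than Q_i CDFs: baseline subtraction in
Q_i cancels the common-mode background, raw 792 cm^-1 intensities do not.

**What the generator does not emulate** (so what passing tests do not
show about real data): spatial correlation of hotspots and drying-ring
("coffee-ring") structure — amplitudes are i.i.d. per spectrum; detector
artifacts (cosmic rays, baseline drift within a scan); wavenumber
calibration error; nonlinear adsorption isotherms (response saturation at
high concentration); and any chemistry of the plasma pretreatment.

## Quality index

`Q_i` averages intensities over the grid point nearest each configured
position and `n = 2` neighbors per side (windows clipped at axis edges;
nearest-point ties break toward the lower wavenumber).  For each peak the
mean of the two baseline windows is subtracted; with `t` peaks the
factors combine as a geometric mean, and any nonpositive factor clips the
index to 0, which keeps the multi-peak combination well-defined without
fractional powers of negative numbers.  The study conditions only
exercise `t = 1` (792 vs 723 cm^-1), where the index reduces to the
baseline-subtracted peak window mean clipped at zero.  The half-window
`n` is not fixed by the method definition; 2 grid points (a 5-point
window at 1 cm^-1 spacing) is narrow enough to stay on the 792 band top.

## CDF calibration

Per well, the nonzero `Q_i` values are sorted ascending; point `i` of `m`
gets probability `i/m` (ties keep duplicate x at distinct probabilities,
preserving the index arithmetic; the last probability is exactly 1) and
`x = log10(Q_i)`.  Pooling all replicates of a concentration before the
same sort/index/divide yields the model CDF.  A degree-4 polynomial
`x = f(p)` is least-squares fitted to the points with `p` in [0.6, 0.9]
and evaluated at 500 evenly spaced probabilities in that band; the
response is the sum over those matched points of the difference against
the blank's fitted model CDF.  Design choices:

* *Blank-referenced differences.*  The pointwise differences are taken
  against the blank model CDF as common reference; any
  adjacent-concentration reading telescopes to the same quantity up to
  grouping, and the blank reference makes the response a monotone
  stochastic-dominance measure.
* *log10 throughout* (concentration and Q_i axes).
* *Positive shift.*  All calibration points (model and replicate) are
  increased by |smallest point|, making the minimum exactly 0; intervals,
  slope and R^2 are unaffected.
* *Model values are regressed*; replicate (per-well) values are reported
  as scatter and feed the RSD tables.
* The raw-intensity variant applies the same positive-value filter to
  uncorrected I(792) values; it exists to quantify what the baseline
  subtraction buys.

The truncated 0.6-0.9 band concentrates the fit on the informative upper
quantiles: at the default hotspot fraction the lower probability mass is
background/noise-dominated and nearly concentration-independent.

## Replicate aggregation and comparison tables

Slopes and R^2 are averaged across experiments.  Replicate responses are
averaged *position-wise* across experiments (well r of each experiment
maps to pooled value r), keeping five values per concentration, before
RSD = sample std (n-1) / mean; S/N is its exact reciprocal (an RSD of 0
reports infinite S/N).  The "mean divided by std" wording sometimes seen
for RSD is inconsistent with defining S/N as its reciprocal; the standard
std/mean definition is used.

## LOQ validation

The PCA inputs are the spectra each calibration method would average:
per-well means (total population) or per-well top-20-by-Q_i means
(Q_i sample), five per class per experiment.  Preprocessing truncates to
585.48-1710.01 cm^-1 and removes the background by IarPLS.

**IarPLS.**  Whittaker smoother with second-difference penalty `lam`
(default 1e5), solved sparsely; weights follow an asymmetric logistic
rule on residuals `d = y - z` scaled by the standard deviation `s` of the
negative residuals, `w = 1 / (1 + exp(t (d - 2s) / s))` with the
iteration index `t` sharpening the transition.  Iteration stops when the
relative change of the weight vector drops below 1e-3 (default), when the
negative-residual scale falls to solver-noise level (1e-9 of the data
scale — this makes peak-free inputs converge to themselves immediately),
or at 50 iterations, in which case the result is flagged unconverged
rather than raised.  Defaults recover a smooth synthetic baseline under
narrow peaks to ~0.15% of the tallest peak height.

**PCA and ellipses.**  Mean-centered PCA (scikit-learn, full SVD), two
components; each component is oriented so its largest-magnitude loading
is positive, making score signs reproducible.  PCA is refused only for
zero-variance input; rank-1 data legitimately yields explained-variance
ratios [1, 0].  Each class's 95% ellipse is centered on the class mean
with shape `cov * chi2_{2,0.95}`; overlap is decided geometrically
(360-point boundary sampling against the other ellipse's open interior,
plus mutual center containment), matching the visual criterion of a score
plot rather than a hypothesis test.  Tangent ellipses count as disjoint.

## Pipeline and determinism

Experiment `i` of a run uses seed `base_seed + i`; within a plate each
well draws from an independent child of one `numpy` `SeedSequence`, so
streaming and whole-plate generation are bit-identical and reruns of the
pipeline produce byte-identical reports (no timestamps in outputs).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run full-geometry plates
(1806 spectra/well, 72,240/plate) for geometry counts, noise-free
recovery, blank-subtraction invariance and the LOQ contrast; the
stochastic method-ranking check uses three full replicate experiments.
Unit and property tests use a reduced 6 x 7 raster with three standards,
which exercises every code path at a fraction of the cost.

## Known limitations

* The Sigma DeltaQCDF response is not exactly linear in log10(c) under
  the generator's ground truth (log of an affine function of mu(c)); its
  R^2 is high but structurally below 1 on multi-point series, consistent
  with the CDF method's slightly lower linearity in practice.
* Ellipse overlap from five points per class is a coarse criterion; it is
  a reproduction of figure-style practice, not inference.
* The comparison tables use the default generator regime; absolute
  slopes/RSDs are in synthetic units and are not comparable to any
  instrument's.
* No LOD/LOQ formula (3-sigma/10-sigma) is provided; the LOQ claim is the
  PCA separation criterion only.
* PLS/MLR calibration and spectral deconvolution of the 792/807 cm^-1
  overlap are out of scope.
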