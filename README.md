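# sersquant

Statistical quantification of spatially resolved SERS (surface-enhanced
Raman spectroscopy) spectral maps, built around the problem of monitoring
an antiretroviral drug (emtricitabine, FTC) in pretreated human blood
plasma dried onto a multi-well substrate.

SERS enhancement on a dried, nanoparticle-aggregated surface is dominated
by sparse "hotspots": when a well is raster-scanned (42 lines x 43
positions = 1806 spectra per well, 72,240 per 8 x 5 plate), most spectra
carry little or no analyte signal while a few are very intense, and the
per-spectrum analyte intensity is approximately exponentially distributed.
Conventional practice — averaging every spectrum of a surface and reading
one peak intensity — throws this structure away.  `sersquant` implements
and compares three calibration strategies that treat the map as a
statistical population, plus the machinery to validate the limit of
quantification (LOQ).  It is aimed at analytical-spectroscopy researchers
who want a tested, reproducible reference implementation of these methods,
with a synthetic-data generator standing in for instrument data.

## Methods implemented

**Quality index.** Every spectrum gets a figure of merit

    Q_i = [ prod_k ( mean(I, p_k +/- n) - ( mean(I, b1_k +/- n) + mean(I, b2_k +/- n) ) / 2 ) ]^(1/t)

the baseline-subtracted mean intensity about each analysis peak, combined
geometrically over the t peaks and clipped at zero.  Defaults: one peak,
p = 792 cm^-1 (FTC ring-breathing band), b1 = b2 = 723 cm^-1 (the adjacent
trough), n = 2 grid points.  Q_i is invariant to constant offsets and, for
t = 1, scales linearly with the spectrum.

**Three calibration methods** regress a response on log10(concentration):

* *total population*: average all 1806 spectra of a well; the response is
  I(792) - I(723) of the well-mean spectrum.
* *Q_i sample*: average only each well's top-20 spectra ranked by Q_i,
  then take the same intensity difference.
* *CDF*: build the empirical cumulative distribution of each well's (and
  each concentration's pooled) nonzero Q_i values on a log10(Q_i) axis,
  fit a 4th-order polynomial x = f(probability) on the 0.6-0.9 probability
  band, and use

      Sigma DeltaQCDF_n = sum over 500 matched probability points of ( x_n(p) - x_blank(p) )

  as the response, with the matrix blank's pooled CDF as the common
  reference; all calibration points are then shifted up by the absolute
  value of the smallest point.

**Method comparison** averages slopes and R^2 over replicate experiments
and tabulates the per-concentration relative standard deviation
(RSD = sample std / mean of replicate responses) and its reciprocal,
reported as S/N.

**LOQ validation** takes the spectra each averaging method would use,
truncates them to 585.48-1710.01 cm^-1, removes the background with an
IarPLS (improved asymmetrically reweighted penalized least squares)
Whittaker smoother, runs mean-centered PCA, and asks whether the 95%
confidence ellipses of the matrix blank and the lowest concentration
overlap in the first two score dimensions.

A synthetic plate generator (`sersquant.synthetic`) provides the study
conditions: twofold standards 5000 -> 78 ng/mL plus a matrix blank, five
replicate wells each, exponential hotspot amplitudes whose mean is linear
in log10(concentration), Lorentzian FTC bands at 792/1586/1672 cm^-1, a
congested plasma background including an interfering band at 807 cm^-1,
and additive detector noise.  See `docs/methods.md` for the model details
and parameter rationale.

## Worked example

```python
import sersquant as sq

cfg = sq.GeneratorConfig(rng_seed=1)
plate = sq.generate_plate(sq.make_default_design(cfg), cfg)

for build in (sq.total_population_curve, sq.qi_sample_curve, sq.cdf_curve):
    curve = build(plate)
    print(f"{curve.method:>16}: slope={curve.slope:7.2f}  R^2={curve.r_squared:.3f}")

strong = sq.GeneratorConfig(amplitude_scale=20.0, rng_seed=1)
plate2 = sq.generate_plate(sq.make_default_design(strong), strong)
for method in ("qi", "total"):
    loq = sq.validate_loq(plate2, method=method)
    verdict = "overlap" if loq.overlap else "disjoint"
    print(f"LOQ check ({method:>5}): blank vs {loq.analyte_label} ellipsoids {verdict}")
```

prints

```
total_population: slope=   3.32  R^2=0.995
       qi_sample: slope=  43.67  R^2=0.990
             cdf: slope=  54.77  R^2=0.995
LOQ check (   qi): blank vs 78 ng/mL ellipsoids disjoint
LOQ check (total): blank vs 78 ng/mL ellipsoids overlap
```

The slope is the analytical sensitivity of each method.  Ranking every
spectrum by Q_i and averaging only the hotspot-rich top 20 multiplies the
sensitivity of plain population averaging by an order of magnitude, and
the CDF method — which uses *all* informative spectra without diluting
them in zeros — is more sensitive still.  At a stronger signal setting the
LOQ check shows the practical consequence near the detection limit: the
Q_i-sampled inputs separate a 78 ng/mL sample from the matrix blank while
population averages do not.

The same workflow is available from the shell:

```sh
sersquant generate --out plate/ --seed 1
sersquant calibrate --plate plate/manifest.yaml --method all --out curves/
sersquant validate-loq --plate plate/manifest.yaml --method qi --out loq/
sersquant run --out run/            # 3 replicate experiments end to end
```

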