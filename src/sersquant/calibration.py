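"""Calibration-curve construction for spectral-map plates.

Three quantification strategies are implemented, all regressing a response
against log10(concentration, ng/mL) over the non-blank samples:

* **total population** — average all spectra of a well, take the intensity
  difference I(792) - I(723) cm^-1 of the well-mean spectrum, regress the
  per-concentration replicate means.
* **Q_i sample** — rank every spectrum of a well by its quality index,
  average only the top-k (default 20) spectra, then proceed as above.
* **CDF** — build the empirical distribution of the nonzero Q_i values of
  each well / pooled concentration, fit a 4th-order polynomial to
  log10(Q_i) as a function of cumulative probability on the 0.6-0.9 band,
  and use the summed pointwise difference against the blank's fitted model
  CDF over 500 matched probability points (the Sigma-DeltaQCDF response).
  All calibration points are then shifted up by the absolute value of the
  smallest point, and the model (pooled) values are regressed.

A raw-intensity CDF variant (building the distribution from I(792) instead
of Q_i) is provided for contrast: without the baseline subtraction the
congested background dominates the distribution and degrades calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    CdfFitError,
    ConsistencyError,
    EmptyCdfError,
    RegressionError,
)
from .quality import QiConfig, compute_qi_map
from .spectra import Plate, SpectralMap, Spectrum, nearest_index

__all__ = [
    "EmpiricalCdf",
    "CdfPolyFit",
    "CalibrationCurve",
    "mean_spectrum",
    "peak_response",
    "peak_intensity_values",
    "linear_regression",
    "total_population_curve",
    "select_top_k_by_qi",
    "qi_sample_curve",
    "build_cdf",
    "build_model_cdf",
    "fit_cdf_poly",
    "sigma_delta_qcdf",
    "cdf_curve",
    "blank_subtract",
    "blank_mean_spectrum",
]

PEAK_CM = 792.0
TROUGH_CM = 723.0
CDF_PROB_RANGE = (0.6, 0.9)
CDF_FIT_POINTS = 500
CDF_POLY_DEGREE = 4


# ---------------------------------------------------------------------------
# elementary spectral operations


def mean_spectrum(source: SpectralMap | Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean spectrum of a map or a list of spectra."""
    if isinstance(source, SpectralMap):
        if source.n_spectra == 0:
            raise ValueError("cannot average an empty map")
        return Spectrum(source.wavenumbers, source.intensities.mean(axis=0))
    spectra = list(source)
    if not spectra:
        raise ValueError("cannot average an empty spectrum collection")
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, axis):
            raise ConsistencyError("spectra do not share a wavenumber axis")
    return Spectrum(axis, np.mean([s.intensities for s in spectra], axis=0))


def pooled_mean_spectrum(maps: Iterable[SpectralMap]) -> Spectrum:
    """Spectrum-count-weighted mean over all spectra of several maps."""
    total = None
    count = 0
    axis = None
    for m in maps:
        if axis is None:
            axis = m.wavenumbers
            total = np.zeros(axis.size)
        elif not np.array_equal(m.wavenumbers, axis):
            raise ConsistencyError("maps do not share a wavenumber axis")
        total += m.intensities.sum(axis=0)
        count += m.n_spectra
    if count == 0:
        raise ValueError("cannot average an empty map collection")
    return Spectrum(axis, total / count)


def peak_response(
    spectrum: Spectrum, peak: float = PEAK_CM, trough: float = TROUGH_CM
) -> float:
    """Intensity difference I(peak) - I(trough) at the nearest grid points."""
    w = spectrum.wavenumbers
    return float(
        spectrum.intensities[nearest_index(w, peak)]
        - spectrum.intensities[nearest_index(w, trough)]
    )


def peak_intensity_values(smap: SpectralMap, center: float = PEAK_CM) -> np.ndarray:
    """Raw intensity of every spectrum at the grid point nearest ``center``."""
    return smap.intensities[:, nearest_index(smap.wavenumbers, center)].copy()


def linear_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, R^2).

    R^2 is the squared Pearson correlation.  A constant response is fitted
    with slope 0 and R^2 0 by convention; a constant abscissa raises
    :class:`RegressionError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise RegressionError("at least two points are required")
    if np.ptp(x) == 0:
        raise RegressionError("abscissa is constant; regression undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# calibration curves


@dataclass
class CalibrationCurve:
    """One calibration experiment for one quantification method.

    ``replicate_responses`` has shape (n_concentrations, n_replicates), in
    descending concentration order; ``regression_responses`` holds the
    per-concentration values actually fitted (replicate means for the
    averaging methods, pooled model-CDF values for the CDF method), after
    the positive shift where applicable.
    """

    method: str
    concentrations: np.ndarray
    replicate_responses: np.ndarray
    regression_responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    shift_offset: float = 0.0

    @property
    def mean_responses(self) -> np.ndarray:
        return self.replicate_responses.mean(axis=1)

    @property
    def log_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)


def _nonblank_responses(
    plate: Plate, well_response
) -> tuple[np.ndarray, np.ndarray]:
    """(concentrations, per-well responses) over non-blank samples."""
    samples = plate.design.nonblank_samples
    if len(samples) < 2:
        raise RegressionError("need at least two non-blank concentrations")
    concentrations = np.array([s.concentration for s in samples])
    responses = np.array(
        [
            [well_response(plate.maps[w]) for w in plate.design.wells_for(s.index)]
            for s in samples
        ]
    )
    return concentrations, responses


def _finish_curve(
    method: str, concentrations: np.ndarray, replicate_responses: np.ndarray
) -> CalibrationCurve:
    regression_responses = replicate_responses.mean(axis=1)
    slope, intercept, r2 = linear_regression(
        np.log10(concentrations), regression_responses
    )
    return CalibrationCurve(
        method=method,
        concentrations=concentrations,
        replicate_responses=replicate_responses,
        regression_responses=regression_responses,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )


def total_population_curve(
    plate: Plate, peak: float = PEAK_CM, trough: float = TROUGH_CM
) -> CalibrationCurve:
    """Calibration by averaging every spectrum of each well."""
    def well_response(smap: SpectralMap) -> float:
        return peak_response(mean_spectrum(smap), peak, trough)

    concentrations, responses = _nonblank_responses(plate, well_response)
    return _finish_curve("total_population", concentrations, responses)


def select_top_k_by_qi(
    smap: SpectralMap, qi_values: np.ndarray, k: int
) -> SpectralMap:
    """The k spectra with the largest Q_i; ties keep earlier raster order."""
    qi_values = np.asarray(qi_values, dtype=float)
    if qi_values.shape != (smap.n_spectra,):
        raise ValueError("qi_values must have one entry per spectrum")
    if k <= 0:
        raise ValueError("k must be positive")
    if k > smap.n_spectra:
        raise ValueError(f"k={k} exceeds spectrum count {smap.n_spectra}")
    order = np.argsort(-qi_values, kind="stable")[:k]
    return smap.subset(order)


def qi_sample_curve(
    plate: Plate,
    qi_config: QiConfig = QiConfig(),
    k: int = 20,
    peak: float = PEAK_CM,
    trough: float = TROUGH_CM,
) -> CalibrationCurve:
    """Calibration from the mean of each well's top-k Q_i spectra."""
    def well_response(smap: SpectralMap) -> float:
        qi = compute_qi_map(smap, qi_config)
        top = select_top_k_by_qi(smap, qi, k)
        return peak_response(mean_spectrum(top), peak, trough)

    concentrations, responses = _nonblank_responses(plate, well_response)
    return _finish_curve("qi_sample", concentrations, responses)


# ---------------------------------------------------------------------------
# empirical CDFs and the Sigma-DeltaQCDF response


@dataclass(frozen=True)
class EmpiricalCdf:
    """Sorted log10 values vs cumulative probability i/m.

    Ties are kept as duplicate x with distinct probabilities, preserving the
    index arithmetic; the last probability is exactly 1.
    """

    x: np.ndarray
    probabilities: np.ndarray
    source: str = ""
    metric: str = "qi"

    @property
    def n(self) -> int:
        return self.x.size


def build_cdf(
    values: np.ndarray, metric: str = "qi", source: str = ""
) -> EmpiricalCdf:
    """Empirical CDF of the positive values (zeros/negatives are discarded).

    Sorted ascending; the i-th point (1-based) has probability i/m and
    x = log10(value).
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise EmptyCdfError(f"no positive {metric} values to build a CDF from")
    v = np.sort(v)
    m = v.size
    return EmpiricalCdf(
        x=np.log10(v),
        probabilities=np.arange(1, m + 1) / m,
        source=source,
        metric=metric,
    )


def build_model_cdf(
    replicate_value_sets: Sequence[np.ndarray],
    metric: str = "qi",
    source: str = "model",
) -> EmpiricalCdf:
    """Pooled CDF over all replicates of a concentration (single array)."""
    if len(replicate_value_sets) == 0:
        raise EmptyCdfError("no replicate value sets given")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in replicate_value_sets])
    return build_cdf(pooled, metric=metric, source=source)


@dataclass(frozen=True)
class CdfPolyFit:
    """Degree-4 polynomial x = f(probability) over the 0.6-0.9 band.

    ``probabilities`` are the 500 evenly spaced fit points and ``fitted_x``
    the polynomial evaluated there.
    """

    coefficients: np.polynomial.Polynomial
    prob_range: tuple[float, float]
    probabilities: np.ndarray
    fitted_x: np.ndarray


def fit_cdf_poly(
    cdf: EmpiricalCdf,
    prob_range: tuple[float, float] = CDF_PROB_RANGE,
    degree: int = CDF_POLY_DEGREE,
    n_points: int = CDF_FIT_POINTS,
) -> CdfPolyFit:
    """Least-squares polynomial fit to the in-range CDF points."""
    lo, hi = prob_range
    mask = (cdf.probabilities >= lo) & (cdf.probabilities <= hi)
    if int(mask.sum()) < degree + 1:
        raise CdfFitError(
            f"only {int(mask.sum())} CDF points in probability range "
            f"[{lo}, {hi}]; need at least {degree + 1}"
        )
    poly = np.polynomial.Polynomial.fit(
        cdf.probabilities[mask], cdf.x[mask], deg=degree
    )
    grid = np.linspace(lo, hi, n_points)
    return CdfPolyFit(
        coefficients=poly,
        prob_range=prob_range,
        probabilities=grid,
        fitted_x=poly(grid),
    )


def sigma_delta_qcdf(fit_n: CdfPolyFit, fit_ref: CdfPolyFit) -> float:
    """Sum over matched probability points of x_n(p) - x_ref(p)."""
    if fit_n.probabilities.shape != fit_ref.probabilities.shape or not np.allclose(
        fit_n.probabilities, fit_ref.probabilities
    ):
        raise ValueError("fits do not share the same probability grid")
    return float(np.sum(fit_n.fitted_x - fit_ref.fitted_x))


def _well_cdf_values(
    smap: SpectralMap, qi_config: QiConfig, metric: str
) -> np.ndarray:
    if metric == "qi":
        return compute_qi_map(smap, qi_config)
    if metric == "raw_intensity":
        return peak_intensity_values(smap)
    raise ValueError(f"unknown CDF metric {metric!r}")


def cdf_curve(
    plate: Plate,
    qi_config: QiConfig = QiConfig(),
    metric: str = "qi",
) -> CalibrationCurve:
    """Calibration from Sigma-DeltaQCDF against the blank model CDF.

    Per concentration, the pooled (model) CDF of all replicates and each
    replicate well's own CDF are fitted on the 0.6-0.9 probability band and
    differenced against the blank's fitted model CDF over the 500 matched
    probability points.  All calibration points (model and replicate) are
    then increased by the absolute value of the smallest point, and the
    shifted model values are regressed on log10(concentration).
    """
    design = plate.design
    blank = design.blank_sample
    if blank is None:
        raise ValueError("CDF method requires a blank sample as reference")
    samples = design.nonblank_samples
    if len(samples) < 2:
        raise RegressionError("need at least two non-blank concentrations")

    blank_values = [
        _well_cdf_values(plate.maps[w], qi_config, metric)
        for w in design.wells_for(blank.index)
    ]
    ref_fit = fit_cdf_poly(build_model_cdf(blank_values, metric=metric, source="blank"))

    concentrations = np.array([s.concentration for s in samples])
    model_values = np.empty(len(samples))
    replicate_values = np.empty((len(samples), design.replicate_wells_per_sample))
    for i, sample in enumerate(samples):
        wells = design.wells_for(sample.index)
        value_sets = [
            _well_cdf_values(plate.maps[w], qi_config, metric) for w in wells
        ]
        model_fit = fit_cdf_poly(
            build_model_cdf(value_sets, metric=metric, source=sample.label)
        )
        model_values[i] = sigma_delta_qcdf(model_fit, ref_fit)
        for j, values in enumerate(value_sets):
            rep_fit = fit_cdf_poly(build_cdf(values, metric=metric, source=wells[j]))
            replicate_values[i, j] = sigma_delta_qcdf(rep_fit, ref_fit)

    offset = abs(float(min(model_values.min(), replicate_values.min())))
    model_values = model_values + offset
    replicate_values = replicate_values + offset

    slope, intercept, r2 = linear_regression(np.log10(concentrations), model_values)
    return CalibrationCurve(
        method="cdf" if metric == "qi" else f"cdf_{metric}",
        concentrations=concentrations,
        replicate_responses=replicate_values,
        regression_responses=model_values,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        shift_offset=offset,
    )


# ---------------------------------------------------------------------------
# curve serialization (CSV with metadata comment lines)


def write_curve_csv(curve: CalibrationCurve, path) -> None:
    """Persist a calibration curve as CSV with ``#``-prefixed metadata."""
    import pandas as pd

    n_rep = curve.replicate_responses.shape[1]
    frame = pd.DataFrame(
        curve.replicate_responses,
        columns=[f"rep_{j + 1}" for j in range(n_rep)],
    )
    frame.insert(0, "concentration_ng_mL", curve.concentrations)
    frame["regression_response"] = curve.regression_responses
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={curve.method}\n")
        fh.write(f"# slope={curve.slope!r}\n")
        fh.write(f"# intercept={curve.intercept!r}\n")
        fh.write(f"# r_squared={curve.r_squared!r}\n")
        fh.write(f"# shift_offset={curve.shift_offset!r}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_curve_csv(path) -> CalibrationCurve:
    """Read a curve written by :func:`write_curve_csv`."""
    import pandas as pd

    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        frame = pd.read_csv(fh, float_precision="round_trip")
    rep_cols = [c for c in frame.columns if c.startswith("rep_")]
    return CalibrationCurve(
        method=meta.get("method", "unknown"),
        concentrations=frame["concentration_ng_mL"].to_numpy(),
        replicate_responses=frame[rep_cols].to_numpy(),
        regression_responses=frame["regression_response"].to_numpy(),
        slope=float(meta["slope"]),
        intercept=float(meta["intercept"]),
        r_squared=float(meta["r_squared"]),
        shift_offset=float(meta.get("shift_offset", "0.0")),
    )


# ---------------------------------------------------------------------------
# blank subtraction


def blank_mean_spectrum(plate: Plate) -> Spectrum:
    """Pooled mean spectrum over every spectrum of the blank wells."""
    blank = plate.design.blank_sample
    if blank is None:
        raise ValueError("plate has no blank sample")
    return pooled_mean_spectrum(plate.maps_for(blank.index))


def blank_subtract(plate: Plate, reference: Spectrum | None = None) -> Plate:
    """Subtract the pooled blank mean spectrum from every spectrum.

    Returns a new plate; the blank wells themselves are subtracted too.
    """
    ref = reference if reference is not None else blank_mean_spectrum(plate)
    new_maps = {}
    for well_id, smap in plate.maps.items():
        if not np.array_equal(smap.wavenumbers, ref.wavenumbers):
            raise ConsistencyError("reference spectrum axis does not match maps")
        new_maps[well_id] = SpectralMap(
            well_id,
            smap.wavenumbers,
            smap.intensities - ref.intensities[None, :],
            smap.coordinates,
        )
    return Plate(design=plate.design, maps=new_maps)
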