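"""Synthetic SERS spectral-map generator.

Emulates the statistical structure of spatially resolved SERS maps of a
drug analyte (emtricitabine, FTC) dried from pretreated human plasma onto a
multi-well plate:

* a raster scan per well (default 42 lines x 43 positions = 1806 spectra),
* a twofold concentration series (5000 -> 78 ng/mL) plus a matrix blank,
  each deposited in five replicate wells of an 8 x 5 plate,
* sparse "hotspot" enhancement: each spectrum independently carries analyte
  signal with probability ``hotspot_fraction``, with an amplitude drawn from
  an exponential law (optionally mixed with a clipped normal component)
  whose mean is linear in log10(concentration),
* an FTC signature of Lorentzian bands at 792 / 1586 / 1672 cm^-1 riding on
  a congested plasma background of broad Gaussian humps, including a
  glutathione-like interferent band at 807 cm^-1 that leaks into the 792
  cm^-1 analysis window,
* additive white Gaussian detector noise.

The generator is fully deterministic under a fixed ``rng_seed``: each well
draws from an independent child of one :class:`numpy.random.SeedSequence`,
so streaming well-by-well generation and whole-plate generation produce
bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import CapacityError, ConfigurationError
from .spectra import Plate, PlateDesign, Sample, SpectralMap, Spectrum, well_name

__all__ = [
    "GeneratorConfig",
    "twofold_series",
    "wavenumber_axis",
    "background_profile",
    "analyte_signature",
    "mean_amplitude",
    "sample_analyte_amplitude",
    "generate_spectrum",
    "generate_map",
    "make_default_design",
    "generate_plate",
    "iter_well_maps",
]

AMPLITUDE_LAWS = ("exponential", "exponential_plus_normal", "constant")


def twofold_series(top: float = 5000.0, count: int = 7) -> tuple[float, ...]:
    """Twofold dilution series from ``top``, truncated to integers.

    ``twofold_series(5000, 7)`` ends at 78 ng/mL (5000 / 2^6 = 78.125 -> 78),
    matching how serial-dilution standards are conventionally reported.
    """
    return tuple(float(int(top / 2**n)) for n in range(count))


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic plate generator.

    Units: wavenumbers in cm^-1, intensities in detector counts,
    concentrations in ng/mL.  ``amplitude_scale`` is the mean hotspot
    amplitude gained per decade of concentration above
    ``reference_concentration``; the mean amplitude at concentration c is
    ``max(0, amplitude_scale * log10(c / reference_concentration))`` so the
    generator's ground-truth response is linear in log10(c).
    """

    wavenumber_start: float = 400.0
    wavenumber_end: float = 1800.0
    wavenumber_step: float = 1.0
    raster_lines: int = 42
    raster_per_line: int = 43
    concentrations: tuple[float, ...] = field(default_factory=twofold_series)
    replicate_wells_per_sample: int = 5
    hotspot_fraction: float = 0.35
    amplitude_law: str = "exponential"
    amplitude_scale: float = 10.0
    reference_concentration: float = 39.0
    normal_weight: float = 0.25
    normal_mean: float = 25.0
    normal_sd: float = 8.0
    # (center cm^-1, width, height); Gaussian humps emulating the plasma
    # background, plus a narrow interferent band at 807 cm^-1
    background_bands: tuple[tuple[float, float, float], ...] = (
        (670.0, 110.0, 90.0),
        (990.0, 200.0, 110.0),
        (807.0, 10.0, 45.0),
        (1330.0, 130.0, 60.0),
        (1450.0, 90.0, 40.0),
        (1600.0, 70.0, 35.0),
    )
    # (center cm^-1, half-width, relative height); Lorentzian FTC signature
    analyte_bands: tuple[tuple[float, float, float], ...] = (
        (792.0, 5.0, 1.0),
        (1586.0, 6.0, 0.45),
        (1672.0, 6.0, 0.30),
    )
    noise_sd: float = 8.0
    # relative spectrum-to-spectrum variability of the whole plasma
    # background (lognormal scaling factor with mean 1); emulates matrix
    # heterogeneity across the dried well surface
    background_variability: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.wavenumber_start < self.wavenumber_end:
            raise ConfigurationError("wavenumber_start must be < wavenumber_end")
        if self.wavenumber_step <= 0:
            raise ConfigurationError("wavenumber_step must be positive")
        if self.raster_lines < 1 or self.raster_per_line < 1:
            raise ConfigurationError("raster dimensions must be positive")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ConfigurationError("hotspot_fraction must lie in [0, 1]")
        if self.amplitude_scale < 0:
            raise ConfigurationError("amplitude_scale must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.background_variability < 0:
            raise ConfigurationError("background_variability must be nonnegative")
        if self.reference_concentration <= 0:
            raise ConfigurationError("reference_concentration must be positive")
        if self.amplitude_law not in AMPLITUDE_LAWS:
            raise ConfigurationError(
                f"unknown amplitude law {self.amplitude_law!r}; "
                f"expected one of {AMPLITUDE_LAWS}"
            )
        if not 0.0 <= self.normal_weight <= 1.0:
            raise ConfigurationError("normal_weight must lie in [0, 1]")
        if self.normal_sd < 0:
            raise ConfigurationError("normal_sd must be nonnegative")
        if self.replicate_wells_per_sample < 1:
            raise ConfigurationError("replicate_wells_per_sample must be >= 1")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0) or (c.size > 1 and np.any(np.diff(c) >= 0)):
            raise ConfigurationError(
                "concentrations must be strictly decreasing and positive"
            )
        for bands, shape in ((self.background_bands, "background"),
                             (self.analyte_bands, "analyte")):
            for center, width, height in bands:
                if width <= 0:
                    raise ConfigurationError(f"{shape} band width must be positive")


def wavenumber_axis(config: GeneratorConfig) -> np.ndarray:
    """The shared acquisition axis implied by the config (end inclusive)."""
    n = int(np.floor(
        (config.wavenumber_end - config.wavenumber_start) / config.wavenumber_step
    )) + 1
    return config.wavenumber_start + config.wavenumber_step * np.arange(n)


def _gaussian(w: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((w - center) / width) ** 2)


def _lorentzian(w: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height / (1.0 + ((w - center) / width) ** 2)


def background_profile(w: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Deterministic plasma background (broad humps + 807 cm^-1 interferent)."""
    y = np.zeros_like(w, dtype=float)
    for center, width, height in config.background_bands:
        y += _gaussian(w, center, width, height)
    return y


def analyte_signature(w: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Unit-amplitude analyte signature (Lorentzian FTC bands)."""
    y = np.zeros_like(w, dtype=float)
    for center, width, height in config.analyte_bands:
        y += _lorentzian(w, center, width, height)
    return y


def mean_amplitude(concentration: float, config: GeneratorConfig) -> float:
    """Ground-truth mean hotspot amplitude mu(c), linear in log10(c)."""
    if concentration <= 0:
        return 0.0
    return max(
        0.0,
        config.amplitude_scale
        * np.log10(concentration / config.reference_concentration),
    )


def _sample_amplitudes(
    concentration: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    size: int,
) -> np.ndarray:
    mu = mean_amplitude(concentration, config)
    hot = rng.random(size) < config.hotspot_fraction
    amps = np.zeros(size)
    k = int(hot.sum())
    if mu > 0 and k > 0:
        if config.amplitude_law == "exponential":
            draws = rng.exponential(mu, k)
        elif config.amplitude_law == "exponential_plus_normal":
            draws = rng.exponential(mu, k)
            from_normal = rng.random(k) < config.normal_weight
            m = int(from_normal.sum())
            if m:
                draws[from_normal] = np.clip(
                    rng.normal(config.normal_mean, config.normal_sd, m), 0.0, None
                )
        else:  # constant
            draws = np.full(k, mu)
        amps[hot] = draws
    return amps


def sample_analyte_amplitude(
    concentration: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> float:
    """Draw one per-spectrum analyte amplitude.

    Returns 0 with probability ``1 - hotspot_fraction`` (a miss off any
    hotspot), and 0 always for the blank (concentration 0); otherwise a
    draw from the configured amplitude law with mean ``mean_amplitude``.
    """
    if concentration < 0:
        raise ConfigurationError("concentration must be nonnegative")
    return float(_sample_amplitudes(concentration, config, rng, 1)[0])


def _background_factors(
    config: GeneratorConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Per-spectrum lognormal background scaling with mean exactly 1."""
    cv = config.background_variability
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def generate_spectrum(
    concentration: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """One synthetic spectrum: background + amplitude * signature + noise."""
    w = wavenumber_axis(config)
    amp = sample_analyte_amplitude(concentration, config, rng)
    factor = _background_factors(config, rng, 1)[0]
    y = factor * background_profile(w, config) + amp * analyte_signature(w, config)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, w.size)
    return Spectrum(w, y)


def _raster_coordinates(config: GeneratorConfig) -> np.ndarray:
    lines = np.repeat(np.arange(config.raster_lines), config.raster_per_line)
    pos = np.tile(np.arange(config.raster_per_line), config.raster_lines)
    return np.column_stack([lines, pos])


def generate_map(
    well_id: str,
    concentration: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> SpectralMap:
    """Synthesize the full raster map of one well (vectorized)."""
    w = wavenumber_axis(config)
    n = config.raster_lines * config.raster_per_line
    amps = _sample_amplitudes(concentration, config, rng, n)
    factors = _background_factors(config, rng, n)
    intensities = (
        factors[:, None] * background_profile(w, config)[None, :]
        + amps[:, None] * analyte_signature(w, config)[None, :]
    )
    if config.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, config.noise_sd, (n, w.size))
    return SpectralMap(well_id, w, intensities, _raster_coordinates(config))


def make_default_design(
    config: GeneratorConfig, rows: int = 8, cols: int = 5
) -> PlateDesign:
    """Row-per-sample plate design: the configured concentrations plus a blank.

    With the defaults this is the 8 x 5 plate: seven twofold concentrations
    from 5000 ng/mL (index 0) down to 78 ng/mL, plus the matrix blank
    (index 7), five replicate wells each.
    """
    samples = [
        Sample(label=f"{c:g} ng/mL", concentration=float(c), index=i)
        for i, c in enumerate(config.concentrations)
    ]
    samples.append(
        Sample(label="blank", concentration=0.0, index=len(config.concentrations))
    )
    reps = config.replicate_wells_per_sample
    if len(samples) * reps > rows * cols:
        raise CapacityError(
            f"{len(samples)} samples x {reps} replicates do not fit on a "
            f"{rows} x {cols} plate"
        )
    well_to_sample: dict[str, int] = {}
    slot = 0
    for sample in samples:
        for _ in range(reps):
            r, c = divmod(slot, cols)
            well_to_sample[well_name(r, c)] = sample.index
            slot += 1
    return PlateDesign(
        rows=rows,
        cols=cols,
        samples=tuple(samples),
        well_to_sample=well_to_sample,
        replicate_wells_per_sample=reps,
    )


def iter_well_maps(
    design: PlateDesign, config: GeneratorConfig
) -> Iterator[SpectralMap]:
    """Generate well maps one at a time (identical data to `generate_plate`)."""
    seeds = np.random.SeedSequence(config.rng_seed).spawn(design.n_wells)
    for well_id, seed in zip(design.well_ids, seeds):
        rng = np.random.default_rng(seed)
        concentration = design.sample_of(well_id).concentration
        yield generate_map(well_id, concentration, config, rng)


def generate_plate(design: PlateDesign, config: GeneratorConfig) -> Plate:
    """Synthesize every well of the plate; reproducible under ``rng_seed``."""
    maps = {m.well_id: m for m in iter_well_maps(design, config)}
    return Plate(design=design, maps=maps)


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of ``config`` with a different RNG seed."""
    return replace(config, rng_seed=seed)
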