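"""PCA-based limit-of-quantification validation.

Confirms that the lowest analyte concentration is distinguishable from the
matrix blank: the spectra each calibration method would average are
truncated to the informative window (585.48-1710.01 cm^-1 by default),
baseline-corrected with an improved asymmetrically reweighted penalized
least-squares (IarPLS) Whittaker smoother, decomposed by mean-centered PCA,
and the two classes' 95% confidence ellipses in the first two score
dimensions are tested for geometric overlap.  Disjoint ellipses are the
figure-style criterion for "the classes separate at this concentration".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .calibration import mean_spectrum, select_top_k_by_qi
from .errors import ConfigurationError, DegeneracyError, SpectralRangeError
from .quality import QiConfig, compute_qi_map
from .spectra import Plate, Spectrum

__all__ = [
    "BaselineConfig",
    "BaselineResult",
    "EllipsoidSummary",
    "PcaResult",
    "LoqResult",
    "truncate_spectrum",
    "iarpls_baseline",
    "run_pca",
    "confidence_ellipsoid",
    "ellipsoids_overlap",
    "validate_loq",
]

TRUNCATION_WINDOW = (585.48, 1710.01)


@dataclass(frozen=True)
class BaselineConfig:
    """IarPLS tunables: smoothness penalty, iteration cap, stop tolerance.

    ``smoothness`` is the weight on the second-difference penalty of the
    Whittaker smoother (larger -> stiffer baseline); iteration stops when
    the relative change of the weight vector drops below ``tolerance``.
    """

    smoothness: float = 1e5
    max_iterations: int = 50
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if self.smoothness <= 0:
            raise ConfigurationError("smoothness must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")


@dataclass
class BaselineResult:
    baseline: Spectrum
    corrected: Spectrum
    converged: bool
    n_iterations: int


def truncate_spectrum(
    spectrum: Spectrum,
    lo: float = TRUNCATION_WINDOW[0],
    hi: float = TRUNCATION_WINDOW[1],
) -> Spectrum:
    """Retain the grid points with lo <= wavenumber <= hi (inclusive)."""
    if lo > hi:
        raise SpectralRangeError(f"empty truncation window [{lo}, {hi}]")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise SpectralRangeError(
            f"truncation window [{lo}, {hi}] does not overlap the axis"
        )
    return Spectrum(spectrum.wavenumbers[mask], spectrum.intensities[mask])


def iarpls_baseline(
    spectrum: Spectrum, cfg: BaselineConfig = BaselineConfig()
) -> BaselineResult:
    """Estimate and remove a smooth baseline by IarPLS.

    Iteratively solves the penalized weighted least-squares (Whittaker)
    problem ``(W + lam * D2' D2) z = W y`` and reweights with an asymmetric
    logistic rule on the residuals ``d = y - z`` scaled by the standard
    deviation of the negative residuals, sharpened by the iteration index:
    points far above the current baseline (peaks) lose weight quickly,
    points at or below it keep full weight.  Non-convergence within
    ``max_iterations`` is flagged, not raised.
    """
    y = spectrum.intensities
    n = y.size
    if n < 10:
        raise ValueError("baseline correction needs at least 10 points")
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )
    penalty = cfg.smoothness * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    converged = False
    iteration = 0
    for iteration in range(1, cfg.max_iterations + 1):
        lhs = sparse.diags_array(w, format="csc") + penalty
        z = spsolve(lhs.tocsc(), w * y)
        d = y - z
        negatives = d[d < 0]
        if negatives.size == 0:
            converged = True
            break
        s = negatives.std()
        # residuals at solver-noise level: baseline has converged onto the data
        if s <= 1e-9 * max(1.0, float(np.abs(y).max())):
            converged = True
            break
        arg = np.clip(iteration * (d - 2 * s) / s, -500.0, 500.0)
        w_new = 1.0 / (1.0 + np.exp(arg))
        if np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-300) < cfg.tolerance:
            w = w_new
            converged = True
            break
        w = w_new
    baseline = Spectrum(spectrum.wavenumbers, z)
    corrected = Spectrum(spectrum.wavenumbers, y - z)
    return BaselineResult(
        baseline=baseline,
        corrected=corrected,
        converged=converged,
        n_iterations=iteration,
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_spectra, n_components)
    labels: np.ndarray  # class label per row
    explained_variance_ratio: np.ndarray


def run_pca(
    groups: dict[str, list[Spectrum]], n_components: int = 2
) -> PcaResult:
    """Mean-centered PCA over the pooled class spectra.

    Each principal component is oriented so its largest-magnitude loading
    is positive, making score signs reproducible across runs.
    """
    labels = []
    rows = []
    axis = None
    for label, spectra in groups.items():
        if len(spectra) < 3:
            raise ValueError(f"class {label!r} needs at least 3 spectra")
        for s in spectra:
            if axis is None:
                axis = s.wavenumbers
            elif not np.array_equal(s.wavenumbers, axis):
                raise ValueError("all spectra must share one truncated axis")
            rows.append(s.intensities)
            labels.append(label)
    matrix = np.vstack(rows)
    centered = matrix - matrix.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < 1:
        raise DegeneracyError(
            "pooled spectra have no variance; PCA is undefined"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    # deterministic sign: largest-|loading| entry of each PC is positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        scores=scores,
        labels=np.asarray(labels),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class EllipsoidSummary:
    """A class's confidence ellipse in 2-D score space.

    The ellipse is centered on the class mean with shape from the score
    covariance scaled by the chi-square(2 df) quantile at ``level``.
    """

    label: str
    center: np.ndarray
    covariance: np.ndarray
    level: float
    boundary: np.ndarray  # (n_boundary, 2)


def confidence_ellipsoid(
    scores: np.ndarray,
    level: float = 0.95,
    label: str = "",
    n_boundary: int = 360,
) -> EllipsoidSummary:
    """Confidence ellipse of one class's 2-D scores."""
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 1e-12 * max(np.max(eigvals), 1e-300):
        raise DegeneracyError("singular score covariance; ellipse undefined")
    r2 = chi2.ppf(level, df=2)
    theta = np.linspace(0.0, 2 * np.pi, n_boundary, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    boundary = center + circle * np.sqrt(eigvals * r2) @ eigvecs.T
    return EllipsoidSummary(
        label=label, center=center, covariance=cov, level=level, boundary=boundary
    )


def _strictly_inside(e: EllipsoidSummary, points: np.ndarray) -> np.ndarray:
    r2 = chi2.ppf(e.level, df=2)
    diff = np.atleast_2d(points) - e.center
    q = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(e.covariance), diff)
    return q < r2 * (1.0 - 1e-9)


def ellipsoids_overlap(e1: EllipsoidSummary, e2: EllipsoidSummary) -> bool:
    """True iff the open interiors of the two ellipses intersect.

    Tested by dense boundary sampling (each ellipse's boundary points
    against the other's interior) plus mutual center containment, which
    also covers full containment.
    """
    return bool(
        _strictly_inside(e2, e1.boundary).any()
        or _strictly_inside(e1, e2.boundary).any()
        or _strictly_inside(e2, e1.center[None, :]).any()
        or _strictly_inside(e1, e2.center[None, :]).any()
    )


@dataclass
class LoqResult:
    """Outcome of the blank vs lowest-concentration separation check."""

    method: str
    blank_label: str
    analyte_label: str
    pca: PcaResult
    ellipsoids: dict[str, EllipsoidSummary]
    overlap: bool


def _calibration_input_spectra(
    plate: Plate, sample_index: int, method: str, qi_config: QiConfig, k: int
) -> list[Spectrum]:
    spectra = []
    for smap in plate.maps_for(sample_index):
        if method == "total":
            spectra.append(mean_spectrum(smap))
        elif method == "qi":
            qi = compute_qi_map(smap, qi_config)
            spectra.append(mean_spectrum(select_top_k_by_qi(smap, qi, k)))
        else:
            raise ValueError(f"unknown LOQ method {method!r} (use 'total' or 'qi')")
    return spectra


def validate_loq(
    plate: Plate,
    method: str = "qi",
    qi_config: QiConfig = QiConfig(),
    k: int = 20,
    baseline_cfg: BaselineConfig = BaselineConfig(),
    window: tuple[float, float] = TRUNCATION_WINDOW,
    level: float = 0.95,
) -> LoqResult:
    """Blank vs lowest-concentration PCA separation for one method.

    The PCA inputs are the per-well spectra the calibration method would
    average (well means for 'total', top-k means for 'qi'), truncated and
    IarPLS-corrected.
    """
    design = plate.design
    blank = design.blank_sample
    if blank is None:
        raise ValueError("LOQ validation requires a blank sample")
    lowest = min(design.nonblank_samples, key=lambda s: s.concentration)

    groups: dict[str, list[Spectrum]] = {}
    for sample in (blank, lowest):
        raw = _calibration_input_spectra(plate, sample.index, method, qi_config, k)
        processed = []
        for s in raw:
            t = truncate_spectrum(s, *window)
            processed.append(iarpls_baseline(t, baseline_cfg).corrected)
        groups[sample.label] = processed

    pca = run_pca(groups, n_components=2)
    ellipsoids = {}
    for label in groups:
        pts = pca.scores[pca.labels == label]
        ellipsoids[label] = confidence_ellipsoid(pts, level=level, label=label)
    overlap = ellipsoids_overlap(ellipsoids[blank.label], ellipsoids[lowest.label])
    return LoqResult(
        method=method,
        blank_label=blank.label,
        analyte_label=lowest.label,
        pca=pca,
        ellipsoids=ellipsoids,
        overlap=overlap,
    )
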