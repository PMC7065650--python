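"""Spectral preprocessing chain for probe-based Raman tissue maps.

The chain turns raw, fluorescence-dominated probe spectra into background-
corrected, unity-normalized Raman spectra:

wavenumber calibration -> intensity calibration -> dark subtraction ->
cosmic-spike removal -> PCA noise filtering -> Savitzky-Golay smoothing ->
cropping to the 600-3100 cm^-1 working range -> background correction ->
unity normalization.

Background correction offers four methods: EMSC (extended multiplicative
signal correction, the primary one — a least-squares fit of a reference
spectrum, interferent spectra such as the fiber-probe background, and
polynomial terms), plus ALS (asymmetric penalized least squares), the
iterative clipped polynomial fit of Lieber and Mahadevan-Jansen, and SNIP
peak clipping as alternates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from numpy.polynomial import Legendre, Polynomial
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, savgol_filter
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .types import HyperspectralMap, Spectrum, WavenumberAxis

__all__ = [
    "CalibrationStandard",
    "ACETAMINOPHEN",
    "CalibrationResult",
    "EMSCBasis",
    "EMSCCoefficients",
    "PreprocessConfig",
    "calibrate_wavenumber",
    "calibrate_intensity",
    "subtract_dark",
    "remove_cosmic_spikes",
    "pca_denoise",
    "savitzky_golay",
    "emsc_correct",
    "als_baseline",
    "lieber_polyfit",
    "snip_baseline",
    "crop",
    "normalize_unity",
    "run_preprocessing",
]


# --------------------------------------------------------------------------
# helpers: operate uniformly on a Spectrum or a HyperspectralMap


def _matrix(obj: Spectrum | HyperspectralMap) -> tuple[WavenumberAxis, np.ndarray]:
    if isinstance(obj, Spectrum):
        return obj.axis, obj.intensity[None, :]
    return obj.axis, obj.intensities


def _rebuild(obj, axis: WavenumberAxis, matrix: np.ndarray):
    if isinstance(obj, Spectrum):
        return Spectrum(axis, matrix[0])
    return obj.with_axis(axis, matrix)


# --------------------------------------------------------------------------
# wavenumber calibration

#: Reference Raman shifts of solid N-acetyl-p-aminophenol (acetaminophen),
#: the ASTM E1840 wavenumber standard.
ACETAMINOPHEN_PEAKS = (
    390.9, 465.1, 504.0, 651.6, 710.8, 797.2, 834.5, 857.9, 968.7,
    1105.5, 1168.5, 1236.8, 1278.5, 1323.9, 1371.5, 1561.6, 1648.4,
    2931.1, 3064.6,
)


@dataclass(frozen=True)
class CalibrationStandard:
    name: str = "acetaminophen"
    reference_peak_positions: tuple[float, ...] = ACETAMINOPHEN_PEAKS
    matching_tolerance: float = 6.0  # cm^-1

    def __post_init__(self) -> None:
        if len(self.reference_peak_positions) < 3:
            raise ValueError("a calibration standard needs at least 3 reference peaks")


ACETAMINOPHEN = CalibrationStandard()


@dataclass
class CalibrationResult:
    matched_detected: np.ndarray  # positions on the uncalibrated axis
    matched_reference: np.ndarray
    poly_degree: int
    coefficients: np.ndarray  # power-basis mapping detected -> true, ascending
    residuals: np.ndarray  # per matched peak, after refit

    def apply(self, axis: WavenumberAxis) -> WavenumberAxis:
        return WavenumberAxis(Polynomial(self.coefficients)(axis.values))


def calibrate_wavenumber(
    measured_standard: Spectrum,
    standard: CalibrationStandard = ACETAMINOPHEN,
    maps: Sequence[HyperspectralMap] = (),
    prominence: float = 0.02,
) -> tuple[list[HyperspectralMap], CalibrationResult]:
    """Refit the pixel-to-wavenumber mapping against a solid standard.

    Peaks are detected in the measured standard spectrum as local maxima
    above a prominence threshold (relative to the spectrum's dynamic range),
    matched to the nearest reference position within the standard's
    tolerance, and a least-squares polynomial of degree ``min(3, matched-1)``
    through the (detected, reference) pairs re-maps every axis.
    """
    y = measured_standard.intensity
    axis_values = measured_standard.axis.values
    rng_amp = float(y.max() - y.min())
    peaks, _ = find_peaks(y, prominence=prominence * max(rng_amp, 1e-30))
    detected = []
    for i in peaks:
        if 0 < i < y.size - 1:
            tri = y[i - 1 : i + 2]
            # sub-channel vertex; log-parabola is exact for Gaussian peaks
            tri = np.log(tri) if np.all(tri > 0) else tri
            denom = tri[0] - 2 * tri[1] + tri[2]
            delta = 0.5 * (tri[0] - tri[2]) / denom if denom < 0 else 0.0
            detected.append(
                axis_values[i] + delta * 0.5 * (axis_values[i + 1] - axis_values[i - 1])
            )
        else:
            detected.append(axis_values[i])
    detected = np.asarray(detected)

    matched_d, matched_r = [], []
    for ref in standard.reference_peak_positions:
        if detected.size == 0:
            continue
        j = int(np.argmin(np.abs(detected - ref)))
        if abs(detected[j] - ref) <= standard.matching_tolerance:
            matched_d.append(detected[j])
            matched_r.append(ref)
    if len(matched_d) < 3:
        raise ValueError(
            f"wavenumber calibration failed: only {len(matched_d)} standard "
            "peaks matched (need at least 3)"
        )
    md = np.asarray(matched_d)
    mr = np.asarray(matched_r)
    degree = min(3, md.size - 1)
    poly = Polynomial.fit(md, mr, degree).convert()
    residuals = poly(md) - mr
    result = CalibrationResult(md, mr, degree, poly.coef, residuals)
    corrected = [m.with_axis(result.apply(m.axis), m.intensities) for m in maps]
    return corrected, result


# --------------------------------------------------------------------------
# intensity calibration and dark subtraction


def calibrate_intensity(
    obj: Spectrum | HyperspectralMap,
    measured_white: Spectrum,
    reference_white: Spectrum,
):
    """Correct the instrument response via a standardized white-light source.

    Multiplies each spectrum pointwise by reference_white / measured_white.
    """
    axis, D = _matrix(obj)
    if not np.array_equal(axis.values, measured_white.axis.values):
        raise ValueError("white-light spectrum is not on the data axis")
    mw = measured_white.intensity
    if np.any(mw <= 0):
        raise ValueError("measured white-light spectrum must be strictly positive")
    factor = reference_white.intensity / mw
    return _rebuild(obj, axis, D * factor[None, :])


def subtract_dark(obj: Spectrum | HyperspectralMap, dark: Spectrum):
    """Remove the constant offset bias and dark current."""
    axis, D = _matrix(obj)
    if not np.array_equal(axis.values, dark.axis.values):
        raise ValueError("dark spectrum is not on the data axis")
    return _rebuild(obj, axis, D - dark.intensity[None, :])


# --------------------------------------------------------------------------
# cosmic spikes


def remove_cosmic_spikes(
    hsmap: HyperspectralMap,
    threshold: float = 8.0,
    kernel: int = 7,
) -> tuple[HyperspectralMap, list[tuple[int, float, float]]]:
    """Detect and repair cosmic-ray spikes in a map.

    A sample is flagged when it is simultaneously a narrow spectral outlier
    (residual against a running-median envelope exceeding ``threshold``
    MAD-based SDs of its own spectrum) and spatially inconsistent (the same
    excess against the median of the 4-connected neighbour pixels at that
    channel) — real Raman bands are shared by neighbours, spikes are not.
    Flagged samples are replaced by linear interpolation along the
    wavenumber axis from unflagged channels.  Returns the repaired map and a
    log of (pixel index, wavenumber, original value).
    """
    if hsmap.n_pixels < 2:
        raise ValueError("spike removal needs at least 2 pixels of context")
    D = hsmap.intensities
    n_px, n_ch = D.shape
    env = median_filter(D, size=(1, kernel), mode="nearest")
    resid = D - env
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    sigma = 1.4826 * np.maximum(mad, 1e-12)
    z_spec = resid / sigma

    # spatial test on the detrended residual: raw intensities differ between
    # neighbours through the per-pixel fluorescence amplitude alone, whereas
    # the median-envelope residual isolates narrow features
    rows, cols = hsmap.grid_shape
    grid = np.full((rows, cols, n_ch), np.nan)
    grid[hsmap.coords[:, 0], hsmap.coords[:, 1]] = resid
    padded = np.full((rows + 2, cols + 2, n_ch), np.nan)
    padded[1:-1, 1:-1] = grid
    stack = np.stack(
        [
            padded[:-2, 1:-1],  # up
            padded[2:, 1:-1],  # down
            padded[1:-1, :-2],  # left
            padded[1:-1, 2:],  # right
        ]
    )
    with np.errstate(all="ignore"):
        neigh = np.nanmedian(stack, axis=0)
    neigh_px = neigh[hsmap.coords[:, 0], hsmap.coords[:, 1]]
    z_spat = (resid - neigh_px) / sigma
    flags = (z_spec > threshold) & (z_spat > threshold)

    out = D.copy()
    log: list[tuple[int, float, float]] = []
    axis_values = hsmap.axis.values
    for px in np.nonzero(flags.any(axis=1))[0]:
        bad = flags[px]
        good = ~bad
        out[px, bad] = np.interp(axis_values[bad], axis_values[good], out[px, good])
        for ch in np.nonzero(bad)[0]:
            log.append((int(px), float(axis_values[ch]), float(D[px, ch])))
    return hsmap.with_intensities(out), log


# --------------------------------------------------------------------------
# noise filtering and smoothing


def pca_denoise(obj: Spectrum | HyperspectralMap | np.ndarray, n_components: int):
    """Reconstruct each spectrum from the top principal components.

    The map's spectra are mean-centred, decomposed by SVD, and rebuilt from
    the leading ``n_components`` directions — the standard PCA noise filter
    for hyperspectral stacks.
    """
    if isinstance(obj, np.ndarray):
        axis, D = None, np.asarray(obj, dtype=float)
    else:
        axis, D = _matrix(obj)
    n, p = D.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound {min(n, p)}"
        )
    mean = D.mean(axis=0)
    U, s, Vt = np.linalg.svd(D - mean, full_matrices=False)
    k = n_components
    rec = mean + (U[:, :k] * s[:k]) @ Vt[:k]
    if isinstance(obj, np.ndarray):
        return rec
    return _rebuild(obj, axis, rec)


def savitzky_golay(obj: Spectrum | HyperspectralMap, window: int = 11, order: int = 3):
    """Local polynomial least-squares smoothing along the wavenumber axis."""
    if window % 2 == 0 or window <= order:
        raise ValueError(
            f"Savitzky-Golay window must be odd and larger than the order "
            f"(got window={window}, order={order})"
        )
    axis, D = _matrix(obj)
    return _rebuild(obj, axis, savgol_filter(D, window, order, axis=-1))


# --------------------------------------------------------------------------
# EMSC


@dataclass
class EMSCBasis:
    """Design for extended multiplicative signal correction.

    Columns of the least-squares design are the reference ("pure") spectrum,
    the interferent spectra (fiber, substrate backgrounds) and polynomial
    terms of degree 0..poly_order; internally the polynomials are Legendre
    on the axis domain for conditioning, but fitted polynomial coefficients
    are reported in the ordinary power basis of the wavenumber.
    """

    reference: Spectrum
    interferents: list[Spectrum] = field(default_factory=list)
    poly_order: int = 5

    def __post_init__(self) -> None:
        for s in self.interferents:
            if not np.array_equal(s.axis.values, self.reference.axis.values):
                raise ValueError("interferent spectra must share the reference axis")
        if np.linalg.matrix_rank(self.design_matrix()) < self.n_columns:
            raise ValueError("EMSC design matrix is rank deficient")

    @property
    def n_columns(self) -> int:
        return 1 + len(self.interferents) + self.poly_order + 1

    def legendre_columns(self) -> np.ndarray:
        v = self.reference.axis.values
        t = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
        return np.polynomial.legendre.legvander(t, self.poly_order)

    def design_matrix(self) -> np.ndarray:
        cols = [self.reference.intensity]
        cols += [s.intensity for s in self.interferents]
        return np.column_stack(cols + [self.legendre_columns()])


@dataclass
class EMSCCoefficients:
    reference: np.ndarray  # (n_spectra,)
    interferents: np.ndarray  # (n_spectra, n_interferents)
    poly: np.ndarray  # (n_spectra, poly_order + 1), power basis in wavenumber

    def single(self) -> tuple[float, np.ndarray, np.ndarray]:
        return float(self.reference[0]), self.interferents[0], self.poly[0]


def emsc_correct(
    obj: Spectrum | HyperspectralMap,
    basis: EMSCBasis,
    min_reference_coef: float = 1e-8,
):
    """Fit and strip background by extended multiplicative signal correction.

    Each spectrum is regressed on [reference | interferents | polynomials];
    the corrected spectrum is (y - interferent and polynomial parts) divided
    by the reference coefficient, which also undoes multiplicative
    intensity variation.  A reference coefficient at or below
    ``min_reference_coef`` means the fit is degenerate and raises.
    """
    axis, D = _matrix(obj)
    if not np.array_equal(axis.values, basis.reference.axis.values):
        raise ValueError("spectrum axis does not match the EMSC basis axis")
    A = basis.design_matrix()
    coeffs, *_ = np.linalg.lstsq(A, D.T, rcond=None)
    coeffs = coeffs.T  # (n_spectra, n_columns)
    n_int = len(basis.interferents)
    b_ref = coeffs[:, 0]
    if np.any(np.abs(b_ref) <= min_reference_coef):
        raise ValueError(
            "degenerate EMSC fit: reference coefficient magnitude at or below "
            f"{min_reference_coef:g}"
        )
    background = coeffs[:, 1:] @ A[:, 1:].T
    corrected = (D - background) / b_ref[:, None]

    v = axis.values
    leg_coefs = coeffs[:, 1 + n_int :]
    poly_power = np.vstack(
        [
            _pad(Legendre(c, domain=[v[0], v[-1]]).convert(kind=Polynomial).coef,
                 basis.poly_order + 1)
            for c in leg_coefs
        ]
    )
    out = EMSCCoefficients(b_ref, coeffs[:, 1 : 1 + n_int], poly_power)
    return _rebuild(obj, axis, corrected), out


def _pad(c: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[: c.size] = c
    return out


# --------------------------------------------------------------------------
# alternate baseline estimators


def als_baseline(
    spectrum: Spectrum,
    lam: float = 1e4,
    p: float = 0.01,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[Spectrum, bool]:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights: points above the fit get weight p, below 1-p)."""
    if lam <= 0 or not 0 < p < 1 or n_iter < 1:
        raise ValueError("ALS hyper-parameters must be positive (and 0 < p < 1)")
    y = spectrum.intensity
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z_new = spsolve(W + penalty, w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        if np.array_equal(w_new, w) or np.max(np.abs(z_new - z)) < tol * max(
            1.0, float(np.max(np.abs(y)))
        ):
            z = z_new
            converged = True
            break
        z, w = z_new, w_new
    return spectrum.with_intensity(z), converged


def lieber_polyfit(
    spectrum: Spectrum,
    degree: int = 9,
    n_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[Spectrum, bool]:
    """Modified polynomial baseline (Lieber & Mahadevan-Jansen style):
    iterative polynomial fit where the target is clipped to
    min(spectrum, previous fit), so peaks stop pulling the fit upward."""
    if degree < 0 or n_iter < 1:
        raise ValueError("degree and n_iter must be positive")
    v = spectrum.axis.values
    target = spectrum.intensity.copy()
    converged = False
    fit = target
    for _ in range(n_iter):
        poly = Polynomial.fit(v, target, degree)
        fit = poly(v)
        new_target = np.minimum(spectrum.intensity, fit)
        if np.max(np.abs(new_target - target)) < tol * max(
            1.0, float(np.max(np.abs(spectrum.intensity)))
        ):
            converged = True
            break
        target = new_target
    return spectrum.with_intensity(fit), converged


def snip_baseline(
    spectrum: Spectrum,
    max_halfwidth: int = 16,
) -> tuple[Spectrum, bool]:
    """SNIP baseline: iterative clipping against window-endpoint averages
    with growing half-width, on the customary log-log-sqrt (LLS) transform."""
    if max_halfwidth < 1:
        raise ValueError("max_halfwidth must be at least 1")
    y = spectrum.intensity
    offset = float(y.min())
    v = np.log(np.log(np.sqrt(y - offset + 1.0) + 1.0) + 1.0)
    n = v.size
    for m in range(1, min(max_halfwidth, (n - 1) // 2) + 1):
        clipped = v.copy()
        avg = 0.5 * (v[: n - 2 * m] + v[2 * m :])
        clipped[m : n - m] = np.minimum(v[m : n - m], avg)
        v = clipped
    baseline = (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0 + offset
    return spectrum.with_intensity(baseline), True


# --------------------------------------------------------------------------
# cropping and normalization


def crop(obj: Spectrum | HyperspectralMap, lo: float = 600.0, hi: float = 3100.0):
    """Keep the closed wavenumber interval [lo, hi]."""
    axis, D = _matrix(obj)
    mask = axis.window(lo, hi)
    if not mask.any():
        raise ValueError(f"cropping to [{lo:g}, {hi:g}] cm-1 leaves no channels")
    return _rebuild(obj, WavenumberAxis(axis.values[mask]), D[:, mask])


def normalize_unity(obj: Spectrum | HyperspectralMap, kind: str = "l2"):
    """Scale each spectrum so the chosen norm equals one.

    ``l2`` (Euclidean, the default), ``l1``, ``area`` (integral over the
    axis) or ``max`` are available.
    """
    axis, D = _matrix(obj)
    if kind == "l2":
        norms = np.linalg.norm(D, axis=1)
    elif kind == "l1":
        norms = np.abs(D).sum(axis=1)
    elif kind == "area":
        norms = np.abs(np.trapezoid(D, axis.values, axis=1))
    elif kind == "max":
        norms = np.abs(D).max(axis=1)
    else:
        raise ValueError(f"unknown normalization kind {kind!r}")
    if np.any(norms <= 0):
        raise ValueError("cannot normalize a zero spectrum")
    return _rebuild(obj, axis, D / norms[:, None])


# --------------------------------------------------------------------------
# the full chain


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (order is fixed, steps can be
    switched off individually)."""

    crop_lo: float = 600.0
    crop_hi: float = 3100.0
    spike_threshold: float = 8.0
    spike_kernel: int = 7
    n_pca_components: int = 10
    savgol_window: int = 11
    savgol_order: int = 3
    background_method: str = "emsc"  # emsc | als | polyfit | snip
    emsc_poly_order: int = 5
    als_lam: float = 1e4
    als_p: float = 0.01
    als_n_iter: int = 50
    lieber_degree: int = 9
    lieber_n_iter: int = 200
    snip_max_halfwidth: int = 16
    normalization: str = "l2"
    subtract_dark: bool = True
    remove_spikes: bool = True
    denoise: bool = True
    smooth: bool = True
    correct_background: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("Savitzky-Golay window must be odd and > order")
        if self.crop_lo > self.crop_hi:
            raise ValueError("crop range is empty")
        if self.background_method not in ("emsc", "als", "polyfit", "snip"):
            raise ValueError(f"unknown background method {self.background_method!r}")


def _subtract_estimated_baseline(
    hsmap: HyperspectralMap, estimator: Callable[[Spectrum], tuple[Spectrum, bool]]
) -> HyperspectralMap:
    out = np.empty_like(hsmap.intensities)
    for i in range(hsmap.n_pixels):
        baseline, _ = estimator(hsmap.pixel(i))
        out[i] = hsmap.intensities[i] - baseline.intensity
    return hsmap.with_intensities(out)


def run_preprocessing(
    maps: Sequence[HyperspectralMap],
    config: PreprocessConfig | None = None,
    dark: Spectrum | None = None,
    fiber: Spectrum | None = None,
    emsc_reference: Spectrum | None = None,
    measured_standard: Spectrum | None = None,
    standard: CalibrationStandard = ACETAMINOPHEN,
) -> tuple[list[HyperspectralMap], list[list[dict[str, Any]]]]:
    """Apply the full preprocessing chain to a set of biopsy maps.

    ``dark`` and ``fiber`` are instrument reference spectra (recorded dark
    spectrum; measured fiber-probe background used as the EMSC interferent).
    The EMSC reference defaults to the mean of all spectra after the
    spike/denoise/smoothing stages — a label-free, purely unsupervised
    choice — unless an explicit reference spectrum is supplied.

    Returns the processed maps and, per biopsy, an ordered provenance log of
    every applied step with its parameters.
    """
    config = config or PreprocessConfig()
    logs: list[list[dict[str, Any]]] = [[] for _ in maps]
    work = list(maps)

    if measured_standard is not None:
        work, calib = calibrate_wavenumber(measured_standard, standard, work)
        for log in logs:
            log.append(
                {
                    "step": "calibrate_wavenumber",
                    "standard": standard.name,
                    "matched_peaks": int(calib.matched_reference.size),
                    "max_residual": float(np.max(np.abs(calib.residuals))),
                }
            )

    if config.subtract_dark and dark is not None:
        work = [subtract_dark(m, dark) for m in work]
        for log in logs:
            log.append({"step": "subtract_dark"})

    if config.remove_spikes:
        repaired = []
        for m, log in zip(work, logs):
            m2, spikes = remove_cosmic_spikes(
                m, threshold=config.spike_threshold, kernel=config.spike_kernel
            )
            repaired.append(m2)
            log.append(
                {
                    "step": "remove_cosmic_spikes",
                    "threshold": config.spike_threshold,
                    "n_spikes": len(spikes),
                }
            )
        work = repaired

    if config.denoise:
        out = []
        for m, log in zip(work, logs):
            k = min(config.n_pca_components, m.n_pixels, len(m.axis))
            out.append(pca_denoise(m, k))
            log.append({"step": "pca_denoise", "n_components": k})
        work = out

    if config.smooth:
        work = [savitzky_golay(m, config.savgol_window, config.savgol_order) for m in work]
        for log in logs:
            log.append(
                {
                    "step": "savitzky_golay",
                    "window": config.savgol_window,
                    "order": config.savgol_order,
                }
            )

    work = [crop(m, config.crop_lo, config.crop_hi) for m in work]
    for log in logs:
        log.append({"step": "crop", "lo": config.crop_lo, "hi": config.crop_hi})

    if config.correct_background:
        if config.background_method == "emsc":
            axis = work[0].axis
            if emsc_reference is None:
                mean_all = np.mean(
                    np.vstack([m.intensities for m in work]), axis=0
                )
                reference = Spectrum(axis, mean_all)
                ref_kind = "mean-of-dataset"
            else:
                reference = emsc_reference
                ref_kind = "supplied"
                if not np.array_equal(reference.axis.values, axis.values):
                    reference = crop(reference, config.crop_lo, config.crop_hi)
            interferents = []
            if fiber is not None:
                fib = fiber
                if not np.array_equal(fib.axis.values, axis.values):
                    fib = crop(fib, config.crop_lo, config.crop_hi)
                interferents.append(fib)
            basis = EMSCBasis(reference, interferents, config.emsc_poly_order)
            work = [emsc_correct(m, basis)[0] for m in work]
            step = {
                "step": "emsc_correct",
                "reference": ref_kind,
                "n_interferents": len(interferents),
                "poly_order": config.emsc_poly_order,
            }
        elif config.background_method == "als":
            work = [
                _subtract_estimated_baseline(
                    m,
                    lambda s: als_baseline(s, config.als_lam, config.als_p, config.als_n_iter),
                )
                for m in work
            ]
            step = {"step": "als_baseline", "lam": config.als_lam, "p": config.als_p}
        elif config.background_method == "polyfit":
            work = [
                _subtract_estimated_baseline(
                    m, lambda s: lieber_polyfit(s, config.lieber_degree, config.lieber_n_iter)
                )
                for m in work
            ]
            step = {"step": "lieber_polyfit", "degree": config.lieber_degree}
        else:
            work = [
                _subtract_estimated_baseline(
                    m, lambda s: snip_baseline(s, config.snip_max_halfwidth)
                )
                for m in work
            ]
            step = {"step": "snip_baseline", "max_halfwidth": config.snip_max_halfwidth}
        for log in logs:
            log.append(dict(step))

    if config.normalize:
        work = [normalize_unity(m, config.normalization) for m in work]
        for log in logs:
            log.append({"step": "normalize_unity", "kind": config.normalization})

    return work, logs
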