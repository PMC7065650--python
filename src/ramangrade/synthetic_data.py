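"""Synthetic hyperspectral bladder-biopsy phantoms.

Real probe-based Raman maps of bladder biopsies are dominated by broad tissue
autofluorescence and fiber-probe background, with a comparatively weak Raman
signature riding on top.  This module builds phantoms with exactly that
structure so that every downstream stage (background correction, two-level
PLS-LDA classification, heterogeneity mapping) can be exercised against full
ground truth:

* a small library of pure-constituent spectra (collagen, lipid, protein,
  nucleic acid) built from Gaussian bands at literature positions;
* per-pixel linear mixing with class-dependent concentrations — non-tumor
  tissue is collagen-rich, tumor tissue is lipid-rich, and low- vs high-grade
  tumor differ mainly on protein-band intensities;
* nuisance terms: a broad fluorescence baseline with per-pixel amplitude and
  tilt, a fixed fiber-probe background shape, a dark offset, shot-like and
  read noise, and sparse cosmic spikes;
* spatial heterogeneity: graded biopsies carry one contiguous tumor blob
  surrounded by non-tumor tissue, as seen in real prediction maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import HyperspectralMap, Spectrum, WavenumberAxis

__all__ = [
    "BAND_TABLE",
    "ComponentLibrary",
    "TissuePhantomConfig",
    "GroundTruth",
    "Cohort",
    "build_component_library",
    "default_axis",
    "fluorescence_shape",
    "fiber_background_shape",
    "generate_biopsy",
    "generate_cohort",
]

#: Band positions (cm^-1) and relative amplitudes per constituent.  Centers
#: follow the standard tissue-Raman assignments for bladder biopsies
#: (collagen backbone / amide III bands, lipid CH2 modes in the fingerprint
#: and high-wavenumber region, protein tyrosine / amide I / CH stretches).
#: The nucleic-acid component reuses the phosphate-bearing positions.
BAND_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "collagen": (
        (729.0, 0.45),
        (869.0, 0.30),
        (937.0, 0.65),
        (1003.0, 0.50),
        (1103.0, 0.30),
        (1265.0, 1.00),
        (1335.0, 0.55),
    ),
    "lipid": (
        (869.0, 0.20),
        (1003.0, 0.15),
        (1064.0, 0.55),
        (1103.0, 0.20),
        (1446.0, 0.85),
        (1656.0, 0.50),
        (2850.0, 1.00),
        (2885.0, 0.80),
        (2930.0, 0.45),
    ),
    "protein": (
        (1103.0, 0.25),
        (1176.0, 0.45),
        (1446.0, 0.60),
        (1656.0, 0.90),
        (2930.0, 1.00),
    ),
    "nucleic_acid": (
        (1003.0, 0.30),
        (1103.0, 0.60),
    ),
}

#: Boundary between the fingerprint and high-wavenumber regions (cm^-1).
HIGH_WAVENUMBER_START = 2500.0


def default_axis(lo: float = 600.0, hi: float = 3100.0, step: float = 2.0) -> WavenumberAxis:
    """Regular working axis, 600–3100 cm^-1 at 2 cm^-1 spacing by default."""
    n = int(round((hi - lo) / step)) + 1
    return WavenumberAxis(np.linspace(lo, hi, n))


def _gaussian_band(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((axis - center) / sigma) ** 2)


@dataclass(frozen=True)
class ComponentLibrary:
    """Pure-constituent spectra as sums of Gaussian bands on a common axis."""

    component_names: tuple[str, ...]
    band_table: Mapping[str, tuple[tuple[float, float, float], ...]]  # (center, fwhm, amp)
    axis: WavenumberAxis
    spectra: np.ndarray  # (n_components, n_wavenumbers)

    def spectrum(self, name: str) -> Spectrum:
        return Spectrum(self.axis, self.spectra[self.component_names.index(name)])


def build_component_library(
    axis: WavenumberAxis,
    fingerprint_fwhm: float = 12.0,
    high_wavenumber_fwhm: float = 35.0,
) -> ComponentLibrary:
    """Build pure spectra for collagen, lipid, protein and nucleic acid.

    Bands are Gaussians at the positions in :data:`BAND_TABLE`; fingerprint
    bands default to 12 cm^-1 FWHM and the broader CH-stretch bands above
    2500 cm^-1 to 35 cm^-1.  Shared bands (e.g. 1003 and 1103 cm^-1) appear
    in every constituent they are assigned to.
    """
    values = axis.values
    if values[0] > 600.0 or values[-1] < 3100.0:
        raise ValueError(
            f"axis {values[0]:g}..{values[-1]:g} cm-1 does not cover the "
            "600–3100 cm-1 working range"
        )
    names = tuple(BAND_TABLE)
    resolved: dict[str, tuple[tuple[float, float, float], ...]] = {}
    spectra = np.zeros((len(names), values.size))
    for i, name in enumerate(names):
        bands = []
        for center, amp in BAND_TABLE[name]:
            if not (values[0] <= center <= values[-1]):
                raise ValueError(
                    f"axis does not cover the {center:g} cm-1 band of {name}"
                )
            fwhm = (
                high_wavenumber_fwhm
                if center >= HIGH_WAVENUMBER_START
                else fingerprint_fwhm
            )
            bands.append((center, fwhm, amp))
            spectra[i] += amp * _gaussian_band(values, center, fwhm)
        resolved[name] = tuple(bands)
    return ComponentLibrary(names, resolved, axis, spectra)


@dataclass(frozen=True)
class ClassConcentration:
    """Mean constituent concentrations for one tissue class plus variability.

    ``pixel_sd`` is the between-pixel SD, ``biopsy_sd`` the SD of a
    biopsy-level random offset shared by all pixels of that class within one
    biopsy (tissue composition varies more between biopsies than between
    neighbouring pixels).
    """

    mean: np.ndarray  # per component, order of ComponentLibrary
    pixel_sd: float = 0.05
    biopsy_sd: float = 0.03


def _default_class_concentrations() -> dict[str, ClassConcentration]:
    # Component order: collagen, lipid, protein, nucleic_acid.
    # Non-tumor is collagen-rich; tumor classes are lipid-rich; low- vs
    # high-grade differ mostly in protein (and nucleic-acid) content.
    return {
        "NT": ClassConcentration(np.array([1.00, 0.30, 0.60, 0.35])),
        "LG": ClassConcentration(np.array([0.40, 0.75, 0.60, 0.50])),
        "HG": ClassConcentration(np.array([0.35, 0.79, 0.74, 0.54])),
    }


@dataclass
class TissuePhantomConfig:
    """Generator settings; the defaults are the study conditions.

    ``baseline_amplitude_ratio`` is the ratio of the fluorescence-background
    peak to the Raman-signal peak (default 10:1 — fluorescence dominates raw
    probe spectra).  ``tumor_fraction`` is the fraction of pixels inside the
    contiguous tumor blob of a graded biopsy.  Noise is shot-like
    (SD proportional to sqrt(intensity)) plus additive read noise.
    """

    class_concentrations: dict[str, ClassConcentration] = field(
        default_factory=_default_class_concentrations
    )
    tumor_fraction: float = 0.55
    baseline_amplitude_ratio: float = 10.0
    fiber_background_amplitude: float = 1.5
    dark_offset: float = 0.2
    noise_shot_scale: float = 0.03
    noise_read_sd: float = 0.02
    spike_rate: float = 0.03
    grid_shape: tuple[int, int] = (16, 16)
    fingerprint_fwhm: float = 12.0
    high_wavenumber_fwhm: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")
        for label, cc in self.class_concentrations.items():
            if np.any(np.asarray(cc.mean) < 0):
                raise ValueError(f"negative mean concentration for class {label}")
        nt = self.class_concentrations["NT"].mean
        for label in ("LG", "HG"):
            tumor = self.class_concentrations[label].mean
            if not nt[0] > tumor[0]:
                raise ValueError("NT collagen must exceed tumor collagen")
            if not tumor[1] > nt[1]:
                raise ValueError("tumor lipid must exceed NT lipid")


@dataclass
class GroundTruth:
    """Per-pixel truth channel for one phantom biopsy."""

    labels: np.ndarray  # (n_pixels,) of "NT" / "tumor"
    concentrations: np.ndarray  # (n_pixels, n_components)
    histo_label: str
    grid_shape: tuple[int, int]

    def label_grid(self) -> np.ndarray:
        return self.labels.reshape(self.grid_shape)

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == "tumor"


def fluorescence_shape(axis: WavenumberAxis) -> np.ndarray:
    """Broad tissue-autofluorescence envelope, peak-normalized to 1."""
    v = axis.values
    shape = np.exp(-(v - v[0]) / 1000.0) + 0.35 * np.exp(-(((v - 1400.0) / 500.0) ** 2))
    return shape / shape.max()


def fiber_background_shape(axis: WavenumberAxis) -> np.ndarray:
    """Fixed smooth fiber-probe background shape, peak-normalized to 1."""
    v = axis.values
    shape = np.exp(-(((v - 800.0) / 350.0) ** 2)) + 0.6 * np.exp(
        -(((v - 1350.0) / 600.0) ** 2)
    )
    return shape / shape.max()


def _grow_blob(grid_shape: tuple[int, int], n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous blob of exactly n_target cells grown by random accretion."""
    rows, cols = grid_shape
    mask = np.zeros((rows, cols), dtype=bool)
    if n_target <= 0:
        return mask
    start = (int(rng.integers(rows)), int(rng.integers(cols)))
    mask[start] = True
    frontier = {start}
    while mask.sum() < n_target:
        candidates: set[tuple[int, int]] = set()
        for r, c in frontier:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]:
                    candidates.add((rr, cc))
        if not candidates:  # blob filled the grid
            break
        ordered = sorted(candidates)
        pick = ordered[int(rng.integers(len(ordered)))]
        mask[pick] = True
        frontier.add(pick)
    return mask


def _raman_peak_scale(config: TissuePhantomConfig, library: ComponentLibrary) -> float:
    """Peak Raman intensity of the mean NT mixture (reference for ratios)."""
    nt = config.class_concentrations["NT"].mean
    return float((nt @ library.spectra).max())


def generate_biopsy(
    config: TissuePhantomConfig,
    histo_label: str,
    rng_seed: int,
    library: ComponentLibrary | None = None,
    axis: WavenumberAxis | None = None,
    tumor_fraction: float | None = None,
    biopsy_id: str = "B000",
    patient_id: str = "P000",
) -> tuple[HyperspectralMap, GroundTruth]:
    """Generate one phantom biopsy raster with full ground truth.

    Each pixel is ``sum_i c_i s_i + fluorescence + fiber + dark + noise``
    with optional cosmic spikes.  Graded biopsies (LG / HG, and ungraded
    tumor "T") carry a contiguous tumor blob occupying about
    ``tumor_fraction`` of the grid; the remaining pixels are non-tumor.
    """
    if histo_label not in ("NT", "LG", "HG", "T"):
        raise ValueError(f"unknown histopathology label {histo_label!r}")
    axis = axis or default_axis()
    library = library or build_component_library(
        axis, config.fingerprint_fwhm, config.high_wavenumber_fwhm
    )
    rng = np.random.default_rng(rng_seed)
    rows, cols = config.grid_shape
    n_px = rows * cols
    frac = config.tumor_fraction if tumor_fraction is None else tumor_fraction

    # "T" (tumor without grading) pixels draw their chemistry from a grade.
    tumor_chem = histo_label if histo_label in ("LG", "HG") else ("LG", "HG")[int(rng.integers(2))]

    if histo_label == "NT":
        tumor_mask = np.zeros(n_px, dtype=bool)
    else:
        tumor_mask = _grow_blob((rows, cols), int(round(frac * n_px)), rng).ravel()

    n_comp = len(library.component_names)
    conc = np.zeros((n_px, n_comp))
    for label, mask in (("NT", ~tumor_mask), (tumor_chem, tumor_mask)):
        if not mask.any():
            continue
        cc = config.class_concentrations[label]
        offset = rng.normal(0.0, cc.biopsy_sd, n_comp)  # biopsy-level random effect
        conc[mask] = cc.mean + offset + rng.normal(0.0, cc.pixel_sd, (int(mask.sum()), n_comp))
    conc = np.clip(conc, 0.0, None)

    signal = conc @ library.spectra

    raman_peak = _raman_peak_scale(config, library)
    fl_shape = fluorescence_shape(axis)
    v = axis.values
    tilt = (v - v.mean()) / (v[-1] - v[0])
    fl_amp = config.baseline_amplitude_ratio * raman_peak * np.clip(
        rng.normal(1.0, 0.25, n_px), 0.1, None
    )
    fl_tilt = rng.normal(0.0, 0.05, n_px)
    baseline = fl_amp[:, None] * fl_shape[None, :] * (1.0 + fl_tilt[:, None] * tilt[None, :])

    fiber = config.fiber_background_amplitude * raman_peak * fiber_background_shape(axis)

    clean = signal + baseline + fiber[None, :] + config.dark_offset
    noise_sd = config.noise_shot_scale * np.sqrt(np.clip(clean, 0.0, None)) + config.noise_read_sd
    intensities = clean + (
        rng.standard_normal(clean.shape) * noise_sd
        if (config.noise_shot_scale or config.noise_read_sd)
        else 0.0
    )

    if config.spike_rate > 0:
        n_spikes = rng.poisson(config.spike_rate, n_px)
        for px in np.nonzero(n_spikes)[0]:
            for _ in range(n_spikes[px]):
                ch = int(rng.integers(intensities.shape[1]))
                local = noise_sd[px, ch] if np.ndim(noise_sd) else noise_sd
                amp = float(rng.uniform(20.0, 120.0)) * max(local, 1e-6)
                intensities[px, ch] += amp
                if ch + 1 < intensities.shape[1] and rng.random() < 0.3:
                    intensities[px, ch + 1] += 0.5 * amp

    coords = np.stack(np.unravel_index(np.arange(n_px), (rows, cols)), axis=1)
    labels = np.where(tumor_mask, "tumor", "NT").astype(object)
    hsmap = HyperspectralMap(
        axis,
        intensities,
        coords,
        meta={
            "biopsy_id": biopsy_id,
            "patient_id": patient_id,
            "histo_label": histo_label,
            "tumor_chemistry": tumor_chem if histo_label != "NT" else "",
        },
    )
    truth = GroundTruth(labels, conc, histo_label, (rows, cols))
    return hsmap, truth


@dataclass
class Cohort:
    """A generated set of biopsies plus the instrument reference spectra.

    ``dark`` and ``fiber`` play the role of the recorded dark spectrum and a
    measured fiber-probe background, available to preprocessing exactly as
    they would be from reference measurements on a real system.
    """

    biopsies: list[tuple[HyperspectralMap, GroundTruth]]
    dark: Spectrum
    fiber: Spectrum
    config: TissuePhantomConfig
    library: ComponentLibrary

    @property
    def maps(self) -> list[HyperspectralMap]:
        return [m for m, _ in self.biopsies]

    @property
    def truths(self) -> dict[str, GroundTruth]:
        return {m.biopsy_id: t for m, t in self.biopsies}

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "biopsy_id": m.biopsy_id,
                    "patient_id": m.patient_id,
                    "histo_label": m.histo_label,
                    "n_pixels": m.n_pixels,
                }
                for m in self.maps
            ]
        )


def _label_counts(class_mix: Mapping[str, float], n: int) -> dict[str, int]:
    total = sum(class_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class mix proportions sum to {total:g}, not 1")
    counts = {k: int(math.floor(p * n)) for k, p in class_mix.items()}
    remainder = n - sum(counts.values())
    # hand the rounding remainder to the largest fractional parts
    fracs = sorted(
        class_mix, key=lambda k: (class_mix[k] * n) - math.floor(class_mix[k] * n), reverse=True
    )
    for k in fracs[:remainder]:
        counts[k] += 1
    return counts


def generate_cohort(
    n_patients: int = 28,
    n_biopsies: int = 48,
    class_mix: Mapping[str, float] | None = None,
    config: TissuePhantomConfig | None = None,
    seed: int = 0,
    biopsies_per_patient: int | None = None,
    tumor_fraction_range: tuple[float, float] = (0.3, 0.8),
) -> Cohort:
    """Generate a cohort of phantom biopsies with patient grouping.

    Defaults emulate the study breakdown: 48 biopsies from 28 patients, with
    non-tumor, low-grade, high-grade and ungraded-tumor ("T") histopathology
    labels.  Graded/ungraded tumor biopsies draw their tumor-blob area
    fraction uniformly from ``tumor_fraction_range``, so the cohort mixes
    near-homogeneous and strongly heterogeneous tumor biopsies.
    """
    config = config or TissuePhantomConfig()
    if biopsies_per_patient is not None:
        n_biopsies = n_patients * biopsies_per_patient
    class_mix = dict(class_mix) if class_mix is not None else {
        "NT": 14 / 48,
        "LG": 14 / 48,
        "HG": 14 / 48,
        "T": 6 / 48,
    }
    if n_biopsies < n_patients:
        raise ValueError("need at least one biopsy per patient")
    rng = np.random.default_rng(seed)
    axis = default_axis()
    library = build_component_library(
        axis, config.fingerprint_fwhm, config.high_wavenumber_fwhm
    )

    counts = _label_counts(class_mix, n_biopsies)
    labels: list[str] = [lab for lab, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    # every patient contributes at least one biopsy; extras spread at random
    owners = list(range(n_patients)) + [
        int(rng.integers(n_patients)) for _ in range(n_biopsies - n_patients)
    ]
    rng.shuffle(owners)

    biopsies = []
    for i, (label, owner) in enumerate(zip(labels, owners)):
        frac = float(rng.uniform(*tumor_fraction_range)) if label != "NT" else 0.0
        hsmap, truth = generate_biopsy(
            config,
            label,
            rng_seed=int(rng.integers(2**31 - 1)),
            library=library,
            axis=axis,
            tumor_fraction=frac,
            biopsy_id=f"B{i:03d}",
            patient_id=f"P{owner:03d}",
        )
        biopsies.append((hsmap, truth))

    dark = Spectrum(axis, np.full(len(axis), config.dark_offset))
    raman_peak = _raman_peak_scale(config, library)
    fiber = Spectrum(
        axis,
        config.fiber_background_amplitude * raman_peak * fiber_background_shape(axis),
    )
    return Cohort(biopsies, dark, fiber, config, library)
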