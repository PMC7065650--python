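"""Core array containers for probe-based Raman hyperspectral data.

A biopsy measurement is a raster of spectra acquired by scanning the sample
under a stationary fiber probe: every pixel of the grid carries one intensity
vector on a shared, calibrated wavenumber axis (Raman shift in cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


class WavenumberAxis:
    """Strictly increasing vector of Raman shifts in cm^-1."""

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("wavenumber axis must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavenumber axis contains non-finite values")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        self.values = values

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        v = self.values
        return f"WavenumberAxis({v[0]:g}..{v[-1]:g} cm-1, n={v.size})"

    @property
    def step(self) -> float:
        """Median channel spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel closest to *wavenumber*."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels in the closed interval [lo, hi]."""
        if lo > hi:
            raise ValueError(f"empty window: lo={lo} > hi={hi}")
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class Spectrum:
    """One intensity vector on a wavenumber axis (counts, arbitrary units)."""

    axis: WavenumberAxis
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("spectrum intensity must be one-dimensional")
        if self.intensity.size != len(self.axis):
            raise ValueError(
                f"intensity length {self.intensity.size} does not match "
                f"axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum intensity contains non-finite values")

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, intensity)


@dataclass
class HyperspectralMap:
    """Raster of spectra for one biopsy.

    ``intensities`` is (n_pixels, n_wavenumbers); ``coords`` is
    (n_pixels, 2) integer (row, col) grid indices, 0-based row-major.
    ``meta`` carries at least biopsy_id, patient_id and histo_label
    (NT / LG / HG / T for tumor without grading).
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    coords: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D pixel x wavenumber matrix")
        if self.intensities.shape[1] != len(self.axis):
            raise ValueError(
                f"intensity row length {self.intensities.shape[1]} does not "
                f"match axis length {len(self.axis)}"
            )
        if self.coords.shape != (self.intensities.shape[0], 2):
            raise ValueError("coords must be (n_pixels, 2) and match intensities")
        seen = {tuple(rc) for rc in self.coords.tolist()}
        if len(seen) != self.coords.shape[0]:
            raise ValueError("duplicate (row, col) pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def biopsy_id(self) -> str:
        return str(self.meta.get("biopsy_id", ""))

    @property
    def patient_id(self) -> str:
        return str(self.meta.get("patient_id", ""))

    @property
    def histo_label(self) -> str:
        return str(self.meta.get("histo_label", ""))

    @property
    def grid_shape(self) -> tuple[int, int]:
        return int(self.coords[:, 0].max()) + 1, int(self.coords[:, 1].max()) + 1

    def pixel(self, index: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[index])

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.axis, self.intensities.mean(axis=0))

    def with_intensities(self, intensities: np.ndarray) -> "HyperspectralMap":
        return replace(self, intensities=intensities)

    def with_axis(
        self, axis: WavenumberAxis, intensities: np.ndarray
    ) -> "HyperspectralMap":
        return replace(self, axis=axis, intensities=intensities)


# Assignment labels used by the 1.5-threshold aggregation rule.
ASSIGN_NT = "NT"
ASSIGN_TUMOR = "tumor"
ASSIGN_NONE = "unassigned"


def assignment_from_mean(mean_prediction: float) -> str:
    """Three-way label from a mean prediction value on the 1..2 code scale.

    Below 1.5 is non-tumor, above 1.5 is tumor; exactly 1.5 is left
    unassigned (the mean sits in the empty density gap between the groups).
    """
    if mean_prediction < 1.5:
        return ASSIGN_NT
    if mean_prediction > 1.5:
        return ASSIGN_TUMOR
    return ASSIGN_NONE


@dataclass
class PredictionMap:
    """Per-pixel aggregated model output for one biopsy raster."""

    coords: np.ndarray
    mean_prediction: np.ndarray
    assignment: np.ndarray  # array of ASSIGN_* strings

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.mean_prediction = np.asarray(self.mean_prediction, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=object)
        n = self.coords.shape[0]
        if self.mean_prediction.shape != (n,) or self.assignment.shape != (n,):
            raise ValueError("coords, mean_prediction and assignment lengths differ")
        expected = np.array(
            [assignment_from_mean(v) for v in self.mean_prediction], dtype=object
        )
        if not np.array_equal(expected, self.assignment):
            raise ValueError("assignment inconsistent with the 1.5 threshold rule")
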