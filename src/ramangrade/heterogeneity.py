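"""Spatial heterogeneity analysis of biopsy prediction maps.

Bladder biopsies are rarely homogeneous: tumor biopsies usually contain
adjacent non-tumor regions.  This module renders the aggregated level-1
output on the acquisition raster, quantifies tumor / non-tumor / unassigned
area fractions, maps single-band intensities (e.g. the 1265 cm^-1 collagen
amide III and 2885 cm^-1 lipid CH bands), and builds the lipid-vs-collagen
scatter that separates tumor from non-tumor point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import band_feature
from .hierarchy import AggregatedPrediction
from .types import (
    ASSIGN_NONE,
    ASSIGN_NT,
    ASSIGN_TUMOR,
    HyperspectralMap,
    PredictionMap,
)

__all__ = [
    "AreaFractionReport",
    "BandImage",
    "prediction_map",
    "area_fractions",
    "band_intensity_image",
    "lipid_collagen_scatter",
]


def prediction_map(
    biopsy: HyperspectralMap, aggregated: AggregatedPrediction
) -> PredictionMap:
    """Raster of per-pixel mean predictions and 1.5-rule assignments."""
    if aggregated.mean_prediction.size != biopsy.n_pixels:
        raise ValueError(
            f"biopsy {biopsy.biopsy_id}: {biopsy.n_pixels} pixels but "
            f"{aggregated.mean_prediction.size} aggregated predictions"
        )
    return PredictionMap(
        biopsy.coords, aggregated.mean_prediction.copy(), aggregated.assignment.copy()
    )


@dataclass
class AreaFractionReport:
    """Tumor / non-tumor / unassigned pixel-count fractions of one biopsy."""

    biopsy_id: str
    fraction_tumor: float
    fraction_nt: float
    fraction_unassigned: float
    n_pixels: int

    def __post_init__(self) -> None:
        total = self.fraction_tumor + self.fraction_nt + self.fraction_unassigned
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"area fractions sum to {total!r}, not 1")


def area_fractions(pmap: PredictionMap, biopsy_id: str = "") -> AreaFractionReport:
    """Exact pixel-count fractions per assignment class."""
    n = pmap.assignment.size
    if n == 0:
        raise ValueError("empty prediction map")
    counts = {
        label: int(np.sum(pmap.assignment == label))
        for label in (ASSIGN_TUMOR, ASSIGN_NT, ASSIGN_NONE)
    }
    return AreaFractionReport(
        biopsy_id,
        counts[ASSIGN_TUMOR] / n,
        counts[ASSIGN_NT] / n,
        counts[ASSIGN_NONE] / n,
        n,
    )


@dataclass
class BandImage:
    """Per-pixel band intensity, min-max scaled to [0, 1] per image."""

    coords: np.ndarray
    values: np.ndarray
    center: float
    half_width: float
    scaled: bool  # False when the raw image was constant and scaling failed

    def grid(self) -> np.ndarray:
        rows = int(self.coords[:, 0].max()) + 1
        cols = int(self.coords[:, 1].max()) + 1
        g = np.full((rows, cols), np.nan)
        g[self.coords[:, 0], self.coords[:, 1]] = self.values
        return g


def band_intensity_image(
    hsmap: HyperspectralMap, center: float, half_width: float = 8.0
) -> BandImage:
    """Mean intensity over the band window, min-max scaled per image.

    A constant image cannot be min-max scaled; in that case the raw values
    are returned with ``scaled=False``.
    """
    raw = band_feature(hsmap.intensities, hsmap.axis, center, half_width)
    lo, hi = float(raw.min()), float(raw.max())
    if hi > lo:
        return BandImage(hsmap.coords, (raw - lo) / (hi - lo), center, half_width, True)
    return BandImage(hsmap.coords, raw, center, half_width, False)


def lipid_collagen_scatter(
    maps: Sequence[HyperspectralMap],
    aggregated: Mapping[str, AggregatedPrediction],
    lipid_band: float = 2885.0,
    collagen_band: float = 1265.0,
    half_width: float = 8.0,
) -> pd.DataFrame:
    """Long table of scaled lipid and collagen band intensities per pixel.

    One row per scored (tumor- or NT-assigned) pixel; unassigned pixels are
    excluded.  Columns: biopsy_id, row, col, intensity_lipid,
    intensity_collagen, assignment.
    """
    frames = []
    for m in maps:
        agg = aggregated.get(m.biopsy_id)
        if agg is None:
            continue
        lip = band_intensity_image(m, lipid_band, half_width)
        col = band_intensity_image(m, collagen_band, half_width)
        scored = agg.assignment != ASSIGN_NONE
        frames.append(
            pd.DataFrame(
                {
                    "biopsy_id": m.biopsy_id,
                    "row": m.coords[scored, 0],
                    "col": m.coords[scored, 1],
                    "intensity_lipid": lip.values[scored],
                    "intensity_collagen": col.values[scored],
                    "assignment": agg.assignment[scored],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "biopsy_id",
                "row",
                "col",
                "intensity_lipid",
                "intensity_collagen",
                "assignment",
            ]
        )
    return pd.concat(frames, ignore_index=True)
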