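"""Shared fixtures: component library, small phantom cohorts, and one
session-scoped full pipeline run on the default study-sized cohort."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ramangrade import pipeline
from ramangrade import synthetic_data as sd
from ramangrade.types import HyperspectralMap


@pytest.fixture(scope="session")
def axis():
    return sd.default_axis()


@pytest.fixture(scope="session")
def library(axis):
    return sd.build_component_library(axis)


@pytest.fixture()
def clean_config():
    """Generator settings with every nuisance term switched off."""
    return sd.TissuePhantomConfig(
        baseline_amplitude_ratio=0.0,
        fiber_background_amplitude=0.0,
        dark_offset=0.0,
        noise_shot_scale=0.0,
        noise_read_sd=0.0,
        spike_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-biopsy cohort on 8x8 grids, cheap enough for unit tests."""
    cfg = sd.TissuePhantomConfig(grid_shape=(8, 8))
    return sd.generate_cohort(n_patients=6, n_biopsies=10, config=cfg, seed=11)


@dataclass
class PipelineRun:
    cohort: sd.Cohort
    processed: list[HyperspectralMap]
    extra_map: HyperspectralMap  # planted 30%-tumor biopsy, preprocessed
    extra_truth: sd.GroundTruth
    result: pipeline.TwoLevelResult


@pytest.fixture(scope="session")
def full_run() -> PipelineRun:
    """Full study-sized run: 28 patients / 48 biopsies, preprocessing, the
    50-model two-level classification, and the one-level comparison.

    An extra heterogeneous biopsy with a planted 30% tumor blob is
    preprocessed alongside the cohort (sharing the EMSC reference) and kept
    aside for the spatial-overlap checks.
    """
    seed = 1
    cohort = sd.generate_cohort(seed=seed)
    extra_raw, extra_truth = sd.generate_biopsy(
        cohort.config,
        "HG",
        rng_seed=987654,
        library=cohort.library,
        axis=cohort.maps[0].axis,
        tumor_fraction=0.30,
        biopsy_id="EXTRA",
        patient_id="PX",
    )
    from ramangrade.preprocess import run_preprocessing

    processed_all, _ = run_preprocessing(
        cohort.maps + [extra_raw], dark=cohort.dark, fiber=cohort.fiber
    )
    processed, extra_map = processed_all[:-1], processed_all[-1]
    result = pipeline.run_two_level(processed, seed=seed, include_one_level=True)
    return PipelineRun(cohort, processed, extra_map, extra_truth, result)
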