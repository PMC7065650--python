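"""End-to-end orchestration: phantom cohort -> preprocessing -> two levels.

Convenience layer tying the modules together the way the analysis is meant
to run: generate or load a cohort, preprocess every biopsy (EMSC background
correction by default), run the 50-model level-1 ensemble, select the
tumor-assigned spectra, and grade them with the level-2 ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from .hierarchy import (
    LevelResult,
    ModelConfig,
    make_cv_plan,
    run_level1,
    run_level2,
    select_tumor_spectra,
)
from .preprocess import PreprocessConfig, run_preprocessing
from .synthetic_data import Cohort
from .types import HyperspectralMap

__all__ = ["TwoLevelResult", "preprocess_cohort", "run_two_level"]


def preprocess_cohort(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> tuple[list[HyperspectralMap], list[list[dict[str, Any]]]]:
    """Run the preprocessing chain on a cohort, using its instrument
    reference spectra (dark, fiber background)."""
    return run_preprocessing(
        cohort.maps, config, dark=cohort.dark, fiber=cohort.fiber
    )


@dataclass
class TwoLevelResult:
    level1: LevelResult
    selection: dict
    selection_warnings: list[str]
    level2: LevelResult
    one_level: LevelResult | None = None


def run_two_level(
    maps: list[HyperspectralMap],
    seed: int = 0,
    model_cfg: ModelConfig | None = None,
    include_one_level: bool = False,
) -> TwoLevelResult:
    """Run the full two-level classification on preprocessed maps.

    With ``include_one_level=True`` the level-2 grading is additionally run
    on unselected whole-biopsy spectra (the classical one-level approach),
    for comparison against the tumor-selected two-level result.
    """
    model_cfg = model_cfg or ModelConfig(seed=seed)
    plan1 = make_cv_plan(
        [(m.biopsy_id, m.histo_label) for m in maps], seed=seed
    )
    level1 = run_level1(maps, plan1, model_cfg)
    selection, warnings = select_tumor_spectra(maps, level1.aggregated)
    level2 = run_level2(maps, selection, model_cfg=model_cfg)
    one_level = None
    if include_one_level:
        one_level = run_level2(maps, None, model_cfg=model_cfg)
    return TwoLevelResult(level1, selection, warnings, level2, one_level)
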