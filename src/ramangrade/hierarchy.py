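"""Two-level cross-validated inference for tumor detection and grading.

Level 1 (ML1) separates tumor from non-tumor tissue, level 2 (ML2) separates
low- from high-grade tumor — trained only on the spectra that level 1
assigned as tumor, so that non-tumor regions of heterogeneous biopsies never
contaminate the grading models.

Both levels follow the same discipline:

* each biopsy is represented by its mean-random-pixel (MRP) set — for every
  k in 1..80, the mean spectrum over k randomly drawn pixel locations;
* biopsies are partitioned into 5 folds, repeated over 10 iterations, giving
  50 train/test model instances; spectra of one biopsy never appear on both
  sides of a pair;
* every individual pixel spectrum is scored by each model whose test fold
  held its biopsy, and the hard class codes (1 / 2) are averaged: a mean
  above 1.5 means tumor, below 1.5 non-tumor, exactly 1.5 stays unassigned
  (the kernel density of biopsy mean predictions is empty around 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    PerformanceReport,
    PLSLDAModel,
    compute_performance,
    fit_plslda,
    select_n_components,
)
from .types import ASSIGN_TUMOR, HyperspectralMap, assignment_from_mean

__all__ = [
    "CVPlan",
    "MRPSet",
    "ModelConfig",
    "PredictionRecord",
    "AggregatedPrediction",
    "GapReport",
    "LevelResult",
    "build_mrp_set",
    "make_cv_plan",
    "run_level1",
    "aggregate_predictions",
    "kernel_density_gap",
    "select_tumor_spectra",
    "run_level2",
    "sweep_sampling_size",
]


# --------------------------------------------------------------------------
# MRP sampling


@dataclass
class MRPSet:
    """Mean-random-pixel representation of one biopsy: for every k in
    1..k_max, the mean spectrum over k randomly drawn pixels."""

    biopsy_id: str
    k_values: np.ndarray
    mean_spectra: np.ndarray  # (k_max, n_wavenumbers)
    draws: list[np.ndarray]  # pixel indices per k, for audit
    seed: int
    with_replacement: np.ndarray  # per k, whether the draw needed replacement


def build_mrp_set(
    hsmap: HyperspectralMap,
    k_max: int = 80,
    rng_seed: int = 0,
    pixel_subset: np.ndarray | None = None,
) -> MRPSet:
    """Draw the MRP set of a biopsy (optionally from a pixel subset).

    Pixels are drawn uniformly without replacement; when k exceeds the
    number of available pixels the draw falls back to sampling with
    replacement, recorded in the ``with_replacement`` flags.
    """
    pool = (
        np.arange(hsmap.n_pixels)
        if pixel_subset is None
        else np.asarray(pixel_subset, dtype=int)
    )
    if pool.size == 0:
        raise ValueError(f"biopsy {hsmap.biopsy_id}: no pixels to sample from")
    rng = np.random.default_rng(rng_seed)
    means = np.empty((k_max, hsmap.intensities.shape[1]))
    draws: list[np.ndarray] = []
    repl = np.zeros(k_max, dtype=bool)
    for i, k in enumerate(range(1, k_max + 1)):
        replace = k > pool.size
        idx = rng.choice(pool, size=k, replace=replace)
        means[i] = hsmap.intensities[idx].mean(axis=0)
        draws.append(idx)
        repl[i] = replace
    return MRPSet(hsmap.biopsy_id, np.arange(1, k_max + 1), means, draws, rng_seed, repl)


# --------------------------------------------------------------------------
# CV plans


@dataclass
class CVPlan:
    """Fold assignments for the 5-fold x 10-iteration two-layer scheme."""

    n_folds: int
    n_iterations: int
    assignments: list[list[list[str]]]  # [iteration][fold] -> biopsy ids
    seed: int

    def pairs(self) -> Iterator[tuple[list[str], list[str]]]:
        """Yield (train_ids, test_ids) for every of the n_folds x
        n_iterations model instances."""
        for partition in self.assignments:
            for f, test in enumerate(partition):
                train = [b for g, fold in enumerate(partition) if g != f for b in fold]
                yield train, test

    @property
    def n_pairs(self) -> int:
        return self.n_folds * self.n_iterations


def make_cv_plan(
    biopsy_table: Sequence[tuple[str, str]] | pd.DataFrame,
    n_folds: int = 5,
    n_iterations: int = 10,
    seed: int = 0,
    group_by: str = "biopsy",
) -> CVPlan:
    """Seeded, histopathology-stratified fold partitions of the biopsies.

    ``biopsy_table`` rows are (biopsy_id, histo_label) pairs (a DataFrame
    with those columns, optionally plus patient_id, also works).  With
    ``group_by="patient"`` all biopsies of one patient land in the same
    fold — the stricter grouping.
    """
    if isinstance(biopsy_table, pd.DataFrame):
        rows = list(
            biopsy_table[
                ["biopsy_id", "histo_label"]
                + (["patient_id"] if "patient_id" in biopsy_table else [])
            ].itertuples(index=False, name=None)
        )
    else:
        rows = [tuple(r) for r in biopsy_table]
    by_class: dict[str, list[tuple]] = {}
    for r in rows:
        by_class.setdefault(r[1], []).append(r)
    for label, members in by_class.items():
        if len(members) < n_folds:
            raise ValueError(
                f"too few biopsies: class {label!r} has {len(members)} < "
                f"{n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    assignments: list[list[list[str]]] = []
    for _ in range(n_iterations):
        folds: list[list[str]] = [[] for _ in range(n_folds)]
        if group_by == "patient":
            patients: dict[str, list[tuple]] = {}
            for r in rows:
                patients.setdefault(r[2] if len(r) > 2 else r[0], []).append(r)
            keys = sorted(patients)
            rng.shuffle(keys)
            for i, key in enumerate(keys):
                folds[i % n_folds].extend(b for b, *_ in patients[key])
        else:
            offset = int(rng.integers(n_folds))
            for label in sorted(by_class):
                members = [b for b, *_ in by_class[label]]
                rng.shuffle(members)
                for i, b in enumerate(members):
                    folds[(i + offset) % n_folds].append(b)
                offset += len(members) % n_folds
        assignments.append(folds)
    return CVPlan(n_folds, n_iterations, assignments, seed)


# --------------------------------------------------------------------------
# prediction records and aggregation


@dataclass
class PredictionRecord:
    """Hard class codes assigned by one model to every pixel spectrum of one
    (held-out) biopsy."""

    biopsy_id: str
    model_index: int
    codes: np.ndarray  # (n_pixels,)


@dataclass
class AggregatedPrediction:
    """Per-pixel mean of ensemble class codes with the 1.5-rule labels."""

    biopsy_id: str
    mean_prediction: np.ndarray
    assignment: np.ndarray
    n_models: int


def aggregate_predictions(
    records: Sequence[PredictionRecord],
) -> dict[str, AggregatedPrediction]:
    """Average hard class codes per pixel spectrum and apply the 1.5 rule."""
    if not records:
        raise ValueError("no prediction records to aggregate")
    grouped: dict[str, list[PredictionRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.biopsy_id, []).append(rec)
    out: dict[str, AggregatedPrediction] = {}
    for biopsy_id, recs in grouped.items():
        lengths = {rec.codes.size for rec in recs}
        if len(lengths) != 1:
            raise ValueError(f"biopsy {biopsy_id}: inconsistent record lengths")
        stack = np.vstack([rec.codes for rec in recs]).astype(float)
        mean = stack.mean(axis=0)
        assignment = np.array([assignment_from_mean(v) for v in mean], dtype=object)
        out[biopsy_id] = AggregatedPrediction(biopsy_id, mean, assignment, len(recs))
    return out


# --------------------------------------------------------------------------
# kernel density gap around the 1.5 threshold


@dataclass
class GapReport:
    bandwidth: float
    density_at_threshold: float
    density_max: float
    gap_interval: tuple[float, float] | None  # widest low-density span around 1.5


def kernel_density_gap(
    biopsy_mean_predictions: Sequence[float],
    bandwidth: float | None = None,
    tol: float = 1e-3,
    threshold: float = 1.5,
) -> GapReport:
    """Gaussian-kernel density of biopsy mean predictions over [1, 2].

    Reports the density at the 1.5 decision threshold and the widest
    interval around it whose density stays below ``tol`` times the density
    maximum — the empty region that justifies leaving spectra with a mean
    prediction of exactly 1.5 unassigned.  Bandwidth defaults to Silverman's
    rule (with a small floor for degenerate samples).
    """
    x = np.asarray(biopsy_mean_predictions, dtype=float)
    if x.size < 5:
        raise ValueError("kernel density gap needs at least 5 biopsies")
    if bandwidth is None:
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * x.size ** (-0.2)
    bandwidth = max(float(bandwidth), 1e-4)

    def density(points: np.ndarray) -> np.ndarray:
        z = (points[:, None] - x[None, :]) / bandwidth
        return np.exp(-0.5 * z**2).mean(axis=1) / (bandwidth * np.sqrt(2 * np.pi))

    grid = np.linspace(1.0, 2.0, 501)
    dens = density(grid)
    d_max = float(dens.max())
    d_thr = float(density(np.array([threshold]))[0])
    low = dens <= tol * d_max
    i_thr = int(np.argmin(np.abs(grid - threshold)))
    gap: tuple[float, float] | None = None
    if low[i_thr]:
        lo = i_thr
        while lo > 0 and low[lo - 1]:
            lo -= 1
        hi = i_thr
        while hi < grid.size - 1 and low[hi + 1]:
            hi += 1
        gap = (float(grid[lo]), float(grid[hi]))
    return GapReport(bandwidth, d_thr, d_max, gap)


# --------------------------------------------------------------------------
# level runners


@dataclass
class ModelConfig:
    """Settings shared by the level-1 and level-2 model ensembles."""

    n_components: int = 8
    select_components: bool = True
    max_components: int = 12
    k_mrp: int = 80
    seed: int = 0


@dataclass
class LevelResult:
    models: list[PLSLDAModel]
    pair_info: list[dict[str, Any]]
    records: list[PredictionRecord]
    aggregated: dict[str, AggregatedPrediction]
    biopsy_truth: list[str]
    biopsy_predicted: list[str]
    performance: PerformanceReport
    skipped_pairs: list[dict[str, Any]] = field(default_factory=list)

    def biopsy_table(self) -> pd.DataFrame:
        return pd.DataFrame({"truth": self.biopsy_truth, "predicted": self.biopsy_predicted})


def _run_level(
    maps: Sequence[HyperspectralMap],
    plan: CVPlan,
    codes: Mapping[str, int],
    labels: tuple[str, str],
    model_cfg: ModelConfig,
    pixel_subsets: Mapping[str, np.ndarray] | None = None,
    positive_class: str | None = None,
) -> LevelResult:
    by_id = {m.biopsy_id: m for m in maps}
    mrp = {
        bid: build_mrp_set(
            m,
            k_max=model_cfg.k_mrp,
            rng_seed=(model_cfg.seed * 1000003 + i) % (2**31 - 1),
            pixel_subset=None if pixel_subsets is None else pixel_subsets[bid],
        )
        for i, (bid, m) in enumerate(sorted(by_id.items()))
    }
    axis = maps[0].axis

    models: list[PLSLDAModel] = []
    pair_info: list[dict[str, Any]] = []
    records: list[PredictionRecord] = []
    truth: list[str] = []
    predicted: list[str] = []
    skipped: list[dict[str, Any]] = []

    for pair_idx, (train_ids, test_ids) in enumerate(plan.pairs()):
        train_codes = np.array([codes[b] for b in train_ids])
        if np.unique(train_codes).size < 2 or len(
            {codes[b] for b in test_ids}
        ) < 1:
            skipped.append({"pair": pair_idx, "reason": "single-class training fold"})
            continue
        X = np.vstack([mrp[b].mean_spectra for b in train_ids])
        y = np.repeat(train_codes, model_cfg.k_mrp)
        if model_cfg.select_components:
            # leave-one-biopsy-out on the biopsy mean spectra: cheap and
            # leakage-free proxy for per-spectrum LOOCV
            Xb = np.vstack([mrp[b].mean_spectra.mean(axis=0) for b in train_ids])
            k = select_n_components(
                Xb, train_codes.astype(float), model_cfg.max_components
            )
        else:
            k = model_cfg.n_components
        model = fit_plslda(
            X,
            y,
            k,
            axis=axis,
            class_labels=labels,
            fingerprint={"pair": pair_idx, "seed": model_cfg.seed, "n_components": k},
        )
        models.append(model)
        pair_info.append(
            {"pair": pair_idx, "train": list(train_ids), "test": list(test_ids), "n_components": k}
        )
        for bid in test_ids:
            pixel_pool = (
                np.arange(by_id[bid].n_pixels)
                if pixel_subsets is None
                else pixel_subsets[bid]
            )
            px_codes = model.predict_codes(by_id[bid].intensities[pixel_pool])
            records.append(PredictionRecord(bid, pair_idx, px_codes))
            mean_code = float(model.predict_codes(mrp[bid].mean_spectra).mean())
            predicted.append(labels[1] if mean_code > 1.5 else labels[0])
            truth.append(labels[1] if codes[bid] == 2 else labels[0])

    if not models:
        raise ValueError("every train/test pair was skipped; cannot fit the level")
    aggregated = aggregate_predictions(records)
    performance = compute_performance(
        truth, predicted, positive_class=positive_class or labels[1]
    )
    return LevelResult(models, pair_info, records, aggregated, truth, predicted, performance, skipped)


def run_level1(
    maps: Sequence[HyperspectralMap],
    plan: CVPlan | None = None,
    model_cfg: ModelConfig | None = None,
) -> LevelResult:
    """Train and validate the 50-model tumor vs non-tumor ensemble (ML1).

    Every biopsy with a tumor histopathology label (low-grade, high-grade or
    ungraded "T") is coded 2, non-tumor 1.  Each model is trained on the MRP
    sets of its training biopsies and scores every individual pixel spectrum
    of its held-out biopsies; those records feed the 1.5-rule aggregation.
    Biopsy-level performance counts one prediction per held-out biopsy per
    model instance (the majority over its MRP spectra).
    """
    model_cfg = model_cfg or ModelConfig()
    codes = {m.biopsy_id: (1 if m.histo_label == "NT" else 2) for m in maps}
    if plan is None:
        plan = make_cv_plan(
            [(m.biopsy_id, m.histo_label) for m in maps], seed=model_cfg.seed
        )
    return _run_level(maps, plan, codes, ("NT", "tumor"), model_cfg)


def select_tumor_spectra(
    maps: Sequence[HyperspectralMap],
    aggregated: Mapping[str, AggregatedPrediction],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Pixel indices assigned as tumor by the aggregated level-1 output.

    Only spectra with a mean prediction strictly above 1.5 pass; unassigned
    (exactly 1.5) spectra never do.  Graded tumor biopsies that end up with
    zero tumor-assigned spectra are dropped with a logged warning.
    """
    selection: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for m in maps:
        agg = aggregated.get(m.biopsy_id)
        if agg is None:
            continue
        idx = np.nonzero(agg.assignment == ASSIGN_TUMOR)[0]
        if idx.size == 0:
            if m.histo_label in ("LG", "HG", "T"):
                warnings.append(
                    f"biopsy {m.biopsy_id} ({m.histo_label}): no tumor-assigned "
                    "spectra; excluded from level 2"
                )
            continue
        selection[m.biopsy_id] = idx
    return selection, warnings


def run_level2(
    maps: Sequence[HyperspectralMap],
    selection: Mapping[str, np.ndarray] | None = None,
    plan: CVPlan | None = None,
    model_cfg: ModelConfig | None = None,
) -> LevelResult:
    """Train and validate the low- vs high-grade ensemble (ML2).

    ``maps`` must be the graded tumor biopsies (histo label LG or HG);
    ``selection`` maps biopsy ids to the pixel indices level 1 assigned as
    tumor — passing ``None`` uses all pixels, which is exactly the one-level
    grading approach the two-level scheme improves on.
    """
    model_cfg = model_cfg or ModelConfig()
    graded = [m for m in maps if m.histo_label in ("LG", "HG")]
    if selection is not None:
        graded = [m for m in graded if m.biopsy_id in selection]
    grades = {m.histo_label for m in graded}
    if grades != {"LG", "HG"}:
        raise ValueError(f"level 2 needs both grades present, got {sorted(grades)}")
    codes = {m.biopsy_id: (1 if m.histo_label == "LG" else 2) for m in graded}
    if plan is None:
        plan = make_cv_plan(
            [(m.biopsy_id, m.histo_label) for m in graded], seed=model_cfg.seed + 1
        )
    subsets = None if selection is None else {b: selection[b] for b in codes}
    return _run_level(
        graded, plan, codes, ("LG", "HG"), model_cfg, pixel_subsets=subsets,
        positive_class="HG",
    )


# --------------------------------------------------------------------------
# sampling-size sweep


def sweep_sampling_size(
    hsmap: HyperspectralMap,
    models: Sequence[PLSLDAModel],
    k_values: Iterable[int] = range(1, 81),
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Tumor-area fraction vs the number of randomly sampled spectra.

    For each k, ``n_repeats`` random draws of k pixels are scored by the
    ensemble (per-pixel mean code, 1.5 rule) and the tumor-assigned fraction
    of the draw is summarized as mean +- SD — the stability analysis of the
    sampling size.
    """
    rng = np.random.default_rng(seed)
    n_px = hsmap.n_pixels
    rows = []
    for k in k_values:
        fractions = np.empty(n_repeats)
        for r in range(n_repeats):
            idx = rng.choice(n_px, size=k, replace=k > n_px)
            codes = np.vstack([m.predict_codes(hsmap.intensities[idx]) for m in models])
            mean = codes.mean(axis=0)
            assigned_tumor = mean > 1.5
            fractions[r] = assigned_tumor.mean()
        rows.append(
            {
                "k": int(k),
                "mean_tumor_fraction": float(fractions.mean()),
                "sd_tumor_fraction": float(fractions.std(ddof=0)) if n_repeats > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
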