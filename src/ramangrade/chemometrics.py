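"""PLS-LDA chemometrics for two-class Raman tissue discrimination.

The classifier chains partial least squares (PLS) regression of the spectra
on numeric class codes (non-tumor = 1, tumor = 2; low-grade = 1, high-grade
= 2) with linear discriminant analysis (LDA) on the latent-variable scores.
PLS acts as a supervised dimension reduction that copes with the large
variable-to-sample ratio of spectral data; the LDA direction back-projected
through the PLS rotation yields a wavenumber-domain coefficient spectrum
whose signs localize the bands driving the separation (negative = class 1,
positive = class 2 under the coding above).

The PLS1 core is a NIPALS implementation kept deliberately explicit so that
leave-one-out predictions for *all* candidate component counts come from a
single decomposition per left-out sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .types import HyperspectralMap, Spectrum, WavenumberAxis

__all__ = [
    "PLS1",
    "PLSLDAModel",
    "PerformanceReport",
    "fit_pls1",
    "select_n_components",
    "fit_plslda",
    "predict_class_code",
    "two_band_classifier",
    "band_feature",
    "compute_performance",
    "clopper_pearson",
]

FORMAT_VERSION = 1


@dataclass
class PLS1:
    """NIPALS partial least squares with a univariate response.

    Attributes hold the centered-model quantities: weights ``W`` (p, k),
    loadings ``P`` (p, k), response loadings ``q`` (k,), and the training
    scores ``T`` (n, k).  ``coef(a)`` returns the regression vector using
    the first ``a`` latent variables, so one fit serves every candidate
    component count.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def rotation(self, a: int | None = None) -> np.ndarray:
        """R such that scores = X_centered @ R (first ``a`` components)."""
        a = a or self.n_components
        W, P = self.W[:, :a], self.P[:, :a]
        return W @ np.linalg.inv(P.T @ W)

    def coef(self, a: int | None = None) -> np.ndarray:
        a = a or self.n_components
        return self.rotation(a) @ self.q[:a]

    def scores(self, X: np.ndarray, a: int | None = None) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.rotation(a)

    def predict(self, X: np.ndarray, a: int | None = None) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.coef(a) + self.y_mean


def fit_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> PLS1:
    """Fit PLS1 by NIPALS (deflating X only, as is standard for PLS1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    k = min(n_components, n - 1, p)
    if k < 1:
        raise ValueError("need at least one extractable latent variable")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    for a in range(k):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # response variance exhausted
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p_load = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
    return PLS1(x_mean, y_mean, W, P, q, T)


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
) -> int:
    """Pick the PLS component count by leave-one-out cross-validation.

    For every candidate count the LOO predictions are scored by their
    root-mean-squared error and their correlation with the response.  Among
    the candidates whose mean squared error lies within one standard error
    of the best, the one with the highest correlation wins, with remaining
    ties resolved toward the smallest count (the most parsimonious model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    if np.unique(y).size < 2:
        raise ValueError("response is degenerate (single class)")
    if max_components >= n:
        raise ValueError("max_components must be smaller than the sample count")
    k_max = max(1, min(max_components, n - 2, X.shape[1]))
    preds = np.full((n, k_max), np.nan)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_pls1(X[keep], y[keep], k_max)
        for a in range(1, model.n_components + 1):
            preds[i, a - 1] = model.predict(X[i : i + 1], a)[0]
        # if deflation exhausted early, reuse the largest available count
        for a in range(model.n_components, k_max):
            preds[i, a] = preds[i, model.n_components - 1]
    sq_err = (preds - y[:, None]) ** 2
    mse = sq_err.mean(axis=0)
    se = sq_err.std(axis=0, ddof=1) / np.sqrt(n)
    best = int(np.argmin(mse))
    within = np.nonzero(mse <= mse[best] + se[best])[0]
    corr = np.array(
        [
            np.corrcoef(preds[:, a], y)[0, 1] if np.std(preds[:, a]) > 1e-12 else -1.0
            for a in within
        ]
    )
    top = corr.max()
    eligible = within[corr >= top - 1e-9]
    return int(eligible.min()) + 1


@dataclass
class PLSLDAModel:
    """Fitted PLS-LDA classifier with its wavenumber-domain footprint.

    ``coefficient_spectrum`` is the LDA direction mapped back through the
    PLS rotation; the hard decision is
    ``code = 2 if coefficient_spectrum . (x - x_mean) + intercept > 0 else 1``
    with exact zeros broken toward the lower code.
    """

    n_components: int
    axis_values: np.ndarray
    x_mean: np.ndarray
    pls_weights: np.ndarray
    pls_loadings: np.ndarray
    rotation: np.ndarray
    lda_direction: np.ndarray
    lda_intercept: float
    coefficient_spectrum: np.ndarray
    class_codes: tuple[int, int] = (1, 2)
    class_labels: tuple[str, str] = ("NT", "tumor")
    training_fingerprint: dict[str, Any] = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.axis_values.size:
            raise ValueError(
                f"spectra have {X.shape[1]} channels, model expects "
                f"{self.axis_values.size}"
            )
        return (X - self.x_mean) @ self.coefficient_spectrum + self.lda_intercept

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        lo, hi = self.class_codes
        return np.where(d > 0, hi, lo)  # d == 0 ties to the lower code

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        codes = self.predict_codes(X)
        return np.where(codes == self.class_codes[1], self.class_labels[1], self.class_labels[0]).astype(object)


def fit_plslda(
    X: np.ndarray,
    y: Sequence[int],
    n_components: int,
    axis: WavenumberAxis | np.ndarray | None = None,
    class_labels: tuple[str, str] = ("NT", "tumor"),
    fingerprint: dict[str, Any] | None = None,
) -> PLSLDAModel:
    """Fit the two-class PLS-LDA model on spectra ``X`` with codes ``y``.

    The PLS stage regresses the spectra on the numeric codes; the LDA stage
    is fitted on the latent-variable scores.  If the within-class scatter of
    the scores is singular the LDA fit falls back to a shrinkage-stabilized
    eigen solver, which is recorded in the training fingerprint.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    codes = tuple(sorted(np.unique(y).tolist()))
    if len(codes) != 2:
        raise ValueError(f"need exactly two classes, got codes {codes}")
    pls = fit_pls1(X, y.astype(float), n_components)
    k = pls.n_components
    R = pls.rotation()
    T = pls.T  # training scores (centered X @ R)
    fingerprint = dict(fingerprint or {})
    # balanced priors: per-spectrum assignment must not inherit the cohort's
    # biopsy class imbalance
    priors = np.array([0.5, 0.5])
    lda = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    lda.fit(T, y)
    if not np.all(np.isfinite(lda.coef_)):
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6, priors=priors)
        lda.fit(T, y)
        fingerprint["lda_solver"] = "eigen+shrinkage=1e-6"
    a = lda.coef_.ravel()  # positive decision -> lda.classes_[1] == higher code
    b = float(lda.intercept_[0])
    coef_spectrum = R @ a
    if axis is None:
        axis_values = np.arange(X.shape[1], dtype=float)
    elif isinstance(axis, WavenumberAxis):
        axis_values = axis.values
    else:
        axis_values = np.asarray(axis, dtype=float)
    return PLSLDAModel(
        n_components=k,
        axis_values=axis_values,
        x_mean=pls.x_mean,
        pls_weights=pls.W,
        pls_loadings=pls.P,
        rotation=R,
        lda_direction=a,
        lda_intercept=b,
        coefficient_spectrum=coef_spectrum,
        class_codes=(int(codes[0]), int(codes[1])),
        class_labels=class_labels,
        training_fingerprint=fingerprint,
    )


def predict_class_code(model: PLSLDAModel, spectra: np.ndarray | Spectrum) -> np.ndarray:
    """Hard class codes for one or more spectra on the model's axis."""
    if isinstance(spectra, Spectrum):
        if not np.array_equal(spectra.axis.values, model.axis_values):
            raise ValueError("spectrum axis does not match the model axis")
        return model.predict_codes(spectra.intensity[None, :])
    return model.predict_codes(spectra)


def band_feature(
    X: np.ndarray, axis: WavenumberAxis, center: float, half_width: float = 8.0
) -> np.ndarray:
    """Mean intensity over the +-half_width window around a band center."""
    mask = axis.window(center - half_width, center + half_width)
    if not mask.any():
        raise ValueError(f"band at {center:g} cm-1 lies outside the axis")
    return np.atleast_2d(X)[:, mask].mean(axis=1)


def two_band_classifier(
    maps: Sequence[HyperspectralMap],
    band1: float = 1305.0,
    band2: float = 2850.0,
    half_width: float = 8.0,
    n_folds: int = 5,
    n_iterations: int = 10,
    k_mrp: int = 80,
    seed: int = 0,
):
    """Tumor vs non-tumor LDA on two band intensities only.

    Uses the collagen-region band at 1305 cm^-1 and the lipid CH2 band at
    2850 cm^-1 by default.  Each biopsy is represented by its mean-random-
    pixel spectra reduced to the two band means; validation follows the same
    biopsy-grouped 5-fold x 10-iteration scheme as the full model, and the
    returned report scores held-out biopsy assignments.
    """
    from .hierarchy import build_mrp_set, make_cv_plan  # runtime import: avoids cycle

    axis = maps[0].axis
    feats: dict[str, np.ndarray] = {}
    codes: dict[str, int] = {}
    for i, m in enumerate(maps):
        mrp = build_mrp_set(m, k_max=k_mrp, rng_seed=seed * 100003 + i)
        M = mrp.mean_spectra
        f = np.column_stack(
            [band_feature(M, axis, band1, half_width), band_feature(M, axis, band2, half_width)]
        )
        feats[m.biopsy_id] = f
        codes[m.biopsy_id] = 1 if m.histo_label == "NT" else 2

    table = [(m.biopsy_id, m.histo_label) for m in maps]
    plan = make_cv_plan(table, n_folds=n_folds, n_iterations=n_iterations, seed=seed)

    truth: list[str] = []
    predicted: list[str] = []
    for train_ids, test_ids in plan.pairs():
        Xtr = np.vstack([feats[b] for b in train_ids])
        ytr = np.concatenate([[codes[b]] * len(feats[b]) for b in train_ids])
        lda = LinearDiscriminantAnalysis(solver="svd").fit(Xtr, ytr)
        for b in test_ids:
            mean_code = float(lda.predict(feats[b]).mean())
            predicted.append("tumor" if mean_code > 1.5 else "NT")
            truth.append("NT" if codes[b] == 1 else "tumor")

    report = compute_performance(truth, predicted, positive_class="tumor")
    X_all = np.vstack([feats[b] for b, _ in table])
    y_all = np.concatenate([[codes[b]] * len(feats[b]) for b, _ in table])
    final = LinearDiscriminantAnalysis(solver="svd").fit(X_all, y_all)
    return final, report


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if n == 0:
        raise ValueError("empty sample")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class PerformanceReport:
    """Two-class confusion counts and derived rates (percent)."""

    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def accuracy_ci(self) -> tuple[float, float]:
        lo, hi = clopper_pearson(self.tp + self.tn, self.n)
        return 100.0 * lo, 100.0 * hi

    def to_dict(self) -> dict[str, Any]:
        lo, hi = self.accuracy_ci
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "positive_class": self.positive_class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "accuracy_ci": [lo, hi],
        }

    def to_text(self) -> str:
        lo, hi = self.accuracy_ci
        return (
            f"Sensitivity          {self.sensitivity:5.1f} %\n"
            f"Specificity          {self.specificity:5.1f} %\n"
            f"Accuracy             {self.accuracy:5.1f} %\n"
            f"Confidence interval  ({lo:.1f}-{hi:.1f})\n"
        )


def compute_performance(
    truth: Sequence[str],
    predicted: Sequence[str],
    positive_class: str,
) -> PerformanceReport:
    """Confusion counts and rates, with a Clopper-Pearson 95% accuracy CI."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    if not truth:
        raise ValueError("empty input")
    pos = positive_class
    tp = sum(1 for t, p in zip(truth, predicted) if t == pos and p == pos)
    fn = sum(1 for t, p in zip(truth, predicted) if t == pos and p != pos)
    tn = sum(1 for t, p in zip(truth, predicted) if t != pos and p != pos)
    fp = sum(1 for t, p in zip(truth, predicted) if t != pos and p == pos)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one sample of each class")
    return PerformanceReport(tp, fn, tn, fp, positive_class=pos)
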