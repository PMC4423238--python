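"""Diagnostic evaluation: ROC/AUC, per-band t-tests, difference spectra.

The ROC curve is built from pooled held-out LOOCV discriminant scores; its
AUC (trapezoid rule) equals the probability that a random cancer spectrum
outscores a random normal spectrum, with ties half-credited.

Band intensity comparisons use the classical pooled-variance (Student)
unpaired two-sided t-test on per-spectrum band means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .lda import CVResult
from .spectra import LABEL_CANCER, LABEL_NORMAL, SpectraSet, Spectrum


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC must run from (0,0) to (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC over all distinct score thresholds; AUC by trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == LABEL_CANCER
    neg = labels == LABEL_NORMAL
    if not np.all(pos | neg):
        bad = sorted({str(v) for v in labels[~(pos | neg)]})
        raise ValueError(f"unknown labels {bad}")
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def roc_from_cv(cv: CVResult) -> ROCResult:
    return roc_curve(cv.scores, cv.y_true)


def band_ttest(
    data: SpectraSet, lo: float, hi: float
) -> tuple[int, float, float]:
    """Pooled-variance two-sided t-test of band intensity between classes.

    The per-spectrum band intensity is the mean intensity over the grid
    variables inside the closed interval [lo, hi].  Returns
    ``(sign, t, p)`` with ``sign = sign(mean_cancer - mean_normal)``.
    """
    data.require_two_classes()
    mask = (data.grid.values >= lo) & (data.grid.values <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] does not overlap the grid")
    band = data.matrix[:, mask].mean(axis=1)
    a = band[data.labels == LABEL_CANCER]
    b = band[data.labels == LABEL_NORMAL]
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs >=2 samples per class")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0, 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return int(np.sign(a.mean() - b.mean())), float(t), float(p)


def band_table(data: SpectraSet, bands) -> list[dict]:
    """Per-band sign/t/p report for a list of (lo, hi) wavenumber intervals."""
    rows = []
    for lo, hi in bands:
        sign, t, p = band_ttest(data, lo, hi)
        rows.append({
            "band_lo": float(lo),
            "band_hi": float(hi),
            "direction": "+" if sign > 0 else "-" if sign < 0 else "0",
            "t": t,
            "p_value": p,
        })
    return rows


def difference_spectrum(data: SpectraSet) -> Spectrum:
    """Pointwise mean(cancer) - mean(normal)."""
    data.require_two_classes()
    diff = (data.class_matrix(LABEL_CANCER).mean(axis=0)
            - data.class_matrix(LABEL_NORMAL).mean(axis=0))
    return Spectrum(grid=data.grid, intensities=diff, label=None,
                    sample_id="difference_cancer_minus_normal")
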