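"""Two-class Fisher linear discriminant, LOOCV, metrics, and PCA-LDA.

The discriminant weight is ``w ∝ (S_w + λI)^{-1}(μ_cancer − μ_normal)`` with
``S_w`` the pooled within-class scatter; the decision threshold is the
midpoint of the projected class means (equal priors), oriented so the cancer
class scores higher.  A sample exactly at the threshold is called normal
(conservative for a screening positive).

``loocv`` refits the discriminant with each spectrum held out, scoring only
that spectrum.  Scatter matrices are downdated per fold and all fold systems
are solved in one batched call, so leave-one-out over ~100 spectra and a few
dozen variables costs about one matrix solve per sample — fast enough to sit
inside a genetic-algorithm fitness function.

PCA (centering only, no variance scaling) is fitted once on the full matrix
by default, mirroring the common chemometric workflow; per-fold refitting is
available via ``refit_per_fold`` and removes the selection-bias caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .spectra import LABEL_CANCER, LABEL_NORMAL

#: default ridge rule: lambda = RIDGE_SCALE * trace(S_w) / p
RIDGE_SCALE = 1e-8


@dataclass
class LDAModel:
    weights: np.ndarray
    threshold: float
    mean_cancer: np.ndarray
    mean_normal: np.ndarray

    def __post_init__(self) -> None:
        # orientation invariant: cancer projects above normal
        if float(self.weights @ self.mean_cancer) <= float(self.weights @ self.mean_normal):
            raise ValueError("LDA model mis-oriented: cancer must score higher")


@dataclass
class CVResult:
    """Per-sample held-out discriminant scores and predictions."""

    ids: np.ndarray
    y_true: np.ndarray  # label strings
    scores: np.ndarray  # held-out discriminant score minus fold threshold
    y_pred: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


@dataclass
class Metrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _masks(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=object)
    pos = y == LABEL_CANCER
    neg = y == LABEL_NORMAL
    if not np.all(pos | neg):
        bad = sorted({str(v) for v in y[~(pos | neg)]})
        raise ValueError(f"unknown labels {bad}")
    return pos, neg


def _ridge_value(ridge, trace: float, p: int) -> float:
    if ridge == "auto":
        return RIDGE_SCALE * trace / p
    return float(ridge)


def fit_lda(X: np.ndarray, y: np.ndarray, ridge="auto") -> LDAModel:
    """Fit the two-class Fisher discriminant.

    ``ridge`` is either "auto" (1e-8 * trace(S_w)/p, the default stabilizer)
    or an explicit non-negative scalar; pass 0 for the exact Fisher solution
    on well-conditioned data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be n x p with p >= 1")
    pos, neg = _masks(y)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError(
            f"need >=2 samples per class, got cancer={int(pos.sum())}, "
            f"normal={int(neg.sum())}"
        )
    mu_p = X[pos].mean(axis=0)
    mu_n = X[neg].mean(axis=0)
    Dp = X[pos] - mu_p
    Dn = X[neg] - mu_n
    Sw = Dp.T @ Dp + Dn.T @ Dn
    p = X.shape[1]
    lam = _ridge_value(ridge, float(np.trace(Sw)), p)
    try:
        w = np.linalg.solve(Sw + lam * np.eye(p), mu_p - mu_n)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class scatter; use the ridge stabilizer (ridge='auto')"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite LDA weights; increase ridge")
    if float(w @ (mu_p - mu_n)) < 0:  # enforce orientation under indefinite solves
        w = -w
    threshold = 0.5 * float(w @ mu_p + w @ mu_n)
    return LDAModel(weights=w, threshold=threshold, mean_cancer=mu_p, mean_normal=mu_n)


def predict(model: LDAModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discriminant scores and labels for one sample or a matrix of samples.

    Label is cancer iff score > threshold; an exact tie is called normal.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.size:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} variables, model expects "
            f"{model.weights.size}"
        )
    scores = x @ model.weights
    labels = np.where(scores > model.threshold, LABEL_CANCER, LABEL_NORMAL).astype(object)
    return scores, labels


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    variables: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    ridge="auto",
) -> CVResult:
    """Leave-one-spectrum-out cross-validated LDA.

    ``variables`` restricts the feature space (applied before every fold's
    fit).  Reported scores are centred on each fold's threshold so that
    score > 0 <=> cancer call across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if variables is not None:
        X = X[:, np.asarray(variables, dtype=int)]
    n, p = X.shape
    if ids is None:
        ids = np.array([str(i) for i in range(n)], dtype=object)
    pos, neg = _masks(y)
    n_p, n_n = int(pos.sum()), int(neg.sum())
    for count, name in ((n_p, LABEL_CANCER), (n_n, LABEL_NORMAL)):
        if count < 3:
            raise ValueError(
                f"class {name!r} has {count} samples; LOOCV needs >=3 so every "
                "training fold keeps >=2"
            )

    mu_p = X[pos].mean(axis=0)
    mu_n = X[neg].mean(axis=0)
    Dp = X[pos] - mu_p
    Dn = X[neg] - mu_n
    Sw = Dp.T @ Dp + Dn.T @ Dn

    # Per-fold downdate: removing x_i from class c updates that class's
    # scatter by -(n_c/(n_c-1)) d d^T with d = x_i - mu_c, and its mean to
    # (n_c mu_c - x_i)/(n_c - 1).
    d = np.where(pos[:, None], X - mu_p, X - mu_n)
    n_own = np.where(pos, n_p, n_n).astype(float)
    factor = n_own / (n_own - 1.0)
    corr = factor[:, None, None] * d[:, :, None] * d[:, None, :]
    Sw_folds = Sw[None, :, :] - corr

    mu_p_folds = np.where(
        pos[:, None], (n_p * mu_p[None, :] - X) / (n_p - 1), mu_p[None, :]
    )
    mu_n_folds = np.where(
        neg[:, None], (n_n * mu_n[None, :] - X) / (n_n - 1), mu_n[None, :]
    )
    diff = mu_p_folds - mu_n_folds

    if ridge == "auto":
        lam = RIDGE_SCALE * np.trace(Sw_folds, axis1=1, axis2=2) / p
    else:
        lam = np.full(n, float(ridge))
    systems = Sw_folds + lam[:, None, None] * np.eye(p)[None, :, :]
    try:
        # batched solve unless the per-fold matrices would be huge
        if n * p * p <= 5_000_000:
            w = np.linalg.solve(systems, diff[:, :, None])[:, :, 0]
        else:
            w = np.stack([np.linalg.solve(systems[i], diff[i]) for i in range(n)])
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class scatter in a LOOCV fold; use ridge='auto'"
        ) from exc
    # orient every fold so cancer scores higher
    flip = np.einsum("ij,ij->i", w, diff) < 0
    w[flip] *= -1.0
    thresholds = 0.5 * (
        np.einsum("ij,ij->i", w, mu_p_folds) + np.einsum("ij,ij->i", w, mu_n_folds)
    )
    raw = np.einsum("ij,ij->i", w, X)
    scores = raw - thresholds
    y_pred = np.where(scores > 0, LABEL_CANCER, LABEL_NORMAL).astype(object)
    return CVResult(ids=np.asarray(ids, dtype=object), y_true=y, scores=scores, y_pred=y_pred)


def compute_metrics(cv: CVResult) -> Metrics:
    """Confusion counts and sensitivity/specificity/accuracy (cancer = positive)."""
    pos, neg = _masks(cv.y_true)
    pred_pos = cv.y_pred == LABEL_CANCER
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("metrics need both classes present")
    return Metrics(
        tp=int(np.sum(pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(neg & ~pred_pos)),
        fp=int(np.sum(neg & pred_pos)),
    )


def pca_scores(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean-centred PCA scores and explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components={n_components} out of range [1, {limit}] for {n}x{p} data"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def pca_lda_loocv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 20,
    ids: np.ndarray | None = None,
    ridge="auto",
    refit_per_fold: bool = False,
) -> CVResult:
    """PCA dimensionality reduction followed by LOOCV-LDA in component space.

    By default PCA is fitted once on the full matrix (the common chemometric
    shortcut; optimistically biased because held-out spectra contribute to
    the components).  ``refit_per_fold=True`` refits PCA inside every fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    if ids is None:
        ids = np.array([str(i) for i in range(n)], dtype=object)
    if not refit_per_fold:
        scores, _ = pca_scores(X, n_components)
        return loocv(scores, y, ids=ids, ridge=ridge)
    out_scores = np.empty(n)
    out_pred = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pca = PCA(n_components=n_components, svd_solver="full")
        Z_train = pca.fit_transform(X[mask])
        model = fit_lda(Z_train, y[mask], ridge=ridge)
        z = pca.transform(X[i][None, :])
        s, lab = predict(model, z)
        out_scores[i] = float(s[0]) - model.threshold
        out_pred[i] = lab[0]
    return CVResult(ids=np.asarray(ids, dtype=object), y_true=y,
                    scores=out_scores, y_pred=out_pred)
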