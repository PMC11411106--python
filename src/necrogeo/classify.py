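"""Sample-origin classification from similarity-matrix ordinations.

The classifier is a binary lasso-penalized logistic regression fit on all
ordination axes of the pairwise similarity matrix: the L1 penalty performs
the axis selection, the penalty strength is chosen by stratified K-fold
cross-validated deviance over a log-spaced grid descending from the
analytic lambda_max (the smallest penalty that zeroes every coefficient).
Coefficients are estimated on standardized features with an unpenalized
intercept, i.e. the glmnet parameterisation

    min_(b0, b)  (1/n) sum_i dev_i(b0, b)  +  lambda * ||b||_1 .

Evaluation follows the leave-one-out jackknife: the ordination is computed
once on all n samples, then the model is refit n times with one sample
held out and used for prediction.  Confidence-aware accuracy curves,
ROC curves, a mock-label permutation control and joint-embedding target
classification complete the workflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from ._solver import cd_path

from .embed import Embedding, embed
from .sketch import AbundanceSketch, SimilarityMatrix, compare_all

__all__ = [
    "LassoLogitModel",
    "JackknifeRecord",
    "AccuracyCurve",
    "RocCurve",
    "PermutationControlResult",
    "fit_lasso_logit",
    "predict_prob",
    "jackknife",
    "accuracy_curve",
    "permutation_control",
    "classify_target",
    "roc_curve",
    "depth_gate",
]

_ZERO_VAR_TOL = 1e-12
_N_LAMBDA = 100
_LAMBDA_MIN_RATIO = 1e-4


@dataclass
class LassoLogitModel:
    """Fitted lasso logistic model on standardized ordination coordinates.

    ``class_labels`` is the ordered pair (reference, positive); predicted
    probabilities refer to the positive class.  ``coef`` lives on the
    standardized feature scale; the standardization constants and the
    indices of retained (non-constant) features are stored so raw
    coordinates can be scored directly.
    """

    class_labels: tuple[str, str]
    intercept: float
    coef: np.ndarray
    lambda_selected: float
    lambda_grid: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    kept_dims: np.ndarray
    cv_deviance: np.ndarray | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    @property
    def prior_only(self) -> bool:
        """True when the selected model kept no coordinate (intercept only)."""
        return self.n_nonzero == 0

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "lambda_selected": self.lambda_selected,
            "lambda_grid": self.lambda_grid.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "kept_dims": self.kept_dims.tolist(),
            "n_nonzero": self.n_nonzero,
        }


def _encode_labels(y: Sequence) -> tuple[np.ndarray, tuple[str, str]]:
    classes = sorted({str(v) for v in y})
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    reference, positive = classes[0], classes[1]
    ybin = np.array([1.0 if str(v) == positive else 0.0 for v in y])
    return ybin, (reference, positive)


def _lambda_max(Xs: np.ndarray, ybin: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero.

    At beta = 0 the intercept equals the prior log-odds and the gradient
    of the mean deviance w.r.t. beta_j is X_j^T (p_bar - y) / n; lasso
    keeps every coefficient at zero iff lambda dominates its magnitude.
    """
    n = len(ybin)
    pbar = ybin.mean()
    grad = Xs.T @ (ybin - pbar) / n
    return float(np.max(np.abs(grad)))


def _default_lambda_grid(lam_max: float) -> np.ndarray:
    lam_max = max(lam_max, 1e-12)
    return np.logspace(
        math.log10(lam_max), math.log10(lam_max * _LAMBDA_MIN_RATIO), _N_LAMBDA
    )


_CV_PATH_TOL = 1e-5  # fold fits only rank penalties; looser is plenty


def _path_fit(
    Xs: np.ndarray,
    ybin: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    max_iter: int,
    final_tol: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the lasso path from strong to weak penalty with warm starts.

    Returns (intercepts, coefs) with coefs of shape (n_lambda, p);
    lambda = 0 entries are fit unpenalized by the same IRLS machinery.
    The path runs at *tol* and the last grid point is polished to
    *final_tol* — CV fold fits only need to rank penalties, while the
    reported model should be converged tightly.
    """
    return cd_path(
        Xs, ybin, np.asarray(lambdas), tol=tol, final_tol=final_tol, max_inner=max_iter
    )


def _binomial_deviance(ybin: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(ybin * np.log(p) + (1 - ybin) * np.log(1 - p)))


def fit_lasso_logit(
    X: np.ndarray,
    y: Sequence,
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int | None = None,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> LassoLogitModel:
    """Fit a CV-tuned lasso logistic regression on coordinates X.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Ordination coordinates (raw scale; standardization is internal).
    y : sequence of length n
        Binary class labels (any two distinct values).
    lambda_grid : sequence of float, optional
        Penalty grid; defaults to 100 log-spaced values from lambda_max
        down to lambda_max * 1e-4.  A single value skips CV.
    cv_folds : int, optional
        Stratified fold count; defaults to min(10, smallest class size).
    seed : int
        Seeds the cross-validation fold shuffling (the coordinate-descent
        solver itself is deterministic).

    Returns
    -------
    LassoLogitModel
        With ``prior_only`` flagged when no coordinate survives the
        selected penalty.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples to fit")
    ybin, class_labels = _encode_labels(y)
    if len(ybin) != X.shape[0]:
        raise ValueError("X and y length mismatch")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    kept = np.flatnonzero(sds > _ZERO_VAR_TOL)
    Xs = (X[:, kept] - means[kept]) / sds[kept]

    lam_max = _lambda_max(Xs, ybin) if Xs.shape[1] else 1.0
    grid = (
        np.asarray(sorted(lambda_grid, reverse=True), dtype=np.float64)
        if lambda_grid is not None
        else _default_lambda_grid(lam_max)
    )

    cv_dev = None
    if len(grid) == 1:
        sel_idx = 0
    else:
        counts = np.bincount(ybin.astype(int))
        min_class = int(counts.min())
        if min_class < 2:
            raise ValueError("smallest class has < 2 samples; cannot cross-validate")
        K = cv_folds if cv_folds is not None else min(10, min_class)
        K = max(2, min(K, min_class))
        folds = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        total_dev = np.zeros(len(grid))
        for tr, te in folds.split(Xs, ybin):
            b0s, betas = _path_fit(Xs[tr], ybin[tr], grid, _CV_PATH_TOL, max_iter)
            eta = Xs[te] @ betas.T + b0s  # (n_te, n_lambda)
            p = 1.0 / (1.0 + np.exp(-eta))
            for i in range(len(grid)):
                total_dev[i] += _binomial_deviance(ybin[te], p[:, i])
        cv_dev = total_dev / len(ybin)
        sel_idx = int(np.argmin(cv_dev))  # ties resolve to the sparser model

    # final fit on all data, warm-started along the path down to the
    # selected penalty, which is polished to full tolerance
    b0s, betas = _path_fit(
        Xs, ybin, grid[: sel_idx + 1], _CV_PATH_TOL, max_iter, final_tol=tol
    )
    return LassoLogitModel(
        class_labels=class_labels,
        intercept=float(b0s[-1]),
        coef=betas[-1].copy(),
        lambda_selected=float(grid[sel_idx]),
        lambda_grid=grid,
        feature_means=means,
        feature_sds=sds,
        kept_dims=kept,
        cv_deviance=cv_dev,
    )


def predict_prob(model: LassoLogitModel, x: np.ndarray) -> float | np.ndarray:
    """Probability of the positive class for raw coordinates *x*.

    Accepts a single coordinate vector or an (m, p) matrix; p must match
    the dimensionality the model was fit on (before dropping constant
    features).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.feature_means):
        raise ValueError(
            f"expected {len(model.feature_means)} coordinates, got {X.shape[1]}"
        )
    kept = model.kept_dims
    Xs = (X[:, kept] - model.feature_means[kept]) / model.feature_sds[kept]
    eta = model.intercept + Xs @ model.coef
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p[0]) if single else p


@dataclass
class JackknifeRecord:
    """One leave-one-out prediction."""

    sample_id: str
    true_label: str
    p_true: float
    predicted_label: str | None
    p_positive: float = float("nan")
    flagged: bool = False

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


def _predict_record(
    model: LassoLogitModel, sample_id: str, true_label: str, x: np.ndarray
) -> JackknifeRecord:
    reference, positive = model.class_labels
    p_pos = float(predict_prob(model, x))
    # p = 0.5 ties break to the reference class
    predicted = positive if p_pos > 0.5 else reference
    p_true = p_pos if true_label == positive else 1.0 - p_pos
    return JackknifeRecord(sample_id, true_label, p_true, predicted, p_positive=p_pos)


def _labels_array(
    labels: Mapping[str, str] | Sequence[str], sample_ids: Sequence[str]
) -> list[str]:
    if isinstance(labels, Mapping):
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise KeyError(f"labels missing for samples {missing}")
        return [str(labels[s]) for s in sample_ids]
    if len(labels) != len(sample_ids):
        raise ValueError("label sequence length does not match sample count")
    return [str(v) for v in labels]


def jackknife(
    S: SimilarityMatrix,
    labels: Mapping[str, str] | Sequence[str],
    embed_method: str = "pca_rows",
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int | None = None,
    seed: int = 0,
    re_embed_per_fold: bool = False,
) -> list[JackknifeRecord]:
    """Leave-one-out evaluation of the origin classifier.

    By default the ordination is computed once on all n samples (the
    held-out sample contributes to the axes, only the logistic fit
    excludes it).  ``re_embed_per_fold=True`` switches to a stricter
    scheme (pca_rows only) where the axes are derived from the training
    samples and the held-out sample is projected onto them.

    A training fold whose classes collapse yields a flagged record with
    NaN probability rather than being dropped.
    """
    n = len(S.sample_ids)
    if n < 6:
        raise ValueError("jackknife needs at least 6 samples")
    y = _labels_array(labels, S.sample_ids)
    counts: dict[str, int] = {}
    for v in y:
        counts[v] = counts.get(v, 0) + 1
    if len(counts) != 2 or min(counts.values()) < 3:
        raise ValueError("jackknife needs 2 classes with >= 3 samples each")

    records: list[JackknifeRecord] = []
    if not re_embed_per_fold:
        emb = embed(S, method=embed_method)
        for i in range(n):
            mask = np.arange(n) != i
            try:
                model = fit_lasso_logit(
                    emb.X[mask],
                    [y[j] for j in range(n) if j != i],
                    lambda_grid=lambda_grid,
                    cv_folds=cv_folds,
                    seed=seed,
                )
            except ValueError:
                records.append(
                    JackknifeRecord(S.sample_ids[i], y[i], float("nan"), None, flagged=True)
                )
                continue
            records.append(_predict_record(model, S.sample_ids[i], y[i], emb.X[i]))
        return records

    if embed_method != "pca_rows":
        raise ValueError("re_embed_per_fold is only supported with pca_rows")
    M = np.asarray(S.values)
    for i in range(n):
        mask = np.arange(n) != i
        sub = M[np.ix_(mask, mask)]
        col_means = sub.mean(axis=0)
        U, s, Vt = np.linalg.svd(sub - col_means, full_matrices=False)
        keep = s > 1e-12 * max(s[0], 1.0)
        Xtr = (U[:, keep] * s[keep])
        x_held = (M[i, mask] - col_means) @ Vt[keep].T
        try:
            model = fit_lasso_logit(
                Xtr,
                [y[j] for j in range(n) if j != i],
                lambda_grid=lambda_grid,
                cv_folds=cv_folds,
                seed=seed,
            )
        except ValueError:
            records.append(
                JackknifeRecord(S.sample_ids[i], y[i], float("nan"), None, flagged=True)
            )
            continue
        records.append(_predict_record(model, S.sample_ids[i], y[i], x_held))
    return records


@dataclass
class AccuracyCurve:
    """Share of samples correctly classified with confidence >= t."""

    thresholds: np.ndarray
    values: np.ndarray

    def value_at(self, t: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - t)))
        return float(self.values[idx])


def accuracy_curve(
    records: Sequence[JackknifeRecord],
    thresholds: Sequence[float] | None = None,
) -> AccuracyCurve:
    """Accuracy(t) = #{correct and p_true >= t} / n over a grid of t.

    Flagged records (NaN probability) count as incorrect at every
    threshold, so the curve is a conservative summary.
    """
    t = (
        np.asarray(thresholds, dtype=np.float64)
        if thresholds is not None
        else np.linspace(0.5, 1.0, 51)
    )
    n = len(records)
    if n == 0:
        return AccuracyCurve(t, np.zeros_like(t))
    p = np.array(
        [r.p_true if (r.correct and not r.flagged) else -1.0 for r in records]
    )
    values = np.array([(p >= ti).sum() / n for ti in t])
    return AccuracyCurve(t, values)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(records: Sequence[JackknifeRecord]) -> RocCurve:
    """ROC of the jackknife positive-class probabilities (trapezoid AUC)."""
    true = [r.true_label for r in records]
    classes = sorted(set(true))
    if len(classes) < 2:
        raise ValueError("ROC needs both classes present")
    positive = classes[1]
    y = np.array([1 if t == positive else 0 for t in true])
    scores = np.array([r.p_positive for r in records])
    if np.isnan(scores).any():
        raise ValueError("flagged records have no probability; filter them first")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))


@dataclass
class PermutationControlResult:
    """Jackknife evaluation under mock, size-balanced labels."""

    permuted_labels: list[str]
    records: list[JackknifeRecord] = field(repr=False)
    accuracy: float = 0.0
    n_dims_selected: int = 0


def permutation_control(
    S: SimilarityMatrix,
    labels: Mapping[str, str] | Sequence[str],
    seed: int = 0,
    **jackknife_kwargs,
) -> PermutationControlResult:
    """Negative control: rerun the jackknife with random 50/50 labels.

    Samples are reassigned to two mock groups of sizes floor(n/2) and
    ceil(n/2) uniformly at random (seeded).  On data with genuine
    geographic structure the mock model should do no better than chance
    and select (almost) no ordination axes.
    """
    n = len(S.sample_ids)
    _labels_array(labels, S.sample_ids)  # validates shape; values unused
    rng = np.random.default_rng(seed)
    mock = np.array(["mock_A"] * n, dtype=object)
    mock[rng.choice(n, size=n // 2, replace=False)] = "mock_B"
    mock_labels = [str(v) for v in mock]

    records = jackknife(S, mock_labels, seed=seed, **jackknife_kwargs)
    ok = [r for r in records if not r.flagged]
    accuracy = sum(r.correct for r in ok) / len(records) if records else 0.0

    emb = embed(S, method=jackknife_kwargs.get("embed_method", "pca_rows"))
    full = fit_lasso_logit(
        emb.X,
        mock_labels,
        lambda_grid=jackknife_kwargs.get("lambda_grid"),
        cv_folds=jackknife_kwargs.get("cv_folds"),
        seed=seed,
    )
    return PermutationControlResult(
        permuted_labels=mock_labels,
        records=records,
        accuracy=accuracy,
        n_dims_selected=full.n_nonzero,
    )


def classify_target(
    reference_sketches: Sequence[AbundanceSketch],
    reference_labels: Mapping[str, str] | Sequence[str],
    target_sketch: AbundanceSketch,
    embed_method: str = "pca_rows",
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Classify one target sample against a labelled reference panel.

    The target is embedded jointly with the references (its similarities
    shape the axes) but the logistic model is trained on reference
    coordinates only.  Returns class -> probability.  When several
    targets are to be classified, call this once per target: each
    classification is independent of the other targets.
    """
    ref_ids = [s.sample_id for s in reference_sketches]
    if target_sketch.sample_id in ref_ids:
        raise ValueError(
            f"target id {target_sketch.sample_id!r} collides with a reference sample"
        )
    y = _labels_array(reference_labels, ref_ids)
    S = compare_all(list(reference_sketches) + [target_sketch])
    emb = embed(S, method=embed_method)
    model = fit_lasso_logit(
        emb.X[:-1], y, lambda_grid=lambda_grid, cv_folds=cv_folds, seed=seed
    )
    p_pos = float(predict_prob(model, emb.X[-1]))
    reference, positive = model.class_labels
    return {reference: 1.0 - p_pos, positive: p_pos}


def depth_gate(
    read_counts: Mapping[str, int], min_reads: int = 1_000_000
) -> tuple[list[str], list[str]]:
    """Partition samples by post-QC read count.

    Samples with fewer than *min_reads* reads go to the excluded list
    (the boundary count itself is included).
    """
    included = [s for s, c in read_counts.items() if c >= min_reads]
    excluded = [s for s, c in read_counts.items() if c < min_reads]
    return included, excluded
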