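"""Two-model likelihood classification, probabilities, metrics and CV.

A test recording's reduced segment features are scored under the healthy
model M0 and the unhealthy model M1; the label follows the larger total
log-likelihood (equal class priors).  Class probabilities come in two
flavours: the naive probability uses the per-segment-averaged totals
``p0 = e^{l0/m} / (e^{l0/m} + e^{l1/m})``, and the weighted probability
replaces the uniform average with quality weights ``w_i = u_i / Σu_i``
built from the fraction of non-interpolated samples per segment.
Performance is summarized by TPR/TNR and the weighted relative accuracy
WRA = 4·cost·(TPR − FPR)/(1 + cost)², assessed by stratified 5-fold CV with
scaler and PCA fitted on training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from . import hdpgmm, reduction

HEALTHY = 0
UNHEALTHY = 1


@dataclass
class ClassificationOutcome:
    record_id: str
    l0: float
    l1: float
    l0_per_segment: np.ndarray
    l1_per_segment: np.ndarray
    u: np.ndarray
    p0: float
    p1: float
    p0_weighted: float
    p1_weighted: float
    label: int  # HEALTHY or UNHEALTHY


@dataclass
class Metrics:
    tpr: float
    tnr: float
    fpr: float
    wra: float
    cost: float = 1.0


def naive_probabilities(l0: float, l1: float, m: int) -> tuple[float, float]:
    """Naive class probabilities from total log-likelihoods over m segments."""
    if m < 1:
        raise ValueError("m must be at least 1")
    a = np.array([l0 / m, l1 / m])
    p0 = float(np.exp(a[0] - logsumexp(a)))
    return p0, 1.0 - p0


def weighted_probabilities(
    l0_per_segment: np.ndarray, l1_per_segment: np.ndarray, u: np.ndarray,
) -> tuple[float, float]:
    """Quality-weighted class probabilities: w_i = u_i/Σu_i, l' = Σ l(i)·w_i."""
    l0_i = np.asarray(l0_per_segment, dtype=float)
    l1_i = np.asarray(l1_per_segment, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (l0_i.shape == l1_i.shape == u.shape):
        raise ValueError("per-segment lists must align")
    total_u = u.sum()
    if total_u <= 0:
        raise ValueError("no usable signal")
    w = u / total_u
    a = np.array([float(l0_i @ w), float(l1_i @ w)])
    p0 = float(np.exp(a[0] - logsumexp(a)))
    return p0, 1.0 - p0


def classify_recording(
    X: np.ndarray,
    model0: hdpgmm.TrainedModel,
    model1: hdpgmm.TrainedModel,
    u: np.ndarray | None = None,
    record_id: str = "",
) -> ClassificationOutcome:
    """Score one recording under both class models and label it."""
    if model0.prior.q != model1.prior.q:
        raise ValueError("models disagree on feature dimension q")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if u is None:
        u = np.ones(m)
    l0, l0_i = hdpgmm.log_predictive_recording(X, model0)
    l1, l1_i = hdpgmm.log_predictive_recording(X, model1)
    if l0 == l1:
        warnings.warn("exact likelihood tie; labelling healthy")
    p0, p1 = naive_probabilities(l0, l1, m)
    p0w, p1w = weighted_probabilities(l0_i, l1_i, u)
    return ClassificationOutcome(
        record_id=record_id, l0=l0, l1=l1,
        l0_per_segment=l0_i, l1_per_segment=l1_i, u=np.asarray(u, dtype=float),
        p0=p0, p1=p1, p0_weighted=p0w, p1_weighted=p1w,
        label=HEALTHY if l0 >= l1 else UNHEALTHY,
    )


def compute_metrics(
    labels: np.ndarray, predictions: np.ndarray,
    cost: float = 1.0, positive_label: int = UNHEALTHY,
) -> Metrics:
    """Confusion-table rates and weighted relative accuracy.

    By default the positive class is "unhealthy" (detection of a compromised
    fetus); flip ``positive_label`` for the opposite convention.
    """
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("labels and predictions must align and be non-empty")
    pos = y == positive_label
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in the labels")
    tpr = float(np.mean(yhat[pos] == positive_label))
    tnr = float(np.mean(yhat[neg] != positive_label))
    fpr = 1.0 - tnr
    wra = 4.0 * cost * (tpr - fpr) / (1.0 + cost) ** 2
    return Metrics(tpr=tpr, tnr=tnr, fpr=fpr, wra=wra, cost=cost)


@dataclass
class RecordingFeatures:
    """Per-recording feature table: (m × 14) raw features plus qualities."""

    record_id: str
    X: np.ndarray
    u: np.ndarray
    label: int


@dataclass
class PipelineSettings:
    q: int = 2
    sampler: hdpgmm.SamplerSettings = field(
        default_factory=hdpgmm.SamplerSettings)
    prior_kappa0: float = 0.01


def _fit_class_models(
    train: list[RecordingFeatures], settings: PipelineSettings, seed: int,
) -> tuple[hdpgmm.TrainedModel, hdpgmm.TrainedModel,
           reduction.ScalerParams, reduction.PCAParams]:
    X_stack = np.vstack([r.X for r in train])
    _, scaler, pca = reduction.fit_transform_pipeline(X_stack, settings.q)
    groups0, groups1 = {}, {}
    for r in train:
        Z = reduction.transform_pipeline(r.X, scaler, pca)
        (groups0 if r.label == HEALTHY else groups1)[r.record_id] = Z
    Z_all = np.vstack([reduction.transform_pipeline(r.X, scaler, pca)
                       for r in train])
    prior = hdpgmm.NIWPrior.from_data(Z_all, kappa0=settings.prior_kappa0)
    model0 = hdpgmm.fit_hdpgm(groups0, prior=prior, settings=settings.sampler,
                              seed=seed)
    model1 = hdpgmm.fit_hdpgm(groups1, prior=prior, settings=settings.sampler,
                              seed=seed + 1)
    return model0, model1, scaler, pca


def cross_validate(
    dataset: list[RecordingFeatures],
    settings: PipelineSettings | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[Metrics], Metrics]:
    """Stratified k-fold CV of the full scale→PCA→HDPGM pipeline.

    Per fold the scaler, PCA and both class models are fitted on the training
    recordings only; test recordings are transformed and classified, and
    TPR/TNR/WRA are reported per fold and averaged.
    """
    settings = settings or PipelineSettings()
    labels = np.array([r.label for r in dataset])
    for c in (HEALTHY, UNHEALTHY):
        if np.sum(labels == c) < n_folds:
            raise ValueError("each class needs at least one recording per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics: list[Metrics] = []
    for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(len(dataset)), labels)):
        train = [dataset[i] for i in train_idx]
        test = [dataset[i] for i in test_idx]
        model0, model1, scaler, pca = _fit_class_models(
            train, settings, seed=seed * 1000 + fold)
        y_true, y_pred = [], []
        for r in test:
            Z = reduction.transform_pipeline(r.X, scaler, pca)
            outcome = classify_recording(Z, model0, model1, u=r.u,
                                         record_id=r.record_id)
            y_true.append(r.label)
            y_pred.append(outcome.label)
        fold_metrics.append(compute_metrics(np.array(y_true), np.array(y_pred)))
    mean = Metrics(
        tpr=float(np.mean([m.tpr for m in fold_metrics])),
        tnr=float(np.mean([m.tnr for m in fold_metrics])),
        fpr=float(np.mean([m.fpr for m in fold_metrics])),
        wra=float(np.mean([m.wra for m in fold_metrics])),
    )
    return fold_metrics, mean
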