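"""Gesture classification: regularized LDA and leave-one-repetition-out CV.

"LOOCV" throughout this package means leave-one-REPETITION-out block
cross-validation over the protocol repetitions, never leave-one-sample-out:
FSR samples within a hold are strongly autocorrelated at 10 Hz, so
per-sample CV would leak temporally adjacent samples between train and
test.  Classifier inputs are the raw per-sample channel values (no feature
extraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataio import GESTURES, ChannelSubset, FMGDataset

#: Global count of LDA fits, used to audit how much classification work a
#: selection method performs (filter methods must do none).
_FIT_COUNT = 0


def reset_fit_counter() -> None:
    global _FIT_COUNT
    _FIT_COUNT = 0


def fit_count() -> int:
    return _FIT_COUNT


@dataclass(frozen=True)
class LDAModel:
    """Pooled-covariance Gaussian discriminant model.

    Discriminant score for class k at x:
    ``g_k(x) = x' W mu_k - mu_k' W mu_k / 2 + log pi_k`` with ``W`` the
    inverse of the ridge-regularized pooled within-class covariance.
    Prediction is argmax over classes; ties break to the lowest class
    index (classes are kept in first-appearance order of training labels).
    """

    classes: tuple[str, ...]
    means: np.ndarray          # (k, d)
    precision: np.ndarray      # (d, d) inverse pooled covariance
    log_priors: np.ndarray     # (k,)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def lda_fit(train_values: np.ndarray, labels: Sequence[str], reg: float = 1e-6) -> LDAModel:
    """Fit LDA with a ridge-regularized pooled within-class covariance.

    The ridge added to the diagonal is ``reg * trace(S) / d`` (scaled to
    the data), which keeps the pooled covariance invertible for collinear
    or duplicated channels.  Priors are empirical class frequencies.
    Deterministic.
    """
    global _FIT_COUNT
    X = np.asarray(train_values, dtype=float)
    if X.ndim != 2:
        raise ValueError("train_values must be 2-D")
    y = np.asarray(labels, dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match number of rows")
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    # first-appearance order gives a stable, documented tie-break order
    seen: dict[str, int] = {}
    for lbl in y:
        seen.setdefault(str(lbl), len(seen))
    classes = tuple(seen)
    if len(classes) < 2:
        raise ValueError("LDA requires at least two classes in the training data")

    n, d = X.shape
    means = np.empty((len(classes), d))
    priors = np.empty(len(classes))
    S = np.zeros((d, d))
    for k, cls in enumerate(classes):
        Xk = X[y == cls]
        priors[k] = len(Xk) / n
        means[k] = Xk.mean(axis=0)
        R = Xk - means[k]
        S += R.T @ R
    S /= max(n - len(classes), 1)

    tr = float(np.trace(S))
    if tr <= 0:
        # zero within-class variance: legitimate for noise-free data with
        # distinct class means, an error only if the input is all-constant
        if np.allclose(X, X[0]):
            raise ValueError("all-constant training input: pooled covariance has zero trace")
        scale = max(float(np.mean(X**2)), 1.0)
        S_reg = max(reg, 1e-12) * scale * np.eye(d)
    else:
        S_reg = S + (reg * tr / d) * np.eye(d)
    precision = np.linalg.inv(S_reg)
    _FIT_COUNT += 1
    return LDAModel(
        classes=classes,
        means=means,
        precision=precision,
        log_priors=np.log(priors),
    )


def lda_predict(model: LDAModel, values: np.ndarray) -> np.ndarray:
    """Predict gesture labels by argmax discriminant score per row."""
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} columns, model was trained with {model.n_features}"
        )
    WM = model.precision @ model.means.T                    # (d, k)
    scores = X @ WM - 0.5 * np.sum(model.means * WM.T, axis=1) + model.log_priors
    # argmax takes the first maximum -> ties break to the lowest class index
    idx = np.argmax(scores, axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


def discriminant_scores(model: LDAModel, values: np.ndarray) -> np.ndarray:
    """Raw per-class discriminant scores (rows × classes); used in tests."""
    X = np.atleast_2d(np.asarray(values, dtype=float))
    WM = model.precision @ model.means.T
    return X @ WM - 0.5 * np.sum(model.means * WM.T, axis=1) + model.log_priors


@dataclass(frozen=True)
class CVResult:
    """Leave-one-repetition-out accuracy summary.

    ``fold_accuracies`` holds one entry per held-out repetition (ascending
    repetition id); ``confusion`` is the 6×6 count matrix summed over
    folds, rows = true gesture, columns = predicted, in :data:`GESTURES`
    order.
    """

    fold_accuracies: tuple[float, ...]
    channels_used: ChannelSubset
    confusion: np.ndarray
    repetition_ids: tuple[int, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def worst_gesture(self) -> str:
        """Gesture with the lowest per-class recall over all folds."""
        totals = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            recall = np.where(totals > 0, np.diag(self.confusion) / totals, np.nan)
        return GESTURES[int(np.nanargmin(recall))]

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "mean": self.mean,
            "sd": self.sd,
            "repetition_ids": list(self.repetition_ids),
            "channels": list(self.channels_used.indices),
            "confusion": self.confusion.tolist(),
        }


def loocv_accuracy(
    dataset: FMGDataset,
    channels: ChannelSubset | Sequence[int],
    reps: Sequence[int] | None = None,
    reg: float = 1e-6,
) -> CVResult:
    """Leave-one-repetition-out LDA accuracy on the given channel subset.

    For each repetition in ``reps`` (default: all repetitions present) the
    model is fit on the remaining repetitions restricted to ``channels``
    and scored on the held-out repetition; fold accuracy is the fraction
    of correctly classified samples.
    """
    if not isinstance(channels, ChannelSubset):
        channels = ChannelSubset(indices=tuple(channels))
    if len(channels) == 0:
        raise ValueError("channel subset is empty; cannot cross-validate")
    rep_ids = sorted(int(r) for r in (reps if reps is not None else dataset.repetition_ids))
    if len(rep_ids) < 2:
        raise ValueError("leave-one-repetition-out needs at least two repetitions")
    for r in rep_ids:
        if r not in dataset.repetition_ids:
            raise ValueError(f"repetition {r} not present in dataset")

    X = dataset.restrict_channels(channels.indices)
    y = dataset.gesture
    rep = dataset.repetition
    in_cv = np.isin(rep, rep_ids)
    g_index = {g: i for i, g in enumerate(GESTURES)}
    confusion = np.zeros((len(GESTURES), len(GESTURES)), dtype=int)
    accs = []
    for r in rep_ids:
        test = in_cv & (rep == r)
        train = in_cv & (rep != r)
        model = lda_fit(X[train], y[train], reg=reg)
        pred = lda_predict(model, X[test])
        truth = y[test]
        accs.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            confusion[g_index[str(t)], g_index[str(p)]] += 1
    return CVResult(
        fold_accuracies=tuple(accs),
        channels_used=channels,
        confusion=confusion,
        repetition_ids=tuple(rep_ids),
    )


def loocv_error(
    dataset: FMGDataset,
    channels: Sequence[int],
    reps: Sequence[int] | None = None,
    reg: float = 1e-6,
) -> float:
    """Mean leave-one-repetition-out misclassification error (wrapper objective)."""
    return 1.0 - loocv_accuracy(dataset, channels, reps=reps, reg=reg).mean


def paired_t_test(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool, bool]:
    """Two-sided Student's paired t-test on per-fold accuracies.

    Returns ``(t, p, reject, degenerate)``; ``reject`` iff ``p < alpha``.
    With five repetitions the test has low power — treat non-rejection
    with caution.  All-zero differences are a degenerate case returning
    ``p = 1`` with the flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least two folds")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0, False, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha), False
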