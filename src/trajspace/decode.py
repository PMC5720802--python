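"""Time-resolved single-trial classification.

A linear SVM (C = 2^-6 by default) is trained independently at each time
point under five-fold interleaved cross-validation. Training folds are
class-balanced by randomly subsampling the majority class (repeated
``n_balance_iters`` times, accuracies averaged); test folds are never
subsampled, and the reported accuracy is the mean of per-class accuracies
(balanced accuracy) so imbalanced test sets cannot inflate scores; the raw
fraction correct is recorded alongside. Features are z-scored per time
point with training-fold statistics, which makes the fixed small C
meaningful across amplitude scales.

Also provides temporal generalization (train at one time, test at all
others), Haufe-style activation patterns (training-set covariance times
decoder weights), and a nearest-template classifier operating on the norm
or angle of the population vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import EpochedRecording
from .statespace import TrajectorySet

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "svm_timecourse",
    "temporal_generalization",
    "activation_patterns",
    "template_decode",
]


@dataclass
class DecoderConfig:
    C: float = 2.0**-6
    n_folds: int = 5
    n_balance_iters: int = 10
    decode_fs: float = 10.0
    rng_seed: int | None = None

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class DecodingResult:
    times: np.ndarray
    accuracy: np.ndarray  # balanced accuracy per time
    accuracy_raw: np.ndarray  # raw fraction correct per time
    per_fold: np.ndarray  # (n_folds, n_times) balanced accuracy
    weights: np.ndarray  # (n_times, n_features)
    activation: np.ndarray  # (n_times, n_features)
    tg_matrix: np.ndarray | None = None  # (n_train_times, n_test_times)


def _as_feature_array(x) -> tuple[np.ndarray, np.ndarray]:
    """Return (trials, features, times) array and the time axis."""
    if isinstance(x, EpochedRecording):
        return x.data, x.times
    if isinstance(x, TrajectorySet):
        return x.values, x.times
    x = np.asarray(x, float)
    if x.ndim != 3:
        raise ValueError("expected (n_trials, n_features, n_times) data")
    return x, np.arange(x.shape[-1], dtype=float)


def _check_labels(y, n_folds):
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; need at least n_folds={n_folds}"
        )
    return (y == classes[1]).astype(int), classes


def _interleaved_folds(n_trials, n_folds):
    """Trial i -> fold i mod n_folds, preserving acquisition order."""
    return np.arange(n_trials) % n_folds


def _balanced_subsets(y_train, n_iters, rng):
    """Indices (into the training set) with equalized class counts.

    When class counts are already equal, subsampling degenerates and a
    single pass over the full training set is used.
    """
    idx0 = np.flatnonzero(y_train == 0)
    idx1 = np.flatnonzero(y_train == 1)
    if len(idx0) == len(idx1):
        return [np.concatenate([idx0, idx1])]
    n = min(len(idx0), len(idx1))
    subsets = []
    for _ in range(n_iters):
        maj = idx0 if len(idx0) > len(idx1) else idx1
        mino = idx1 if len(idx0) > len(idx1) else idx0
        subsets.append(np.concatenate([mino, rng.choice(maj, size=n, replace=False)]))
    return subsets


def _zscore_train(xtr, xte):
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (xtr - mu) / sd, (xte - mu) / sd


def _fit_svm(x, y, C):
    clf = SVC(kernel="linear", C=C)
    clf.fit(x, y)
    return clf


def _balanced_acc(y_true, y_pred):
    accs = [(y_pred[y_true == c] == c).mean() for c in (0, 1) if np.any(y_true == c)]
    return float(np.mean(accs))


def svm_timecourse(x, labels, cfg: DecoderConfig | None = None, tg: bool = False) -> DecodingResult:
    """Linear-SVM decoding accuracy at each time point.

    With ``tg=True`` the full temporal-generalization matrix is computed
    under the same fold structure (entry (i, j): trained at time i, tested
    at time j).
    """
    cfg = cfg or DecoderConfig()
    data, times = _as_feature_array(x)
    y, _ = _check_labels(labels, cfg.n_folds)
    rng = np.random.default_rng(cfg.rng_seed)
    n_trials, n_feat, n_times = data.shape
    folds = _interleaved_folds(n_trials, cfg.n_folds)

    acc = np.zeros((cfg.n_folds, n_times))
    acc_raw = np.zeros((cfg.n_folds, n_times))
    weights = np.zeros((n_times, n_feat))
    activation = np.zeros((n_times, n_feat))
    tg_mat = np.zeros((n_times, n_times)) if tg else None

    for fold in range(cfg.n_folds):
        te = folds == fold
        tr = ~te
        y_tr, y_te = y[tr], y[te]
        subsets = _balanced_subsets(y_tr, cfg.n_balance_iters, rng)
        for ti in range(n_times):
            xtr_full = data[tr, :, ti]
            xte = data[te, :, ti]
            z_tr, z_te = _zscore_train(xtr_full, xte)
            bal, raw, w = [], [], np.zeros(n_feat)
            tg_preds = np.zeros((len(subsets), y_te.size, n_times)) if tg else None
            for si, sub in enumerate(subsets):
                clf = _fit_svm(z_tr[sub], y_tr[sub], cfg.C)
                pred = clf.predict(z_te)
                bal.append(_balanced_acc(y_te, pred))
                raw.append((pred == y_te).mean())
                w += clf.coef_.ravel()
                if tg:
                    for tj in range(n_times):
                        if tj == ti:
                            tg_preds[si, :, tj] = pred
                        else:
                            _, z_te_j = _zscore_train(data[tr, :, tj], data[te, :, tj])
                            tg_preds[si, :, tj] = clf.predict(z_te_j)
            w /= len(subsets)
            acc[fold, ti] = np.mean(bal)
            acc_raw[fold, ti] = np.mean(raw)
            weights[ti] += w / cfg.n_folds
            cov = np.cov(z_tr, rowvar=False)
            activation[ti] += (cov @ w) / cfg.n_folds
            if tg:
                for tj in range(n_times):
                    tg_mat[ti, tj] += np.mean(
                        [_balanced_acc(y_te, tg_preds[si, :, tj]) for si in range(len(subsets))]
                    ) / cfg.n_folds

    return DecodingResult(
        times=times,
        accuracy=acc.mean(axis=0),
        accuracy_raw=acc_raw.mean(axis=0),
        per_fold=acc,
        weights=weights,
        activation=activation,
        tg_matrix=tg_mat,
    )


def temporal_generalization(x, labels, cfg: DecoderConfig | None = None) -> np.ndarray:
    """Temporal-generalization accuracy matrix (train time x test time)."""
    return svm_timecourse(x, labels, cfg, tg=True).tg_matrix


def activation_patterns(weights: np.ndarray, train_data: np.ndarray) -> np.ndarray:
    """Haufe transform: training-data covariance times decoder weights.

    ``weights``: (n_times, n_features); ``train_data``:
    (n_trials, n_features, n_times). The covariance is computed across
    trials at each time point.
    """
    weights = np.asarray(weights, float)
    train_data = np.asarray(train_data, float)
    if weights.shape[1] != train_data.shape[1]:
        raise ValueError(
            f"weights have {weights.shape[1]} features; data has {train_data.shape[1]}"
        )
    out = np.empty_like(weights)
    for ti in range(weights.shape[0]):
        cov = np.cov(train_data[:, :, ti], rowvar=False)
        out[ti] = cov @ weights[ti]
    return out


def template_decode(x, labels, mode: str = "angle") -> np.ndarray:
    """Nearest-template classification from the norm or angle of the
    population vector, with an interleaved odd-even split.

    For each split, per-class mean vectors are computed from the training
    half; each test trial is assigned to the class with the smaller angle
    to the class mean (``mode="angle"``) or the smaller absolute norm
    difference (``mode="norm"``). Accuracy (balanced) is averaged over the
    two splits, per time point. Zero-norm test vectors are excluded from
    angle-mode scoring with a warning.
    """
    if mode not in ("angle", "norm"):
        raise ValueError(f"unknown mode {mode!r}")
    data, _ = _as_feature_array(x)
    y, _ = _check_labels(labels, 2)
    n_trials, n_feat, n_times = data.shape
    parity = np.arange(n_trials) % 2
    accs = np.zeros((2, n_times))
    for split in (0, 1):
        tr = parity == split
        te = ~tr
        if min((y[tr] == 0).sum(), (y[tr] == 1).sum()) < 2:
            raise ValueError("need at least 2 trials per class per split")
        mean0 = data[tr & (y == 0)].mean(axis=0)  # (n_feat, n_times)
        mean1 = data[tr & (y == 1)].mean(axis=0)
        xt = data[te]
        y_te = y[te]
        if mode == "norm":
            n0 = np.linalg.norm(mean0, axis=0)
            n1 = np.linalg.norm(mean1, axis=0)
            nt = np.linalg.norm(xt, axis=1)  # (n_te, n_times)
            pred = (np.abs(nt - n1) < np.abs(nt - n0)).astype(int)
            valid = np.ones_like(pred, bool)
        else:
            nt = np.linalg.norm(xt, axis=1)
            valid = nt > 0
            if not valid.all():
                warnings.warn(
                    f"excluding {int((~valid).sum())} zero-norm trial/time points from angle decoding"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                u = xt / nt[:, None, :]
                c0 = np.einsum("nft,ft->nt", u, mean0 / np.linalg.norm(mean0, axis=0))
                c1 = np.einsum("nft,ft->nt", u, mean1 / np.linalg.norm(mean1, axis=0))
            # smaller angle == larger cosine
            pred = (c1 > c0).astype(int)
        for ti in range(n_times):
            v = valid[:, ti]
            accs[split, ti] = _balanced_acc(y_te[v], pred[v, ti])
    return accs.mean(axis=0)
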