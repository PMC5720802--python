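"""PCA state-space construction and trajectory geometry.

The state space is defined by the eigenvectors of the sensor-by-sensor
Pearson correlation matrix, computed on time series concatenated across
trials. Sensor signals are standardized (per-sensor mean/s.d. from the fit
scope) before projection, consistent with a correlation-matrix
decomposition. Geometry operations (distance, velocity, volume, norm,
angle, dispersion) act on the resulting component-by-time trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochedRecording

__all__ = [
    "PCModel",
    "TrajectorySet",
    "AlignmentMap",
    "fit_pca",
    "project",
    "choose_k",
    "align_components",
    "condition_average",
    "distance_timecourse",
    "velocity_timecourse",
    "vector_norm",
    "vector_angle",
    "volume_timecourse",
    "dispersion_timecourse",
    "sensor_sd_timecourse",
]

#: Default pre-stimulus baseline window (seconds, half-open).
DEFAULT_BASELINE = (-1.0, -0.25)


@dataclass
class PCModel:
    """Sensor-space principal components of the correlation (or covariance)
    matrix of standardized sensor signals.

    ``loadings`` columns are orthonormal eigenvectors sorted by explained
    variance; ``var_explained`` are the corresponding variance fractions
    (summing to 1 over all components). ``mean_``/``std_`` are the
    per-sensor statistics used for standardization at projection time.
    """

    loadings: np.ndarray
    var_explained: np.ndarray
    eigenvalues: np.ndarray
    mean_: np.ndarray
    std_: np.ndarray
    source_band: str
    fit_scope: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class TrajectorySet:
    """Per-trial component-by-time activity: values (n_trials, k, n_samples)."""

    values: np.ndarray
    times: np.ndarray
    meta: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def select_trials(self, mask) -> "TrajectorySet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrajectorySet(
            self.values[idx], self.times, self.meta.iloc[idx].reset_index(drop=True)
        )

    def time_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        return (self.times >= t_start - 1e-9) & (self.times < t_stop - 1e-9)


@dataclass
class AlignmentMap:
    """Permutation + sign flips mapping one subject's top-k components onto
    a reference subject's components (in reference order)."""

    permutation: np.ndarray  # permutation[i] = source component for ref comp i
    signs: np.ndarray  # +/- 1 per reference component

    def __post_init__(self):
        perm = np.asarray(self.permutation)
        if sorted(perm.tolist()) != list(range(len(perm))):
            raise ValueError("alignment permutation must be a bijection on 0..k-1")

    def apply(self, loadings: np.ndarray) -> np.ndarray:
        """Reorder/sign-flip loading columns into reference order."""
        return loadings[:, self.permutation] * self.signs


_SCOPES = ("all_trials", "seen_only", "unseen_only")


def _scope_mask(rec: EpochedRecording, scope: str) -> np.ndarray:
    if scope == "all_trials":
        return np.ones(rec.n_trials, dtype=bool)
    if scope == "seen_only":
        return rec.meta["seen"].to_numpy().astype(bool)
    if scope == "unseen_only":
        return ~rec.meta["seen"].to_numpy().astype(bool)
    raise ValueError(f"unknown fit scope {scope!r}; expected one of {_SCOPES}")


def fit_pca(rec: EpochedRecording, scope: str = "all_trials", method: str = "correlation") -> PCModel:
    """Eigen-decomposition of the sensor correlation matrix.

    Time series are concatenated across the trials in ``scope``; Pearson
    correlation between all sensor pairs is decomposed with ``eigh``. With
    ``method="covariance"`` the covariance matrix of the raw signals is
    decomposed instead and projection only centers (no per-sensor
    scaling); on externally standardized data the two methods coincide.

    Each loading column is sign-fixed so that its largest-magnitude
    coefficient is positive (eigenvector sign is arbitrary).
    """
    if method not in ("correlation", "covariance"):
        raise ValueError(f"unknown method {method!r}")
    mask = _scope_mask(rec, scope)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError(f"need at least 2 trials in scope {scope!r}")
    # accumulate sums / cross-products trial-by-trial in float64 so large
    # (possibly float32) recordings never get copied whole
    ns = rec.n_sensors
    total = 0
    s1 = np.zeros(ns)
    s2 = np.zeros(ns)
    xprod = np.zeros((ns, ns))
    for i in idx:
        x = np.asarray(rec.data[i], dtype=np.float64)
        total += x.shape[1]
        s1 += x.sum(axis=1)
        s2 += (x**2).sum(axis=1)
        xprod += x @ x.T
    mean = s1 / total
    var = s2 / total - mean**2
    var = np.clip(var, 0, None)
    std = np.sqrt(var)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(
            f"constant (zero-variance) sensor(s): {[rec.sensor_names[i] for i in zero]}"
        )
    cov = xprod / total - np.outer(mean, mean)
    if method == "correlation":
        mat = cov / np.outer(std, std)
    else:
        # covariance of the *raw* signals; projection then centers only
        mat = cov
        std = np.ones(ns)
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|coefficient| entry positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    return PCModel(
        loadings=evecs,
        var_explained=evals / evals.sum(),
        eigenvalues=evals,
        mean_=mean,
        std_=std,
        source_band=rec.band,
        fit_scope=scope,
    )


def project(rec: EpochedRecording, model: PCModel, k: int | None = None) -> TrajectorySet:
    """Project standardized sensor data onto the top-k components."""
    if k is None:
        k = model.n_components
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds {model.n_components} components")
    if rec.n_sensors != model.loadings.shape[0]:
        raise ValueError(
            f"recording has {rec.n_sensors} sensors; model expects {model.loadings.shape[0]}"
        )
    load = model.loadings[:, :k]
    scaled_load = load / model.std_[:, None]  # fold standardization into the map
    offset = (model.mean_ / model.std_) @ load  # (k,)
    values = np.empty((rec.n_trials, k, rec.n_samples))
    for i in range(rec.n_trials):  # trial-wise: avoids a full standardized copy
        proj = scaled_load.T @ np.asarray(rec.data[i], np.float64)  # (k, T)
        values[i] = proj - offset[:, None]
    return TrajectorySet(values=values, times=rec.times, meta=rec.meta.copy())


def back_project(ts: TrajectorySet, model: PCModel) -> np.ndarray:
    """Reconstruct standardized sensor data from component activity."""
    k = ts.k
    return np.einsum("nkt,sk->nst", ts.values, model.loadings[:, :k], optimize=True)


def choose_k(model: PCModel, threshold: float = 0.7) -> int:
    """Smallest k whose cumulative explained variance exceeds ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cum = np.cumsum(model.var_explained)
    return int(np.searchsorted(cum, threshold, side="left") + 1)


def align_components(models, reference_index: int = 0, k: int = 5):
    """Greedy one-to-one alignment of top-k component topographies.

    In reference-component order 1..k, each step picks the not-yet-assigned
    candidate component with the highest absolute Pearson correlation of
    loading vectors, flipping its sign when the correlation is negative.
    Ties break to the lower original index.

    Returns one :class:`AlignmentMap` per model (the reference maps to
    itself with the identity).
    """
    ref = models[reference_index]
    if any(m.loadings.shape[0] != ref.loadings.shape[0] for m in models):
        raise ValueError("all models must share the sensor set")
    if any(k > m.n_components for m in models):
        raise ValueError("k exceeds available components")
    maps = []
    for m in models:
        perm = np.empty(k, dtype=int)
        signs = np.empty(k)
        available = list(range(k))
        for i in range(k):
            corrs = np.array(
                [np.corrcoef(ref.loadings[:, i], m.loadings[:, j])[0, 1] for j in available]
            )
            best = int(np.argmax(np.abs(corrs)))  # argmax takes first on ties
            j = available.pop(best)
            perm[i] = j
            signs[i] = -1.0 if corrs[best] < 0 else 1.0
        maps.append(AlignmentMap(permutation=perm, signs=signs))
    return maps


def condition_average(ts: TrajectorySet, group_cols) -> TrajectorySet:
    """Average trajectories across trials of the same type.

    ``group_cols`` is a metadata column name or list of names; output has
    one "trial" per group, with group labels in the output metadata.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    groups = ts.meta.groupby(group_cols, sort=True, dropna=False).indices
    if not groups:
        raise ValueError("no groups found")
    rows, values = [], []
    for key, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {key!r}")
        values.append(ts.values[idx].mean(axis=0))
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_cols, key), n_trials=len(idx)))
    return TrajectorySet(
        values=np.stack(values), times=ts.times, meta=pd.DataFrame(rows)
    )


# -- geometry ---------------------------------------------------------------

def distance_timecourse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance between two (k, n_samples) trajectories per time."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"trajectory shapes differ: {a.shape} vs {b.shape}")
    return np.sqrt(((a - b) ** 2).sum(axis=0))


def velocity_timecourse(ts: TrajectorySet, mode: str = "trial_averaged", dt: float | None = None):
    """Trajectory speed: distance between adjacent time points / dt.

    ``trial_averaged`` takes the velocity of the across-trial mean
    trajectory; ``single_trial`` averages per-trial velocities. Output has
    length n_samples - 1, timestamped at the left endpoint of each pair.
    """
    if ts.values.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if dt is None:
        dt = float(np.median(np.diff(ts.times)))
    if mode == "trial_averaged":
        traj = ts.values.mean(axis=0)
        v = np.sqrt((np.diff(traj, axis=-1) ** 2).sum(axis=0)) / dt
    elif mode == "single_trial":
        steps = np.diff(ts.values, axis=-1)
        v = np.sqrt((steps**2).sum(axis=1)).mean(axis=0) / dt
    else:
        raise ValueError(f"unknown velocity mode {mode!r}")
    return v, ts.times[:-1]


def vector_norm(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Euclidean length of state vectors."""
    v = np.asarray(v)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite state vector")
    return np.sqrt((v**2).sum(axis=axis))


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians, [0, pi]) between two state vectors.

    Symmetric and invariant to positive rescaling of either argument; the
    cosine is clamped to [-1, 1] before arccos.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero-norm vector")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(c))


def volume_timecourse(ts: TrajectorySet, baseline=DEFAULT_BASELINE) -> np.ndarray:
    """State-space volume as % change from the pre-stimulus baseline.

    Volume(t) = product over components of the across-trial s.d.; output is
    ``100 * (V(t) - mean V over baseline) / mean V over baseline``.
    """
    if ts.n_trials < 3:
        raise ValueError("need at least 3 trials for across-trial s.d.")
    bmask = ts.time_mask(*baseline)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} outside the epoch")
    sd = ts.values.std(axis=0, ddof=1)  # (k, n_samples)
    vol = np.exp(np.log(sd).sum(axis=0))  # product over k, numerically stable
    vbase = vol[bmask].mean()
    if vbase == 0:
        raise ValueError("baseline volume is zero; % change undefined")
    return 100.0 * (vol - vbase) / vbase


def dispersion_timecourse(ts: TrajectorySet, mode: str) -> np.ndarray:
    """Across-trial dispersion per time point.

    ``mode="angle"``: mean pairwise angle over all C(n,2) unordered trial
    pairs. ``mode="norm"``: s.d. of the vector norm across trials.
    Zero-norm vectors at a time point are skipped (angle mode) with a
    warning.
    """
    x = ts.values  # (n, k, t)
    if mode == "norm":
        if ts.n_trials < 2:
            raise ValueError("need at least 2 trials")
        return np.sqrt((x**2).sum(axis=1)).std(axis=0, ddof=1)
    if mode != "angle":
        raise ValueError(f"unknown dispersion mode {mode!r}")
    if ts.n_trials < 2:
        raise ValueError("need at least one trial pair")
    norms = np.sqrt((x**2).sum(axis=1))  # (n, t)
    bad = norms == 0
    if bad.any():
        import warnings

        warnings.warn(
            f"skipping {int(bad.sum())} zero-norm trial/time points in angle dispersion"
        )
    out = np.empty(x.shape[-1])
    iu = np.triu_indices(ts.n_trials, k=1)
    for t in range(x.shape[-1]):
        ok = ~bad[:, t]
        u = x[ok, :, t] / norms[ok, t][:, None]
        g = np.clip(u @ u.T, -1.0, 1.0)
        if ok.sum() == ts.n_trials:
            out[t] = np.arccos(g[iu]).mean()
        elif ok.sum() >= 2:
            sub = np.triu_indices(int(ok.sum()), k=1)
            out[t] = np.arccos(g[sub]).mean()
        else:
            out[t] = np.nan
    return out


def sensor_sd_timecourse(rec: EpochedRecording, baseline=DEFAULT_BASELINE) -> np.ndarray:
    """Per-sensor across-trial s.d. minus its pre-stimulus baseline mean."""
    if rec.n_trials < 3:
        raise ValueError("need at least 3 trials")
    bmask = rec.time_mask(*baseline)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} outside the epoch")
    sd = rec.data.std(axis=0, ddof=1)  # (n_sensors, n_samples)
    return sd - sd[:, bmask].mean(axis=1, keepdims=True)
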