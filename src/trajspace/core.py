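"""Core data containers for epoched multichannel recordings.

The universal currency of the pipeline is :class:`EpochedRecording`: a
``(n_trials, n_sensors, n_samples)`` array with an explicit time axis
(seconds relative to stimulus onset), sensor names following the CTF
convention ``M[L|R|Z][C|F|O|P|T]<number>``, and a per-trial metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochedRecording",
    "BandSpec",
    "BANDS",
    "ctf_sensor_names",
    "sensor_lobes",
    "LOBE_CODES",
    "META_COLUMNS",
]

#: Required columns of the trial-metadata table.
META_COLUMNS = ["subject_id", "session_id", "seen", "orientation", "response", "correct"]

#: CTF third-letter region codes.
LOBE_CODES = {
    "F": "frontal",
    "C": "central",
    "P": "parietal",
    "O": "occipital",
    "T": "temporal",
}


@dataclass(frozen=True)
class BandSpec:
    """Butterworth band-pass specification.

    Parameters
    ----------
    name : str
        Label recorded in the output recording's ``band`` descriptor.
    low_hz, high_hz : float
        Passband edges in Hz. ``0 < low_hz < high_hz <= fs/2``. ``low_hz``
        may be ``None`` for a pure low-pass (used when a high-pass edge
        would fall below the reciprocal of the epoch length and is
        therefore not identifiable on epoched data).
    order : int
        Butterworth order (per edge), default 4.
    notches : tuple of float
        Line frequencies removed with an IIR notch when they fall inside
        the passband. Default (60, 120).
    two_pass : bool
        Forward-backward (zero-phase) filtering when True (default).
    """

    name: str
    low_hz: float
    high_hz: float
    order: int = 4
    notches: tuple = (60.0, 120.0)
    two_pass: bool = True

    def __post_init__(self):
        if self.low_hz is not None and not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, got "
                f"({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz <= 0:
            raise ValueError("high_hz must be positive")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_fs(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: high edge {self.high_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )


#: Canonical analysis bands.
BANDS = {
    "scp": BandSpec("scp", 0.05, 5.0),
    "alpha": BandSpec("alpha", 5.0, 15.0),
    "beta": BandSpec("beta", 15.0, 30.0),
    "low_gamma": BandSpec("low_gamma", 30.0, 60.0),
    "high_gamma": BandSpec("high_gamma", 60.0, 150.0),
    "broadband": BandSpec("broadband", 0.05, 150.0),
    "low_broad": BandSpec("low_broad", 0.05, 30.0),
}

# Region counts used when synthesizing a CTF-like 273-sensor layout.
_REGION_COUNTS = (("F", 75), ("C", 60), ("P", 45), ("T", 54), ("O", 39))


def ctf_sensor_names(n_sensors: int = 273) -> list[str]:
    """Deterministic list of CTF-style sensor names ``M[L|R|Z]<region><num>``.

    Regions are interleaved with left/right/midline prefixes in fixed
    proportions so that every lobe is represented for any ``n_sensors``.
    """
    names = []
    sides = ("L", "R", "Z")
    for region, count in _REGION_COUNTS:
        for i in range(count):
            side = sides[i % 3]
            names.append(f"M{side}{region}{i // 3 + 11}")
    # Cycle the full 273-name layout if more are requested.
    full = names
    while len(full) < n_sensors:
        full = full + [f"{nm}x{len(full) // len(names)}" for nm in names]
    if n_sensors >= len(full):
        return full[:n_sensors]
    # subsample evenly so every lobe stays represented at any count
    idx = np.unique(np.round(np.linspace(0, len(full) - 1, n_sensors)).astype(int))
    return [full[i] for i in idx]


def sensor_lobes(sensor_names) -> np.ndarray:
    """Map CTF-style sensor names to lobe labels via the third character."""
    lobes = []
    for nm in sensor_names:
        if len(nm) < 3 or nm[2] not in LOBE_CODES:
            raise ValueError(f"sensor name {nm!r} does not follow the CTF convention")
        lobes.append(LOBE_CODES[nm[2]])
    return np.asarray(lobes)


@dataclass
class EpochedRecording:
    """Epoched multichannel recording: trials x sensors x samples.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_samples)
        Sensor time series (tesla for real MEG; arbitrary for synthetic).
    fs : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Seconds relative to stimulus onset; strictly increasing with step
        ``1/fs``; 0.0 is one of the samples.
    sensor_names : list of str
    meta : pandas.DataFrame
        One row per trial with columns ``subject_id, session_id, seen,
        orientation, response, correct``.
    band : str
        Descriptor of applied filtering; ``"raw"`` if none.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    sensor_names: list
    meta: pd.DataFrame
    band: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_samples)")
        n_trials, n_sensors, n_samples = self.data.shape
        if len(self.times) != n_samples:
            raise ValueError(
                f"times has {len(self.times)} entries for {n_samples} samples"
            )
        if n_samples >= 2:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("time step must equal 1/fs")
        if n_samples and not np.any(np.abs(self.times) < 1e-9):
            raise ValueError("stimulus onset (t=0) must be one of the samples")
        if len(self.sensor_names) != n_sensors:
            raise ValueError(
                f"{len(self.sensor_names)} sensor names for {n_sensors} sensors"
            )
        if len(self.meta) != n_trials:
            raise ValueError(
                f"metadata has {len(self.meta)} rows for {n_trials} trials"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.times)))

    def time_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        """Boolean mask selecting ``t_start <= t < t_stop`` (half-open)."""
        return (self.times >= t_start - 1e-9) & (self.times < t_stop - 1e-9)

    def select_trials(self, mask) -> "EpochedRecording":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            meta=self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )

    def copy_with(self, **kw) -> "EpochedRecording":
        return replace(self, **kw)


def default_times(fs: float = 600.0, t_start: float = -1.0, t_stop: float = 3.0) -> np.ndarray:
    """Half-open epoch grid [t_start, t_stop) with onset exactly on a sample."""
    n = int(round((t_stop - t_start) * fs))
    return t_start + np.arange(n) / fs


__all__.append("default_times")
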