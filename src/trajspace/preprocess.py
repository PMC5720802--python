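"""Signal conditioning for epoched recordings.

All operations are deterministic and shape-preserving unless documented
otherwise (moving averages and resampling change the time grid). Band-pass
filtering is fourth-order Butterworth, zero-phase (forward-backward) by
default, with reflect padding of one filter length at the epoch edges; the
first/last ~250 ms of a filtered epoch should be treated as edge-affected.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.signal as sps

from .core import BandSpec, EpochedRecording

__all__ = [
    "filter_epochs",
    "hilbert_envelope",
    "moving_average",
    "resample_epochs",
    "power_spectrum",
]


def _band_sos(band: BandSpec, fs: float) -> np.ndarray:
    if band.low_hz is None:
        return sps.butter(band.order, band.high_hz, btype="lowpass", output="sos", fs=fs)
    return sps.butter(
        band.order, [band.low_hz, band.high_hz], btype="bandpass", output="sos", fs=fs
    )


def filter_epochs(rec: EpochedRecording, band: BandSpec) -> EpochedRecording:
    """Band-pass filter every trial/sensor trace.

    Fourth-order (by default) Butterworth band-pass; IIR notches (Q=35) at
    line frequencies that fall inside the passband; zero-phase when
    ``band.two_pass`` (the default), so in-band peak latencies are preserved.
    """
    band.validate_fs(rec.fs)
    sos = _band_sos(band, rec.fs)
    padlen = min(rec.n_samples - 1, 3 * (2 * sos.shape[0] + 1) * 10)
    low_edge = band.low_hz if band.low_hz is not None else 0.0
    notches = [
        sps.iirnotch(line, Q=35, fs=rec.fs)
        for line in band.notches
        if low_edge < line < band.high_hz and line < rec.fs / 2
    ]
    out = np.empty_like(rec.data)
    # trial-chunked so large recordings never allocate a second full-size
    # float64 intermediate
    chunk = max(1, int(np.ceil(2e7 / max(1, rec.n_sensors * rec.n_samples))))
    for lo in range(0, max(rec.n_trials, 1), chunk):
        block = rec.data[lo : lo + chunk]
        if block.size == 0:
            continue
        if band.two_pass:
            fb = sps.sosfiltfilt(sos, block, axis=-1, padtype="even", padlen=padlen)
        else:
            fb = sps.sosfilt(sos, block, axis=-1)
        for b, a in notches:
            if band.two_pass:
                fb = sps.filtfilt(b, a, fb, axis=-1, padtype="even", padlen=padlen)
            else:
                fb = sps.lfilter(b, a, fb, axis=-1)
        out[lo : lo + chunk] = fb
    return rec.copy_with(data=out, band=band.name)


def hilbert_envelope(rec: EpochedRecording) -> EpochedRecording:
    """Amplitude envelope (magnitude of the analytic signal) per trace."""
    env = np.abs(sps.hilbert(rec.data, axis=-1))
    return rec.copy_with(data=env, band=f"{rec.band}-envelope")


def moving_average(rec: EpochedRecording, win_s: float, step_s: float) -> EpochedRecording:
    """Sliding-window mean; output times are the window centers.

    Windows are ``[i*step, i*step + win)`` in samples, giving
    ``floor((T - win)/step) + 1`` output points.
    """
    win_n = int(round(win_s * rec.fs))
    step_n = max(1, int(round(step_s * rec.fs)))
    if win_n < 1:
        raise ValueError("window must be at least one sample")
    if win_n > rec.n_samples:
        raise ValueError(
            f"window of {win_n} samples longer than epoch ({rec.n_samples})"
        )
    n_out = (rec.n_samples - win_n) // step_n + 1
    csum = np.cumsum(rec.data, axis=-1, dtype=np.float64)
    csum = np.concatenate([np.zeros(rec.data.shape[:-1] + (1,)), csum], axis=-1)
    starts = np.arange(n_out) * step_n
    out = (csum[..., starts + win_n] - csum[..., starts]) / win_n
    centers = rec.times[starts] + (win_n - 1) / (2.0 * rec.fs)
    new_fs = rec.fs / step_n
    # Keep the container invariant (uniform grid); onset need not be a
    # sample on a window-center grid, so fall back to a plain container
    # carrying the true centers when it is not.
    return _regrid(rec, out, centers, new_fs, band=f"{rec.band}-ma{win_s:g}s")


def resample_epochs(rec: EpochedRecording, fs_new: float) -> EpochedRecording:
    """Polyphase anti-aliased resampling to ``fs_new`` (< fs).

    The epoch start and the stimulus-onset sample are preserved on the new
    grid; ``fs_new`` must relate to ``fs`` by a rational factor.
    """
    if fs_new >= rec.fs:
        raise ValueError("fs_new must be smaller than the current rate")
    frac = Fraction(fs_new / rec.fs).limit_denominator(10000)
    if abs(float(frac) - fs_new / rec.fs) > 1e-12:
        raise ValueError(f"cannot reach {fs_new} Hz from {rec.fs} Hz by a rational factor")
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.data, up, down, axis=-1)
    n_out = out.shape[-1]
    times = rec.times[0] + np.arange(n_out) / fs_new
    if not np.any(np.abs(times) < 1e-9):
        raise ValueError(
            "stimulus onset does not fall on a sample of the resampled grid; "
            "choose fs_new so that -times[0]*fs_new is an integer"
        )
    return rec.copy_with(data=out, fs=float(fs_new), times=times)


def power_spectrum(rec: EpochedRecording, nperseg: int | None = None):
    """Per-sensor Welch power spectrum averaged across trials.

    Returns ``(freqs, power)`` with ``power`` of shape (n_sensors, n_freqs),
    non-negative, with frequencies up to Nyquist.
    """
    if rec.n_samples < 2:
        raise ValueError("need more than one sample to estimate a spectrum")
    if nperseg is None:
        nperseg = min(rec.n_samples, max(256, rec.n_samples // 2))
    freqs, pxx = sps.welch(rec.data, fs=rec.fs, axis=-1, nperseg=nperseg)
    return freqs, pxx.mean(axis=0)


def _regrid(rec, data, centers, fs_new, band):
    """Build an output recording on the window-center grid.

    If onset is not exactly a center, shift the reported grid so that the
    closest center is labelled 0 (the shift is below half a step and is the
    standard convention for sliding-window analyses locked to an event).
    """
    if len(centers) and not np.any(np.abs(centers) < 1e-9):
        shift = centers[np.argmin(np.abs(centers))]
        if abs(shift) < 0.5 / fs_new:
            centers = centers - shift
    return rec.copy_with(data=data, fs=float(fs_new), times=centers, band=band)
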