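"""Synthetic epoched-recording generator.

The generator emulates the statistical structure that the downstream
analyses assume, in a low-dimensional latent space mixed into sensors:

* Each trial's latent state is ``x_i(t) = r_i(t) u_i(t)``: a *norm*
  ``r_i`` whose distribution is stationary throughout the epoch and
  carries no condition information, and a *direction* ``u_i`` that carries
  all of it. This mirrors the empirical dissociation in which awareness is
  encoded in the relative activity pattern (angle), not total energy (norm).
* Trial-specific deviations ``d_i(t)`` are the sum of a slow "state"
  process (band-limited around 0.15-0.8 Hz, so it survives epoch-wise
  band-pass filtering yet acts as a per-trial initial condition) and
  faster within-trial wander (low-pass below ~4 Hz).
* Whether a trial is *seen* is decided by the pre-stimulus state itself: a
  probit selection on the trial's mean pre-stimulus projection onto a
  dedicated latent axis, calibrated so that the marginal seen-rate equals
  ``p_seen`` and the seen/unseen separation of that projection equals
  ``initial_offset`` (in units of its across-trial s.d.). With
  ``initial_offset = 0`` perception is independent of the initial state.
* The condition mean direction performs a post-stimulus *rotational
  transient* whose angular speed follows a gamma-density profile peaking
  at ``transient_peak_s`` — a much larger total rotation in seen than
  unseen trials — plus a small orientation-specific evoked component.
* In seen trials the angular deviation of each trial's direction about the
  condition mean is contracted after onset by a smooth envelope; the inner
  contraction factor is calibrated numerically so that the realized
  per-latent-dimension across-trial s.d. ratio equals ``contraction`` at
  the envelope peak, while norms are untouched (direction-only
  contraction).
* Sensors receive the latent state through a fixed orthonormal mixing
  matrix (reproducible per ``mixing_seed``), plus 1/f-like broadband noise
  and narrowband alpha/beta "oscillations", all synthesized spectrally
  with random phases per trial and sensor (no phase-locking); seen trials
  optionally quench alpha power after onset.
* Behavior follows a signal-detection model: unseen responses arise from a
  Gaussian decision variable with sensitivity solved to match the
  configured unseen accuracy, an innate criterion shift toward "left", and
  an optional coupling that shifts the criterion with the trial's
  pre-stimulus latent similarity to the orientation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import brentq

from .core import EpochedRecording, ctf_sensor_names, default_times

__all__ = ["SimulationConfig", "generate_latent", "generate_behavior",
           "generate_subject", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study. Defaults are the study conditions."""

    n_subjects: int = 4
    n_trials_per_subject: int = 300
    n_sensors: int = 273
    fs: float = 600.0
    t_start: float = -1.0
    t_stop: float = 3.0
    k_lat: int = 5
    mixing_seed: int = 1234

    # behavior
    p_seen: float = 0.489
    p_correct_seen: float = 0.968
    p_correct_unseen: float = 0.62
    innate_bias_c: float = -0.58  # SDT criterion; negative = liberal toward "left"
    prestim_coupling: float = 0.4

    # latent dynamics
    initial_offset: float = 0.8  # seen-unseen separation of the prestim state, in s.d. units
    transient_peak_s: float = 0.4
    transient_shape: float = 3.0
    transient_gain_seen: float = 3.0  # total direction rotation, radians
    transient_gain_unseen: float = 0.35
    contraction: float = 0.88  # target per-dimension post/pre s.d. ratio (seen)
    contraction_peak_s: float = 0.7
    direction_concentration: float = 1.0
    mixing_gain_range: tuple = (1.5, 0.65)  # sensor gain of 1st..k-th latent dim
    orientation_gain: float = 0.4
    orientation_peak_s: float = 0.15
    sigma_trial: float = 1.0  # slow-state s.d. per latent dimension
    slow_band_hz: tuple = (0.15, 0.8)
    sigma_within: float = 0.4  # within-trial wander s.d.
    within_cutoff_hz: float = 4.0

    # sensor composition (arbitrary units; data_scale maps to tesla-like values)
    signal_scale: float = 125.0
    noise_sd: float = 15.0
    noise_exponent: float = 1.0
    noise_fmax: float = 150.0
    alpha_amp: float = 8.0
    beta_amp: float = 5.0
    alpha_quench_seen: float = 0.3
    data_scale: float = 1e-14
    dtype: str = "float32"  # sensor-array dtype; keeps a full subject lean

    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_seen", "p_correct_seen", "p_correct_unseen"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.contraction <= 1):
            raise ValueError("contraction must be in (0, 1]")
        if self.k_lat > self.n_sensors:
            raise ValueError("k_lat cannot exceed n_sensors")
        if self.k_lat < 2:
            raise ValueError("need at least 2 latent dimensions")

    @property
    def times(self) -> np.ndarray:
        return default_times(self.fs, self.t_start, self.t_stop)

    @property
    def sigma_dev(self) -> float:
        """Across-trial latent deviation s.d. per dimension."""
        return float(np.hypot(self.sigma_trial, self.sigma_within))


# -- deterministic building blocks -----------------------------------------

def _speed_profile(times: np.ndarray, peak_s: float, shape: float):
    """Gamma-density angular-speed profile peaking at ``peak_s`` and its
    cumulative integral (both zero before onset)."""
    scale = peak_s / (shape - 1.0)
    t = np.clip(times, 0.0, None)
    f = st.gamma.pdf(t, a=shape, scale=scale)
    F = st.gamma.cdf(t, a=shape, scale=scale)
    f[times < 0] = 0.0
    F[times < 0] = 0.0
    return f, F


def _unit_bump(times: np.ndarray, peak_s: float, shape: float = 3.0) -> np.ndarray:
    """Gamma-density bump normalized to peak 1 at ``peak_s``; 0 pre-stimulus."""
    scale = peak_s / (shape - 1.0)
    t = np.clip(times, 0.0, None)
    b = st.gamma.pdf(t, a=shape, scale=scale)
    b[times < 0] = 0.0
    mx = b.max()
    return b / mx if mx > 0 else b


def _latent_frame(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent directions (columns): base, seen/unseen state axis,
    transient-rotation axis, orientation axis.

    The frame is axis-aligned: the transient rotation happens in the plane
    of the first two latent axes, which carry equal sensor gains, so the
    rotating mean never changes the gain-metric geometry of the state
    cloud (norm distributions stay stationary by symmetry).
    """
    k = cfg.k_lat
    e = np.eye(k)
    order = [0, 2 % k, 1 % k, 3 % k]  # base, state, rotation, orientation
    return np.stack([e[:, j] for j in order], axis=1)


def _rotate_in_plane(vec: np.ndarray, e1: np.ndarray, e2: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate ``vec`` (k,) by angles ``phi`` (T,) within the (e1, e2) plane.

    Components orthogonal to the plane are preserved. Returns (k, T).
    """
    a, b = vec @ e1, vec @ e2
    rest = vec - a * e1 - b * e2
    c, s = np.cos(phi), np.sin(phi)
    return (
        rest[:, None]
        + np.outer(e1, a * c - b * s)
        + np.outer(e2, a * s + b * c)
    )


def _rotate_trajectories(y: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                         phi: np.ndarray) -> np.ndarray:
    """Rotate trajectories (n, k, T) by per-time angles ``phi`` (T,) within
    the (e1, e2) plane; orthogonal components are untouched."""
    a = np.einsum("nkt,k->nt", y, e1)
    b = np.einsum("nkt,k->nt", y, e2)
    rest = y - a[:, None, :] * e1[None, :, None] - b[:, None, :] * e2[None, :, None]
    c, s = np.cos(phi)[None, :], np.sin(phi)[None, :]
    return (
        rest
        + (a * c - b * s)[:, None, :] * e1[None, :, None]
        + (a * s + b * c)[:, None, :] * e2[None, :, None]
    )


def _synth_from_amplitude(amp, n_series, n_samples, sd, rng, dtype=np.float64):
    """Time series with the given one-sided spectral amplitude profile,
    random phases, and total s.d. ``sd``."""
    w = np.full_like(amp, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    var = (w * amp**2).sum() / n_samples**2
    scale = sd / np.sqrt(2.0 * var) if var > 0 else 0.0
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    g = rng.standard_normal((n_series, amp.size, 2)).astype(dtype)
    c = (amp.astype(dtype) * (g[..., 0] + 1j * g[..., 1])).astype(cdtype)
    return np.fft.irfft(c, n=n_samples, axis=-1).astype(dtype) * dtype(scale)


def _band_amplitude(freqs, f_lo, f_hi, taper_frac=0.25):
    """Flat band-pass amplitude profile with cosine edges."""
    amp = np.zeros_like(freqs)
    width = (f_hi - f_lo) * taper_frac
    core = (freqs >= f_lo + width) & (freqs <= f_hi - width)
    amp[core] = 1.0
    for lo_edge, rising in ((f_lo, True), (f_hi - width, False)):
        sel = (freqs >= lo_edge) & (freqs < lo_edge + width)
        ph = (freqs[sel] - lo_edge) / width
        amp[sel] = 0.5 * (1 - np.cos(np.pi * ph)) if rising else 0.5 * (1 + np.cos(np.pi * ph))
    return amp


def _smooth_noise(n_series, n_samples, fs, cutoff, sd, rng, dtype=np.float64):
    """Low-pass Gaussian noise with a cosine roll-off above ``cutoff``."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.ones_like(freqs)
    roll = (freqs > cutoff) & (freqs < 1.5 * cutoff)
    amp[roll] = 0.5 * (1 + np.cos(np.pi * (freqs[roll] - cutoff) / (0.5 * cutoff)))
    amp[freqs >= 1.5 * cutoff] = 0.0
    amp[0] = 0.0
    return _synth_from_amplitude(amp, n_series, n_samples, sd, rng, dtype)


def _slow_state_noise(n_series, n_samples, fs, band, sd, rng, dtype=np.float64):
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    return _synth_from_amplitude(_band_amplitude(freqs, *band), n_series,
                                 n_samples, sd, rng, dtype)


def _combine_amplitudes(parts, n_samples):
    """Merge (amplitude profile, target sd) pairs into one profile + sd.

    Each profile is rescaled to its target variance; the merged profile's
    power is the sum, so a single synthesis pass reproduces the sum of
    independent syntheses in distribution.
    """
    w = None
    total_power = None
    total_var = 0.0
    for amp, sd in parts:
        if sd <= 0:
            continue
        if w is None:
            w = np.full_like(amp, 2.0)
            w[0] = 1.0
            if n_samples % 2 == 0:
                w[-1] = 1.0
            total_power = np.zeros_like(amp)
        var = 2.0 * (w * amp**2).sum() / n_samples**2
        if var == 0:
            continue
        total_power += amp**2 * (sd**2 / var)
        total_var += sd**2
    if total_power is None or total_var == 0:
        return np.zeros(1), 0.0
    return np.sqrt(total_power), float(np.sqrt(total_var))


def _one_over_f_amplitude(freqs, exponent, fmax):
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[freqs > fmax] = 0.0
    return amp


def _contract_directions(v: np.ndarray, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Unit directions of ``v`` with their angle to ``unit(mu)`` scaled by kappa.

    v: (n, k, T); mu: (n, k, T) or (k, T); kappa: (T,). Returns unit vectors.
    """
    eps = 1e-12
    vu = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), eps)
    mu_u = mu / np.maximum(np.linalg.norm(mu, axis=-2, keepdims=True), eps)
    if mu_u.ndim == 2:
        mu_u = mu_u[None]
    cos_t = np.clip((vu * mu_u).sum(axis=1, keepdims=True), -1.0, 1.0)
    theta = np.arccos(cos_t)
    tang = vu - cos_t * mu_u
    sin_t = np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), eps)
    tau = tang / sin_t
    theta2 = kappa[None, None, :] * theta
    out = np.cos(theta2) * mu_u + np.sin(theta2) * tau
    degen = np.sin(theta) < 1e-9  # v (anti)parallel to mu: unchanged
    return np.where(degen, vu, out)


def _mixing_gains(cfg: SimulationConfig) -> np.ndarray:
    """Per-latent-dimension sensor gains (decaying -> distinct eigenvalues).

    The first two axes span the transient-rotation plane and share one gain
    (their geometric mean) so rotation is an isometry of the gain metric.
    """
    g = np.geomspace(*cfg.mixing_gain_range, cfg.k_lat)
    if cfg.k_lat >= 2:
        g[0] = g[1] = np.sqrt(g[0] * g[1])
    return g


def _rescale_to_gain_norm(u_dir: np.ndarray, ref: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Scale unit directions so the gain-metric norm |G x| equals |G ref|.

    The downstream analyses measure norms in component space, where latent
    dimensions carry the mixing gains; anchoring |G x| to the (stationary)
    reference ensemble keeps the observed norm distribution stationary.
    With no contraction this reproduces ``ref`` exactly.
    """
    g = gains[None, :, None]
    r_g = np.linalg.norm(g * ref, axis=1)
    denom = np.maximum(np.linalg.norm(g * u_dir, axis=1), 1e-12)
    return (r_g / denom)[:, None, :] * u_dir


def _calibrate_kappa(cfg: SimulationConfig, frame: np.ndarray) -> float:
    """Inner angular-contraction factor hitting the configured per-dimension
    s.d. ratio at the envelope peak (deterministic Monte-Carlo bisection).

    Realized s.d. ratios are evaluated in the gain metric (component
    space), matching what the analyses observe; the transient rotation is
    a gain-metric isometry and does not enter.
    """
    if cfg.contraction >= 1.0:
        return 1.0
    rng = np.random.default_rng(987654321)
    k = cfg.k_lat
    gains = _mixing_gains(cfg)
    mu0 = cfg.direction_concentration * frame[:, 0]
    d = rng.standard_normal((6000, k)) * cfg.sigma_dev
    ref = (mu0[None] + d)[:, :, None]  # (n, k, 1)
    g_ref = gains[None, :] * ref[:, :, 0]
    target = np.log(cfg.contraction) * k  # log of the s.d.-product ratio
    base = np.log(g_ref.std(axis=0, ddof=1)).sum()

    def log_ratio(kappa):
        u = _contract_directions(ref, mu0[:, None], np.array([kappa]))
        x = _rescale_to_gain_norm(u, ref, gains)[:, :, 0]
        sd = np.maximum((gains[None, :] * x).std(axis=0, ddof=1), 1e-300)
        return np.log(sd).sum() - base

    if log_ratio(0.0) > target:
        return 0.0
    if log_ratio(1.0) <= target:
        return 1.0
    return float(brentq(lambda kp: log_ratio(kp) - target, 0.0, 1.0, xtol=1e-4))


def _selection_params(cfg: SimulationConfig):
    """Probit-selection coefficients (a, b): P(seen | z) = Phi(a z + b),
    calibrated so the marginal seen-rate is ``p_seen`` and the seen/unseen
    separation of the standardized pre-stimulus state z is ``initial_offset``."""
    p = min(max(cfg.p_seen, 1e-6), 1 - 1e-6)
    tau = st.norm.ppf(1 - p)
    rho = cfg.initial_offset * p * (1 - p) / st.norm.pdf(tau)
    rho = float(np.clip(rho, 0.0, 0.99))
    a = rho / np.sqrt(1 - rho**2)
    b = st.norm.ppf(p) * np.sqrt(1 + a**2)
    return a, b


# -- latent machinery -------------------------------------------------------

def _draw_deviations(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Trial deviations d_i(t) = slow state + within-trial wander, (n, k, T)."""
    T = len(cfg.times)
    slow = _slow_state_noise(n * cfg.k_lat, T, cfg.fs, cfg.slow_band_hz,
                             cfg.sigma_trial, rng).reshape(n, cfg.k_lat, T)
    fast = _smooth_noise(n * cfg.k_lat, T, cfg.fs, cfg.within_cutoff_hz,
                         cfg.sigma_within, rng).reshape(n, cfg.k_lat, T)
    return slow + fast


def _prestim_state(cfg: SimulationConfig, d: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Mean pre-stimulus deviation along a latent axis, standardized."""
    pre = cfg.times < 0
    z = d[:, :, pre].mean(axis=2) @ axis
    sd = z.std()
    return z / sd if sd > 0 else z


def _assemble_latents(cfg: SimulationConfig, d: np.ndarray, seen: np.ndarray,
                      orientations: np.ndarray, kappa_min: float,
                      frame: np.ndarray) -> np.ndarray:
    """Compose latent trajectories from deviations + condition structure.

    The cloud is built around the *fixed* baseline mean (direction-only
    contraction with norms anchored to the stationary reference ensemble
    ``mu0 + d``), then the whole cloud is rotated by the transient angle
    profile. The rotation plane spans two equal-gain axes, so it is an
    isometry of both the latent and the gain metric: norms, angles and the
    across-trial s.d. product are all exactly preserved by the rotation.
    """
    times = cfg.times
    u_base, u_off, e_rot, u_ori = frame.T
    mu0 = cfg.direction_concentration * u_base
    _, F = _speed_profile(times, cfg.transient_peak_s, cfg.transient_shape)
    ori_bump = cfg.orientation_gain * cfg.sigma_dev * _unit_bump(times, cfg.orientation_peak_s)
    env = _unit_bump(times, cfg.contraction_peak_s)
    gains = _mixing_gains(cfg)
    x = np.empty_like(d)
    for flag in (True, False):
        idx = np.flatnonzero(np.asarray(seen, bool) == flag)
        if idx.size == 0:
            continue
        mu = mu0[None, :, None] + (
            np.asarray(orientations, float)[idx, None, None]
            * ori_bump[None, None, :] * u_ori[None, :, None]
        )
        v = mu + d[idx]
        if flag and cfg.contraction < 1.0:
            kappa = 1.0 - (1.0 - kappa_min) * env
        else:
            kappa = np.ones_like(times)
        u = _contract_directions(v, mu, kappa)
        y = _rescale_to_gain_norm(u, mu0[None, :, None] + d[idx], gains)
        gain = cfg.transient_gain_seen if flag else cfg.transient_gain_unseen
        x[idx] = _rotate_trajectories(y, u_base, e_rot, gain * F)
    return x


def generate_latent(cfg: SimulationConfig, seen: bool, orientations: np.ndarray,
                    rng: np.random.Generator, kappa_min: float | None = None,
                    frame: np.ndarray | None = None):
    """Latent trajectories (n_trials, k_lat, n_samples) for one condition.

    Trials are rejection-sampled so their pre-stimulus state is distributed
    as in trials selected seen (or unseen) by the probit rule.
    ``orientations`` is +1 for "left" (135 deg), -1 for "right" (45 deg).
    Returns ``(x, prestim_ori)``: the trajectories and each trial's
    standardized mean pre-stimulus projection on the orientation axis (the
    quantity that may bias unseen responses).
    """
    n = len(orientations)
    if frame is None:
        frame = _latent_frame(cfg, np.random.default_rng(cfg.mixing_seed))
    if kappa_min is None:
        kappa_min = _calibrate_kappa(cfg, frame)
    a, b = _selection_params(cfg)

    kept = []
    n_kept = 0
    while n_kept < n:
        batch = max(32, int(1.5 * (n - n_kept) / max(cfg.p_seen if seen else 1 - cfg.p_seen, 0.05)))
        d = _draw_deviations(cfg, batch, rng)
        z = _prestim_state(cfg, d, frame[:, 1])
        p_seen_given_z = st.norm.cdf(a * z + b)
        accept = rng.random(batch) < (p_seen_given_z if seen else 1 - p_seen_given_z)
        d = d[accept][: n - n_kept]
        if d.shape[0]:
            kept.append(d)
            n_kept += d.shape[0]
    d = np.concatenate(kept, axis=0)
    flags = np.full(n, bool(seen))
    x = _assemble_latents(cfg, d, flags, orientations, kappa_min, frame)
    return x, _prestim_state(cfg, d, frame[:, 3])


def _solve_unseen_dprime(cfg: SimulationConfig) -> float:
    theta = cfg.innate_bias_c
    s = float(np.hypot(1.0, cfg.prestim_coupling))

    def acc(dp):
        return 0.5 * (st.norm.cdf((dp / 2 - theta) / s) + st.norm.cdf((dp / 2 + theta) / s)) - cfg.p_correct_unseen

    if acc(0.0) >= 0:
        return 0.0
    return float(brentq(acc, 0.0, 20.0))


def generate_behavior(cfg: SimulationConfig, seen: np.ndarray, orientations: np.ndarray,
                      prestim_ori: np.ndarray, rng: np.random.Generator):
    """Per-trial responses (+1 left / -1 right) from the SDT model.

    Seen trials answer correctly with probability ``p_correct_seen``.
    Unseen trials threshold a Gaussian decision variable with sensitivity
    solved to match ``p_correct_unseen``, criterion ``innate_bias_c``
    (negative = liberal toward "left"), and a criterion shift of
    ``prestim_coupling * prestim_ori`` toward the orientation whose evoked
    template the pre-stimulus state resembles.
    """
    seen = np.asarray(seen, bool)
    orientations = np.asarray(orientations, float)
    n = len(seen)
    responses = np.empty(n)
    correct_seen = rng.random(int(seen.sum())) < cfg.p_correct_seen
    responses[seen] = np.where(correct_seen, orientations[seen], -orientations[seen])

    uns = ~seen
    dp = _solve_unseen_dprime(cfg)
    v = (dp / 2) * orientations[uns] + cfg.prestim_coupling * np.asarray(prestim_ori)[uns] \
        + rng.standard_normal(int(uns.sum()))
    responses[uns] = np.where(v > cfg.innate_bias_c, 1.0, -1.0)
    return responses


# -- full dataset -----------------------------------------------------------

_ORI_LABEL = {1.0: "left", -1.0: "right"}


def generate_subject(cfg: SimulationConfig, subject_index: int = 0,
                     seed: int | None = None, chunk: int = 50):
    """One synthetic subject: EpochedRecording (band="raw") + ground truth.

    Deterministic given (cfg, seed, subject_index). Sensor data is
    ``signal_scale * mixing @ latent + 1/f noise + band oscillations``,
    scaled to tesla-like magnitudes by ``data_scale``.
    """
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng([int(seed) % (2**31), subject_index])
    mix_rng = np.random.default_rng(cfg.mixing_seed)
    frame = _latent_frame(cfg, mix_rng)
    mixing, _ = np.linalg.qr(mix_rng.standard_normal((cfg.n_sensors, cfg.k_lat)))
    # decaying per-dimension sensor gains give the PC spectrum a realistic
    # decay (distinct eigenvalues -> stable component identity across fits)
    mixing = mixing * _mixing_gains(cfg)[None, :]
    kappa_min = _calibrate_kappa(cfg, frame)
    a, b = _selection_params(cfg)

    n = cfg.n_trials_per_subject
    times = cfg.times
    T = len(times)
    dtype = np.dtype(cfg.dtype).type

    d = _draw_deviations(cfg, n, rng)
    z = _prestim_state(cfg, d, frame[:, 1])
    seen = rng.random(n) < st.norm.cdf(a * z + b)
    orientations = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    latent = _assemble_latents(cfg, d, seen, orientations, kappa_min, frame)
    prestim_ori = _prestim_state(cfg, d, frame[:, 3])
    del d
    responses = generate_behavior(cfg, seen, orientations, prestim_ori, rng)

    freqs = np.fft.rfftfreq(T, 1.0 / cfg.fs)
    amp_alpha = _band_amplitude(freqs, 8.0, 12.0)
    alpha_sd = cfg.alpha_amp / np.sqrt(2.0)
    beta_sd = cfg.beta_amp / np.sqrt(2.0)
    # broadband 1/f and beta share one synthesis pass (amplitudes add in power)
    amp_bb, bb_sd = _combine_amplitudes(
        [(_one_over_f_amplitude(freqs, cfg.noise_exponent, cfg.noise_fmax), cfg.noise_sd),
         (_band_amplitude(freqs, 17.0, 25.0), beta_sd)],
        T,
    )
    quench = (1.0 - cfg.alpha_quench_seen * _unit_bump(times, 0.5)).astype(dtype)

    data = np.empty((n, cfg.n_sensors, T), dtype=dtype)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        block = np.einsum("sk,nkt->nst", mixing, latent[lo:hi]).astype(dtype)
        block *= dtype(cfg.signal_scale)
        if bb_sd > 0:
            block += _synth_from_amplitude(amp_bb, m * cfg.n_sensors, T,
                                           bb_sd, rng, np.float32
                                           ).reshape(m, cfg.n_sensors, T)
        if cfg.alpha_amp > 0:
            alpha = _synth_from_amplitude(amp_alpha, m * cfg.n_sensors, T,
                                          alpha_sd, rng, np.float32
                                          ).reshape(m, cfg.n_sensors, T)
            if cfg.alpha_quench_seen:
                alpha[seen[lo:hi]] *= quench[None, None, :]
            block += alpha
            del alpha
        data[lo:hi] = block * dtype(cfg.data_scale)
        del block

    sid = f"S{subject_index + 1:02d}"
    meta = pd.DataFrame({
        "subject_id": sid,
        "session_id": "sess1",
        "seen": seen.astype(int),
        "orientation": [_ORI_LABEL[o] for o in orientations],
        "response": [_ORI_LABEL[o] for o in responses],
        "correct": (responses == orientations).astype(int),
    })
    rec = EpochedRecording(
        data=data, fs=cfg.fs, times=times,
        sensor_names=ctf_sensor_names(cfg.n_sensors), meta=meta, band="raw",
    )
    truth = {
        "subject_id": sid,
        "kappa_min": kappa_min,
        "selection_a_b": (a, b),
        "unseen_d_prime": _solve_unseen_dprime(cfg),
        "frame": frame.tolist(),
        "prestim_ori": prestim_ori.tolist(),
        "prestim_state": z.tolist(),
        "config": asdict(cfg),
    }
    return rec, truth


def generate_dataset(cfg: SimulationConfig, seed: int | None = None):
    """All subjects of the synthetic study. Returns (recordings, truths)."""
    recs, truths = [], []
    for s in range(cfg.n_subjects):
        rec, tr = generate_subject(cfg, s, seed=seed)
        recs.append(rec)
        truths.append(tr)
    return recs, truths
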