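"""Synthetic direction-tuned sessions for an 8-target center-out task.

The generator plants, in a controllable way, the two statistical
structures the decoder exploits:

* delta band (0.3-4 Hz) — the inter-channel covariance varies smoothly
  and 360-deg-periodically with target direction. Band-limited Gaussian
  sources are mixed into channels through a direction-dependent mixing
  matrix ``A(theta) = (1-e) A0 + e * sum_p vM(theta; phi_p, kappa) A_p``,
  a von Mises-weighted blend of a few fixed "columnar" patterns, so
  neighboring directions have similar spatial covariances;
* upper gamma band (48-200 Hz) — per-channel envelope gain is cosine
  tuned: ``g_c(theta, t) = b_c (1 + gamma_depth cos(theta - phi_c) r(t))``.

Both effects follow the task-epoch ramp ``r(t)``: zero during the
baseline, ``delay_leak`` from cue onset through the delay (weak
preparatory information), rising linearly to 1 at movement onset and
staying there through movement and hold. Spatially correlated pink
noise, optional line noise, and cosine-tuned Poisson spiking complete
the picture.

Trial epochs follow the instructed-delay timeline: 800 ms baseline
hold, 600 ms cue, 900 ms delay, 1000 ms movement, 800 ms target hold;
time 0 = movement onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .io import SpikeSet, TrialSet

__all__ = ["SimConfig", "simulate_session", "simulate_spikes", "drift_session"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (defaults = the standard strong-effect session).

    delta_effect and gamma_depth set the planted effect sizes in [0, 1];
    delay_leak is the fraction of the full effect already present during
    the cue/delay period; drift jitters the session-specific structure
    (mixing phases, channel gains) for cross-session stability studies.
    """

    n_trials_per_class: int = 40
    n_channels: int = 32
    K: int = 8
    fs: float = 1000.0
    baseline_ms: float = 800.0
    cue_ms: float = 600.0
    delay_ms: float = 900.0
    move_ms: float = 1000.0
    hold_ms: float = 800.0
    rise_ms: float = 300.0
    delta_sources: int = 6
    kappa: float = 2.0
    delta_effect: float = 0.8
    gamma_depth: float = 0.5
    delay_leak: float = 0.3
    noise_sigma: float = 2.5
    common_noise_frac: float = 0.3
    drift: float = 0.0
    line_noise_channels: tuple = ()
    line_noise_amp: float = 0.0
    seed: int = 0
    session_index: int = 0

    def validate(self) -> "SimConfig":
        for name in ("delta_effect", "gamma_depth", "delay_leak",
                     "common_noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        for name in ("baseline_ms", "cue_ms", "delay_ms", "move_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.drift < 0:
            raise ConfigurationError("drift must be >= 0")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        return self

    @property
    def epoch_ms(self) -> float:
        return (self.baseline_ms + self.cue_ms + self.delay_ms
                + self.move_ms + self.hold_ms)

    @property
    def t0_ms(self) -> float:
        """Time of the first sample relative to movement onset."""
        return -(self.baseline_ms + self.cue_ms + self.delay_ms)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms * self.fs / 1000.0))


def drift_session(cfg: SimConfig, session_index: int) -> SimConfig:
    """Config for a later recording session of the same implant.

    The structural parameters (mixing phases, channel gains) are jittered
    by Gaussian noise of SD ``cfg.drift`` deterministically per
    (seed, session_index); trial noise is independent across sessions
    either way.
    """
    return replace(cfg, session_index=int(session_index))


# ------------------------------------------------------------------
# internals
# ------------------------------------------------------------------

def _ramp(cfg: SimConfig) -> np.ndarray:
    """Task-epoch information ramp at cfg.fs, in [0, 1]."""
    t = cfg.t0_ms + 1000.0 * np.arange(cfg.n_samples) / cfg.fs
    r = np.zeros_like(t)
    cue_on = -(cfg.cue_ms + cfg.delay_ms)
    r[t >= cue_on] = cfg.delay_leak
    rise = (t >= -cfg.rise_ms) & (t < 0)
    r[rise] = cfg.delay_leak + (1.0 - cfg.delay_leak) * (
        (t[rise] + cfg.rise_ms) / cfg.rise_ms
    )
    r[t >= 0] = 1.0
    return r


def _bandlimited_noise(rng, shape, low, high, fs) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz (FFT mask)."""
    n = shape[-1]
    x = rng.standard_normal(shape)
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    X[..., (f < low) | (f > high)] = 0.0
    y = np.fft.irfft(X, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def _pink_noise(rng, shape, fs, f_min=0.3) -> np.ndarray:
    """Unit-variance 1/f ("pink") noise, flat below f_min."""
    n = shape[-1]
    x = rng.standard_normal(shape)
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, f_min))
    scale[0] = 0.0  # no DC
    y = np.fft.irfft(X * scale, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def _structure(cfg: SimConfig) -> Dict[str, np.ndarray]:
    """Session-level structural parameters, deterministic from the seed.

    With session_index != 0 and drift > 0, the mixing-pattern phases and
    the gamma channel gains are jittered (same structural identity,
    non-stationary details).
    """
    rng = np.random.default_rng([cfg.seed, 101])
    C, J, P = cfg.n_channels, cfg.delta_sources, cfg.K
    A0 = rng.standard_normal((C, J)) / np.sqrt(J)
    A_p = rng.standard_normal((P, C, J)) / np.sqrt(J)
    phi_p = 2.0 * np.pi * np.arange(P) / P
    b_c = rng.uniform(0.5, 1.0, size=C)
    phi_c = rng.uniform(0.0, 2.0 * np.pi, size=C)
    if cfg.session_index != 0 and cfg.drift > 0:
        drift_rng = np.random.default_rng([cfg.seed, 202, cfg.session_index])
        phi_p = phi_p + drift_rng.normal(0.0, cfg.drift, size=P)
        b_c = np.clip(b_c + drift_rng.normal(0.0, cfg.drift, size=C), 0.1, None)
        phi_c = phi_c + drift_rng.normal(0.0, cfg.drift, size=C)
    return dict(A0=A0, A_p=A_p, phi_p=phi_p, b_c=b_c, phi_c=phi_c)


def _vm_weights(theta: float, phi_p: np.ndarray, kappa: float) -> np.ndarray:
    w = np.exp(kappa * np.cos(theta - phi_p))
    return w / w.sum()


def mixing_matrix(cfg: SimConfig, theta: float, struct=None) -> np.ndarray:
    """Direction-dependent delta mixing matrix A(theta) at full effect."""
    s = struct or _structure(cfg)
    w = _vm_weights(theta, s["phi_p"], cfg.kappa)
    A_dir = np.tensordot(w, s["A_p"], axes=1)
    return (1.0 - cfg.delta_effect) * s["A0"] + cfg.delta_effect * A_dir


def delta_covariance(cfg: SimConfig, theta: float) -> np.ndarray:
    """Analytic peri-movement delta covariance A(theta) A(theta)'."""
    A = mixing_matrix(cfg, theta)
    return A @ A.T


# ------------------------------------------------------------------
# session generation
# ------------------------------------------------------------------

def simulate_session(cfg: SimConfig) -> tuple[TrialSet, Dict]:
    """Generate one session; returns (TrialSet, ground-truth record).

    Reproducible bit-for-bit from (seed, session_index). The ground
    truth holds every parameter plus the per-trial direction angle.
    """
    cfg.validate()
    s = _structure(cfg)
    rng = np.random.default_rng([cfg.seed, 17, cfg.session_index])
    C, n = cfg.n_channels, cfg.n_samples
    K = cfg.K
    n_trials = cfg.n_trials_per_class * K
    labels = np.repeat(np.arange(K), cfg.n_trials_per_class)
    rng.shuffle(labels)
    ramp = _ramp(cfg)
    e_t = cfg.delta_effect * ramp  # time-varying mixing depth

    data = np.empty((n_trials, C, n), dtype=np.float32)
    for i, k in enumerate(labels):
        theta = 2.0 * np.pi * k / K
        # (a) delta component: direction-dependent mixing, ramped
        src = _bandlimited_noise(rng, (cfg.delta_sources, n), 0.3, 4.0, cfg.fs)
        w = _vm_weights(theta, s["phi_p"], cfg.kappa)
        A_dir = np.tensordot(w, s["A_p"], axes=1)
        base = s["A0"] @ src
        tuned = A_dir @ src
        delta = base * (1.0 - e_t) + tuned * e_t
        # (b) gamma component: cosine-tuned envelope gain, ramped
        carrier = _bandlimited_noise(rng, (C, n), 48.0, 200.0, cfg.fs)
        gain = s["b_c"][:, None] * (
            1.0 + cfg.gamma_depth
            * np.cos(theta - s["phi_c"])[:, None] * ramp[None, :]
        )
        gamma = gain * carrier
        # (c) spatially correlated pink background noise
        common = _pink_noise(rng, (1, n), cfg.fs)
        private = _pink_noise(rng, (C, n), cfg.fs)
        noise = cfg.noise_sigma * (
            np.sqrt(cfg.common_noise_frac) * common
            + np.sqrt(1.0 - cfg.common_noise_frac) * private
        )
        x = delta + gamma + noise
        if cfg.line_noise_channels and cfg.line_noise_amp > 0:
            t = np.arange(n) / cfg.fs
            tone = cfg.line_noise_amp * np.sin(
                2.0 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
            )
            for ch in cfg.line_noise_channels:
                x[ch] += tone
        data[i] = x.astype(np.float32)

    trialset = TrialSet(
        data=data, fs=cfg.fs, labels=labels,
        alignment="movement_onset", t0_ms=cfg.t0_ms,
        session_id=cfg.session_index, n_classes=K,
    )
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "theta_deg": (labels * 360.0 / K).tolist(),
    }
    return trialset, truth


# ------------------------------------------------------------------
# spiking
# ------------------------------------------------------------------

def simulate_spikes(
    cfg: SimConfig,
    n_units: int = 24,
    base_rate: float = 25.0,
    mod_depth: float = 0.8,
) -> SpikeSet:
    """Cosine-tuned inhomogeneous-Poisson spike trains.

    Unit u fires at ``base_rate * (1 + mod_depth cos(theta - pref_u)) *
    r(t)`` where r(t) is the task-epoch ramp; preferred directions are
    uniform on the circle. Times are drawn by inverting the cumulative
    rate, so the process is exactly Poisson in the time-rescaled sense.
    """
    cfg.validate()
    if base_rate * (1.0 - mod_depth) < 0:
        raise ConfigurationError("base_rate * (1 - mod_depth) must be >= 0")
    rng = np.random.default_rng([cfg.seed, 23, cfg.session_index])
    K = cfg.K
    n_trials = cfg.n_trials_per_class * K
    labels = np.repeat(np.arange(K), cfg.n_trials_per_class)
    rng.shuffle(labels)
    prefs = rng.uniform(0.0, 2.0 * np.pi, size=n_units)
    ramp = _ramp(cfg)
    dt = 1.0 / cfg.fs
    t_ms = cfg.t0_ms + 1000.0 * np.arange(cfg.n_samples) / cfg.fs
    units: List[List[np.ndarray]] = [[] for _ in range(n_units)]
    for j, k in enumerate(labels):
        theta = 2.0 * np.pi * k / K
        for u in range(n_units):
            rate = base_rate * (1.0 + mod_depth * np.cos(theta - prefs[u])) * ramp
            cum = np.cumsum(rate) * dt
            total = cum[-1]
            n_sp = rng.poisson(total)
            if n_sp == 0:
                units[u].append(np.empty(0))
                continue
            u01 = np.sort(rng.uniform(0.0, total, size=n_sp))
            times = np.interp(u01, cum, t_ms)
            units[u].append(times)
    return SpikeSet(
        units=units, labels=labels, alignment="movement_onset",
        session_id=cfg.session_index, n_classes=K,
    )
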