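"""Synthetic rehabilitation-exercise recordings.

Emulates the structure the recognition/evaluation stack assumes: four
movement classes, each performed at three quality levels (good / average /
bad), each recording being ten repetitions in a row by one subject.  Every
action has a distinct per-axis template (Gaussian activation bumps plus a
sinusoid at an action-specific repetition frequency); quality degrades by
shrinking movement amplitude, adding timing jitter, and adding tremor.
Subjects contribute a random time-warp and gain.  A constant gravity vector
(about 1 g, with a small action-specific tilt) underlies the body motion so
the gravity/body separation is meaningful.

Not modelled: biomechanics, sensor drift, inter-sensor placement variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SignalRecording

__all__ = ["SynthConfig", "generate_dataset", "generate_known_gmm"]

# per-axis templates: (bumps [(amp, center, width)], sine amp, sine phase)
# actions differ in repetition frequency (cycles per repetition) and bumps
_ACTION_FREQ = [1.0, 2.0, 3.0, 4.0]
_ACTION_BUMPS = [
    [[(0.8, 0.30, 0.08), (0.5, 0.70, 0.10)],
     [(0.6, 0.50, 0.12)],
     [(0.4, 0.25, 0.07), (0.4, 0.75, 0.07)]],
    [[(0.7, 0.20, 0.06), (0.7, 0.60, 0.06)],
     [(0.9, 0.40, 0.10), (0.3, 0.80, 0.08)],
     [(0.5, 0.55, 0.15)]],
    [[(0.5, 0.45, 0.18)],
     [(0.8, 0.25, 0.08), (0.6, 0.65, 0.09)],
     [(0.7, 0.35, 0.08), (0.3, 0.85, 0.06)]],
    [[(0.9, 0.55, 0.09), (0.4, 0.15, 0.06)],
     [(0.4, 0.30, 0.14), (0.6, 0.70, 0.07)],
     [(0.8, 0.50, 0.10)]],
]
_SINE_AMP = [0.35, 0.30, 0.30, 0.25]
_GRAVITY_TILT = [0.0, 0.12, 0.24, 0.36]  # radians about the x-axis, per action


@dataclass
class SynthConfig:
    n_actions: int = 4
    n_levels: int = 3
    n_subjects: int = 20
    reps_per_recording: int = 10
    fs: float = 32.0
    rep_duration: float = 2.5            # seconds per repetition
    seed: int = 0
    noise_sd: float = 0.05               # g-units, sensor noise
    # quality degradation, index 0 = good
    level_amplitude: tuple = (1.0, 0.7, 0.4)
    level_jitter: tuple = (0.01, 0.03, 0.05)   # per-rep duration jitter sd
    level_tremor: tuple = (0.0, 0.04, 0.08)    # high-frequency tremor sd
    subject_warp: float = 0.10           # +-10% time-warp
    subject_gain: float = 0.15           # +-15% gain

    def __post_init__(self):
        if not all(a > b for a, b in zip(self.level_amplitude,
                                         self.level_amplitude[1:])):
            raise ValueError("level amplitudes must strictly decrease "
                             "good -> bad")


def _template(action: int, tau: np.ndarray) -> np.ndarray:
    """Noise-free per-axis body acceleration over phase tau in [0, 1)."""
    out = np.zeros((len(tau), 3))
    freq = _ACTION_FREQ[action]
    for axis in range(3):
        v = np.zeros_like(tau)
        for amp, c, w in _ACTION_BUMPS[action][axis]:
            v += amp * np.exp(-0.5 * ((tau - c) / w) ** 2)
        v += _SINE_AMP[action] * np.sin(2 * np.pi * freq * tau
                                        + 0.7 * axis + 0.3 * action)
        out[:, axis] = v
    return out


def _gravity(action: int) -> np.ndarray:
    a = _GRAVITY_TILT[action]
    return np.array([0.0, np.sin(a), np.cos(a)])


def generate_recording(cfg: SynthConfig, action: int, level: int,
                       subject: int, rng: np.random.Generator
                       ) -> SignalRecording:
    warp = 1.0 + rng.uniform(-cfg.subject_warp, cfg.subject_warp)
    gain = 1.0 + rng.uniform(-cfg.subject_gain, cfg.subject_gain)
    amp = cfg.level_amplitude[level] * gain
    parts = []
    boundaries = [0]
    for _ in range(cfg.reps_per_recording):
        jitter = 1.0 + np.clip(rng.normal(0.0, cfg.level_jitter[level]),
                               -0.15, 0.15)
        n = max(8, int(round(cfg.fs * cfg.rep_duration * warp * jitter)))
        tau = (np.arange(n) + 0.5) / n
        body = amp * _template(action, tau)
        if cfg.level_tremor[level] > 0:
            # high-frequency tremor: white noise modulated by movement phase
            body += rng.normal(0.0, cfg.level_tremor[level], (n, 3))
        parts.append(body)
        boundaries.append(boundaries[-1] + n)
    body = np.concatenate(parts, axis=0)
    acc = body + _gravity(action)[None, :]
    acc += rng.normal(0.0, cfg.noise_sd, acc.shape)
    t = np.arange(len(acc)) / cfg.fs
    return SignalRecording(
        t=t, acc=acc, action_label=action, level_label=level,
        recording_id=f"S{subject:02d}_A{action}_L{level}", subject=subject,
        rep_boundaries=np.array(boundaries))


def generate_dataset(cfg: SynthConfig) -> list[SignalRecording]:
    """One recording per (subject, action, level); fully determined by
    cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    recs = []
    for subject in range(cfg.n_subjects):
        for action in range(cfg.n_actions):
            for level in range(cfg.n_levels):
                recs.append(generate_recording(cfg, action, level, subject, rng))
    return recs


@dataclass
class KnownGmm:
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    samples: np.ndarray = field(repr=False)


def generate_known_gmm(dim: int = 4, K_g: int = 1, seed: int = 0,
                       n_samples: int = 2000, separation: float = 8.0
                       ) -> KnownGmm:
    """Samples from a known mixture plus its true parameters, for
    parameter-recovery tests."""
    if K_g < 1:
        raise ValueError("K_g must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.full(K_g, 1.0 / K_g)
    means = rng.normal(0.0, 1.0, (K_g, dim)) + \
        separation * np.arange(K_g)[:, None]
    covs = np.empty((K_g, dim, dim))
    for k in range(K_g):
        A = rng.normal(0.0, 1.0, (dim, dim)) / np.sqrt(dim)
        covs[k] = A @ A.T + 0.5 * np.eye(dim)
    comp = rng.choice(K_g, size=n_samples, p=weights)
    samples = np.empty((n_samples, dim))
    for k in range(K_g):
        idx = comp == k
        L = np.linalg.cholesky(covs[k])
        samples[idx] = means[k] + rng.normal(size=(idx.sum(), dim)) @ L.T
    return KnownGmm(weights, means, covs, samples)
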