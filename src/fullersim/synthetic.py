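"""Synthetic inputs with known ground truth.

These generators emulate the statistical structure the analysis stages
assume — thermally jittered cage configurations, radius-of-gyration-like
signals with known frequency content, and zero-net-charge point-charge
sets — so every observable can be tested without running dynamics.
All generators are pure functions of their inputs and a seed
(numpy ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fullersim.cage import CageGeometry

__all__ = [
    "SyntheticSpec",
    "SyntheticSignal",
    "jittered_cage",
    "synthetic_rg_signal",
    "random_zero_sum_charges",
]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic Rg-like signal.

    Defaults emulate a desk-scale recording: 10 ps at a 10 fs sampling
    stride around the C60 radius of gyration (3.44 Å), with tone
    frequencies in the terahertz band of the cage breathing modes.
    """

    seed: int = 0
    sigma_jitter: float = 0.05  # Å, thermal displacement scale at ~300 K
    tone_freqs: list[float] = field(default_factory=lambda: [3.3])  # THz
    tone_amps: list[float] = field(default_factory=lambda: [0.01])  # Å
    noise_sigma: float = 0.0  # Å
    n_samples: int = 1000
    dt: float = 10.0  # fs between samples
    baseline: float = 3.44  # Å

    def __post_init__(self) -> None:
        if self.sigma_jitter < 0:
            raise ValueError("sigma_jitter must be >= 0")
        if self.n_samples < 16:
            raise ValueError("need n_samples >= 16")
        nyquist = 1.0e3 / (2.0 * self.dt)  # THz
        if any(f >= nyquist for f in self.tone_freqs):
            raise ValueError(f"tone frequency above Nyquist ({nyquist:.3f} THz)")
        if len(self.tone_freqs) != len(self.tone_amps):
            raise ValueError("tone_freqs and tone_amps must have equal length")


@dataclass
class SyntheticSignal:
    """A generated signal together with its ground truth."""

    times: np.ndarray  # fs
    values: np.ndarray  # Å
    true_freqs: list[float]  # THz
    true_amps: list[float]  # Å
    dt: float  # fs


def jittered_cage(
    geometry: CageGeometry | np.ndarray, sigma: float, seed: int
) -> np.ndarray:
    """Positions with i.i.d. Gaussian displacement of scale sigma (Å)
    on every coordinate; deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = geometry.positions if isinstance(geometry, CageGeometry) else np.asarray(geometry)
    rng = np.random.default_rng(seed)
    return x + sigma * rng.standard_normal(x.shape)


def synthetic_rg_signal(spec: SyntheticSpec) -> SyntheticSignal:
    """Baseline + Σ amp·sin(2π f t + φ(seed)) + Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    t = spec.dt * np.arange(spec.n_samples)  # fs
    y = np.full(spec.n_samples, spec.baseline)
    for f, a in zip(spec.tone_freqs, spec.tone_amps):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y = y + a * np.sin(2.0 * np.pi * (f * 1.0e-3) * t + phase)  # THz·fs
    if spec.noise_sigma > 0:
        y = y + spec.noise_sigma * rng.standard_normal(spec.n_samples)
    return SyntheticSignal(times=t, values=y, true_freqs=list(spec.tone_freqs),
                           true_amps=list(spec.tone_amps), dt=spec.dt)


def random_zero_sum_charges(n: int, scale: float, seed: int) -> np.ndarray:
    """i.i.d. Gaussian charges (e) recentered to sum exactly to zero."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    q = scale * rng.standard_normal(n)
    q -= q.sum() / n
    q -= q.sum() / n  # second pass clears the O(eps) residual
    return q
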