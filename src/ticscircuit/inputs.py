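"""External drives: Gaussian-shaped pulses for dopamine bursts and cortical input."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PulseSpec", "gaussian_drive", "cortical_pulse"]


@dataclass(frozen=True)
class PulseSpec:
    """A Gaussian-shaped external drive.

    height : peak drive (activation-potential units; for the dopamine burst,
             the 0-100 burst scale, converted by the DA input gain)
    sd     : temporal standard deviation (seconds)
    center : pulse centre relative to trial start (seconds)
    per_channel_uniform_scaling : if True the pulse sent to each channel is
             independently multiplied by a Uniform(0, 1) draw, capturing
             differential inputs received by the three channels.
    """

    height: float
    sd: float
    center: float
    per_channel_uniform_scaling: bool = False

    def __post_init__(self):
        if self.height < 0:
            raise ValueError("pulse height must be non-negative")
        if self.height > 0 and self.sd <= 0:
            raise ValueError("pulse sd must be positive when height > 0")

    def profile(self, n_steps: int, dt: float, t0: float = 0.0) -> np.ndarray:
        """Unit-channel drive trace evaluated at step times ``t0 + k*dt``."""
        if self.height == 0:
            return np.zeros(n_steps)
        t = t0 + dt * np.arange(n_steps)
        return self.height * np.exp(-0.5 * ((t - self.center) / self.sd) ** 2)


def gaussian_drive(height, sd, center, n_steps, dt, t0=0.0):
    """Convenience wrapper: Gaussian pulse trace of length ``n_steps``."""
    return PulseSpec(height, sd if height > 0 else 1.0, center).profile(n_steps, dt, t0)


def cortical_pulse(spec: PulseSpec, rng: np.random.Generator, n_steps: int,
                   dt: float, n_channels: int = 3, t0: float = 0.0) -> np.ndarray:
    """Per-channel M1 drive traces, shape ``(n_steps, n_channels)``.

    All channels share the pulse's height, sd and centre; if the spec asks
    for per-channel uniform scaling, each channel's trace is multiplied by
    an independent Uniform(0, 1) draw.
    """
    base = spec.profile(n_steps, dt, t0)
    if spec.per_channel_uniform_scaling:
        scales = rng.uniform(0.0, 1.0, n_channels)
    else:
        scales = np.ones(n_channels)
    return np.outer(base, scales)
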