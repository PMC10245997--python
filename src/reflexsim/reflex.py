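"""Simulated H-reflex generator.

The feedback signal of the conditioning game is a synthetic H-reflex: a
single-period sine whose peak-to-peak amplitude is an affine function of the
wrapped angular error between the dial and the hidden target, multiplied by a
Gaussian "biological variability" factor beta ~ N(mu, sigma2) and corrupted by
an additive zero-mean noise sequence whose dominant spectral amplitude is
``noise_aN``.  The quantity shown to the player (and scored) is the
peak-to-peak magnitude of the realized noisy waveform.

Conventions
-----------
* Angles are degrees; the dial is circular, so errors are wrapped to [0, 180].
* Amplitudes are dimensionless, normalized so that the noiseless peak-to-peak
  is 0.5 at zero error (the best attainable performance) and 1.0 at 180 deg.
* Gaussian variates are produced by an explicit Box-Muller transform driven by
  a seeded uniform stream, so every draw is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HReflexParams",
    "HReflexTrialSignal",
    "wrap_error",
    "signed_delta",
    "peak_to_peak_map",
    "box_muller_pair",
    "draw_variability",
    "estimate_noise_power",
    "generate_noise",
    "simulate_hreflex",
    "trial_rng",
]

#: Variance of the biological-variability multiplier at the low / high setting.
SIGMA2_LV = 0.25
SIGMA2_HV = 0.75


@dataclass(frozen=True)
class HReflexParams:
    """Waveform, variability and noise parameters of the simulated reflex.

    Parameters
    ----------
    gain_g
        Slope of the noiseless peak-to-peak magnitude, per degree of wrapped
        error.  The default 0.5/180 makes the magnitude climb from 0.5 at
        perfect alignment to 1.0 at the maximal 180 deg error.
    intercept_c0
        Noiseless peak-to-peak magnitude at zero error (best performance).
    mu
        Mean of the variability multiplier beta.  1.0 centres the realized
        amplitude on the canonical one.
    sigma2
        Variance of beta; 0.25 and 0.75 are the low/high settings.
    noise_aN
        Dominant spectral amplitude of the additive noise sequence.
    n_samples
        Number of evenly spaced samples over the single sine period.
    rng_seed
        Master seed for the trial's random substreams.
    """

    gain_g: float = 0.5 / 180.0
    intercept_c0: float = 0.5
    mu: float = 1.0
    sigma2: float = SIGMA2_LV
    noise_aN: float = 0.05
    n_samples: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gain_g >= 0):
            raise ValueError(f"gain_g must be >= 0, got {self.gain_g}")
        if not (self.intercept_c0 >= 0):
            raise ValueError(f"intercept_c0 must be >= 0, got {self.intercept_c0}")
        if not (self.sigma2 >= 0):
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if not (self.noise_aN >= 0):
            raise ValueError(f"noise_aN must be >= 0, got {self.noise_aN}")
        if not (int(self.n_samples) == self.n_samples and self.n_samples >= 8):
            raise ValueError(f"n_samples must be an integer >= 8, got {self.n_samples}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HReflexParams":
        return cls(**d)


@dataclass(frozen=True)
class HReflexTrialSignal:
    """One realized simulated H-reflex: waveform, magnitude and components."""

    waveform: np.ndarray
    pkpk: float
    beta_drawn: float
    noise_component: np.ndarray

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=float)
        nz = np.asarray(self.noise_component, dtype=float)
        object.__setattr__(self, "waveform", wf)
        object.__setattr__(self, "noise_component", nz)
        if wf.shape != nz.shape:
            raise ValueError("waveform and noise_component must share a shape")
        if self.pkpk < 0:
            raise ValueError("pkpk must be nonnegative")


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def wrap_error(theta: float, theta_tar: float) -> float:
    """Minimal circular distance between two dial angles, in [0, 180] degrees."""
    theta = _check_finite("theta", theta)
    theta_tar = _check_finite("theta_tar", theta_tar)
    d = abs(theta - theta_tar) % 360.0
    return min(d, 360.0 - d)


def signed_delta(theta: float, theta_prev: float) -> float:
    """Signed minimal angular change theta - theta_prev, wrapped to [-180, 180)."""
    theta = _check_finite("theta", theta)
    theta_prev = _check_finite("theta_prev", theta_prev)
    return (theta - theta_prev + 180.0) % 360.0 - 180.0


def peak_to_peak_map(error: float, params: HReflexParams) -> float:
    """Noiseless peak-to-peak magnitude for a wrapped error in [0, 180] deg."""
    error = _check_finite("error", error)
    if not (0.0 <= error <= 180.0):
        raise ValueError(f"error must lie in [0, 180] (wrap first), got {error}")
    return params.intercept_c0 + params.gain_g * error


def box_muller_pair(u1: float, u2: float) -> tuple[float, float]:
    """Box-Muller transform: two independent standard normals from two uniforms.

    ``u1`` must lie in (0, 1] (the log singularity at 0 is rejected) and
    ``u2`` in [0, 1).
    """
    u1 = _check_finite("u1", u1)
    u2 = _check_finite("u2", u2)
    if not (0.0 < u1 <= 1.0):
        raise ValueError(f"u1 must lie in (0, 1], got {u1}")
    if not (0.0 <= u2 < 1.0):
        raise ValueError(f"u2 must lie in [0, 1), got {u2}")
    r = math.sqrt(-2.0 * math.log(u1))
    angle = 2.0 * math.pi * u2
    return r * math.cos(angle), r * math.sin(angle)


def _box_muller_stream(rng: np.random.Generator, size: int) -> np.ndarray:
    """Vectorized standard normals via the cosine branch of Box-Muller."""
    # 1 - U maps [0,1) onto (0,1], keeping the log argument strictly positive.
    u1 = 1.0 - rng.random(size)
    u2 = rng.random(size)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


def draw_variability(
    params: HReflexParams,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw beta ~ N(mu, sigma2) realizations via the seeded Box-Muller stream.

    With ``size=None`` returns a scalar, otherwise an array of ``size`` draws.
    ``sigma2 = 0`` returns exactly ``mu``.
    """
    n = 1 if size is None else int(size)
    z = _box_muller_stream(rng, n)
    beta = params.mu + math.sqrt(params.sigma2) * z
    return float(beta[0]) if size is None else beta


def _amplitude_spectrum(x: np.ndarray) -> np.ndarray:
    """Single-sided amplitude spectrum of a real sequence (DC excluded later)."""
    n = x.size
    amp = np.abs(np.fft.rfft(x)) * (2.0 / n)
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0  # Nyquist bin is not doubled
    return amp


def estimate_noise_power(signals: Iterable[Sequence[float]]) -> float:
    """Dominant non-fundamental spectral amplitude, averaged over waveforms.

    Each waveform is mean-subtracted and Fourier-transformed; the DC and
    fundamental (one-cycle-per-window) bins are excluded, and the amplitude of
    the largest remaining component is averaged across waveforms.  For a pure
    single-period sine this is 0; for a sine plus a second harmonic of
    amplitude a it is a.
    """
    maxima = []
    for sig in signals:
        x = np.asarray(sig, dtype=float)
        if x.ndim != 1 or x.size < 8:
            raise ValueError("each waveform must be 1-D with >= 8 samples")
        amp = _amplitude_spectrum(x - x.mean())
        maxima.append(float(amp[2:].max()))
    if not maxima:
        raise ValueError("need at least one waveform")
    return float(np.mean(maxima))


def generate_noise(params: HReflexParams, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise sequence whose dominant non-fundamental amplitude is aN.

    White Gaussian samples (Box-Muller stream) are mean-subtracted and rescaled
    so that ``estimate_noise_power`` applied to the result returns exactly
    ``noise_aN``.  ``noise_aN = 0`` yields all zeros.
    """
    n = int(params.n_samples)
    if params.noise_aN == 0.0:
        return np.zeros(n)
    raw = _box_muller_stream(rng, n)
    x = raw - raw.mean()
    dom = _amplitude_spectrum(x)[2:].max()
    if dom == 0.0:  # degenerate draw; no spectral content to scale
        return np.zeros(n)
    return x * (params.noise_aN / dom)


def simulate_hreflex(
    theta: float,
    theta_tar: float,
    params: HReflexParams,
    rng: np.random.Generator,
) -> HReflexTrialSignal:
    """Generate one simulated H-reflex for a committed dial position.

    The waveform is ``sin(2 pi i / n) * a * beta + p[i]`` where the sine
    amplitude ``a`` is half the noiseless peak-to-peak for the wrapped error,
    beta is the variability draw and p the additive noise.  The feedback
    magnitude is the peak-to-peak of the realized waveform.
    """
    error = wrap_error(theta, theta_tar)
    amplitude = peak_to_peak_map(error, params) / 2.0
    beta = draw_variability(params, rng)
    noise = generate_noise(params, rng)
    t = 2.0 * np.pi * np.arange(params.n_samples) / params.n_samples
    waveform = np.sin(t) * amplitude * beta + noise
    pkpk = float(waveform.max() - waveform.min())
    return HReflexTrialSignal(
        waveform=waveform, pkpk=pkpk, beta_drawn=beta, noise_component=noise
    )


def trial_rng(seed: int, k: int) -> np.random.Generator:
    """Deterministic per-trial substream derived from (seed, trial index).

    Trials are order-independent: trial k's draws depend only on the seed and
    k, never on how many draws earlier trials consumed.
    """
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), int(k)))))
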