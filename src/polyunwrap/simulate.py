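"""Synthetic wrapped-phase datasets with known ground truth.

Two phantoms are provided, matching the benchmark protocols this package
is validated against:

* a **Gaussian-bump** phantom: a smooth radially symmetric true phase
  (Gaussian profile, SD 20 voxels, 100³ grid) embedded in a complex signal
  with additive complex Gaussian noise; sweeping the magnitude from 10 to
  100 at noise SD 20 yields SNR 0.5 … 5;
* a **variable-gradient** phantom (101×101×51): a separable sinusoidal
  phase whose oscillation amplitude varies linearly along z, so different
  slices probe different phase-change levels; height 5, magnitude 50,
  noise SD 10 (SNR 5).

Noise is added to the *complex* signal (independent real/imaginary
channels, each with the given SD), so the observable wrapped phase carries
the realistic, magnitude-dependent phase noise of MR data.  The evaluation
reference is not the clean truth but the truth plus the noise-induced
principal phase change: a perfect unwrapper can then score an exact zero
error, since the reference is congruent to the noisy wrapped phase
modulo 2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import TWO_PI, wrap_to_principal, principal_difference

__all__ = [
    "SimulatedDataset",
    "simulate_gaussian_dataset",
    "simulate_eq_dataset",
    "reference_phase",
]


@dataclass
class SimulatedDataset:
    """A synthetic dataset with ground truth for scoring unwrappers."""

    true_phase: np.ndarray
    complex_data: np.ndarray
    wrapped_phase: np.ndarray
    reference_phase: np.ndarray
    magnitude_setting: float
    noise_sd: float
    snr: float
    seed: object

    @property
    def shape(self) -> tuple:
        return self.true_phase.shape

    def to_volume(self):
        """Package the wrapped phase (+ measured magnitude) as a WrappedVolume."""
        from .core import WrappedVolume
        return WrappedVolume(self.wrapped_phase,
                             magnitude=np.abs(self.complex_data))


def _angle_principal(data: np.ndarray) -> np.ndarray:
    """Principal argument in (-pi, pi] (np.angle may return exactly -pi)."""
    w = np.angle(data)
    w[w <= -np.pi] += TWO_PI
    return w


def reference_phase(true_phase: np.ndarray, wrapped_noisy: np.ndarray) -> np.ndarray:
    """Noise-corrected reference: truth plus the noise-induced phase change.

    ``reference = true + wrap(wrapped_noisy - wrap(true))`` — congruent to
    the noisy wrapped phase modulo 2*pi, and within pi of the truth.
    """
    true_phase = np.asarray(true_phase, dtype=float)
    wrapped_noisy = np.asarray(wrapped_noisy, dtype=float)
    if true_phase.shape != wrapped_noisy.shape:
        raise ValueError("shape mismatch between truth and wrapped phase")
    return true_phase + principal_difference(wrapped_noisy,
                                             wrap_to_principal(true_phase))


def _assemble(true_phase: np.ndarray, magnitude: float, noise_sd: float,
              seed) -> SimulatedDataset:
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    clean = magnitude * np.exp(1j * true_phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, true_phase.shape) \
            + 1j * rng.normal(0.0, noise_sd, true_phase.shape)
        data = clean + noise
    else:
        data = clean
    wrapped = _angle_principal(data)
    if noise_sd == 0:
        ref = true_phase.copy()
    else:
        ref = reference_phase(true_phase, wrapped)
    return SimulatedDataset(
        true_phase=true_phase, complex_data=data, wrapped_phase=wrapped,
        reference_phase=ref, magnitude_setting=float(magnitude),
        noise_sd=float(noise_sd),
        snr=float(magnitude / noise_sd) if noise_sd > 0 else float("inf"),
        seed=seed)


def simulate_gaussian_dataset(shape: Tuple[int, int, int] = (100, 100, 100),
                              gaussian_sd: float = 20.0,
                              peak: float = 20.0,
                              magnitude: float = 100.0,
                              noise_sd: float = 20.0,
                              seed=None) -> SimulatedDataset:
    """Gaussian-bump phantom with complex Gaussian noise.

    ``true_phase(v) = peak * exp(-||v - center||^2 / (2 * gaussian_sd^2))``
    with the bump centered at the exact volume center.  ``snr`` is
    ``magnitude / noise_sd``; the default sweep of the benchmark varies the
    magnitude from 10 to 100 at noise SD 20 (SNR 0.5 … 5).

    The peak of 20 rad (about three wraps from center to edge at the
    default geometry) keeps the voxelwise phase gradient well below pi.
    """
    if gaussian_sd <= 0:
        raise ValueError("gaussian_sd must be positive")
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                        indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    true_phase = peak * np.exp(-r2 / (2.0 * gaussian_sd ** 2))
    return _assemble(true_phase, magnitude, noise_sd, seed)


def simulate_eq_dataset(shape: Tuple[int, int, int] = (101, 101, 51),
                        height: float = 5.0,
                        magnitude: float = 50.0,
                        noise_sd: float = 10.0,
                        seed=None,
                        xy_scale: float = 0.25) -> SimulatedDataset:
    """Variable-gradient sinusoidal phantom.

    ``true = height * [(sin(x)/pi) * (1.50 - z) + (sin(y)/pi) * (0.49 + z)]``
    where ``x`` and ``y`` are the voxel indices times ``xy_scale`` (radians)
    and ``z`` is the slice index normalized to [0, 1].  The oscillation
    amplitude along x decreases and along y increases with z, producing
    different phase-change levels per slice.

    The default ``xy_scale`` of 0.25 gives a sinusoid period of ~25 voxels
    (four periods per axis) and a maximal phase gradient of ~0.6 rad/voxel
    — the same gradient scale as the Gaussian-bump phantom, and steep
    enough to produce several wrap lines per axis.  A scale of 1.0 (raw
    indices as radians, period 2*pi voxels) makes neighboring voxels
    differ by up to ~2.4 rad, which no windowed polynomial model can
    track; the parameter is exposed for such stress tests.
    """
    nx, ny, nz = shape
    x = np.arange(nx, dtype=float)[:, None, None] * xy_scale
    y = np.arange(ny, dtype=float)[None, :, None] * xy_scale
    z = (np.arange(nz, dtype=float) / max(1, nz - 1))[None, None, :]
    true_phase = height * ((np.sin(x) / np.pi) * (1.50 - z)
                           + (np.sin(y) / np.pi) * (0.49 + z))
    true_phase = np.ascontiguousarray(
        np.broadcast_to(true_phase, shape), dtype=np.float64)
    return _assemble(true_phase, magnitude, noise_sd, seed)
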