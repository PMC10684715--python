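"""Core domain types and principal-value phase arithmetic.

The wrapped phase measured by an MR scanner is the principal value of the
true phase: both agree modulo 2*pi, and unwrapping amounts to choosing the
integer number of 2*pi turns to add back at every voxel.  This module fixes
the conventions used throughout the package:

* the principal interval is the half-open ``(-pi, pi]`` (the ``atan2``
  convention, with the boundary ``-pi`` mapped to ``+pi``);
* ``unwrapped = wrapped + 2*pi*k`` with ``k`` an integer volume (``k`` may
  be negative — the sign of ``k`` is not externally observable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "wrap_to_principal",
    "principal_difference",
    "apply_offsets",
    "WrappedVolume",
    "UnwrapState",
]


def wrap_to_principal(angle):
    """Reduce an angle (scalar or array, radians) to the interval ``(-pi, pi]``.

    The reduction is exact modulo 2*pi: ``wrap_to_principal(x) - x`` is an
    integer multiple of 2*pi up to floating-point rounding.  ``-pi`` maps to
    ``+pi`` so every equivalence class has exactly one representative.

    Raises
    ------
    ValueError
        If any input value is NaN or infinite.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_to_principal requires finite input")
    # mod maps to [0, 2*pi); reflecting puts the result in (-pi, pi] with
    # both -pi and +pi landing on +pi.
    out = np.pi - np.mod(np.pi - a, TWO_PI)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def principal_difference(a, b):
    """Principal value of ``a - b`` in ``(-pi, pi]``, elementwise.

    This is the phase difference an observer of the wrapped signal can
    actually measure; it is used for quality maps and the noise-corrected
    reference phase.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape and a.shape != () and b.shape != ():
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return wrap_to_principal(a - b)


def apply_offsets(phase, k):
    """Return ``phase + 2*pi*k`` voxelwise.

    ``k`` must be integer-valued (any dtype); shapes must agree.
    """
    phase = np.asarray(phase, dtype=float)
    k = np.asarray(k)
    if phase.shape != k.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {k.shape}")
    if not np.issubdtype(k.dtype, np.integer):
        kf = np.asarray(k, dtype=float)
        if not np.all(kf == np.round(kf)):
            raise ValueError("k must be integer-valued")
        k = np.round(kf)
    return phase + TWO_PI * np.asarray(k, dtype=float)


@dataclass
class WrappedVolume:
    """A 3D wrapped-phase volume with optional magnitude and ROI mask.

    Parameters
    ----------
    phase
        3D array of radians; every in-mask value must lie in ``(-pi, pi]``.
    magnitude
        Optional 3D array of nonnegative signal intensity, same shape.
    mask
        Optional 3D boolean ROI; defaults to the full volume.
    affine
        Optional 4x4 voxel-to-world matrix carried through I/O round trips.
    """

    phase: np.ndarray
    magnitude: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.phase = np.ascontiguousarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 3:
            raise ValueError(f"phase must be 3D, got shape {self.phase.shape}")
        if self.mask is None:
            self.mask = np.ones(self.phase.shape, dtype=bool)
        else:
            self.mask = np.ascontiguousarray(self.mask, dtype=bool)
            if self.mask.shape != self.phase.shape:
                raise ValueError("mask shape must match phase shape")
        if self.magnitude is not None:
            self.magnitude = np.ascontiguousarray(self.magnitude, dtype=np.float64)
            if self.magnitude.shape != self.phase.shape:
                raise ValueError("magnitude shape must match phase shape")
        masked = self.phase[self.mask]
        if masked.size and not np.all(np.isfinite(masked)):
            raise ValueError("phase contains non-finite values inside the mask")
        if masked.size and (masked.min() <= -np.pi or masked.max() > np.pi):
            raise ValueError(
                "masked phase must lie in (-pi, pi]; use WrappedVolume.from_phase "
                "to wrap arbitrary angles first"
            )

    @property
    def shape(self) -> tuple:
        return self.phase.shape

    @classmethod
    def from_phase(cls, phase, magnitude=None, mask=None, affine=None) -> "WrappedVolume":
        """Build a volume from arbitrary finite angles, wrapping them first."""
        return cls(wrap_to_principal(np.asarray(phase, dtype=float)),
                   magnitude=magnitude, mask=mask, affine=affine)

    @classmethod
    def from_complex(cls, data, mask=None, affine=None) -> "WrappedVolume":
        """Build a volume from complex signal: phase = arg, magnitude = abs."""
        data = np.asarray(data)
        return cls.from_phase(np.angle(data), magnitude=np.abs(data),
                              mask=mask, affine=affine)


@dataclass
class UnwrapState:
    """Evolving unwrapped phase during region growing.

    Wherever ``done`` is true, ``unwrapped == phase + 2*pi*k`` holds exactly
    (to 1e-9 rad); ``done`` is always a subset of the ROI mask.
    """

    unwrapped: np.ndarray
    k: np.ndarray
    done: np.ndarray

    def check_consistency(self, vol: WrappedVolume, atol: float = 1e-9) -> None:
        """Assert the 2*pi-consistency contract; raises AssertionError on failure."""
        d = self.done
        if not np.all(self.done <= vol.mask):
            raise AssertionError("done extends outside the ROI mask")
        resid = self.unwrapped[d] - (vol.phase[d] + TWO_PI * self.k[d])
        if resid.size and np.max(np.abs(resid)) > atol:
            raise AssertionError(
                f"unwrapped != phase + 2*pi*k (max dev {np.max(np.abs(resid)):.3g})"
            )

    @classmethod
    def empty(cls, shape) -> "UnwrapState":
        return cls(
            unwrapped=np.zeros(shape, dtype=np.float64),
            k=np.zeros(shape, dtype=np.int32),
            done=np.zeros(shape, dtype=bool),
        )
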