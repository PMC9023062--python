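"""Shared domain types for the ball-and-stick pipeline.

The ball-and-stick model describes the diffusion-weighted MR signal in a
voxel as a mixture of one isotropic compartment (the "ball") and K perfectly
anisotropic compartments (the "sticks"), each stick j carrying a volume
fraction ``f_j`` and an orientation given in spherical polar coordinates
``(theta_j, phi_j)``.  The predicted signal for b-value ``b`` and unit
gradient direction ``g`` is::

    mu = S0 * [ (1 - sum_j f_j) * exp(-b d)
                + sum_j f_j * exp(-b d (g . v_j)**2) ]

with ``v_j`` the unit vector of stick j and ``d`` the (mean) diffusivity.

The spherical convention used throughout the package is the physics one:
``v = (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta))`` with theta
measured from +z, theta in [0, pi], phi in [-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PDF_PARAMS",
    "DegenerateInputError",
    "GradientTable",
    "BallStickParams",
    "spherical_to_unit",
    "unit_to_spherical",
]

#: Canonical parameter ordering used for flat per-voxel state vectors.
PARAM_NAMES = ("d", "S0", "f1", "f2", "th1", "ph1", "th2", "ph2")

#: The six per-voxel posterior distributions that enter the statistical
#: comparison (diffusivity and baseline signal are summarised by their means
#: and are not part of the distribution-shape tests).
PDF_PARAMS = ("f1", "f2", "ph1", "th1", "ph2", "th2")

#: b-values at or below this (s/mm^2) are treated as non-diffusion-weighted.
B0_THRESHOLD = 10.0


class DegenerateInputError(ValueError):
    """Raised when a voxel's signal cannot support a model fit (e.g. all-zero)."""


def spherical_to_unit(theta, phi):
    """Map polar angles to unit vectors.

    Parameters
    ----------
    theta, phi : float or array-like
        Polar angle from +z in [0, pi] and azimuth in radians.

    Returns
    -------
    ndarray
        Unit vector(s), shape ``(3,)`` for scalars or ``(..., 3)``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    v = np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)
    return v


def unit_to_spherical(v):
    """Inverse of :func:`spherical_to_unit`; returns ``(theta, phi)``."""
    v = np.asarray(v, dtype=float)
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    return theta, phi


@dataclass
class GradientTable:
    """Single-shell acquisition scheme: b-values and unit gradient directions.

    bvecs for b=0 entries may be zero vectors; all diffusion-weighted entries
    must be unit-norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs must have equal length")
        dw = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit-norm")

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask


@dataclass
class BallStickParams:
    """Per-voxel ball-and-stick state: diffusivity, baseline, K sticks.

    Invariants: ``d >= 0``, ``S0 > 0``, each ``f_j`` in [0, 1] with
    ``sum f_j <= 1``, ``theta_j`` in [0, pi], ``phi_j`` in [-pi, pi].
    """

    d: float
    S0: float
    f: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.f.size == 0:
            self.theta = np.zeros(0)
            self.phi = np.zeros(0)
        if not (len(self.f) == len(self.theta) == len(self.phi)):
            raise ValueError("f, theta, phi must have equal length")

    @property
    def n_fibres(self) -> int:
        return len(self.f)

    def validate(self):
        """Raise ``ValueError`` on any invariant violation; return self."""
        if self.d < 0:
            raise ValueError("diffusivity d must be >= 0")
        if self.S0 <= 0:
            raise ValueError("baseline S0 must be > 0")
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ValueError("fibre fractions must lie in [0, 1]")
        if self.f.sum() > 1 + 1e-12:
            raise ValueError("fibre fractions must sum to <= 1")
        if np.any(self.theta < 0) or np.any(self.theta > np.pi):
            raise ValueError("theta must lie in [0, pi]")
        if np.any(self.phi < -np.pi) or np.any(self.phi > np.pi):
            raise ValueError("phi must lie in [-pi, pi]")
        return self

    def stick_vectors(self) -> np.ndarray:
        """Unit orientation vectors of all sticks, shape (K, 3)."""
        if self.n_fibres == 0:
            return np.zeros((0, 3))
        return spherical_to_unit(self.theta, self.phi)

    def to_vector(self, n_fibres: int = 2) -> np.ndarray:
        """Flatten to the canonical ``(d, S0, f1, f2, th1, ph1, th2, ph2)`` order.

        Missing sticks are padded with zero fraction and arbitrary (zero)
        angles.
        """
        f = np.zeros(n_fibres)
        th = np.zeros(n_fibres)
        ph = np.zeros(n_fibres)
        k = min(self.n_fibres, n_fibres)
        f[:k] = self.f[:k]
        th[:k] = self.theta[:k]
        ph[:k] = self.phi[:k]
        # layout: d, S0, f1..fK, th1, ph1, th2, ph2, ...
        out = np.empty(2 + 3 * n_fibres)
        out[0] = self.d
        out[1] = self.S0
        out[2:2 + n_fibres] = f
        for j in range(n_fibres):
            out[2 + n_fibres + 2 * j] = th[j]
            out[3 + n_fibres + 2 * j] = ph[j]
        return out

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "BallStickParams":
        """Inverse of :meth:`to_vector`."""
        x = np.asarray(x, dtype=float).ravel()
        n_fibres = (len(x) - 2) // 3
        f = x[2:2 + n_fibres]
        th = x[2 + n_fibres::2][:n_fibres]
        ph = x[3 + n_fibres::2][:n_fibres]
        return cls(d=x[0], S0=x[1], f=f, theta=th, phi=ph)
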