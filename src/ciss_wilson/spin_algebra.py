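"""SU(2) / Pauli primitives for Wilson-loop analysis.

Spin-dependent bond operators of a tight-binding chain with spin-orbit
coupling (SOC) factorize as ``T = -t*I + i*lam*(v.sigma) = -R * U`` with a
real amplitude ``R = sqrt(t**2 + (lam*|v|)**2)`` and a pure SU(2) rotation
``U = exp(-i*phi*(n.sigma))``, ``phi = arctan(lam*|v| / t)``, ``n = v/|v|``.
This module provides the construction, decomposition and triviality tests for
those link rotations; everything downstream (Wilson loops, gauges) is built
from them.

Conventions
-----------
* Standard Pauli basis, spin-up = first component, fixed lab frame.
* The rotation angle is the *full* angle in the exponent, ``U = exp(-i *
  angle * (axis.sigma))``, stored on the branch ``angle in [0, pi]`` with the
  axis sign absorbing the remainder.  This is the convention under which
  ``phi = arctan(Lambda/t)`` reconstructs the bond matrix entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "SIGMA_X",
    "SIGMA_Y",
    "SIGMA_Z",
    "PAULI",
    "ID2",
    "pauli_dot",
    "SpinRotation",
    "BondDecomposition",
    "TrivialityCheck",
    "su2_from_axis_angle",
    "axis_angle_from_su2",
    "decompose_bond",
    "is_trivial",
]

SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
PAULI = np.stack([SIGMA_X, SIGMA_Y, SIGMA_Z])
ID2 = np.eye(2, dtype=complex)

_Z_AXIS = np.array([0.0, 0.0, 1.0])


def pauli_dot(v: np.ndarray) -> np.ndarray:
    """Return ``v . sigma`` for a real (or complex) 3-vector ``v``."""
    v = np.asarray(v)
    return v[0] * SIGMA_X + v[1] * SIGMA_Y + v[2] * SIGMA_Z


@dataclass(frozen=True)
class SpinRotation:
    """An SU(2) rotation with its axis-angle view.

    ``matrix == exp(-i * angle * (axis.sigma))`` with ``angle in [0, pi]``
    and ``axis`` a unit 3-vector (``z`` by convention when the rotation is
    proportional to the identity and the axis is undefined).
    """

    matrix: np.ndarray
    angle: float
    axis: np.ndarray

    @property
    def inverse(self) -> "SpinRotation":
        return SpinRotation(
            self.matrix.conj().T.copy(), self.angle, -self.axis if self.angle > 0 else self.axis
        )

    def __matmul__(self, other: "SpinRotation") -> "SpinRotation":
        m = self.matrix @ other.matrix
        angle, axis = axis_angle_from_su2(m)
        return SpinRotation(m, angle, axis)


@dataclass(frozen=True)
class BondDecomposition:
    """Polar-type split ``T = -amplitude * rotation`` of a bond operator.

    ``amplitude`` (eV) is ``sqrt(t**2 + Lambda**2)`` with
    ``Lambda = lam*|v|``; ``rotation`` is the SU(2) link matrix the Wilson
    loop is built from.
    """

    amplitude: float
    rotation: SpinRotation


class TrivialityCheck(NamedTuple):
    trivial: bool
    deviation: float


def su2_from_axis_angle(angle: float, axis: np.ndarray) -> SpinRotation:
    """Build ``exp(-i*angle*(axis.sigma))`` from an axis-angle pair.

    The axis is normalized internally; a zero axis is rejected.  The stored
    angle is reduced modulo 2*pi to ``[0, pi]`` with an axis flip absorbing
    the sign, so round trips through :func:`axis_angle_from_su2` are unique.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-300 or not np.all(np.isfinite(axis)):
        raise ValueError("rotation axis must be a finite non-zero 3-vector")
    n = axis / norm
    angle = float(angle) % (2.0 * np.pi)
    if angle > np.pi:
        angle = 2.0 * np.pi - angle
        n = -n
    matrix = np.cos(angle) * ID2 - 1j * np.sin(angle) * pauli_dot(n)
    return SpinRotation(matrix, angle, n)


def axis_angle_from_su2(rotation: np.ndarray | SpinRotation, tol: float = 1e-10):
    """Recover ``(angle, axis)`` with ``M = exp(-i*angle*(axis.sigma))``.

    ``angle`` lands in ``[0, pi]``.  For +-identity the axis is undefined and
    the documented default ``z`` is returned.  Non-unitary or det != 1 input
    is rejected with the measured deviation in the message.
    """
    m = rotation.matrix if isinstance(rotation, SpinRotation) else np.asarray(rotation, dtype=complex)
    if m.shape != (2, 2):
        raise ValueError("expected a 2x2 matrix")
    unit_dev = float(np.max(np.abs(m.conj().T @ m - ID2)))
    det_dev = float(abs(np.linalg.det(m) - 1.0))
    if unit_dev > tol or det_dev > tol:
        raise ValueError(
            f"not an SU(2) matrix: unitarity deviation {unit_dev:.3e}, det-1 deviation {det_dev:.3e}"
        )
    # M = cos(a) I - i sin(a) (n.sigma)  =>  b_k := i Tr(M sigma_k)/2 = sin(a) n_k
    a = float(np.real(np.trace(m)) / 2.0)
    b = np.array([np.real(1j * np.trace(m @ s) / 2.0) for s in PAULI])
    s = float(np.linalg.norm(b))
    angle = float(np.arctan2(s, a))
    axis = b / s if s > tol else _Z_AXIS.copy()
    return angle, axis


def decompose_bond(t: float, lam: float, v: np.ndarray) -> BondDecomposition:
    """Split the bond matrix ``T = -t*I + i*lam*(v.sigma)`` as ``-R*U``.

    ``R = sqrt(t**2 + (lam*|v|)**2)`` and ``U`` is SU(2); the reconstruction
    ``-R*U.matrix`` reproduces ``T`` entrywise.  A bond with ``t`` and
    ``lam*|v|`` both zero is absent and rejected.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("SOC axis must be a finite 3-vector")
    lam_eff = lam * np.linalg.norm(v)
    amplitude = float(np.hypot(t, lam_eff))
    if amplitude < 1e-300:
        raise ValueError("bond absent: t and lam*|v| both vanish")
    u = (t * ID2 - 1j * lam * pauli_dot(v)) / amplitude
    angle, axis = axis_angle_from_su2(u, tol=1e-9)
    return BondDecomposition(amplitude, SpinRotation(u, angle, axis))


def is_trivial(matrix: np.ndarray | SpinRotation, tol: float = 1e-10) -> TrivialityCheck:
    """Check whether a unitary is proportional to the identity.

    True iff ``||M - (Tr M / 2) I|| < tol`` and ``|Tr M|/2 > 1 - tol``; both
    ``+I`` and ``-I`` (and any global phase) count as trivial.  The measured
    deviation is reported either way.
    """
    m = matrix.matrix if isinstance(matrix, SpinRotation) else np.asarray(matrix, dtype=complex)
    c = np.trace(m) / 2.0
    off = float(np.max(np.abs(m - c * ID2)))
    mag = float(abs(c))
    deviation = max(off, abs(1.0 - mag))
    return TrivialityCheck(off < tol and mag > 1.0 - tol, deviation)
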