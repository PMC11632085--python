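"""Angular-momentum toolbox: Wigner rotation functions, helical polarization
vectors and the Cartesian-to-spherical basis matrix.

Conventions
-----------
Rotations are *active* z-y-z Euler rotations R = R_z(phi) R_y(theta) R_z(psi).
The Wigner D-matrix element follows the Varshalovich convention,

    D^l_{m lam}(phi, theta, psi) = exp(-i m phi) d^l_{m lam}(theta) exp(-i lam psi),

so that the spherical components of a vector (ordered m = -1, 0, +1)
transform as  a' = D^1 a  under the active rotation of the vector itself.
The Cartesian-to-spherical matrix ``C`` returned here is the unique bridge
between these m-ordered components and (x, y, z) components; the identity
C R3 C^dagger = D^1(R) is asserted by the test suite for random rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, factorial, sin, sqrt

import numpy as np


@dataclass(frozen=True)
class EulerAngles:
    """Active z-y-z Euler angles (radians)."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self):
        for name in ("phi", "theta", "psi"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"Euler angle {name} must be finite")


def check_helicity(lam: int) -> int:
    """Validate a helicity index; exactly +1 and -1 are admissible."""
    if lam not in (+1, -1):
        raise ValueError(f"helicity must be +1 or -1, got {lam!r}")
    return int(lam)


def wigner_small_d(l: int, m: int, lam: int, theta: float) -> float:
    """Wigner d-function d^l_{m lam}(theta) (Varshalovich sign convention).

    Evaluated from the explicit factorial series; exact for the small l used
    throughout (l = 1 in the dipolar pipeline) and stable for moderate l.
    """
    if l < 0 or l != int(l):
        raise ValueError(f"l must be a non-negative integer, got {l!r}")
    l, m, lam = int(l), int(m), int(lam)
    if abs(m) > l or abs(lam) > l:
        raise ValueError(f"indices out of range: |m|={abs(m)}, |lam|={abs(lam)}, l={l}")
    c, s = cos(theta / 2.0), sin(theta / 2.0)
    pref = sqrt(
        factorial(l + m) * factorial(l - m) * factorial(l + lam) * factorial(l - lam)
    )
    total = 0.0
    for k in range(max(0, lam - m), min(l + lam, l - m) + 1):
        num = (-1.0) ** (m - lam + k)
        den = (
            factorial(l + lam - k)
            * factorial(k)
            * factorial(m - lam + k)
            * factorial(l - m - k)
        )
        total += num / den * c ** (2 * l + lam - m - 2 * k) * s ** (m - lam + 2 * k)
    return pref * total


def wigner_D(l: int, m: int, lam: int, euler: EulerAngles) -> complex:
    """Wigner D-matrix element D^l_{m lam}(phi, theta, psi)."""
    d = wigner_small_d(l, m, lam, euler.theta)
    return np.exp(-1j * m * euler.phi) * d * np.exp(-1j * lam * euler.psi)


def wigner_D_matrix_l1(phi: float, theta: float, psi: float = 0.0) -> np.ndarray:
    """3x3 matrix D^1_{m m'}(phi, theta, psi), rows/cols ordered m = (-1, 0, +1).

    Closed forms for l = 1 keep the hot rotation path cheap.
    """
    ct, st = cos(theta), sin(theta)
    d = np.array(
        [
            [(1 + ct) / 2, st / sqrt(2), (1 - ct) / 2],
            [-st / sqrt(2), ct, st / sqrt(2)],
            [(1 - ct) / 2, -st / sqrt(2), (1 + ct) / 2],
        ]
    )
    ms = np.array([-1.0, 0.0, 1.0])
    return np.exp(-1j * ms[:, None] * phi) * d * np.exp(-1j * ms[None, :] * psi)


def propagation_unit_vectors(theta_k: float, phi_k: float):
    """Return (khat, theta_hat, phi_hat) for a propagation direction.

    At the poles theta_k in {0, pi} the tangent vectors are the continuous
    limits at the given phi_k, matching the fixed-azimuth convention of the
    axial scattering geometry (phi_i = 0).
    """
    st, ct = sin(theta_k), cos(theta_k)
    sp, cp = sin(phi_k), cos(phi_k)
    khat = np.array([st * cp, st * sp, ct])
    theta_hat = np.array([ct * cp, ct * sp, -st])
    phi_hat = np.array([-sp, cp, 0.0])
    return khat, theta_hat, phi_hat


def helical_polarization(theta_k: float, phi_k: float, lam: int) -> np.ndarray:
    """Helical polarization vector e_lam(khat) = (-lam theta_hat - i phi_hat)/sqrt(2).

    Unit-norm, orthogonal to khat, eigenvector of i khat x (.) with
    eigenvalue lam.
    """
    lam = check_helicity(lam)
    _, theta_hat, phi_hat = propagation_unit_vectors(theta_k, phi_k)
    return (-lam * theta_hat - 1j * phi_hat) / sqrt(2)


def cartesian_to_spherical_matrix() -> np.ndarray:
    """Unitary matrix C mapping (x, y, z) components to spherical components.

    Rows are ordered m = (-1, 0, +1); row m is the conjugate of the standard
    (Condon-Shortley) spherical basis vector e_m, so (C a)_m = e_m^dagger a.
    """
    s = 1.0 / sqrt(2)
    return np.array(
        [
            [s, 1j * s, 0.0],
            [0.0, 0.0, 1.0],
            [-s, 1j * s, 0.0],
        ]
    )
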