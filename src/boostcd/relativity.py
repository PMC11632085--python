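"""Active Lorentz boosts along z for axial plane-wave states.

The scattering geometry is fixed: the incident wave propagates along -z and
the molecule moves along -z with speed beta*c, so the only relativistic
ingredients needed are the axial Doppler factors e^{-xi} and e^{+xi} with
rapidity xi = artanh(beta), and the fact that helicity is invariant under
boosts.  Boosting spherical-wave coefficients directly (which would mix
multipole orders) is deliberately out of scope; amplitudes are boosted in
the plane-wave basis where a collinear boost rescales the wavenumber only.

The common helicity-independent amplitude scale s(beta) picked up by the
inverse boost cancels identically in the TCD ratio and is set to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum


class BoostSense(Enum):
    """Direction of the active boost: lab->molecule (forward) or back."""

    ACTIVE_FORWARD = "active_forward"   # F -> F'
    ACTIVE_INVERSE = "active_inverse"   # F' -> F


@dataclass(frozen=True)
class BoostZ:
    """Active z-boost with speed fraction beta in [0, 1)."""

    beta: float
    sense: BoostSense = BoostSense.ACTIVE_FORWARD

    def __post_init__(self):
        if not (0.0 <= self.beta < 1.0) or not math.isfinite(self.beta):
            raise ValueError(f"beta must satisfy 0 <= beta < 1, got {self.beta!r}")

    @property
    def xi(self) -> float:
        """Rapidity artanh(beta)."""
        return math.atanh(self.beta)

    def inverse(self) -> "BoostZ":
        sense = (
            BoostSense.ACTIVE_INVERSE
            if self.sense is BoostSense.ACTIVE_FORWARD
            else BoostSense.ACTIVE_FORWARD
        )
        return BoostZ(beta=self.beta, sense=sense)


def doppler_factor(boost: BoostZ, propagation_sign: int = -1) -> float:
    """Axial Doppler factor for a wave propagating along sign*z.

    For a -z-propagating wave the forward boost (lab to molecule frame)
    rescales the wavenumber by e^{-xi} = sqrt((1-beta)/(1+beta)); the inverse
    sense returns e^{+xi}.  The two factors multiply to 1.

    The square-root form is used instead of exp(atanh(...)) for accuracy at
    beta close to 1.
    """
    if propagation_sign not in (-1, +1):
        raise ValueError("propagation_sign must be -1 or +1")
    b = boost.beta
    factor = math.sqrt((1.0 - b) / (1.0 + b))  # e^{-xi}
    if propagation_sign == +1:
        factor = 1.0 / factor
    if boost.sense is BoostSense.ACTIVE_INVERSE:
        factor = 1.0 / factor
    return factor


def boost_incident(wave, boost: BoostZ):
    """Boost an axial (-z) plane wave of pure helicity into the molecule frame.

    Helicity is invariant under the boost (the opposite-helicity channel
    remains exactly empty); the wavenumber is multiplied by the forward
    Doppler factor and the propagation direction is unchanged.
    """
    from .errors import GeometryError  # local import avoids a cycle

    if abs(wave.theta_k - math.pi) > 1e-12:
        raise GeometryError(
            "only -z-propagating plane waves are supported (theta_k = pi)"
        )
    factor = doppler_factor(replace(boost, sense=BoostSense.ACTIVE_FORWARD), -1)
    return replace(wave, k=wave.k * factor)


def inverse_boost_scattered(amplitudes, k_prime: float, boost: BoostZ):
    """Boost forward-direction scattered amplitudes from F' back to F.

    Helicity labels are preserved and every amplitude is multiplied by one
    common scale s(beta) = 1 (any helicity-independent scale cancels in the
    TCD ratio); the wavenumber maps back with the inverse Doppler factor,
    returning ``(amplitudes, k_lab)``.
    """
    if k_prime <= 0:
        raise ValueError("k_prime must be positive")
    factor = doppler_factor(replace(boost, sense=BoostSense.ACTIVE_FORWARD), -1)
    k_lab = k_prime / factor
    scaled = replace(amplitudes, k_s=k_lab)
    return scaled, k_lab
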