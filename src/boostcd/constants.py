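"""Physical constants (CODATA 2018) and package-wide convention constants.

Every convention choice that is not fixed by physics — the helicity sign of
the parity-to-helicity mixing, the single normalization constant of the
forward far-field amplitudes, the atomic-unit import factors — lives here so
that there is exactly one place where a sign or scale can be flipped.
"""

from __future__ import annotations

import math

# --- CODATA 2018 exact / recommended values (SI) ---
C0 = 299_792_458.0           # speed of light in vacuum [m/s]
MU0 = 1.25663706212e-6       # vacuum permeability [N/A^2]
EPS0 = 8.8541878128e-12      # vacuum permittivity [F/m]
Z0 = 376.730313668           # vacuum impedance [Ohm]
EV = 1.602176634e-19         # Joule per electronvolt (exact)
HBAR = 1.054571817e-34       # reduced Planck constant [J s]
HC_EV_NM = 1239.8419843320026  # h*c expressed in eV*nm

# Atomic unit of electric-dipole polarizability, e^2 a0^2 / E_h,
# expressed in C^2 m^2 / J.  This single named constant converts
# atomic-unit tensors into the package's reduced internal units; the same
# common-dimension scheme is applied to all four tensor blocks (see
# docs/methods.md for the rationale).
AU_POLARIZABILITY = 1.64877727436e-41

AU_TO_INTERNAL = {
    "ee": AU_POLARIZABILITY,
    "em": AU_POLARIZABILITY,
    "me": AU_POLARIZABILITY,
    "mm": AU_POLARIZABILITY,
}

# --- convention constants -------------------------------------------------
# Positive-helicity multipole channel is (N + M)/sqrt(2).  Flipping this
# constant flips the sign of every TCD/ACD spectrum; it is pinned by the
# synthetic-preset acceptance suite.
HELICITY_PLUS_IS_N_PLUS_M = True

# Plane-wave -> l=1 spherical-wave expansion constant sqrt(3/4pi) for a wave
# travelling along -z (only m = -lambda survives).
PW_EXPANSION_NORM = math.sqrt(3.0 / (4.0 * math.pi))

# Forward (-z) far-field amplitude per unit scattered dipole coefficient.
# Derived by stationary phase from the direction-integral definition of the
# outgoing helicity vector spherical wavefunctions: the e^{ikr}/(kr) envelope
# is dropped and E_{s,lam} = FORWARD_NORM * B_{1, m=-lam, lam}.  All radial
# delta-weights and the polar-component prefactor are absorbed here; the
# value is validated against an independent spherical-Hankel summation.
FORWARD_NORM = -1j * math.sqrt(12.0 * math.pi)


def wavenumber_from_energy(energy_ev, c_h: float = C0):
    """Host-medium wavenumber k = E/(hbar c_h) [rad/m] for photon energy in eV."""
    return energy_ev * EV / (HBAR * c_h)


def energy_from_wavenumber(k, c_h: float = C0):
    """Photon energy in eV for a host-medium wavenumber in rad/m."""
    return k * HBAR * c_h / EV


def wavelength_nm_from_energy(energy_ev):
    """Vacuum wavelength in nm for a photon energy in eV."""
    return HC_EV_NM / energy_ev
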