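"""Plane-wave expansion, T-matrix scattering, forward far fields,
transmissions and the transmission circular dichroism (TCD).

The pipeline implemented here works entirely at dipole order (l = 1): an
axial plane wave of pure helicity populates a single spherical-wave channel
(m = -lambda), the 6x6 helicity-basis T-matrix maps incident to scattered
dipole coefficients, and the forward (-z) far-field amplitude per outgoing
helicity is a single T-matrix entry times one documented normalization
constant.  The omitted e^{ikr}/(kr) envelope and the radial delta-weights
are part of that constant; the TCD, being a ratio of transmissions, is
insensitive to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .angular import check_helicity
from .constants import FORWARD_NORM, PW_EXPANSION_NORM
from .errors import BasisError, GeometryError
from .tmatrix import HELICITY, TMatrix6

INCIDENT = "incident"
SCATTERED = "scattered"

#: flattened (lambda, m) order shared with the helicity-basis T-matrix
HELICITY_M_ORDER = [(+1, -1), (+1, 0), (+1, +1), (-1, -1), (-1, 0), (-1, +1)]


def helicity_m_index(lam: int, m: int) -> int:
    """Position of the (lambda, m) dipole channel in the 6-vector layout."""
    check_helicity(lam)
    if m not in (-1, 0, +1):
        raise ValueError(f"m must be in {{-1, 0, 1}}, got {m}")
    return (0 if lam == +1 else 3) + (m + 1)


@dataclass(frozen=True)
class PlaneWaveState:
    """Monochromatic plane wave of pure helicity.

    The delta-function structure of the single-plane-wave expansion is
    absorbed into this record: direction (theta_k, phi_k), host wavenumber k
    and a single complex amplitude (unit by default).
    """

    lam: int
    k: float
    theta_k: float = math.pi
    phi_k: float = 0.0
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self):
        check_helicity(self.lam)
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"wavenumber must be positive and finite, got {self.k}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class DipoleCoefficients:
    """Six complex l=1 spherical-wave amplitudes indexed by (lambda, m).

    ``values`` follows :data:`HELICITY_M_ORDER`; ``role`` distinguishes the
    incident (A') from the scattered (B') coefficients.
    """

    values: np.ndarray
    role: str = INCIDENT

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (6,):
            raise ValueError("dipole coefficients must be a 6-vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dipole coefficients contain non-finite entries")
        if self.role not in (INCIDENT, SCATTERED):
            raise ValueError(f"unknown role {self.role!r}")

    def get(self, lam: int, m: int) -> complex:
        return complex(self.values[helicity_m_index(lam, m)])


@dataclass(frozen=True)
class ForwardFieldPair:
    """Forward (-z) outgoing amplitudes for both incident helicities.

    ``e_s_plus``/``e_s_minus`` hold the scattered amplitudes
    (E_{s,lam=+1}, E_{s,lam=-1}) produced by an incident wave of positive /
    negative helicity; ``e_in`` holds the co-propagating incoming amplitudes
    (E_in,+1, E_in,-1).  The common 1/(k r) envelope is a documented global
    scale and is not carried.
    """

    e_s_plus: tuple
    e_s_minus: tuple
    e_in: tuple = (1.0 + 0.0j, 1.0 + 0.0j)
    k_s: float = float("nan")


@dataclass
class TCDGrid:
    """Rotationally averaged TCD over (beta, lab wavelength) pairs."""

    beta: np.ndarray
    wavelength_nm: np.ndarray
    tcd: np.ndarray
    t_plus: np.ndarray
    t_minus: np.ndarray
    orientation_count: int
    seed: int | None = None
    excluded_wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.wavelength_nm = np.atleast_1d(np.asarray(self.wavelength_nm, float))
        self.tcd = np.atleast_1d(np.asarray(self.tcd, dtype=float))
        self.t_plus = np.atleast_1d(np.asarray(self.t_plus, dtype=float))
        self.t_minus = np.atleast_1d(np.asarray(self.t_minus, dtype=float))
        n = self.tcd.shape[0]
        if not (
            self.beta.shape == self.wavelength_nm.shape == (n,)
            and self.t_plus.shape == self.t_minus.shape == (n,)
        ):
            raise ValueError("TCD grid columns must share one length")
        if np.any(np.abs(self.tcd) > 1.0 + 1e-12):
            raise ValueError("|TCD| must not exceed 1")


# --- operations -----------------------------------------------------------

def expand_plane_wave(wave: PlaneWaveState) -> DipoleCoefficients:
    """l=1 spherical-wave coefficients of an axial (-z) pure-helicity wave.

    Only the (m = -lambda, lambda) channel is populated, with magnitude
    sqrt(3/4pi) times the amplitude; the Wigner selection rule
    d^1_{m lambda}(pi) = delta_{m,-lambda} makes every other entry an exact
    zero.  The delta/k^2 radial weight of the continuum expansion collapses
    to a constant for a monochromatic wave and is absorbed into the global
    normalization.
    """
    if abs(wave.theta_k - math.pi) > 1e-12:
        raise GeometryError(
            "only -z-propagating plane waves are supported (theta_k = pi)"
        )
    values = np.zeros(6, dtype=complex)
    values[helicity_m_index(wave.lam, -wave.lam)] = PW_EXPANSION_NORM * wave.amplitude
    return DipoleCoefficients(values=values, role=INCIDENT)


def apply_tmatrix(t_rot: TMatrix6, a: DipoleCoefficients) -> DipoleCoefficients:
    """Scattered dipole coefficients B' = T^H A' (helicity basis)."""
    if t_rot.basis != HELICITY:
        raise BasisError("apply_tmatrix expects a helicity-basis T-matrix")
    if a.role != INCIDENT:
        raise BasisError("apply_tmatrix expects incident-role coefficients")
    return DipoleCoefficients(values=t_rot.entries @ a.values, role=SCATTERED)


def farfield_forward(b: DipoleCoefficients, k_s: float) -> tuple:
    """Forward (-z) scattered plane-wave amplitudes (E_{s,+1}, E_{s,-1}).

    At theta_s = pi the same Wigner selection rule that feeds the incident
    expansion leaves only the m = -lambda channel per outgoing helicity, so
    each amplitude is FORWARD_NORM times one entry of B'.  The e^{ikr}/(kr)
    envelope is dropped.
    """
    if b.role != SCATTERED:
        raise BasisError("farfield_forward expects scattered-role coefficients")
    if k_s <= 0:
        raise ValueError("k_s must be positive")
    e_plus = FORWARD_NORM * b.get(+1, -1)
    e_minus = FORWARD_NORM * b.get(-1, +1)
    return (e_plus, e_minus)


def scatter_forward(
    t_hel: TMatrix6, amplitude: complex = 1.0 + 0.0j
) -> ForwardFieldPair:
    """Run expand -> apply -> far-field for both incident helicities.

    The incoming forward amplitude per helicity equals the incident
    plane-wave amplitude (the incoming/incident split convention is part of
    the one global normalization constant).
    """
    out = {}
    for lam in (+1, -1):
        wave = PlaneWaveState(lam=lam, k=t_hel.k, amplitude=amplitude)
        a = expand_plane_wave(wave)
        b = apply_tmatrix(t_hel, a)
        out[lam] = farfield_forward(b, t_hel.k)
    return ForwardFieldPair(
        e_s_plus=out[+1],
        e_s_minus=out[-1],
        e_in=(amplitude, amplitude),
        k_s=t_hel.k,
    )


def transmissions(f: ForwardFieldPair) -> tuple:
    """Forward transmissions (T_plus, T_minus).

    The incoming amplitude is added only to the co-helical scattered channel
    (the non-interacting part of the incoming field still reaches the
    forward observer); the cross-helical channel enters purely scattered.
    """
    ep_co, ep_cross = f.e_s_plus
    em_cross, em_co = f.e_s_minus
    t_plus = abs(ep_co + f.e_in[0]) ** 2 + abs(ep_cross) ** 2
    t_minus = abs(em_cross) ** 2 + abs(em_co + f.e_in[1]) ** 2
    return (float(t_plus), float(t_minus))


def tcd(t_plus: float, t_minus: float) -> float:
    """Transmission circular dichroism (T_minus - T_plus)/(T_minus + T_plus)."""
    if t_plus < 0 or t_minus < 0:
        raise ValueError("transmissions must be non-negative")
    denom = t_plus + t_minus
    if denom == 0.0:
        raise ZeroDivisionError("TCD undefined: both transmissions vanish")
    return (t_minus - t_plus) / denom


# --- absorption / ACD reconstruction -------------------------------------

@dataclass
class SpectrumSet:
    """Rotationally averaged cross-section spectra per incident helicity."""

    energies: np.ndarray
    ext_plus: np.ndarray
    ext_minus: np.ndarray
    sca_plus: np.ndarray
    sca_minus: np.ndarray
    abs_plus: np.ndarray
    abs_minus: np.ndarray
    acd: np.ndarray


def absorption_acd_spectra(stack) -> SpectrumSet:
    """Orientation-averaged extinction/scattering/absorption and ACD.

    Standard trace formulas on the helicity-basis stack: per incident
    helicity block, extinction is -(2pi/k^2) Re trace of the diagonal block,
    scattering is (2pi/k^2) times the squared Frobenius weight of that
    block's columns, absorption their difference, and
    ACD = absorption(+) - absorption(-).  All three are rotation invariant,
    so no explicit orientation sampling is needed.
    """
    if stack.basis != HELICITY:
        raise BasisError("absorption_acd_spectra expects a helicity-basis stack")
    k2 = stack.ks**2
    pref = 2.0 * math.pi / k2
    t = stack.entries
    ext_p = -pref * np.real(np.trace(t[:, :3, :3], axis1=1, axis2=2))
    ext_m = -pref * np.real(np.trace(t[:, 3:, 3:], axis1=1, axis2=2))
    sca_p = pref * np.sum(np.abs(t[:, :, :3]) ** 2, axis=(1, 2))
    sca_m = pref * np.sum(np.abs(t[:, :, 3:]) ** 2, axis=(1, 2))
    abs_p = ext_p - sca_p
    abs_m = ext_m - sca_m
    return SpectrumSet(
        energies=stack.energies.copy(),
        ext_plus=ext_p,
        ext_minus=ext_m,
        sca_plus=sca_p,
        sca_minus=sca_m,
        abs_plus=abs_p,
        abs_minus=abs_m,
        acd=abs_p - abs_m,
    )
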