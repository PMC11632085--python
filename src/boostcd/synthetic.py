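"""Synthetic chiral/achiral polarizability sets built from damped Lorentzian
oscillators — the fixture generator that stands in for the quantum-chemistry
stage so the whole pipeline runs with no external data.

Line shape
----------
Each oscillator n contributes a complex resonance

    Lambda_n(E) = 1 / (E_n - E - i * gamma)        [1/eV]

whose imaginary part gamma/((E - E_n)^2 + gamma^2) is positive on the whole
grid (retarded sign convention) and has exactly the prescribed half-width at
half-maximum ``gamma_hwhm``.  The tensors are rank-one moment outer products

    alpha_ee = sum_n  p_n p_n^T Lambda_n
    alpha_mm = sum_n  m_n m_n^T Lambda_n
    alpha_em = sum_n  i kappa_n p_n m_n^T Lambda_n
    alpha_me = -alpha_em^T

so reciprocity holds exactly by construction, the mirror molecule is
kappa -> -kappa, and |kappa| <= 1 keeps the induced T-matrices passive.

Moments are given in arbitrary units of order one; a single documented
constant (``MOMENT_SCALE``) maps them to the reduced internal polarizability
units so that T-matrix entries stay far below one (deep-subwavelength,
weak-scatterer regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tmatrix import PolarizabilitySet

#: bridge from order-one synthetic moments to reduced internal units;
#: chosen so preset |T| entries sit around 1e-4..1e-2.
MOMENT_SCALE = 1.0e-18

#: HWHM damping presets in eV: broad nucleic-acid-like and narrow
#: chlorophyll-like broadening regimes.
GAMMA_BROAD_EV = 0.15
GAMMA_NARROW_EV = 0.03


@dataclass(frozen=True)
class OscillatorSpec:
    """One damped electric/magnetic dipole oscillator.

    ``chirality_coupling`` (kappa) sets the electric-magnetic cross coupling;
    kappa = 0 is achiral, the sign selects the enantiomer, and |kappa| <= 1
    guarantees passivity of the induced response.
    """

    resonance_energy: float
    gamma_hwhm: float
    electric_moment: tuple
    magnetic_moment: tuple = (0.0, 0.0, 0.0)
    chirality_coupling: float = 0.0

    def __post_init__(self):
        if self.resonance_energy <= 0:
            raise ValueError("resonance_energy must be positive (eV)")
        if self.gamma_hwhm <= 0:
            raise ValueError("gamma_hwhm must be positive (eV)")
        if len(self.electric_moment) != 3 or len(self.magnetic_moment) != 3:
            raise ValueError("moments must be real 3-vectors")
        if abs(self.chirality_coupling) > 1.0:
            raise ValueError("|chirality_coupling| must not exceed 1 (passivity)")


def lorentzian(energy_ev, resonance_ev: float, gamma_hwhm_ev: float):
    """Damped complex line shape 1/(E_n - E - i gamma), HWHM = gamma."""
    return 1.0 / (resonance_ev - np.asarray(energy_ev, float) - 1j * gamma_hwhm_ev)


def generate_polarizabilities(
    oscillators, energy_grid
) -> PolarizabilitySet:
    """Bianisotropic polarizability set of a sum of Lorentzian oscillators."""
    oscillators = list(oscillators)
    energy_grid = np.asarray(energy_grid, dtype=float)
    if not oscillators:
        raise ValueError("need at least one oscillator")
    if energy_grid.ndim != 1 or energy_grid.size == 0:
        raise ValueError("energy grid must be a non-empty 1-d array")
    n = energy_grid.size
    a_ee = np.zeros((n, 3, 3), dtype=complex)
    a_mm = np.zeros((n, 3, 3), dtype=complex)
    a_em = np.zeros((n, 3, 3), dtype=complex)
    for osc in oscillators:
        lam = lorentzian(energy_grid, osc.resonance_energy, osc.gamma_hwhm)
        p = MOMENT_SCALE * np.asarray(osc.electric_moment, dtype=float)
        m = MOMENT_SCALE * np.asarray(osc.magnetic_moment, dtype=float)
        a_ee += lam[:, None, None] * np.outer(p, p)
        a_mm += lam[:, None, None] * np.outer(m, m)
        a_em += lam[:, None, None] * (1j * osc.chirality_coupling * np.outer(p, m))
    a_me = -np.swapaxes(a_em, 1, 2)
    return PolarizabilitySet(
        energies=energy_grid,
        alpha_ee=a_ee,
        alpha_em=a_em,
        alpha_me=a_me,
        alpha_mm=a_mm,
        unit_system_tag="internal",
    )


# --- presets --------------------------------------------------------------

def _achiral_iso():
    oscillators = [
        OscillatorSpec(3.1, GAMMA_BROAD_EV, (1.0, 0.0, 0.0)),
        OscillatorSpec(3.1, GAMMA_BROAD_EV, (0.0, 1.0, 0.0)),
        OscillatorSpec(3.1, GAMMA_BROAD_EV, (0.0, 0.0, 1.0)),
    ]
    return oscillators, np.linspace(2.0, 4.5, 101)


def _chiral_single():
    # single chiral resonance at 3.1 eV (~400 nm), narrow damping: mirrors the
    # strong chlorophyll-like ACD region around 400 nm.
    oscillators = [
        OscillatorSpec(
            3.1,
            GAMMA_NARROW_EV,
            electric_moment=(1.0, 0.3, 0.1),
            magnetic_moment=(0.2, 1.0, 0.4),
            chirality_coupling=0.4,
        )
    ]
    return oscillators, np.linspace(1.8, 4.4, 131)


def _chiral_dna_like():
    # broad UV bands with alternating chirality sign, nucleic-acid-like
    # 0.15 eV HWHM damping in the 200-320 nm window.
    oscillators = [
        OscillatorSpec(
            4.6,
            GAMMA_BROAD_EV,
            electric_moment=(1.0, 0.2, 0.0),
            magnetic_moment=(0.1, 0.8, 0.3),
            chirality_coupling=0.35,
        ),
        OscillatorSpec(
            4.9,
            GAMMA_BROAD_EV,
            electric_moment=(0.3, 1.0, 0.2),
            magnetic_moment=(0.7, 0.1, 0.5),
            chirality_coupling=-0.3,
        ),
        OscillatorSpec(
            5.4,
            GAMMA_BROAD_EV,
            electric_moment=(0.2, 0.3, 1.0),
            magnetic_moment=(0.4, 0.5, 0.2),
            chirality_coupling=0.25,
        ),
    ]
    return oscillators, np.linspace(3.8, 6.2, 121)


def _chiral_chl_like():
    # a weak red band and a strong blue band with opposite chirality signs,
    # narrow 0.03 eV HWHM damping.
    oscillators = [
        OscillatorSpec(
            1.9,
            GAMMA_NARROW_EV,
            electric_moment=(0.8, 0.3, 0.1),
            magnetic_moment=(0.2, 0.6, 0.1),
            chirality_coupling=-0.2,
        ),
        OscillatorSpec(
            3.1,
            GAMMA_NARROW_EV,
            electric_moment=(1.0, 0.1, 0.4),
            magnetic_moment=(0.3, 0.9, 0.2),
            chirality_coupling=0.45,
        ),
    ]
    return oscillators, np.linspace(1.6, 3.6, 201)


_PRESETS = {
    "achiral-iso": _achiral_iso,
    "chiral-single": _chiral_single,
    "chiral-dna-like": _chiral_dna_like,
    "chiral-chl-like": _chiral_chl_like,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str):
    """Deterministic (oscillators, energy_grid) for a named preset."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory()


def preset_polarizabilities(name: str) -> PolarizabilitySet:
    """Convenience: generate the polarizability set of a named preset."""
    oscillators, grid = preset(name)
    return generate_polarizabilities(oscillators, grid)
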