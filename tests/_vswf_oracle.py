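"""Independent vector-spherical-wavefunction oracle used by the tests.

Everything here is built from textbook l=1 multipole fields (closed-form
spherical harmonics, scipy spherical Bessel/Hankel radial functions) and a
brute-force direction-integral quadrature — deliberately sharing no code
with the package's forward far-field path, so it can pin the package's
normalization constant.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import spherical_jn, spherical_yn

SQ34 = np.sqrt(3.0 / (4.0 * np.pi))
SQ38 = np.sqrt(3.0 / (8.0 * np.pi))


def y1m(m, th, ph):
    if m == 0:
        return SQ34 * np.cos(th)
    if m == 1:
        return -SQ38 * np.sin(th) * np.exp(1j * ph)
    return SQ38 * np.sin(th) * np.exp(-1j * ph)


def dtheta_y1m(m, th, ph):
    if m == 0:
        return -SQ34 * np.sin(th)
    if m == 1:
        return -SQ38 * np.cos(th) * np.exp(1j * ph)
    return SQ38 * np.cos(th) * np.exp(-1j * ph)


def m_over_sin_y1m(m, th, ph):
    # (m / sin(theta)) * Y_1m, regular at the poles
    if m == 0:
        return 0.0
    if m == 1:
        return -SQ38 * np.exp(1j * ph)
    return -SQ38 * np.exp(-1j * ph)


def unit_vectors(th, ph):
    st, ct, sp, cp = np.sin(th), np.cos(th), np.sin(ph), np.cos(ph)
    rhat = np.array([st * cp, st * sp, ct])
    that = np.array([ct * cp, ct * sp, -st])
    phat = np.array([-sp, cp, 0.0])
    return rhat, that, phat


def vswf_MN(m, kr, th, ph, kind="j"):
    """Textbook l=1 multipole fields M_lm, N_lm in Cartesian components."""
    if kind == "j":
        z = spherical_jn(1, kr)
        zp = spherical_jn(1, kr, derivative=True)
    elif kind == "h1":
        z = spherical_jn(1, kr) + 1j * spherical_yn(1, kr)
        zp = spherical_jn(1, kr, derivative=True) + 1j * spherical_yn(
            1, kr, derivative=True
        )
    else:
        raise ValueError(kind)
    xzp_over_x = z / kr + zp  # (1/x) d/dx (x z(x))
    rhat, that, phat = unit_vectors(th, ph)
    Y = y1m(m, th, ph)
    dY = dtheta_y1m(m, th, ph)
    mY = m_over_sin_y1m(m, th, ph)
    M = z * (1j * mY * that - dY * phat)
    N = 2.0 * (z / kr) * Y * rhat + xzp_over_x * (dY * that + 1j * mY * phat)
    return M, N


def helicity_wave(m, lam, kr, th, ph, kind="j"):
    """(N + lam*M)/sqrt(2) in the textbook normalization."""
    M, N = vswf_MN(m, kr, th, ph, kind)
    return (N + lam * M) / np.sqrt(2.0)


def direction_integral_wave(m, lam, r_vec, k, nth=64, nph=128):
    """Brute-force quadrature of the direction-integral helicity VSWF,

        sqrt(3/4pi) * Int dOmega_k  conj(D^1_{m lam}(phi_k, theta_k, 0))
                       * e_lam(khat) * exp(i k . r).
    """
    from boostcd.angular import EulerAngles, helical_polarization, wigner_D

    xs, ws = leggauss(nth)
    phis = 2.0 * np.pi * np.arange(nph) / nph
    acc = np.zeros(3, dtype=complex)
    for x, w in zip(xs, ws):
        th = np.arccos(x)
        st = np.sin(th)
        for ph in phis:
            D = wigner_D(1, m, lam, EulerAngles(ph, th, 0.0))
            e = helical_polarization(th, ph, lam)
            kvec = k * np.array([st * np.cos(ph), st * np.sin(ph), x])
            acc += np.conj(D) * e * np.exp(1j * (kvec @ r_vec)) * w
    return SQ34 * acc * (2.0 * np.pi / nph)


def forward_amplitudes_oracle(values, c_bridge, kr=1.0e6):
    """Forward (-z) helicity amplitudes of sum_i values[i] * outgoing VSWF,
    with the e^{ikr}/(kr) envelope divided out; textbook path only."""
    from boostcd.angular import helical_polarization
    from boostcd.scattering import HELICITY_M_ORDER

    E = np.zeros(3, dtype=complex)
    for idx, (lam, m) in enumerate(HELICITY_M_ORDER):
        E += values[idx] * c_bridge * helicity_wave(m, lam, kr, np.pi, 0.0, "h1")
    E /= np.exp(1j * kr) / kr
    ep = np.vdot(helical_polarization(np.pi, 0.0, +1), E)
    em = np.vdot(helical_polarization(np.pi, 0.0, -1), E)
    return complex(ep), complex(em)
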