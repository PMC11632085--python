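"""Uniformly spread molecular orientations and the rotational average of
the Lorentz-boosted TCD.

Orientations are directions of the rotated molecular z-axis, parameterized
by (theta, Phi) with the third Euler angle fixed to zero.  Uniform spread is
obtained by minimizing a Thomson-style inverse-chord-distance repulsion
energy with projected gradient descent from a seeded random start; any
uniform-dispersion optimum serves, since the physically meaningful check is
the invariance of the averaged TCD under a global pre-rotation of the
molecule, not the particular point layout.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .errors import BasisError, WindowError
from .relativity import BoostZ, boost_incident, inverse_boost_scattered
from .scattering import (
    ForwardFieldPair,
    PlaneWaveState,
    TCDGrid,
    scatter_forward,
    tcd,
    transmissions,
)
from .tmatrix import HELICITY, TMatrix6, rotation_matrix6


@dataclass
class OrientationSet:
    """n orientation angle pairs, deterministic for fixed (n, seed)."""

    pairs: np.ndarray  # shape (n, 2): columns (theta, Phi)
    n: int
    seed: int
    energy: float  # final repulsion energy (diagnostic; 0 for n = 1)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.shape != (self.n, 2):
            raise ValueError("pairs must have shape (n, 2)")
        th, ph = self.pairs[:, 0], self.pairs[:, 1]
        if np.any((th < 0) | (th >= math.pi)) or np.any((ph < 0) | (ph >= 2 * math.pi)):
            raise ValueError("angles out of range: theta in [0, pi), Phi in [0, 2pi)")

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            fh.write(f"# orientation set: n={self.n} seed={self.seed}\n")
            fh.write("theta_rad,Phi_rad\n")
            for th, ph in self.pairs:
                fh.write(f"{float(th)!r},{float(ph)!r}\n")

    @classmethod
    def from_csv(cls, path, seed: int = -1):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("theta"):
                    continue
                th, ph = next(csv.reader([line]))
                rows.append((float(th), float(ph)))
        pairs = np.array(rows)
        return cls(pairs=pairs, n=len(rows), seed=seed, energy=float("nan"))


def _repulsion_energy_grad(x: np.ndarray):
    """Inverse-chord-distance energy and its (ambient) gradient."""
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(d, np.inf)
    energy = 0.5 * np.sum(1.0 / d)
    grad = -np.sum(diff / d[:, :, None] ** 3, axis=1)
    return energy, grad


def _to_angles(x: np.ndarray) -> np.ndarray:
    theta = np.arccos(np.clip(x[:, 2], -1.0, 1.0))
    theta = np.minimum(theta, np.nextafter(math.pi, 0.0))
    phi = np.mod(np.arctan2(x[:, 1], x[:, 0]), 2.0 * math.pi)
    phi[phi >= 2.0 * math.pi] = 0.0
    return np.column_stack([theta, phi])


def sample_orientations(
    n: int, seed: int = 0, max_iter: int = 2000, tol: float = 1e-12
) -> OrientationSet:
    """Thomson-style repulsion sampler for n near-uniform sphere directions.

    Projected gradient descent with a monotone step-halving schedule from a
    seeded random start; converged when the tangential gradient norm drops
    below ``tol`` (relative to the energy scale) or ``max_iter`` is reached.
    Bitwise deterministic for fixed (n, seed).
    """
    if n < 1:
        raise ValueError(f"orientation count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return OrientationSet(pairs=_to_angles(x), n=1, seed=seed, energy=0.0)

    energy, grad = _repulsion_energy_grad(x)
    step = 0.1 / math.sqrt(n)
    for _ in range(max_iter):
        # project gradient on the tangent planes
        tang = grad - np.sum(grad * x, axis=1, keepdims=True) * x
        gnorm = np.sqrt(np.sum(tang**2, axis=1)).max()
        if gnorm < tol * max(energy, 1.0):
            break
        x_new = x - step * tang / max(gnorm, 1e-300)
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new, g_new = _repulsion_energy_grad(x_new)
        if e_new < energy:
            x, energy, grad = x_new, e_new, g_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-17:
                break
    return OrientationSet(pairs=_to_angles(x), n=n, seed=seed, energy=float(energy))


def min_pairwise_angle(orients: OrientationSet) -> float:
    """Smallest angular separation (radians) between any two orientations."""
    th, ph = orients.pairs[:, 0], orients.pairs[:, 1]
    x = np.column_stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )
    dots = np.clip(x @ x.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    return float(np.arccos(dots.max()))


# --- rotational average ---------------------------------------------------

def admissible_window_nm(stack, boost: BoostZ) -> tuple:
    """Lab-frame wavelength window [min, max] (nm) mapping into the grid."""
    from .relativity import doppler_factor

    f = doppler_factor(boost, -1)  # e^{-xi}
    kmax, kmin = stack.ks.max(), stack.ks.min()
    # lab k = k'/f  ->  L_lab = 2 pi f / k'
    return (2e9 * math.pi * f / kmax, 2e9 * math.pi * f / kmin)


def grid_lab_wavelengths_nm(stack, boost: BoostZ) -> np.ndarray:
    """Lab wavelengths whose boosted counterparts hit the grid nodes exactly,
    ordered by increasing wavelength."""
    from .relativity import doppler_factor

    f = doppler_factor(boost, -1)
    return np.sort(2e9 * math.pi * f / stack.ks)


def _select_tmatrices(stack, k_prime: np.ndarray, interp: bool):
    """T-matrix entries at the rest-frame wavenumbers k_prime.

    Grid mode (default) matches nodes to 1e-6 relative; the optional linear
    interpolator in k is provided for off-grid use but off by default, since
    the optical response is tabulated only on the imported grid.
    """
    ks = stack.ks
    if interp:
        idx = np.searchsorted(ks, k_prime)
        idx = np.clip(idx, 1, len(ks) - 1)
        k0, k1 = ks[idx - 1], ks[idx]
        w = ((k_prime - k0) / (k1 - k0))[:, None, None]
        return (1.0 - w) * stack.entries[idx - 1] + w * stack.entries[idx]
    nearest = np.clip(np.searchsorted(ks, k_prime), 0, len(ks) - 1)
    lower = np.clip(nearest - 1, 0, len(ks) - 1)
    cand = np.where(
        np.abs(ks[nearest] - k_prime) <= np.abs(ks[lower] - k_prime), nearest, lower
    )
    rel = np.abs(ks[cand] - k_prime) / k_prime
    if np.any(rel > 1e-6):
        worst = float(rel.max())
        raise ValueError(
            "requested wavenumbers fall between grid nodes "
            f"(worst relative offset {worst:.3e}); pass interp=True or use "
            "grid-derived lab wavelengths"
        )
    return stack.entries[cand]


def rotational_average_tcd(
    t_stack,
    orientations: OrientationSet,
    boost: BoostZ,
    lab_wavelengths_nm,
    interp: bool = False,
    incident_amplitude: complex = 1.0 + 0.0j,
) -> TCDGrid:
    """Rotationally averaged TCD at one speed over lab wavelengths.

    For each lab wavelength the incident wave is boosted into the molecule
    frame, the (rotated) T-matrix produces the forward scattered amplitudes,
    those are inverse-boosted back, and the per-orientation TCD values are
    averaged with uniform 1/n weights — the average is taken over the TCD
    ratio, not over amplitudes.  Lab wavelengths whose boosted counterpart
    falls outside the tabulated grid are excluded and reported.
    """
    if t_stack.basis != HELICITY:
        raise BasisError("rotational_average_tcd expects a helicity-basis stack")
    lab_l = np.atleast_1d(np.asarray(lab_wavelengths_nm, dtype=float))
    if np.any(lab_l <= 0):
        raise ValueError("lab wavelengths must be positive")
    k_lab = 2.0e9 * math.pi / lab_l

    # boost each incident wave into the molecule frame (helicity preserved)
    k_prime = np.array(
        [boost_incident(PlaneWaveState(lam=+1, k=k), boost).k for k in k_lab]
    )
    slack = 1e-9
    inside = (k_prime >= t_stack.ks.min() * (1 - slack)) & (
        k_prime <= t_stack.ks.max() * (1 + slack)
    )
    if not np.any(inside):
        lo, hi = admissible_window_nm(t_stack, boost)
        raise WindowError(
            f"no admissible lab wavelength at beta={boost.beta}: the boosted "
            f"grid covers {lo:.2f}-{hi:.2f} nm in the lab frame"
        )
    excluded = lab_l[~inside]
    lab_l, k_lab, k_prime = lab_l[inside], k_lab[inside], k_prime[inside]

    t_sel = _select_tmatrices(t_stack, k_prime, interp)  # (nk, 6, 6)

    rot = np.stack(
        [rotation_matrix6(th, ph) for th, ph in orientations.pairs]
    )  # (no, 6, 6)
    t_rot = np.einsum("oab,kbc,odc->okad", rot, t_sel, rot.conj())

    # forward amplitudes in F' per incident helicity, then the inverse boost
    # (common scale 1, wavenumber back to the lab value)
    from .constants import FORWARD_NORM, PW_EXPANSION_NORM

    chain = FORWARD_NORM * PW_EXPANSION_NORM * incident_amplitude
    ep_co = chain * t_rot[..., 0, 0]   # incident +, outgoing +
    ep_cross = chain * t_rot[..., 5, 0]  # incident +, outgoing -
    em_co = chain * t_rot[..., 5, 5]   # incident -, outgoing -
    em_cross = chain * t_rot[..., 0, 5]  # incident -, outgoing +
    amp_in = incident_amplitude
    t_plus = np.abs(ep_co + amp_in) ** 2 + np.abs(ep_cross) ** 2
    t_minus = np.abs(em_cross) ** 2 + np.abs(em_co + amp_in) ** 2
    tcd_per = (t_minus - t_plus) / (t_minus + t_plus)

    return TCDGrid(
        beta=np.full(lab_l.shape, boost.beta),
        wavelength_nm=lab_l,
        tcd=tcd_per.mean(axis=0),
        t_plus=t_plus.mean(axis=0),
        t_minus=t_minus.mean(axis=0),
        orientation_count=orientations.n,
        seed=orientations.seed,
        excluded_wavelengths_nm=excluded,
    )


def single_orientation_tcd(
    t_hel: TMatrix6,
    boost: BoostZ,
    lab_wavelength_nm: float,
    theta: float = 0.0,
    Phi: float = 0.0,
    incident_amplitude: complex = 1.0 + 0.0j,
) -> float:
    """Granular single-orientation pipeline (reference path).

    Chains the elementary operations one by one — boost, rotate, expand,
    scatter, far field, inverse boost, transmissions, TCD — and is used as
    the oracle for the vectorized rotational average.
    """
    from .tmatrix import rotate_tmatrix

    k_lab = 2.0e9 * math.pi / lab_wavelength_nm
    wave = PlaneWaveState(lam=+1, k=k_lab, amplitude=incident_amplitude)
    boosted = boost_incident(wave, boost)
    rel = abs(t_hel.k - boosted.k) / boosted.k
    if rel > 1e-6:
        raise ValueError(
            f"T-matrix wavenumber {t_hel.k} does not match boosted {boosted.k}"
        )
    t_rot = rotate_tmatrix(t_hel, theta, Phi)
    pair_fprime = scatter_forward(t_rot, amplitude=incident_amplitude)
    pair_lab, _k_lab = inverse_boost_scattered(pair_fprime, t_hel.k, boost)
    tp, tm = transmissions(pair_lab)
    return tcd(tp, tm)
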