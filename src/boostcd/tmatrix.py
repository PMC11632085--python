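"""Build, transform, rotate, mirror, validate and serialize 6x6 dipolar
T-matrices from bianisotropic polarizability tensors.

Internal tensor units
---------------------
The four tensors alpha_ee, alpha_em, alpha_me, alpha_mm are stored in
*reduced* SI units that all share the dimension of alpha_ee (C^2 m^2 / J):

    alpha_em_red = alpha_em / Z0,   alpha_me_red = alpha_me / c0,
    alpha_mm_red = alpha_mm / (c0 Z0).

In these units the Onsager reciprocity relation for a reciprocal scatterer
is the plain transpose  alpha_me_red = -alpha_em_red^T, and the dipolar
T-matrix construction reads, with C the Cartesian-to-spherical matrix,

    T = (i c_h Z_h k_h^3 / 6 pi) *
        [[ C a_ee C^-1,                (Z0/Z_h) C (-i a_em) C^-1 ],
         [ (c0/c_h) C (i a_me) C^-1,   (c0 Z0/(c_h Z_h)) C a_mm C^-1 ]]

which reduces to the textbook vacuum form for the default medium c_h = c0.

Index conventions
-----------------
parity basis rows/cols:   [(N, m=-1), (N, 0), (N, +1), (M, -1), (M, 0), (M, +1)]
helicity basis rows/cols: [(lam=+1, m=-1..+1), (lam=-1, m=-1..+1)]
with the positive-helicity channel (N + M)/sqrt(2).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .angular import cartesian_to_spherical_matrix, wigner_D_matrix_l1
from .errors import BasisError, ParseError

PARITY = "parity"
HELICITY = "helicity"

PARITY_INDEX_ORDER = "[(N,-1),(N,0),(N,+1),(M,-1),(M,0),(M,+1)]"
HELICITY_INDEX_ORDER = "[(+1,-1),(+1,0),(+1,+1),(-1,-1),(-1,0),(-1,+1)]"

_TENSOR_NAMES = ("ee", "em", "me", "mm")
_COMPONENTS = ("xx", "xy", "xz", "yx", "yy", "yz", "zx", "zy", "zz")


@dataclass(frozen=True)
class MediumParams:
    """Relative permittivity/permeability of the (non-dispersive) host medium.

    The default reproduces the vacuum-speed choice used to construct the
    molecular T-matrices (the implicit solvent is already part of the
    quantum-chemistry response, so c_h = c0).
    """

    eps_h: float = 1.0
    mu_h: float = 1.0

    def __post_init__(self):
        if self.eps_h <= 0 or self.mu_h <= 0:
            raise ValueError("eps_h and mu_h must be positive")

    @property
    def c_h(self) -> float:
        return constants.C0 / math.sqrt(self.eps_h * self.mu_h)

    @property
    def Z_h(self) -> float:
        return constants.Z0 * math.sqrt(self.mu_h / self.eps_h)


@dataclass
class PolarizabilitySet:
    """Four complex 3x3 dynamic polarizability tensors per photon energy.

    ``energies`` is a strictly increasing grid in eV; each ``alpha_xy`` stack
    has shape (n, 3, 3) in the reduced internal units described in the module
    docstring.
    """

    energies: np.ndarray
    alpha_ee: np.ndarray
    alpha_em: np.ndarray
    alpha_me: np.ndarray
    alpha_mm: np.ndarray
    unit_system_tag: str = "internal"

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        for name in ("alpha_ee", "alpha_em", "alpha_me", "alpha_mm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=complex))
        self.validate()

    def validate(self):
        n = self.energies.shape[0]
        if self.energies.ndim != 1 or n == 0:
            raise ValueError("energy grid must be a non-empty 1-d array")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energy grid contains non-finite values")
        for name in ("alpha_ee", "alpha_em", "alpha_me", "alpha_mm"):
            arr = getattr(self, name)
            if arr.shape != (n, 3, 3):
                raise ValueError(f"{name} must have shape ({n}, 3, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    def __len__(self) -> int:
        return self.energies.shape[0]

    def is_reciprocal(self, rtol: float = 1e-10) -> bool:
        """Check alpha_ee, alpha_mm symmetric and alpha_me = -alpha_em^T."""
        scale = max(
            np.abs(self.alpha_ee).max(),
            np.abs(self.alpha_mm).max(),
            np.abs(self.alpha_em).max(),
            1e-300,
        )
        tol = rtol * scale
        eeT = np.swapaxes(self.alpha_ee, 1, 2)
        mmT = np.swapaxes(self.alpha_mm, 1, 2)
        emT = np.swapaxes(self.alpha_em, 1, 2)
        return (
            np.abs(self.alpha_ee - eeT).max() <= tol
            and np.abs(self.alpha_mm - mmT).max() <= tol
            and np.abs(self.alpha_me + emT).max() <= tol
        )


@dataclass
class TMatrix6:
    """6x6 complex dipolar transition matrix at a single wavenumber."""

    k: float
    basis: str
    entries: np.ndarray

    def __post_init__(self):
        if self.basis not in (PARITY, HELICITY):
            raise ValueError(f"unknown basis {self.basis!r}")
        self.entries = np.asarray(self.entries, dtype=complex)
        if self.entries.shape != (6, 6):
            raise ValueError("T-matrix entries must have shape (6, 6)")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("T-matrix contains non-finite entries")

    @property
    def index_order(self) -> str:
        return PARITY_INDEX_ORDER if self.basis == PARITY else HELICITY_INDEX_ORDER


@dataclass
class TMatrixStack:
    """A T-matrix per energy-grid point, all in one basis."""

    energies: np.ndarray
    ks: np.ndarray
    entries: np.ndarray  # shape (n, 6, 6)
    basis: str
    medium: MediumParams = field(default_factory=MediumParams)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.ks = np.asarray(self.ks, dtype=float)
        self.entries = np.asarray(self.entries, dtype=complex)
        n = self.energies.shape[0]
        if self.ks.shape != (n,) or self.entries.shape != (n, 6, 6):
            raise ValueError("inconsistent stack shapes")
        if self.basis not in (PARITY, HELICITY):
            raise ValueError(f"unknown basis {self.basis!r}")

    def __len__(self) -> int:
        return self.energies.shape[0]

    def __getitem__(self, i: int) -> TMatrix6:
        return TMatrix6(k=float(self.ks[i]), basis=self.basis, entries=self.entries[i])


# --- construction ---------------------------------------------------------

def _sandwich(C, Cinv, tensor):
    return C @ tensor @ Cinv


def build_tmatrix(
    pol: PolarizabilitySet, medium: MediumParams, grid_index: int
) -> TMatrix6:
    """Dipolar parity-basis T-matrix at one energy-grid point.

    Implements the polarizability-to-T-matrix relation with prefactor
    i c_h Z_h k_h^3/(6 pi) and the four C-sandwiched blocks; linear in each
    tensor block.
    """
    n = len(pol)
    if not (0 <= int(grid_index) < n):
        raise IndexError(f"grid_index {grid_index} outside 0..{n - 1}")
    i = int(grid_index)
    c_h, Z_h = medium.c_h, medium.Z_h
    k = constants.wavenumber_from_energy(pol.energies[i], c_h)
    C = cartesian_to_spherical_matrix()
    Cinv = C.conj().T
    pref = 1j * c_h * Z_h * k**3 / (6.0 * math.pi)
    z_ratio = constants.Z0 / Z_h
    c_ratio = constants.C0 / c_h
    t = np.empty((6, 6), dtype=complex)
    t[:3, :3] = _sandwich(C, Cinv, pol.alpha_ee[i])
    t[:3, 3:] = z_ratio * _sandwich(C, Cinv, -1j * pol.alpha_em[i])
    t[3:, :3] = c_ratio * _sandwich(C, Cinv, 1j * pol.alpha_me[i])
    t[3:, 3:] = c_ratio * z_ratio * _sandwich(C, Cinv, pol.alpha_mm[i])
    return TMatrix6(k=float(k), basis=PARITY, entries=pref * t)


def build_tmatrix_stack(
    pol: PolarizabilitySet,
    medium: MediumParams | None = None,
    basis: str = HELICITY,
) -> TMatrixStack:
    """T-matrix at every grid energy, optionally converted to the helicity basis."""
    medium = medium or MediumParams()
    mats = [build_tmatrix(pol, medium, i) for i in range(len(pol))]
    if basis == HELICITY:
        mats = [parity_to_helicity(t) for t in mats]
    elif basis != PARITY:
        raise ValueError(f"unknown basis {basis!r}")
    return TMatrixStack(
        energies=pol.energies.copy(),
        ks=np.array([t.k for t in mats]),
        entries=np.stack([t.entries for t in mats]),
        basis=basis,
        medium=medium,
    )


# --- basis changes and rotations -----------------------------------------

def _parity_helicity_mixer() -> np.ndarray:
    # Unitary map from parity (N/M) to helicity channels; with the
    # (N + M)/sqrt(2) sign convention it is symmetric and self-inverse.
    s = 1.0 / math.sqrt(2)
    eye = np.eye(3)
    if constants.HELICITY_PLUS_IS_N_PLUS_M:
        return np.block([[s * eye, s * eye], [s * eye, -s * eye]])
    return np.block([[s * eye, -s * eye], [s * eye, s * eye]])


def parity_to_helicity(t: TMatrix6) -> TMatrix6:
    """Convert a parity-basis T-matrix to the helicity basis.

    The mixing matrix sends the N/M channels into (N +- M)/sqrt(2); it is
    unitary, so the round trip through :func:`helicity_to_parity` returns the
    input exactly up to rounding.
    """
    if t.basis != PARITY:
        raise BasisError(f"expected parity basis, got {t.basis}")
    U = _parity_helicity_mixer()
    return TMatrix6(k=t.k, basis=HELICITY, entries=U @ t.entries @ U.conj().T)


def helicity_to_parity(t: TMatrix6) -> TMatrix6:
    """Inverse of :func:`parity_to_helicity`."""
    if t.basis != HELICITY:
        raise BasisError(f"expected helicity basis, got {t.basis}")
    U = _parity_helicity_mixer()
    return TMatrix6(k=t.k, basis=PARITY, entries=U.conj().T @ t.entries @ U)


def rotation_matrix6(theta: float, Phi: float) -> np.ndarray:
    """Block-diagonal l=1 Wigner rotation acting identically on both
    helicity blocks.

    The orientation (theta, Phi) enters as the active rotation
    R = R_y(theta) R_z(Phi), i.e. Euler angles (0, theta, Phi): the molecule
    is first spun about its own z-axis by Phi and then tilted by theta.  The
    remaining z-y-z Euler angle — a rotation about the beam axis — is
    omitted, because for an axial circularly polarized illumination it only
    multiplies the forward co-/cross-helicity amplitudes by pure phases that
    cancel in every intensity.  Averaging (theta, Phi) with the uniform
    sphere measure then reproduces the full rotational (Haar) average of any
    forward-transmission observable.
    """
    D1 = wigner_D_matrix_l1(0.0, theta, Phi)
    R = np.zeros((6, 6), dtype=complex)
    R[:3, :3] = D1
    R[3:, 3:] = D1
    return R


def rotate_tmatrix(t: TMatrix6, theta: float, Phi: float) -> TMatrix6:
    """Rotated T-matrix T_R = R T R^-1 for molecular orientation (theta, Phi).

    The third Euler angle is omitted: for an axial circularly polarized
    illumination it only contributes a global phase that cancels in every
    intensity.
    """
    if t.basis != HELICITY:
        raise BasisError("rotate_tmatrix expects a helicity-basis T-matrix")
    R = rotation_matrix6(theta, Phi)
    return TMatrix6(k=t.k, basis=HELICITY, entries=R @ t.entries @ R.conj().T)


def rotate_stack(stack: TMatrixStack, theta: float, Phi: float) -> TMatrixStack:
    """Apply one global rotation to every T-matrix of a helicity stack."""
    if stack.basis != HELICITY:
        raise BasisError("rotate_stack expects a helicity-basis stack")
    R = rotation_matrix6(theta, Phi)
    return replace(stack, entries=np.einsum("ab,nbc,dc->nad", R, stack.entries, R.conj()))


def mirror_enantiomer(pol: PolarizabilitySet) -> PolarizabilitySet:
    """Polarizability set of the mirror molecule: the electric-magnetic
    cross-coupling tensors change sign, the direct tensors do not."""
    return PolarizabilitySet(
        energies=pol.energies.copy(),
        alpha_ee=pol.alpha_ee.copy(),
        alpha_em=-pol.alpha_em,
        alpha_me=-pol.alpha_me,
        alpha_mm=pol.alpha_mm.copy(),
        unit_system_tag=pol.unit_system_tag,
    )


# --- validity -------------------------------------------------------------

def passivity_margin(t: TMatrix6 | np.ndarray) -> float:
    """Smallest eigenvalue of -(T + T^dagger)/2 - T^dagger T.

    Non-negative (to rounding) for any passive scatterer; the acceptance
    suite requires >= -1e-12 for every shipped synthetic preset.
    """
    m = t.entries if isinstance(t, TMatrix6) else np.asarray(t, dtype=complex)
    h = -(m + m.conj().T) / 2.0 - m.conj().T @ m
    return float(np.linalg.eigvalsh(h).min())


# --- polarizability CSV ---------------------------------------------------

def _pol_columns():
    cols = ["energy_eV"]
    for t in _TENSOR_NAMES:
        for comp in _COMPONENTS:
            cols.append(f"{t}_{comp}_re")
            cols.append(f"{t}_{comp}_im")
    return cols


def write_polarizabilities(pol: PolarizabilitySet, path, units: str = "si"):
    """Write the 73-column polarizability CSV dialect.

    ``units='si'`` writes the reduced internal values verbatim; ``'au'``
    divides by the atomic-unit conversion constants on export so that an
    au-flagged round trip is exact.
    """
    if units not in ("si", "au"):
        raise ValueError(f"units must be 'si' or 'au', got {units!r}")
    tensors = {
        "ee": pol.alpha_ee,
        "em": pol.alpha_em,
        "me": pol.alpha_me,
        "mm": pol.alpha_mm,
    }
    if units == "au":
        tensors = {k: v / constants.AU_TO_INTERNAL[k] for k, v in tensors.items()}
    with open(path, "w", newline="") as fh:
        fh.write(f"# units: {units}\n")
        fh.write(
            "# polarizability tensors: reduced internal units (see docs/methods.md)\n"
            if units == "si"
            else "# polarizability tensors: atomic units\n"
        )
        fh.write(",".join(_pol_columns()) + "\n")
        for i, e in enumerate(pol.energies):
            row = [repr(float(e))]
            for t in _TENSOR_NAMES:
                a = tensors[t][i]
                for r in range(3):
                    for c in range(3):
                        row.append(repr(float(a[r, c].real)))
                        row.append(repr(float(a[r, c].imag)))
            fh.write(",".join(row) + "\n")


def read_polarizabilities(path, units: str | None = None) -> PolarizabilitySet:
    """Read the polarizability CSV dialect.

    The unit system is taken from the ``# units:`` header line; an explicit
    ``units`` argument must agree with the header when both are present.
    Atomic-unit tables are converted to the reduced internal units exactly
    once on import.
    """
    header_units = None
    rows = []
    line_numbers = []
    columns = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("units:"):
                    header_units = body.split(":", 1)[1].strip().lower()
                continue
            fields = next(csv.reader([line]))
            if columns is None:
                columns = [f.strip() for f in fields]
                expected = _pol_columns()
                if columns != expected:
                    raise ParseError(
                        f"{path}, line {lineno}: unexpected header; expected the "
                        f"{len(expected)}-column polarizability dialect"
                    )
                continue
            if len(fields) != 73:
                raise ParseError(
                    f"{path}, line {lineno}: expected 73 fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            line_numbers.append(lineno)
    if columns is None or not rows:
        raise ParseError(f"{path}: no data rows found")
    eff_units = header_units or units
    if eff_units is None:
        raise ParseError(f"{path}: no '# units:' header and no units argument")
    if units is not None and header_units is not None and units != header_units:
        raise ParseError(
            f"{path}: units argument {units!r} conflicts with header {header_units!r}"
        )
    if eff_units not in ("si", "au"):
        raise ParseError(f"{path}: unknown unit system {eff_units!r}")
    data = np.array(rows)
    energies = data[:, 0]
    diffs = np.diff(energies)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise ParseError(
            f"{path}, line {line_numbers[bad[0] + 1]}: energy column must be "
            f"strictly increasing (duplicate or decreasing energy)"
        )
    tensors = {}
    for j, t in enumerate(_TENSOR_NAMES):
        block = data[:, 1 + 18 * j : 1 + 18 * (j + 1)]
        cplx = block[:, 0::2] + 1j * block[:, 1::2]
        arr = cplx.reshape(-1, 3, 3)
        if eff_units == "au":
            arr = arr * constants.AU_TO_INTERNAL[t]
        tensors[t] = arr
    return PolarizabilitySet(
        energies=energies,
        alpha_ee=tensors["ee"],
        alpha_em=tensors["em"],
        alpha_me=tensors["me"],
        alpha_mm=tensors["mm"],
        unit_system_tag="internal",
    )


# --- T-matrix JSON store --------------------------------------------------

def write_tmatrix(stack: TMatrixStack, path):
    """Serialize a T-matrix stack to the JSON store (lossless for doubles)."""
    doc = {
        "metadata": {
            "basis": stack.basis,
            "index_order": PARITY_INDEX_ORDER
            if stack.basis == PARITY
            else HELICITY_INDEX_ORDER,
            "medium": {"eps_h": stack.medium.eps_h, "mu_h": stack.medium.mu_h},
            "energy_unit": "eV",
        },
        "records": [
            {
                "energy_eV": float(stack.energies[i]),
                "k": float(stack.ks[i]),
                "entries": [
                    [[float(z.real), float(z.imag)] for z in row]
                    for row in stack.entries[i]
                ],
            }
            for i in range(len(stack))
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tmatrix(path) -> TMatrixStack:
    """Read a T-matrix stack from the JSON store."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}, line {exc.lineno}: {exc.msg}") from None
    try:
        meta = doc["metadata"]
        basis = meta["basis"]
        med = meta.get("medium", {})
        records = doc["records"]
        energies = np.array([r["energy_eV"] for r in records], dtype=float)
        ks = np.array([r["k"] for r in records], dtype=float)
        entries = np.array(
            [
                [[complex(re, im) for re, im in row] for row in r["entries"]]
                for r in records
            ],
            dtype=complex,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed T-matrix store ({exc})") from None
    if np.any(np.diff(energies) <= 0):
        raise ParseError(f"{path}: energy records must be strictly increasing")
    return TMatrixStack(
        energies=energies,
        ks=ks,
        entries=entries,
        basis=basis,
        medium=MediumParams(
            eps_h=float(med.get("eps_h", 1.0)), mu_h=float(med.get("mu_h", 1.0))
        ),
    )
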