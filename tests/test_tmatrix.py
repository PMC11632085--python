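"""T-matrix construction, basis algebra, rotations, mirror symmetry,
validity checks and serialization."""

import math

import numpy as np
import pytest

from boostcd import constants
from boostcd.errors import BasisError, ParseError
from boostcd.synthetic import preset_polarizabilities
from boostcd.tmatrix import (
    HELICITY,
    PARITY,
    MediumParams,
    PolarizabilitySet,
    TMatrix6,
    build_tmatrix,
    build_tmatrix_stack,
    helicity_to_parity,
    mirror_enantiomer,
    parity_to_helicity,
    passivity_margin,
    read_polarizabilities,
    read_tmatrix,
    rotate_tmatrix,
    write_polarizabilities,
    write_tmatrix,
)

J_FLIP = np.array([[-1.0, 0, 0], [0, 1.0, 0], [0, 0, -1.0]])  # (-1)^m antidiagonal


def make_set(energies, ee=None, em=None, me=None, mm=None):
    n = len(energies)
    zero = np.zeros((n, 3, 3), dtype=complex)

    def fill(x):
        if x is None:
            return zero.copy()
        x = np.asarray(x, dtype=complex)
        return np.broadcast_to(x, (n, 3, 3)).copy()

    return PolarizabilitySet(
        energies=np.asarray(energies, float),
        alpha_ee=fill(ee),
        alpha_em=fill(em),
        alpha_me=fill(me),
        alpha_mm=fill(mm),
    )


def prefactor(energy_ev, medium=None):
    medium = medium or MediumParams()
    k = constants.wavenumber_from_energy(energy_ev, medium.c_h)
    return 1j * medium.c_h * medium.Z_h * k**3 / (6 * math.pi)


class TestBuild:
    def test_zero_tensors_give_zero_matrix(self):
        pol = make_set([2.0, 3.0])
        t = build_tmatrix(pol, MediumParams(), 0)
        assert t.basis == PARITY
        assert np.all(t.entries == 0)

    def test_scalar_electric_block(self):
        a = (3.0 + 0.5j) * 1e-40
        pol = make_set([2.5], ee=a * np.eye(3))
        t = build_tmatrix(pol, MediumParams(), 0)
        pref = prefactor(2.5)
        assert np.allclose(t.entries[:3, :3], pref * a * np.eye(3), rtol=1e-14)
        assert np.all(t.entries[:3, 3:] == 0)
        assert np.all(t.entries[3:, :] == 0)
        assert t.k == pytest.approx(constants.wavenumber_from_energy(2.5))

    def test_scalar_magnetoelectric_block_sign(self):
        # the -i in the em block cancels the global i: in reduced units
        # T_NM = (c_h Z_h k^3 / 6 pi) * alpha_em_red, purely real prefactor.
        g = (0.4 - 0.2j) * 1e-40
        pol = make_set([2.5], em=g * np.eye(3))
        t = build_tmatrix(pol, MediumParams(), 0)
        k = constants.wavenumber_from_energy(2.5)
        expect = constants.C0 * constants.Z0 * k**3 / (6 * math.pi) * g
        assert np.allclose(t.entries[:3, 3:], expect * np.eye(3), rtol=1e-14)

    def test_linearity_superposition(self, rng):
        energies = [2.2]
        blocks = []
        for _ in range(2):
            blocks.append(
                [
                    1e-40
                    * (rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3)))
                    for _ in range(4)
                ]
            )
        def build(b):
            pol = make_set(energies, ee=b[0], em=b[1], me=b[2], mm=b[3])
            return build_tmatrix(pol, MediumParams(), 0).entries

        summed = build([x + y for x, y in zip(blocks[0], blocks[1])])
        parts = build(blocks[0]) + build(blocks[1])
        assert np.allclose(summed, parts, rtol=1e-12, atol=0)

    def test_reciprocity_preserved_in_spherical_blocks(self, rng):
        # alpha_me = -alpha_em^T with symmetric ee/mm implies, in the
        # m-ordered spherical basis, T_xy = J T_xy^T J per block pair.
        sym = lambda a: (a + a.T) / 2
        a_ee = sym(rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))) * 1e-40
        a_mm = sym(rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))) * 1e-40
        a_em = (rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))) * 1e-40
        pol = make_set([2.0], ee=a_ee, em=a_em, me=-a_em.T, mm=a_mm)
        assert pol.is_reciprocal()
        t = build_tmatrix(pol, MediumParams(), 0).entries
        nn, nm, mn, mm = t[:3, :3], t[:3, 3:], t[3:, :3], t[3:, 3:]
        assert np.allclose(nn, J_FLIP @ nn.T @ J_FLIP, rtol=1e-12)
        assert np.allclose(mm, J_FLIP @ mm.T @ J_FLIP, rtol=1e-12)
        assert np.allclose(mn, J_FLIP @ nm.T @ J_FLIP, rtol=1e-12)

    def test_nonfinite_tensors_rejected(self):
        with pytest.raises(ValueError):
            make_set([2.0], ee=np.full((3, 3), np.nan))

    def test_grid_index_out_of_range(self):
        pol = make_set([2.0, 3.0])
        with pytest.raises(IndexError):
            build_tmatrix(pol, MediumParams(), 2)


class TestBasisAndRotation:
    def test_parity_helicity_round_trip(self, rng):
        entries = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        t = TMatrix6(k=1e7, basis=PARITY, entries=entries)
        back = helicity_to_parity(parity_to_helicity(t))
        assert np.allclose(back.entries, entries, atol=1e-14 * np.abs(entries).max())

    def test_achiral_diagonal_maps_to_scalar_helicity(self):
        tval = 0.3 - 0.1j
        entries = np.zeros((6, 6), complex)
        entries[:3, :3] = tval * np.eye(3)
        entries[3:, 3:] = tval * np.eye(3)
        h = parity_to_helicity(TMatrix6(k=1.0, basis=PARITY, entries=entries))
        assert np.allclose(h.entries, tval * np.eye(6), atol=1e-15)

    def test_basis_tag_enforced(self):
        t = TMatrix6(k=1.0, basis=HELICITY, entries=np.zeros((6, 6)))
        with pytest.raises(BasisError):
            parity_to_helicity(t)
        tp = TMatrix6(k=1.0, basis=PARITY, entries=np.zeros((6, 6)))
        with pytest.raises(BasisError):
            helicity_to_parity(tp)
        with pytest.raises(BasisError):
            rotate_tmatrix(tp, 0.1, 0.2)

    def test_rotation_identity_and_isotropic(self, rng):
        entries = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        t = TMatrix6(k=1.0, basis=HELICITY, entries=entries)
        r0 = rotate_tmatrix(t, 0.0, 0.0)
        assert np.allclose(r0.entries, entries, atol=1e-14 * np.abs(entries).max())
        iso = TMatrix6(k=1.0, basis=HELICITY, entries=(1.2 - 3.4j) * np.eye(6))
        riso = rotate_tmatrix(iso, 1.1, 2.2)
        assert np.allclose(riso.entries, iso.entries, atol=1e-14)

    def test_rotation_preserves_singular_values(self, rng):
        entries = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        t = TMatrix6(k=1.0, basis=HELICITY, entries=entries)
        sv0 = np.linalg.svd(entries, compute_uv=False)
        for _ in range(5):
            th, ph = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
            sv = np.linalg.svd(rotate_tmatrix(t, th, ph).entries, compute_uv=False)
            assert np.allclose(sv, sv0, rtol=1e-12)


class TestMirror:
    def test_achiral_fixed_point(self):
        pol = make_set([2.0], ee=np.eye(3) * 1e-40, mm=np.eye(3) * 1e-41)
        m = mirror_enantiomer(pol)
        assert np.allclose(m.alpha_ee, pol.alpha_ee)
        assert np.all(m.alpha_em == 0) and np.all(m.alpha_me == 0)

    def test_double_mirror_is_identity(self):
        pol = preset_polarizabilities("chiral-single")
        mm = mirror_enantiomer(mirror_enantiomer(pol))
        for name in ("alpha_ee", "alpha_em", "alpha_me", "alpha_mm"):
            assert np.array_equal(getattr(mm, name), getattr(pol, name))


class TestValidity:
    def test_passivity_margin_signs(self):
        # a weak absorber (negative real diagonal: positive extinction
        # exceeding scattering) is passive ...
        good = TMatrix6(k=1.0, basis=PARITY, entries=-1e-3 * np.eye(6))
        assert passivity_margin(good) > 0
        # ... a gain matrix is not, and neither is a purely scattering-free
        # "lossless" matrix with zero extinction but nonzero scattering
        bad = TMatrix6(k=1.0, basis=PARITY, entries=1e-3 * np.eye(6))
        assert passivity_margin(bad) < -1e-4
        lossy_free = TMatrix6(k=1.0, basis=PARITY, entries=1e-3j * np.eye(6))
        assert passivity_margin(lossy_free) == pytest.approx(-1e-6)

    def test_polarizability_grid_validation(self):
        with pytest.raises(ValueError):
            make_set([2.0, 2.0])
        with pytest.raises(ValueError):
            make_set([3.0, 2.0])


class TestIO:
    def test_polarizability_csv_round_trip_bit_identical(self, tmp_path, rng):
        n = 3
        pol = PolarizabilitySet(
            energies=np.array([1.5, 2.25, 3.0]),
            alpha_ee=1e-40 * (rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))),
            alpha_em=1e-41 * (rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))),
            alpha_me=1e-41 * (rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))),
            alpha_mm=1e-42 * (rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))),
        )
        path = tmp_path / "pol.csv"
        write_polarizabilities(pol, path, units="si")
        back = read_polarizabilities(path)
        for name in ("energies", "alpha_ee", "alpha_em", "alpha_me", "alpha_mm"):
            assert np.array_equal(getattr(back, name), getattr(pol, name))

    def test_au_conversion_constant(self, tmp_path):
        pol = make_set([2.0], ee=np.eye(3) * constants.AU_POLARIZABILITY)
        path = tmp_path / "pol_au.csv"
        write_polarizabilities(pol, path, units="au")
        # the file holds alpha_ee = 1 a.u.; import converts via the CODATA factor
        text = path.read_text()
        assert "ee_xx_re" in text
        back = read_polarizabilities(path)
        assert back.alpha_ee[0, 0, 0] == pytest.approx(constants.AU_POLARIZABILITY)

    def test_non_monotone_energy_rejected_with_line_number(self, tmp_path):
        pol = make_set([1.0, 2.0, 3.0])
        path = tmp_path / "pol.csv"
        write_polarizabilities(pol, path)
        lines = path.read_text().splitlines()
        lines[4], lines[5] = lines[5], lines[4]  # swap two data rows
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="line"):
            read_polarizabilities(path)

    def test_malformed_field_names_line(self, tmp_path):
        pol = make_set([1.0, 2.0])
        path = tmp_path / "pol.csv"
        write_polarizabilities(pol, path)
        text = path.read_text().replace("2.0", "not-a-number", 1)
        path.write_text(text)
        with pytest.raises(ParseError, match="line"):
            read_polarizabilities(path)

    def test_units_conflict_rejected(self, tmp_path):
        pol = make_set([1.0, 2.0])
        path = tmp_path / "pol.csv"
        write_polarizabilities(pol, path, units="si")
        with pytest.raises(ParseError):
            read_polarizabilities(path, units="au")

    def test_tmatrix_store_round_trip_bit_identical(self, tmp_path, chiral_single_stack):
        path = tmp_path / "tmat.json"
        write_tmatrix(chiral_single_stack, path)
        back = read_tmatrix(path)
        assert back.basis == chiral_single_stack.basis
        assert np.array_equal(back.energies, chiral_single_stack.energies)
        assert np.array_equal(back.ks, chiral_single_stack.ks)
        assert np.array_equal(back.entries, chiral_single_stack.entries)

    def test_stack_builder_bases(self, chiral_single_pol):
        hel = build_tmatrix_stack(chiral_single_pol, basis=HELICITY)
        par = build_tmatrix_stack(chiral_single_pol, basis=PARITY)
        assert hel.basis == HELICITY and par.basis == PARITY
        t0 = parity_to_helicity(par[0])
        assert np.allclose(t0.entries, hel.entries[0], atol=1e-16)
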