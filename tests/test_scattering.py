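"""Form factors, Debye-Waller attenuation and structure factors."""

import numpy as np
import pytest
from scipy import integrate, special

from mbit.cells import (AtomSite, CrystalStructure, LocalAxes, SymmetryOp,
                        UnitCell, u_cart_to_cif, u_cif_to_cart)
from mbit.elements import get_element
from mbit.errors import DataError, ReflectionSetTooLarge
from mbit.multipole import AtomDensity, AtomMultipoles, MultipoleParameterSet
from mbit.scattering import (AtomFormFactor, SFCalculator,
                             aspherical_form_factor, debye_waller,
                             generate_reflection_set, slater_bessel,
                             ReflectionSet)


class TestSlaterBessel:
    @pytest.mark.parametrize("n,l,zeta,kval", [
        (2, 0, 16.6, 13.7), (5, 3, 15.1, 8.2), (7, 3, 6.9, 0.62),
        (4, 2, 5.0, 2.5), (6, 4, 8.0, 3.9), (3, 1, 4.0, 12.0),
    ])
    def test_against_quadrature(self, n, l, zeta, kval):
        ref, _ = integrate.quad(
            lambda r: r ** n * np.exp(-zeta * r) * special.spherical_jn(l, kval * r),
            0, 60, limit=400)
        assert slater_bessel(n, zeta, [kval], l)[0] == pytest.approx(ref, rel=1e-9)

    def test_branch_continuity(self):
        # series and closed form must agree where the branch switches
        for n, l, z in [(5, 4, 16.69), (4, 3, 6.0), (3, 2, 4.0)]:
            lo = slater_bessel(n, z, [0.4999 * z], l)[0]
            hi = slater_bessel(n, z, [0.5001 * z], l)[0]
            assert hi == pytest.approx(lo, rel=1e-3)


@pytest.fixture(scope="module")
def rich_mult():
    return AtomMultipoles(pc=2.0, pv=4.0, kappa=1.05, kappa_prime=0.98, lmax=3,
                          plm={(1, 0): 0.2, (2, 1): -0.1, (3, -2): 0.15})


class TestFormFactor:
    def test_zero_angle_is_electron_count(self, rich_mult):
        f = aspherical_form_factor("C", rich_mult, [[0, 0, 0]])[0]
        assert f == pytest.approx(2.0 + 4.0)
        assert f.imag == 0

    def test_kappa_scaling_of_valence(self):
        """f_val(s; kappa) = f_val(s/kappa; kappa=1)."""
        el = get_element("C")
        m1 = AtomMultipoles(pc=0.0, pv=4.0, kappa=1.2, lmax=1)
        m2 = AtomMultipoles(pc=0.0, pv=4.0, kappa=1.0, lmax=1)
        s = np.array([0.3, 0.7, 1.1])
        f1 = AtomFormFactor(el, m1).spherical(2 * np.pi * s)
        f2 = AtomFormFactor(el, m2).spherical(2 * np.pi * s / 1.2)
        assert np.allclose(f1, f2, rtol=1e-12)

    def test_matches_numeric_3d_fourier_integral(self, rich_mult):
        """Analytic transform vs direct quadrature of the real-space density."""
        ad = AtomDensity(get_element("C"), rich_mult)
        c, w = np.polynomial.legendre.leggauss(48)
        phi = np.linspace(0, 2 * np.pi, 97)[:-1]
        dphi = 2 * np.pi / 96
        cc, pp = np.meshgrid(c, phi, indexing="ij")
        sn = np.sqrt(1 - cc ** 2)
        dirs = np.stack([sn * np.cos(pp), sn * np.sin(pp), cc], -1).reshape(-1, 3)
        wang = (w[:, None] * np.ones_like(pp) * dphi).ravel()
        svecs = np.array([[0.3, 0.2, -0.1], [0.0, 0.0, 1.2], [0.9, -0.5, 0.6]])
        ana = aspherical_form_factor("C", rich_mult, svecs)
        for j, sv in enumerate(svecs):
            tot = 0j
            for a, b, npt in [(0, 0.5, 20), (0.5, 1.5, 20), (1.5, 3, 24),
                              (3, 6, 28), (6, 10, 20)]:
                x, wr = np.polynomial.legendre.leggauss(npt)
                r = (x + 1) * (b - a) / 2 + a
                wrr = wr * (b - a) / 2
                for ri, wi in zip(r, wrr):
                    pts = dirs * ri
                    tot += wi * ri * ri * np.sum(
                        ad.density(pts) * np.exp(2j * np.pi * (pts @ sv)) * wang)
            assert abs(ana[j] - tot) < 1e-5


class TestDebyeWaller:
    def test_u_zero_gives_unity(self):
        cell = UnitCell(8, 9, 10)
        t, ok = debye_waller(cell, [[1, 2, 3]], u_cif=np.zeros(6))
        assert t[0] == 1.0 and ok

    def test_iso_equals_aniso_on_random_orthorhombic(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cell = UnitCell(*rng.uniform(5, 12, 3))
            uiso = rng.uniform(0.005, 0.04)
            u6 = u_cart_to_cif(cell, uiso * np.eye(3))
            hkl = rng.integers(-6, 7, (10, 3))
            hkl = hkl[np.any(hkl != 0, axis=1)]
            t_iso, _ = debye_waller(cell, hkl, uiso=uiso)
            t_ani, _ = debye_waller(cell, hkl, u_cif=u6)
            assert np.allclose(t_iso, t_ani, rtol=1e-12)

    def test_monotone_decrease_along_direction(self):
        cell = UnitCell(8, 9, 10)
        rng = np.random.default_rng(6)
        m = rng.normal(size=(3, 3))
        u6 = u_cart_to_cif(cell, 0.01 * (m @ m.T + np.eye(3)))
        hkl = np.array([[1, 2, 1], [2, 4, 2], [3, 6, 3]])
        t, ok = debye_waller(cell, hkl, u_cif=u6)
        assert ok and np.all(np.diff(t) < 0)

    def test_non_psd_flagged_not_raised(self):
        cell = UnitCell(8, 9, 10)
        u6 = np.array([-0.01, 0.02, 0.02, 0.0, 0.0, 0.0])
        _, ok = debye_waller(cell, [[1, 0, 0]], u_cif=u6)
        assert not ok


class TestStructureFactor:
    def test_single_atom_at_origin_equals_form_factor(self):
        cell = UnitCell(10, 10, 10)
        s = AtomSite(label="C1", element="C", xyz=[0, 0, 0])
        s.uiso = 0.0
        st = CrystalStructure(cell=cell, ops=[SymmetryOp.identity()], sites=[s])
        mm = MultipoleParameterSet.neutral(st)
        hkl = np.array([[1, 0, 0], [2, 1, 0], [3, 3, 1]])
        f_struct = SFCalculator(st, mm, dispersion=False).compute(hkl)
        svec = cell.scattering_vectors(hkl)
        f_atom = aspherical_form_factor("C", mm["C1"], svec)
        assert np.allclose(f_struct, f_atom, rtol=1e-12)

    def test_centrosymmetric_pair_is_real(self):
        cell = UnitCell(10, 11, 12)
        s1 = AtomSite(label="C1", element="C", xyz=[0.1, 0.2, 0.3])
        s2 = AtomSite(label="C2", element="C", xyz=[-0.1, -0.2, -0.3])
        for s in (s1, s2):
            s.uiso = 0.02
        st = CrystalStructure(cell=cell, ops=[SymmetryOp.identity()],
                              sites=[s1, s2])
        mm = MultipoleParameterSet.neutral(st)
        f = SFCalculator(st, mm, dispersion=False).compute(
            np.array([[1, 2, 3], [2, -1, 4]]))
        assert np.abs(f.imag).max() < 1e-12

    def test_f000_is_total_electron_count(self, serine):
        st, truth = serine
        f = SFCalculator(st, truth, dispersion=False).compute(
            np.array([[0, 0, 0]]), static=True)
        assert f[0].real == pytest.approx(truth.electron_count(st), rel=1e-8)
        assert abs(f[0].imag) < 1e-8

    def test_symmetry_equivalents_have_equal_magnitude(self, serine):
        st, truth = serine
        calc = SFCalculator(st, truth, dispersion=False)
        hkl = np.array([[2, 3, 1], [1, 4, 2], [5, 1, 3]])
        f0 = np.abs(calc.compute(hkl))
        for op in st.ops[1:]:
            feq = np.abs(calc.compute(hkl @ op.rot_array))
            assert np.allclose(feq, f0, rtol=1e-10)


class TestReflectionSet:
    def test_cubic_enumeration(self):
        cell = UnitCell(10, 10, 10)
        hkl = generate_reflection_set(cell, [SymmetryOp.identity()], 5.0,
                                      friedel=False)
        # all h with h^2+k^2+l^2 <= 4, origin excluded
        expected = {tuple(v) for v in np.ndindex(5, 5, 5)}
        brute = [np.array(h) - 2 for h in expected]
        brute = [h for h in brute if h.any() and h @ h <= 4]
        assert len(hkl) == len(brute)

    def test_friedel_merge_halves_acentric_count(self):
        cell = UnitCell(10, 10, 10)
        full = generate_reflection_set(cell, [SymmetryOp.identity()], 5.0,
                                       friedel=False)
        merged = generate_reflection_set(cell, [SymmetryOp.identity()], 5.0,
                                         friedel=True)
        assert len(full) == 2 * len(merged)  # P1: no centric reflections

    def test_orbit_partition_matches_brute_force(self, serine_structure):
        st = serine_structure
        hkl = generate_reflection_set(st.cell, st.ops, 1.5, friedel=True)
        # brute-force orbits: each unique row must represent a disjoint orbit
        seen = set()
        for h in hkl:
            orbit = set()
            for op in st.ops:
                hp = tuple(int(v) for v in h @ op.rot_array)
                orbit.add(hp)
                orbit.add(tuple(-v for v in hp))
            assert not (orbit & seen)
            seen |= orbit
        # and the union must cover the full d >= 1.5 sphere
        full = generate_reflection_set(st.cell, [SymmetryOp.identity()], 1.5,
                                       friedel=False)
        assert seen == {tuple(v) for v in full}

    def test_count_matches_enumeration_at_08(self, serine_structure, theory_data_08):
        hkl, _ = theory_data_08
        st = serine_structure
        d = st.cell.d_spacing(hkl)
        assert d.min() >= 0.8 - 1e-9
        assert len(hkl) == len(np.unique(hkl, axis=0))

    def test_cap(self):
        with pytest.raises(ReflectionSetTooLarge):
            generate_reflection_set(UnitCell(30, 30, 30),
                                    [SymmetryOp.identity()], 0.2, cap=1000)

    def test_duplicate_rows_rejected(self):
        with pytest.raises(DataError):
            ReflectionSet(hkl=[[1, 0, 0], [1, 0, 0]],
                          fo2=[1.0, 1.0], sigma=[0.1, 0.1])
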