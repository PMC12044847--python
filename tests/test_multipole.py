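"""Real-space pseudoatom and crystal densities."""

import numpy as np
import pytest

from mbit.cells import AtomSite, CrystalStructure, SymmetryOp, UnitCell
from mbit.elements import get_element
from mbit.errors import ConfigurationError
from mbit.fixtures import make_fixture
from mbit.multipole import (AtomDensity, AtomMultipoles, CrystalDensity,
                            MultipoleParameterSet, density_on_grid,
                            eval_atom_density)


@pytest.fixture(scope="module")
def rich_atom():
    mult = AtomMultipoles(pc=2.0, pv=4.2, kappa=1.05, kappa_prime=0.98, lmax=3,
                          plm={(1, 0): 0.2, (2, 1): -0.1, (3, -2): 0.15, (2, 0): 0.05})
    return AtomDensity(get_element("C"), mult)


def radial_angular_integral(ad, rmax=12.0, n_r=120, n_theta=50, n_phi=64):
    """Adaptive-quality quadrature oracle for the full-space integral."""
    c, w = np.polynomial.legendre.leggauss(n_theta)
    phi = np.linspace(0, 2 * np.pi, n_phi + 1)[:-1]
    dphi = 2 * np.pi / n_phi
    cc, pp = np.meshgrid(c, phi, indexing="ij")
    s = np.sqrt(1 - cc ** 2)
    dirs = np.stack([s * np.cos(pp), s * np.sin(pp), cc], -1).reshape(-1, 3)
    wang = (w[:, None] * np.ones_like(pp) * dphi).ravel()
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    r = (xr + 1) * rmax / 2
    wrr = wr * rmax / 2
    total = 0.0
    for ri, wi in zip(r, wrr):
        total += wi * ri * ri * float(ad.density(dirs * ri) @ wang)
    return total


class TestAtomDensity:
    def test_spherical_when_no_multipoles(self):
        mult = AtomMultipoles(pc=2.0, pv=4.0, kappa=1.0, lmax=3)
        ad = AtomDensity(get_element("C"), mult)
        p1 = ad.density(np.array([[0.7, 0.0, 0.0]]))
        p2 = ad.density(np.array([[0.0, -0.7 / np.sqrt(2), 0.7 / np.sqrt(2)]]))
        assert p1[0] == pytest.approx(p2[0], rel=1e-12)

    def test_dipole_antisymmetry(self):
        mult = AtomMultipoles(pc=0.0, pv=0.0, lmax=1, plm={(1, 0): 0.3})
        ad = AtomDensity(get_element("H"), mult)
        up = ad.density(np.array([[0, 0, 0.6]]))[0]
        dn = ad.density(np.array([[0, 0, -0.6]]))[0]
        assert up == pytest.approx(-dn, rel=1e-12)
        assert up > 0

    def test_total_charge_is_pc_plus_pv(self, rich_atom):
        total = radial_angular_integral(rich_atom)
        assert total == pytest.approx(2.0 + 4.2, abs=1e-6)

    def test_gradient_hessian_match_finite_differences(self, rich_atom):
        pts = np.array([[0.5, -0.3, 0.8], [1.2, 0.1, -0.4], [0.1, 0.05, -0.03]])
        rho, g, h = rich_atom.grad_hess(pts)
        eps = 1e-5
        for k, p in enumerate(pts):
            for i in range(3):
                e = np.zeros(3)
                e[i] = eps
                fd = (rich_atom.density((p + e)[None])[0]
                      - rich_atom.density((p - e)[None])[0]) / (2 * eps)
                assert g[k, i] == pytest.approx(fd, rel=1e-5, abs=1e-9)
                _, gp, _ = rich_atom.grad_hess((p + e)[None])
                _, gm, _ = rich_atom.grad_hess((p - e)[None])
                assert np.allclose(h[k, i], (gp[0] - gm[0]) / (2 * eps),
                                   rtol=1e-5, atol=1e-7)
            assert np.allclose(h[k], h[k].T)

    def test_kappa_guard_range(self):
        with pytest.raises(ConfigurationError):
            AtomMultipoles(pc=2, pv=4, kappa=2.5)

    def test_lmax_cap(self):
        with pytest.raises(ConfigurationError):
            AtomMultipoles(pc=2, pv=4, lmax=5)


class TestCrystalDensity:
    def test_single_atom_box_matches_isolated_atom(self):
        cell = UnitCell(15, 15, 15)
        s = AtomSite(label="C1", element="C", xyz=[0.5, 0.5, 0.5])
        st = CrystalStructure(cell=cell, ops=[SymmetryOp.identity()], sites=[s])
        mm = MultipoleParameterSet.neutral(st)
        cd = CrystalDensity(st, mm, cutoff=6.0)
        pts = np.array([[7.5 + 0.9, 7.5, 7.5], [7.5, 7.5 - 1.3, 7.5]])
        crystal = cd.density(pts)
        atom = eval_atom_density("C", mm["C1"], pts, center=np.array([7.5] * 3))
        assert np.allclose(crystal, atom, rtol=1e-10)

    def test_symmetry_invariance(self, serine):
        st, truth = serine
        cd = CrystalDensity(st, truth, cutoff=6.0)
        rng = np.random.default_rng(4)
        frac = rng.uniform(size=(20, 3))
        a = st.cell.frac_to_cart
        rho0 = cd.density(frac @ a.T)
        for op in st.ops[1:]:
            moved = np.array([op.apply(f) for f in frac])
            rho1 = cd.density(moved @ a.T)
            assert np.allclose(rho1, rho0, rtol=1e-10)

    def test_cutoff_convergence(self):
        st, mm = make_fixture("diatomic")
        p = st.cell.frac_to_cart @ np.array([0.5, 0.5, 0.53])
        vals = [CrystalDensity(st, mm, cutoff=c).density(p[None])[0]
                for c in (8.0, 12.0)]
        assert abs(vals[1] - vals[0]) < 1e-8

    def test_gradient_hessian_symmetry_and_trace(self, serine):
        st, truth = serine
        cd = CrystalDensity(st, truth, cutoff=6.0)
        pts = (st.cell.frac_to_cart @ np.array([[0.3, 0.4, 0.2], [0.7, 0.1, 0.6]]).T).T
        rho, g, h = cd.gradient_hessian(pts)
        assert np.allclose(h, h.transpose(0, 2, 1))
        # spherical-atom gradient is radial: checked on the isolated-atom case
        cell = UnitCell(15, 15, 15)
        s = AtomSite(label="C1", element="C", xyz=[0.5, 0.5, 0.5])
        stc = CrystalStructure(cell=cell, ops=[SymmetryOp.identity()], sites=[s])
        cdn = CrystalDensity(stc, MultipoleParameterSet.neutral(stc), cutoff=6.0)
        v = np.array([0.8, -0.5, 0.4])
        _, gg, _ = cdn.gradient_hessian((cell.frac_to_cart @ np.array([0.5] * 3) + v)[None])
        cosang = gg[0] @ v / np.linalg.norm(gg[0]) / np.linalg.norm(v)
        assert abs(abs(cosang) - 1.0) < 1e-10


class TestGridSampling:
    def test_electron_count_on_grid(self, serine):
        st, truth = serine
        grid = density_on_grid(st, truth, (72, 72, 48))
        total = grid.mean() * st.cell.volume
        f000 = truth.electron_count(st)
        assert total == pytest.approx(f000, rel=2e-3)


class TestParameterSet:
    def test_dict_roundtrip_bit_stable(self, serine_truth):
        d = serine_truth.to_dict()
        back = MultipoleParameterSet.from_dict(d)
        for lbl in serine_truth.labels():
            t, b = serine_truth[lbl], back[lbl]
            assert t.pv == b.pv and t.kappa == b.kappa
            assert t.plm == b.plm

    def test_neutral_electron_count(self, serine_structure):
        mm = MultipoleParameterSet.neutral(serine_structure)
        # C3 H7 N O3 has 56 electrons; Z = 4
        assert mm.electron_count(serine_structure) == pytest.approx(4 * 56)
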