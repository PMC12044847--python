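"""Weighted least squares on F²: weights, statistics, recovery, extinction."""

import numpy as np
import pytest

from mbit.errors import DataError, RefinementError
from mbit.fixtures import make_fixture, simulate_intensities
from mbit.multipole import MultipoleParameterSet
from mbit.refine import (RefinementProtocol, Stage, extinction_correct,
                         extinction_kernel, fit_statistics, lsq_refine,
                         optimal_scale, shelxl_weight,
                         three_step_coordinate_protocol)
from mbit.scattering import ReflectionSet, SFCalculator


class TestWeights:
    def test_zero_constants_reduce_to_sigma_weights(self):
        w = shelxl_weight([100.0], [2.0], [90.0], 0.0, 0.0)
        assert w[0] == pytest.approx(1 / 4.0)

    def test_hand_evaluated_case(self):
        # P = (100 + 200)/3 = 100; w = 1/(4 + (0.05*100)^2) = 1/29
        w = shelxl_weight([100.0], [2.0], [100.0], 0.05, 0.0)
        assert w[0] == pytest.approx(1 / 29.0)

    def test_negative_intensity_clamped_in_p(self):
        # P = (0 + 60)/3 = 20, finite weight
        w = shelxl_weight([-5.0], [1.0], [30.0], 0.1, 0.1)
        assert np.isfinite(w[0])
        assert w[0] == pytest.approx(1 / (1 + 4.0 + 2.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DataError):
            shelxl_weight([1.0], [0.0], [1.0], 0.0, 0.0)


class TestStatistics:
    def test_perfect_fit_gives_zero(self):
        fc = np.array([3.0 + 0j, 4.0 + 0j])
        stats = fit_statistics(np.abs(fc) ** 2, np.array([0.1, 0.1]), fc, 1.0)
        assert stats.r1 == pytest.approx(0.0)
        assert stats.wr2 == pytest.approx(0.0)

    def test_two_reflection_hand_sum(self):
        # |Fo| = (10, 20), |Fc| = (11, 18) -> R1 = (1+2)/30 = 10%
        fo2 = np.array([100.0, 400.0])
        fc = np.array([11.0 + 0j, 18.0 + 0j])
        stats = fit_statistics(fo2, np.array([1.0, 1.0]), fc, 1.0)
        assert stats.r1 == pytest.approx(10.0)

    def test_empty_set_rejected(self):
        with pytest.raises(DataError):
            fit_statistics(np.array([]), np.array([]), np.array([]), 1.0)

    def test_fitted_scale_never_increases_wr2(self):
        rng = np.random.default_rng(7)
        fc2 = rng.uniform(1, 100, 40)
        fo2 = 1.44 * fc2 * (1 + rng.normal(0, 0.05, 40))
        sig = 0.05 * fo2
        w = 1.0 / sig ** 2
        k = optimal_scale(fo2, fc2, w)
        fc = np.sqrt(fc2).astype(complex)
        wr2_fit = fit_statistics(fo2, sig, fc, k).wr2
        for k_bad in (1.0, 1.1, 1.3):
            assert wr2_fit <= fit_statistics(fo2, sig, fc, k_bad).wr2 + 1e-12


@pytest.fixture(scope="module")
def serine_clean():
    st, truth = make_fixture("serine_like")
    data = simulate_intensities(st, truth, d_min=0.9, rel_sigma=0.0, seed=0)
    return st, truth, data


class TestRecovery:
    def test_stationary_at_truth(self, serine_clean):
        st, truth, data = serine_clean
        proto = RefinementProtocol(stages=[Stage(name="xyz", xyz=("C1",),
                                                 max_cycles=3)], weight_a=0.0)
        res = lsq_refine(st, truth, data, proto, model="multipole")
        assert res.stats.r1 == pytest.approx(0.0, abs=1e-6)
        d = res.structure.site("C1").xyz - st.site("C1").xyz
        assert np.abs(d - np.rint(d)).max() < 1e-10

    def test_coordinate_recovery_from_002A_shift(self, serine_clean):
        st, truth, data = serine_clean
        pert = st.copy()
        pert.site("C2").xyz[0] += 0.02 / st.cell.a
        proto = RefinementProtocol(stages=[Stage(name="xyz", xyz=("C2",))],
                                   weight_a=0.0)
        res = lsq_refine(pert, truth, data, proto, model="multipole")
        d = res.structure.site("C2").xyz - st.site("C2").xyz
        d -= np.rint(d)
        assert np.linalg.norm(st.cell.frac_to_cart @ d) < 1e-5

    def test_uiso_recovery(self, serine_clean):
        st, truth, data = serine_clean
        pert = st.copy()
        site = pert.site("H7")
        from mbit.cells import u_equiv, u_cart_to_cif
        u0 = u_equiv(st.cell, site.u_cif)
        # simulate data for an isotropic-H7 variant so truth is in model class
        iso = st.copy()
        iso.site("H7").u_cif = None
        iso.site("H7").uiso = u0
        data_iso = simulate_intensities(iso, truth, d_min=0.9, rel_sigma=0.0, seed=0)
        pert = iso.copy()
        pert.site("H7").uiso = u0 + 0.005
        proto = RefinementProtocol(stages=[Stage(name="u", uiso=("H7",))],
                                   weight_a=0.0)
        res = lsq_refine(pert, truth, data_iso, proto, model="multipole")
        assert abs(res.structure.site("H7").uiso - u0) < 1e-6

    def test_one_gauss_newton_cycle_is_quadratically_accurate(self, serine_clean):
        """A single damped-GN cycle from an epsilon-perturbed start lands
        within O(epsilon^2) of the solution (the linear-problem limit)."""
        st, truth, data = serine_clean
        pert = st.copy()
        eps = 1e-5
        pert.site("O1").xyz[1] += eps
        proto = RefinementProtocol(stages=[Stage(name="xyz", xyz=("O1",),
                                                 max_cycles=1)], weight_a=0.0)
        res = lsq_refine(pert, truth, data, proto, model="multipole", scale0=1.0)
        d = res.structure.site("O1").xyz - st.site("O1").xyz
        d -= np.rint(d)
        # two orders of magnitude below the perturbation after a single cycle
        assert np.linalg.norm(d) < 1e-7

    def test_lattice_translation_invariance(self, serine_clean):
        st, truth, data = serine_clean
        moved = st.copy()
        for s in moved.sites:
            s.xyz = (s.xyz + np.array([1.0, 2.0, -1.0])) % 1.0
        f0 = SFCalculator(st, truth).compute(data.hkl)
        f1 = SFCalculator(moved, truth).compute(data.hkl)
        assert np.allclose(np.abs(f0), np.abs(f1), rtol=1e-12)

    def test_esd_scales_linearly_with_sigma(self, serine_clean):
        st, truth, data = serine_clean
        proto = RefinementProtocol(stages=[Stage(name="xyz", xyz=("C1",),
                                                 max_cycles=4)], weight_a=0.0)
        res1 = lsq_refine(st, truth, data, proto, model="multipole")
        half = ReflectionSet(hkl=data.hkl, fo2=data.fo2, sigma=data.sigma / 2.0)
        res2 = lsq_refine(st, truth, half, proto, model="multipole")
        e1 = res1.esds[("xyz", "C1", 0)]
        e2 = res2.esds[("xyz", "C1", 0)]
        assert e2 == pytest.approx(e1 / 2.0, rel=1e-3)

    def test_underdetermined_stage_rejected(self, serine_clean):
        st, truth, data = serine_clean
        tiny = ReflectionSet(hkl=data.hkl[:3], fo2=data.fo2[:3],
                             sigma=data.sigma[:3])
        proto = three_step_coordinate_protocol(st)
        with pytest.raises(RefinementError):
            lsq_refine(st, truth, tiny, proto, model="multipole")


class TestExtinction:
    def test_identity_at_zero(self):
        fc2 = np.array([10.0, 1000.0])
        assert np.allclose(extinction_correct(fc2, 0.0, np.array([1.0, 1.0])), fc2)

    def test_strong_reflections_attenuated_most(self):
        fc2 = np.array([10.0, 1000.0])
        corr = extinction_correct(fc2, 5.0, np.array([1.0, 1.0])) / fc2
        assert corr[1] < corr[0] < 1.0

    def test_negative_parameter_rejected(self):
        with pytest.raises(DataError):
            extinction_correct(np.array([1.0]), -0.1, np.array([1.0]))

    def test_parameter_recovery(self):
        st, truth = make_fixture("serine_like")
        x_true = 30.0
        data = simulate_intensities(st, truth, d_min=0.9, rel_sigma=0.0,
                                    seed=0, ext_x=x_true)
        proto = RefinementProtocol(
            stages=[Stage(name="ext", extinction=True, max_cycles=30)],
            weight_a=0.0)
        res = lsq_refine(st, truth, data, proto, model="multipole",
                         use_extinction=True, ext0=1.0)
        assert res.ext_x == pytest.approx(x_true, rel=0.05)
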