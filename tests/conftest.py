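"""Shared fixtures.

The expensive artifacts (the 14-atom orthorhombic test crystal, its
theoretical static structure factors and the staged multipole fit) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from mbit.fixtures import make_fixture, simulate_intensities
from mbit.loop import SyntheticOracleBackend, generate_tmmp
from mbit.scattering import ReflectionSet, SFCalculator, generate_reflection_set


@pytest.fixture(scope="session")
def serine():
    return make_fixture("serine_like")


@pytest.fixture(scope="session")
def serine_structure(serine):
    return serine[0]


@pytest.fixture(scope="session")
def serine_truth(serine):
    return serine[1]


@pytest.fixture(scope="session")
def theory_data_08(serine):
    """Theoretical static structure factors of the truth model, d >= 0.8 A."""
    st, truth = serine
    hkl = generate_reflection_set(st.cell, st.ops, 0.8, friedel=True)
    f = SFCalculator(st, truth, dispersion=False).compute(hkl, static=True)
    return hkl, f


@pytest.fixture(scope="session")
def tmmp_fit_08(serine):
    """Staged tMMP fit against the frozen oracle at the default 0.8 A."""
    st, truth = serine
    backend = SyntheticOracleBackend(st, truth, mode="frozen")
    mmps, stats, scale = generate_tmmp(st, backend, d_min_theory=0.8)
    return mmps, stats, scale


@pytest.fixture(scope="session")
def noisy_data_08(serine):
    st, truth = serine
    return simulate_intensities(st, truth, d_min=0.8, rel_sigma=0.02, seed=11)


@pytest.fixture(scope="session")
def clean_data_08(serine):
    st, truth = serine
    return simulate_intensities(st, truth, d_min=0.8, rel_sigma=0.0, seed=0)


def param_errors(truth, fitted):
    """Max abs deviation of (populations, kappas) between two parameter sets."""
    perr, kerr = [], []
    for lbl in truth.labels():
        t, f = truth[lbl], fitted[lbl]
        for l in range(1, t.lmax + 1):
            for m in range(-l, l + 1):
                perr.append(abs(t.get_plm(l, m) - f.get_plm(l, m)))
        perr.append(abs(t.pv - f.pv))
        kerr.append(abs(t.kappa - f.kappa))
        kerr.append(abs(t.kappa_prime - f.kappa_prime))
    return max(perr), max(kerr)


def xh_distances(structure, pairs):
    out = {}
    a = structure.cell.frac_to_cart
    for h, x in pairs.items():
        d = structure.site(h).xyz - structure.site(x).xyz
        d -= np.rint(d)
        out[h] = float(np.linalg.norm(a @ d))
    return out


def bonded_heavy_partner(structure):
    """H label -> nearest heavy-atom label (the bonded partner)."""
    a = structure.cell.frac_to_cart
    pos = {s.label: s.xyz for s in structure.sites}

    def mi_dist(p, q):
        d = pos[p] - pos[q]
        d -= np.rint(d)
        return np.linalg.norm(a @ d)

    return {
        s.label: min(
            ((mi_dist(s.label, o.label), o.label)
             for o in structure.sites if o.element != "H"),
        )[1]
        for s in structure.sites if s.element == "H"
    }
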