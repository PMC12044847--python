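"""Deterministic synthetic crystals and diffraction datasets.

These fixtures play the role of the small molecular test crystals used in
quantum-crystallography method development (an amino-acid zwitterion and a
hydrogen-bond-rich polyol, both in the Sohncke space group P2_1 2_1 2_1),
without requiring any external data: geometry, ground-truth multipole
parameters and ADPs are generated from frozen constants, so the same call
always returns bit-identical structures.

The ground-truth multipole parameters are drawn once from
literature-plausible ranges (|Pv - neutral| <= 0.3 e, |P_lm| <= 0.2 e,
kappa in [0.97, 1.13]) with a fixed internal generator and are independent
of the user-facing `seed`, which only drives the simulated measurement
noise.  Hydrogen atoms carry a positive bond-directed dipole (density pulled
into the X-H bond), the feature responsible for the familiar foreshortening
of X-H distances in spherical-atom refinements.
"""

from __future__ import annotations

import numpy as np

from .cells import AtomSite, CrystalStructure, LocalAxes, SymmetryOp, UnitCell, u_cart_to_cif
from .errors import ConfigurationError, DataError
from .multipole import AtomMultipoles, MultipoleParameterSet
from .refine import extinction_correct, extinction_kernel
from .scattering import ReflectionSet, SFCalculator, generate_reflection_set
from .elements import get_element

__all__ = ["make_fixture", "simulate_intensities", "assign_local_axes", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("serine_like", "xylitol_like", "diatomic", "single_atom")

_TRUTH_SEED = 20230917  # frozen; fixture truth never varies


def _tetra_dirs(d: np.ndarray, phi0: float = 0.0):
    """Three unit vectors completing a tetrahedron around bond direction d."""
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    out = []
    for k in range(3):
        phi = phi0 + 2 * np.pi * k / 3
        out.append(-d / 3.0 + np.sqrt(8.0) / 3.0 * (u * np.cos(phi) + v * np.sin(phi)))
    return [o / np.linalg.norm(o) for o in out]


def _serine_molecule():
    """Zwitterion-shaped C3 H7 N O3 molecule in Cartesian coordinates (A)."""
    t = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    atoms = {}
    atoms["C1"] = np.zeros(3)
    atoms["N1"] = 1.49 * t[0]
    atoms["C3"] = 1.53 * t[1]
    atoms["C2"] = 1.52 * t[2]
    atoms["H4"] = 1.09 * t[3]
    # ammonium hydrogens around N-C1
    for i, d in enumerate(_tetra_dirs(atoms["C1"] - atoms["N1"], 0.3)):
        atoms[f"H{i + 1}"] = atoms["N1"] + 1.03 * d
    # carboxylate: sp2 oxygens
    d = atoms["C1"] - atoms["C3"]
    d /= np.linalg.norm(d)
    n = np.cross(d, [0.0, 0.0, 1.0])
    n /= np.linalg.norm(n)
    p = np.cross(n, d)
    for lbl, sgn in (("O1", 1.0), ("O2", -1.0)):
        atoms[lbl] = atoms["C3"] + 1.25 * (-0.5 * d + sgn * np.sin(np.pi / 3) * p)
    # hydroxymethyl side chain
    dirs = _tetra_dirs(atoms["C1"] - atoms["C2"], 0.9)
    atoms["O3"] = atoms["C2"] + 1.42 * dirs[0]
    atoms["H5"] = atoms["C2"] + 1.09 * dirs[1]
    atoms["H6"] = atoms["C2"] + 1.09 * dirs[2]
    atoms["H7"] = atoms["O3"] + 0.97 * _tetra_dirs(atoms["C2"] - atoms["O3"], 1.2)[0]
    elements = {k: ("H" if k.startswith("H") else k[0]) for k in atoms}
    return atoms, elements


def _xylitol_molecule():
    """Extended-chain pentitol C5 H12 O5 (CH2OH-(CHOH)3-CH2OH)."""
    atoms = {}
    b = 1.53
    dx = b * np.sin(np.radians(54.75))
    dy = b * np.cos(np.radians(54.75))
    for i in range(5):
        atoms[f"C{i + 1}"] = np.array([i * dx, (i % 2) * dy, 0.0])
    for i in range(5):
        c = atoms[f"C{i + 1}"]
        nb = []
        if i > 0:
            nb.append(atoms[f"C{i}"])
        if i < 4:
            nb.append(atoms[f"C{i + 2}"])
        if len(nb) == 2:
            bis = (nb[0] - c) / np.linalg.norm(nb[0] - c) + (nb[1] - c) / np.linalg.norm(nb[1] - c)
            bis /= -np.linalg.norm(bis)
            perp = np.cross(nb[1] - nb[0], [0.0, 0.0, 1.0])
            up = np.array([0.0, 0.0, 1.0]) * (1 if i % 2 == 0 else -1)
            half = np.radians(109.47 / 2)
            d_o = np.cos(half) * bis + np.sin(half) * up
            d_h = np.cos(half) * bis - np.sin(half) * up
            atoms[f"O{i + 1}"] = c + 1.42 * d_o
            atoms[f"H{i + 1}"] = c + 1.09 * d_h
        else:
            other = nb[0]
            dirs = _tetra_dirs(other - c, 0.4 + 0.7 * i)
            atoms[f"O{i + 1}"] = c + 1.42 * dirs[0]
            atoms[f"H{i + 1}"] = c + 1.09 * dirs[1]
            atoms[f"H{i + 1}b"] = c + 1.09 * dirs[2]
    for i in range(5):
        o = atoms[f"O{i + 1}"]
        c = atoms[f"C{i + 1}"]
        atoms[f"HO{i + 1}"] = o + 0.97 * _tetra_dirs(c - o, 0.8 + 1.1 * i)[0]
    elements = {k: k[0] if k[0] in "CO" else "H" for k in atoms}
    return atoms, elements


#: frozen placements (Euler angles in rad, fractional translation) found by a
#: packing search: no intermolecular contact below chemical-sanity limits and
#: at least one intermolecular O-H...O hydrogen bond shorter than 2.0 A.
_PLACEMENTS = {
    "serine_like": {
        "cell": (9.5, 10.0, 6.0),
        "euler": (5.848437, 1.710166, 1.615458),
        "shift": (0.427511, 0.312027, 0.658344),
    },
    "xylitol_like": {
        "cell": (11.5, 9.0, 8.5),
        "euler": (1.851846, 1.781615, 4.654469),
        "shift": (0.089642, 0.63957, 0.707869),
    },
}


def _rotation(euler):
    a, b, g = euler
    rz = lambda t: np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])
    ry = lambda t: np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])
    return rz(a) @ ry(b) @ rz(g)


def _build_molecular_fixture(name: str) -> CrystalStructure:
    atoms, elements = _serine_molecule() if name == "serine_like" else _xylitol_molecule()
    pl = _PLACEMENTS[name]
    cell = UnitCell(*pl["cell"])
    rot = _rotation(pl["euler"])
    shift = np.asarray(pl["shift"])
    ops = [SymmetryOp.from_xyz(s) for s in
           ("x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z")]
    inv = cell.cart_to_frac
    sites = []
    for lbl, pos in atoms.items():
        frac = inv @ (rot @ pos) + shift
        sites.append(AtomSite(label=lbl, element=elements[lbl], xyz=frac % 1.0))
    st = CrystalStructure(cell=cell, ops=ops, sites=sites, name=name)
    assign_local_axes(st)
    _assign_truth_adps(st)
    return st


def assign_local_axes(structure: CrystalStructure) -> None:
    """Auto-assign multipole local axes: z toward the nearest (bonded)
    neighbour, x toward the next non-collinear one.  Uses intramolecular
    (asymmetric-unit) geometry only."""
    a = structure.cell.frac_to_cart
    frac = {s.label: s.xyz for s in structure.sites}

    def mi(frm, to):  # minimum-image Cartesian vector
        d = frac[to] - frac[frm]
        d -= np.rint(d)
        return a @ d

    for s in structure.sites:
        d = sorted(
            ((np.linalg.norm(mi(s.label, o)), o) for o in frac if o != s.label),
            key=lambda t: t[0],
        )
        if not d:
            s.local_axes = None
            continue
        ref_z = d[0][1]
        ref_x = None
        vz = mi(s.label, ref_z)
        for _dist, o in d[1:]:
            v = mi(s.label, o)
            cosang = abs(v @ vz) / (np.linalg.norm(v) * np.linalg.norm(vz))
            if cosang < 0.99:
                ref_x = o
                break
        s.local_axes = LocalAxes(ref_z=ref_z, ref_x=ref_x) if ref_x else None


def _assign_truth_adps(structure: CrystalStructure) -> None:
    rng = np.random.default_rng(_TRUTH_SEED + 1)
    for s in structure.sites:
        lo, hi = (0.025, 0.045) if s.element == "H" else (0.012, 0.028)
        eig = rng.uniform(lo, hi, size=3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        u_cart = q @ np.diag(eig) @ q.T
        s.u_cif = u_cart_to_cif(structure.cell, u_cart)


def _truth_mmps(structure: CrystalStructure) -> MultipoleParameterSet:
    rng = np.random.default_rng(_TRUTH_SEED)
    atoms = {}
    for s in structure.sites:
        el = get_element(s.element)
        if s.element == "H":
            plm = {(1, 0): rng.uniform(0.14, 0.20),
                   (1, 1): rng.uniform(-0.03, 0.03),
                   (1, -1): rng.uniform(-0.03, 0.03)}
            atoms[s.label] = AtomMultipoles(
                pc=0.0, pv=el.n_valence + rng.uniform(-0.25, -0.05),
                kappa=rng.uniform(1.05, 1.13), kappa_prime=rng.uniform(1.0, 1.1),
                lmax=1, plm=plm)
        else:
            # bond-directed dipole plus modest higher multipoles; the heavy
            # deformation terms are kept small relative to the hydrogen bond
            # dipoles, as in refined organic charge densities where the X-H
            # bond density is the dominant aspherical feature near H
            amp = 0.02 if s.element == "O" else 0.04
            plm = {}
            for l in range(2, 4):
                for m in range(-l, l + 1):
                    plm[(l, m)] = rng.uniform(-amp, amp)
            plm[(1, 0)] = rng.uniform(0.01, 0.04)
            plm[(1, 1)] = rng.uniform(-0.02, 0.02)
            plm[(1, -1)] = rng.uniform(-0.02, 0.02)
            atoms[s.label] = AtomMultipoles(
                pc=el.n_core, pv=el.n_valence + rng.uniform(-0.2, 0.3),
                kappa=rng.uniform(0.97, 1.03), kappa_prime=rng.uniform(0.95, 1.05),
                lmax=3, plm=plm)
    return MultipoleParameterSet(atoms)


def _diatomic() -> CrystalStructure:
    cell = UnitCell(12.0, 12.0, 12.0)
    z = 1.10 / 2 / 12.0
    sites = [
        AtomSite(label="N1", element="N", xyz=[0.5, 0.5, 0.5 - z]),
        AtomSite(label="N2", element="N", xyz=[0.5, 0.5, 0.5 + z]),
    ]
    for s in sites:
        s.uiso = 0.02
    return CrystalStructure(cell=cell, ops=[SymmetryOp.identity()], sites=sites,
                            name="diatomic")


def _single_atom() -> CrystalStructure:
    cell = UnitCell(15.0, 15.0, 15.0)
    s = AtomSite(label="C1", element="C", xyz=[0.25, 0.25, 0.25])
    s.uiso = 0.02
    return CrystalStructure(cell=cell, ops=[SymmetryOp.identity()], sites=[s],
                            name="single_atom")


def make_fixture(name: str, seed: int = 0):
    """Build a named fixture: (CrystalStructure, ground-truth multipoles).

    The geometry and truth parameters are frozen constants; `seed` is
    accepted for interface symmetry with :func:`simulate_intensities` but
    does not alter the structure (same name and seed always give identical
    output).
    """
    if name not in FIXTURE_NAMES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
    if name in ("serine_like", "xylitol_like"):
        st = _build_molecular_fixture(name)
        return st, _truth_mmps(st)
    st = _diatomic() if name == "diatomic" else _single_atom()
    mmps = MultipoleParameterSet.neutral(st)
    return st, mmps


def simulate_intensities(structure: CrystalStructure, mmps: MultipoleParameterSet,
                         d_min: float, rel_sigma: float = 0.02, seed: int = 0,
                         scale: float = 1.0, ext_x: float = 0.0,
                         dispersion: bool = True, friedel: bool = True) -> ReflectionSet:
    """Simulated experimental intensities on the unique reflection list:

        Fo² = k² |F|² ext(x) + N(0, sigma²),
        sigma = max(rel_sigma * k² |F|² ext, floor).

    The noise is Gaussian with a relative amplitude `rel_sigma` (2% mirrors
    a good low-temperature dataset) and a small floor so weak reflections
    keep finite weights.
    """
    if d_min <= 0.3:
        raise DataError("d_min below 0.3 A is not supported for simulation")
    if rel_sigma < 0:
        raise DataError("rel_sigma must be non-negative")
    hkl = generate_reflection_set(structure.cell, structure.ops, d_min, friedel=friedel)
    calc = SFCalculator(structure, mmps, dispersion=dispersion)
    fc = calc.compute(hkl)
    fc2 = np.abs(fc) ** 2
    q = extinction_kernel(structure.cell, hkl)
    ideal = scale ** 2 * extinction_correct(fc2, ext_x, q)
    floor = max(rel_sigma * 0.02, 1e-6) * float(np.mean(ideal))
    sigma = np.maximum(rel_sigma * ideal, floor)
    rng = np.random.default_rng(seed)
    fo2 = ideal + (rng.normal(0.0, sigma) if rel_sigma > 0 else 0.0)
    return ReflectionSet(hkl=hkl, fo2=fo2, sigma=sigma)
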