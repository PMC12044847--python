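"""Aspherical form factors and structure factors.

The atomic form factor is the Fourier transform of the pseudoatom density,

    f(h) = Pc f_core(s) + Pv f_val(s/kappa)
           + sum_l 4 pi i^l <j_l>(s/kappa') sum_m P_lm d_lm(h-hat),

with <j_l> the Fourier-Bessel transform of the Slater deformation radial.
For Slater functions r^n exp(-zeta r) the transform has a closed form built
from sin/cos expansions of the spherical Bessel functions; a power series is
used at low scattering angle where the closed form cancels.

The structure factor sums the symmetry-expanded cell,

    F(h) = sum_ops exp(2 pi i h.t) sum_atoms occ (f(h') + f' + i f'')
           T(U, h') exp(2 pi i h'.x),   h' = R^T h,

so each atom is always evaluated with its own ADP and local frame at the
rotation-equivalent reflection h'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd

from . import harmonics
from .cells import CrystalStructure, UnitCell
from .elements import get_element
from .errors import ConfigurationError, DataError, ReflectionSetTooLarge
from .multipole import AtomMultipoles, MultipoleParameterSet, deformation_radial

__all__ = [
    "slater_bessel",
    "AtomFormFactor",
    "aspherical_form_factor",
    "debye_waller",
    "SFCalculator",
    "structure_factor",
    "generate_reflection_set",
    "ReflectionSet",
    "MO_KALPHA",
]

#: Mo K-alpha wavelength in Angstrom (the default radiation).
MO_KALPHA = 0.71073


@lru_cache(maxsize=None)
def _bessel_sincos_coeffs(l: int):
    """j_l(x) = sum_k (S_k sin x + C_k cos x) / x^k as {k: coeff} dicts."""
    s = [{1: Fraction(1)}, {2: Fraction(1)}]
    c = [{}, {1: Fraction(-1)}]
    while len(s) <= l:
        ll = len(s) - 1
        new_s, new_c = {}, {}
        for src, dst in ((s, new_s), (c, new_c)):
            for k, v in src[ll].items():
                dst[k + 1] = dst.get(k + 1, Fraction(0)) + (2 * ll + 1) * v
            for k, v in src[ll - 1].items():
                dst[k] = dst.get(k, Fraction(0)) - v
        s.append(new_s)
        c.append(new_c)
    return s[l], c[l]


_RADIAL_CACHE: dict = {}


def _transform(n: int, zeta: float, k_arr: np.ndarray, l: int, token):
    """Memoized Fourier-Bessel transform for a fixed reflection list
    (`token` identifies the K array); falls back to direct evaluation."""
    if token is None:
        return slater_bessel(n, zeta, k_arr, l)
    key = (n, round(zeta, 12), l, token)
    hit = _RADIAL_CACHE.get(key)
    if hit is None:
        if len(_RADIAL_CACHE) > 4096:
            _RADIAL_CACHE.clear()
        hit = _RADIAL_CACHE[key] = slater_bessel(n, zeta, k_arr, l)
    return hit


def slater_bessel(n: int, zeta: float, k_arr, l: int) -> np.ndarray:
    """I = integral_0^inf r^n exp(-zeta r) j_l(K r) dr, vectorized over K.

    Requires n >= l + 1 (true for all radial functions used here).  Units:
    zeta in A^-1, K in A^-1, result in A^(n+1).
    """
    k_arr = np.atleast_1d(np.asarray(k_arr, dtype=float))
    if n < l + 1:
        raise ConfigurationError(f"slater_bessel requires n >= l+1 (n={n}, l={l})")
    out = np.empty_like(k_arr)
    small = k_arr < 0.5 * zeta
    if np.any(small):
        ks = k_arr[small]
        acc = np.zeros_like(ks)
        for j in range(60):
            num = math.factorial(n + 2 * j + l)
            den = (2.0 ** j) * math.factorial(j) * _double_factorial(2 * l + 2 * j + 1)
            term = ((-1.0) ** j) * ks ** (2 * j + l) * num / (den * zeta ** (n + 2 * j + l + 1))
            acc += term
            if float(np.max(np.abs(term))) <= 1e-17 * (float(np.max(np.abs(acc))) + 1e-300):
                break
        out[small] = acc
    if np.any(~small):
        kb = k_arr[~small]
        z = zeta - 1j * kb
        s_coef, c_coef = _bessel_sincos_coeffs(l)
        acc = np.zeros_like(kb)
        for k, v in s_coef.items():
            a = math.factorial(n - k) / z ** (n - k + 1)
            acc += float(v) * a.imag / kb ** k
        for k, v in c_coef.items():
            a = math.factorial(n - k) / z ** (n - k + 1)
            acc += float(v) * a.real / kb ** k
        out[~small] = acc
    return out


@lru_cache(maxsize=None)
def _double_factorial(n: int) -> int:
    return 1 if n <= 1 else n * _double_factorial(n - 2)


class AtomFormFactor:
    """Fourier transform of one pseudoatom's multipole density.

    Terms mirror the real-space model: each is c r^(m+l) exp(-a r) y_lm and
    transforms to 4 pi i^l c I(m+l+2, a, K, l) y_lm(h-hat).
    """

    def __init__(self, element, mult: AtomMultipoles):
        el = get_element(element) if isinstance(element, str) else element
        self.element = el
        self.mult = mult
        self.sph = []  # (c, p, alpha): c r^p exp(-alpha r) / (4 pi already folded)
        for w, p, alpha in el.density_terms("core"):
            self.sph.append((mult.pc * w * alpha ** (p + 3) / (4 * np.pi * math.factorial(p + 2)), p, alpha))
        k = mult.kappa
        for w, p, alpha in el.density_terms("valence"):
            self.sph.append((mult.pv * w * (alpha * k) ** (p + 3) / (4 * np.pi * math.factorial(p + 2)), p, alpha * k))
        kp = mult.kappa_prime
        self.asph = []  # (plm, c_unit, n_l, alpha, l, m, poly)
        for l in range(1, mult.lmax + 1):
            n_l, zeta, norm = deformation_radial(el, mult, l)
            for mm in range(-l, l + 1):
                c_unit = kp ** (n_l + 3) * norm / harmonics.density_norm_constant(l, mm)
                self.asph.append(
                    (mult.get_plm(l, mm), c_unit, n_l, zeta * kp, l, mm,
                     harmonics.solid_harmonic(l, mm))
                )

    def spherical(self, k_arr: np.ndarray, token=None) -> np.ndarray:
        """Spherical (core + valence) part; real, function of |h| only."""
        out = np.zeros_like(np.atleast_1d(k_arr), dtype=float)
        for c, p, alpha in self.sph:
            out += 4 * np.pi * c * _transform(p + 2, alpha, k_arr, 0, token)
        return out

    def valence_unit(self, k_arr: np.ndarray, token=None) -> np.ndarray:
        """d f / d Pv: the kappa-scaled unit valence transform."""
        out = np.zeros_like(np.atleast_1d(k_arr), dtype=float)
        k = self.mult.kappa
        for w, p, alpha in self.element.density_terms("valence"):
            c = w * (alpha * k) ** (p + 3) / (4 * np.pi * math.factorial(p + 2))
            out += 4 * np.pi * c * _transform(p + 2, alpha * k, k_arr, 0, token)
        return out

    def deformation_basis(self, k_arr: np.ndarray, units: np.ndarray,
                          token=None) -> dict:
        """d f / d P_lm for every (l, m) up to lmax, as complex arrays."""
        vals = harmonics.eval_polys([t[6] for t in self.asph], units)
        out = {}
        for (_plm, c_unit, n_l, alpha, l, mm, _poly), pv in zip(self.asph, vals):
            radial = _transform(n_l + 2, alpha, k_arr, l, token)
            out[(l, mm)] = (4 * np.pi * (1j ** l)) * c_unit * radial * pv
        return out

    def deformation(self, k_arr: np.ndarray, units: np.ndarray,
                    token=None) -> np.ndarray:
        """Aspherical part of f at scattering vectors with unit directions
        `units` expressed in the atom's local frame."""
        active = [t for t in self.asph if t[0] != 0.0]
        out = np.zeros(len(np.atleast_1d(k_arr)), dtype=complex)
        if not active:
            return out
        vals = harmonics.eval_polys([t[6] for t in active], units)
        for (plm, c_unit, n_l, alpha, l, mm, _poly), pv in zip(active, vals):
            radial = _transform(n_l + 2, alpha, k_arr, l, token)
            out += (4 * np.pi * (1j ** l)) * plm * c_unit * radial * pv
        return out

    def __call__(self, k_arr: np.ndarray, units: np.ndarray) -> np.ndarray:
        return self.spherical(k_arr) + self.deformation(k_arr, units)


def aspherical_form_factor(element, mult: AtomMultipoles, svec) -> np.ndarray:
    """Complex form factor (electrons) at Cartesian scattering vectors (A^-1),
    directions taken in the atom's local frame."""
    svec = np.atleast_2d(np.asarray(svec, dtype=float))
    s = np.linalg.norm(svec, axis=1)
    units = np.zeros_like(svec)
    nz = s > 0
    units[nz] = svec[nz] / s[nz, None]
    ff = AtomFormFactor(element, mult)
    return ff.spherical(2 * np.pi * s) + ff.deformation(2 * np.pi * s, units)


def debye_waller(cell: UnitCell, hkl, u_cif=None, uiso=None):
    """Attenuation T = exp(-2 pi^2 sum U^ij h_i h_j a*_i a*_j) in (0, 1].

    Returns (T, psd_ok): a non-positive-semidefinite U yields a flag rather
    than an exception so a refinement can pass through transient states.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    rl = cell.reciprocal_lengths
    if u_cif is not None:
        u11, u22, u33, u12, u13, u23 = np.asarray(u_cif, dtype=float)
        hs = h * rl
        expo = (u11 * hs[:, 0] ** 2 + u22 * hs[:, 1] ** 2 + u33 * hs[:, 2] ** 2
                + 2 * u12 * hs[:, 0] * hs[:, 1] + 2 * u13 * hs[:, 0] * hs[:, 2]
                + 2 * u23 * hs[:, 1] * hs[:, 2])
        m = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
        psd_ok = bool(np.all(np.linalg.eigvalsh(m) >= -1e-12))
    else:
        q2 = np.einsum("ni,ij,nj->n", h, cell.reciprocal_metric, h)
        expo = float(uiso) * q2
        psd_ok = uiso >= 0
    return np.exp(-2 * np.pi ** 2 * expo), psd_ok


class SFCalculator:
    """Vectorized structure factors with analytic parameter derivatives.

    model='multipole' uses the supplied multipole parameters; model='iam'
    substitutes neutral spherical atoms (kappa = 1, all P_lm = 0).
    `static=True` drops the Debye-Waller factors (theoretical static
    structure factors); dispersion adds the tabulated Mo K-alpha f', f''.
    """

    def __init__(self, structure: CrystalStructure, mmps: MultipoleParameterSet | None = None,
                 model: str = "multipole", dispersion: bool = True):
        if model not in ("multipole", "iam"):
            raise ConfigurationError(f"unknown model {model!r}")
        if model == "multipole" and mmps is None:
            raise ConfigurationError("multipole model requires parameters")
        self.structure = structure
        self.model = model
        self.dispersion = dispersion
        self.mmps = MultipoleParameterSet.neutral(structure) if model == "iam" else mmps
        cell = structure.cell
        self.cell = cell
        a = cell.frac_to_cart
        self.bstar = cell.reciprocal_basis
        self.frames = structure.local_frames()
        self.ff = {}
        for s in structure.sites:
            mult = self.mmps[s.label]
            if model == "iam":
                mult = mult.copy()
                mult.plm = {}
                mult.kappa = mult.kappa_prime = 1.0
            self.ff[s.label] = AtomFormFactor(s.element, mult)
        self.rot_cart = [a @ op.rot_array @ np.linalg.inv(a) for op in structure.ops]

    # -- geometry-dependent pieces -------------------------------------------------
    def _prep(self, hkl: np.ndarray):
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        ops = self.structure.ops
        hp = [hkl @ op.rot_array for op in ops]  # h' = R^T h
        q0 = hp[0] @ self.bstar.T
        s = np.linalg.norm(q0, axis=1)
        safe = np.maximum(s, 1e-300)  # at h = 000 the aspherical terms vanish
        units = []
        for o in range(len(ops)):
            q = hp[o] @ self.bstar.T
            units.append(q / safe[:, None])
        op_phase = [np.exp(2j * np.pi * (hkl @ op.tran_array)) for op in ops]
        token = hash(hkl.tobytes())
        return hkl, hp, s, units, op_phase, token

    def atom_contribution(self, label: str, hkl, static: bool = False,
                          derivs: tuple = (), prep=None):
        """One atom's symmetry-summed contribution to F and its derivatives.

        derivs may contain 'xyz', 'adp', 'pv', 'plm'.  Returns (contrib, d)
        where d maps 'xyz' -> (N,3), 'adp' -> (N,6) or (N,1) for Uiso,
        'pv' -> (N,), 'plm' -> dict[(l,m)] -> (N,).
        """
        hkl, hp, s, units, op_phase, token = prep or self._prep(hkl)
        site = self.structure.site(label)
        ff = self.ff[label]
        k_arr = 2 * np.pi * s
        f_sph = ff.spherical(k_arr, token)
        if self.dispersion:
            el = get_element(site.element)
            f_sph = f_sph + el.f_prime + 1j * el.f_double_prime
        want_pv = "pv" in derivs
        want_plm = "plm" in derivs and self.model == "multipole"
        fval_unit = ff.valence_unit(k_arr, token) if want_pv else None
        n = len(hkl)
        contrib = np.zeros(n, dtype=complex)
        d = {}
        if "xyz" in derivs:
            d["xyz"] = np.zeros((n, 3), dtype=complex)
        if "adp" in derivs:
            d["adp"] = np.zeros((n, 6 if site.is_anisotropic else 1), dtype=complex)
        if want_pv:
            d["pv"] = np.zeros(n, dtype=complex)
        if want_plm:
            d["plm"] = {key: np.zeros(n, dtype=complex) for key in
                        [(t[4], t[5]) for t in ff.asph]}
        rl = self.cell.reciprocal_lengths
        frame = self.frames[label]
        for o, op in enumerate(self.structure.ops):
            # equivalent-reflection formulation: the image rotation is already
            # absorbed into h' = R^T h, so the direction in the atom's local
            # frame is simply unit(q(h')) projected onto the original frame
            w = units[o] @ frame
            basis = None
            if want_plm:
                basis = ff.deformation_basis(k_arr, w, token)
                f_def = np.zeros(len(k_arr), dtype=complex)
                for (l, mm), b in basis.items():
                    p_lm = ff.mult.get_plm(l, mm)
                    if p_lm != 0.0:
                        f_def += p_lm * b
            elif self.model == "multipole":
                f_def = ff.deformation(k_arr, w, token)
            else:
                f_def = 0.0
            f = f_sph + f_def
            if static:
                t_fac = np.ones(n)
            elif site.is_anisotropic:
                t_fac, _ = debye_waller(self.cell, hp[o], u_cif=site.u_cif)
            else:
                t_fac, _ = debye_waller(self.cell, hp[o], uiso=site.uiso or 0.0)
            phase = np.exp(2j * np.pi * (hp[o] @ site.xyz)) * op_phase[o]
            base = site.occupancy * f * t_fac * phase
            contrib += base
            if "xyz" in derivs:
                d["xyz"] += base[:, None] * (2j * np.pi * hp[o])
            if "adp" in derivs and not static:
                hs = hp[o] * rl
                if site.is_anisotropic:
                    blocks = np.stack(
                        [hs[:, 0] ** 2, hs[:, 1] ** 2, hs[:, 2] ** 2,
                         2 * hs[:, 0] * hs[:, 1], 2 * hs[:, 0] * hs[:, 2],
                         2 * hs[:, 1] * hs[:, 2]], axis=1)
                else:
                    blocks = (s ** 2)[:, None]
                d["adp"] += base[:, None] * (-2 * np.pi ** 2) * blocks
            if want_pv:
                d["pv"] += site.occupancy * fval_unit * t_fac * phase
            if want_plm:
                for key, val in basis.items():
                    d["plm"][key] += site.occupancy * val * t_fac * phase
        return contrib, d

    def compute(self, hkl, static: bool = False, derivs: tuple = (),
                labels: list | None = None):
        """F(h) for all reflections; optionally per-atom derivative blocks."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        prep = self._prep(hkl)
        f_total = np.zeros(len(hkl), dtype=complex)
        all_d = {}
        for site in self.structure.sites:
            want = derivs if (labels is None or site.label in labels) else ()
            contrib, d = self.atom_contribution(site.label, hkl, static=static,
                                                derivs=want, prep=prep)
            f_total += contrib
            if d:
                all_d[site.label] = d
        if derivs:
            return f_total, all_d
        return f_total


def structure_factor(structure: CrystalStructure, mmps: MultipoleParameterSet | None,
                     hkl, model: str = "multipole", dispersion: bool = True,
                     static: bool = False) -> np.ndarray:
    """Convenience wrapper: complex F(h) for a reflection list."""
    return SFCalculator(structure, mmps, model=model, dispersion=dispersion).compute(
        hkl, static=static)


@dataclass
class ReflectionSet:
    """Indexed reflections with observed intensities and/or model amplitudes."""

    hkl: np.ndarray
    fo2: np.ndarray | None = None
    sigma: np.ndarray | None = None
    fc: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        if self.fo2 is not None:
            self.fo2 = np.asarray(self.fo2, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise DataError("sigma(Fo^2) must be positive for observed rows")
        if self.fc is not None:
            self.fc = np.asarray(self.fc, dtype=complex)
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise DataError("duplicate hkl rows; merge before constructing the set")

    def __len__(self):
        return len(self.hkl)

    def d(self, cell: UnitCell) -> np.ndarray:
        return cell.d_spacing(self.hkl)

    def to_frame(self, cell: UnitCell | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.hkl, columns=["h", "k", "l"])
        if self.fo2 is not None:
            df["Fo2"] = self.fo2
        if self.sigma is not None:
            df["sig"] = self.sigma
        if self.fc is not None:
            df["Fc_re"] = self.fc.real
            df["Fc_im"] = self.fc.imag
        if cell is not None:
            df["d"] = self.d(cell)
        return df

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl.copy(),
            fo2=None if self.fo2 is None else self.fo2.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
            fc=None if self.fc is None else self.fc.copy(),
        )


def generate_reflection_set(cell: UnitCell, ops, d_min: float,
                            friedel: bool = True, cap: int = 2_000_000) -> np.ndarray:
    """Unique hkl with d >= d_min: one representative per symmetry (and
    optionally Friedel) orbit, origin excluded."""
    if d_min <= 0:
        raise DataError("d_min must be positive")
    hmax = np.array([int(np.floor(L / d_min)) for L in (cell.a, cell.b, cell.c)])
    if np.prod(2 * hmax + 1) > cap:
        raise ReflectionSetTooLarge(
            f"reflection list would exceed cap={cap}; raise the cap explicitly")
    axes = [np.arange(-m, m + 1) for m in hmax]
    h = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    h = h[np.any(h != 0, axis=1)]
    q2 = np.einsum("ni,ij,nj->n", h, cell.reciprocal_metric, h)
    h = h[q2 <= 1.0 / d_min ** 2 + 1e-12]
    images = [h @ op.rot_array for op in ops]
    if friedel:
        images += [-im for im in images]
    stacked = np.stack(images, axis=1)  # (N, n_img, 3)
    base = 2 * int(hmax.max()) + 3
    score = ((stacked[:, :, 0] * base) + stacked[:, :, 1]) * base + stacked[:, :, 2]
    pick = np.argmax(score, axis=1)
    canon = stacked[np.arange(len(h)), pick]
    return np.unique(canon, axis=0)
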