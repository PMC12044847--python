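"""Real spherical harmonics for multipole densities.

Two normalizations are needed:

* wavefunction-normalized real harmonics y_lm with the usual orthonormality
  over the sphere (used internally and for Fourier-Bessel algebra);
* density-normalized functions d_lm = y_lm / D_lm with
  integral |d_lm| dOmega = 2 for l >= 1 and integral d_00 dOmega = 1, so a
  multipole population P_lm = 1 transfers one electron between the positive
  and negative lobes.

All evaluation goes through regular solid harmonics Q_lm(r) = y_lm(r-hat) r^l,
which are homogeneous polynomials in (x, y, z).  Their monomial coefficients
are obtained once, at import, by exact least-squares projection of the scipy
harmonics onto the degree-l monomial basis; derivatives are then plain
polynomial calculus, valid everywhere including the z axis.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "LMAX",
    "lm_list",
    "solid_harmonic",
    "eval_real_sph",
    "eval_density_normalized",
    "density_norm_constant",
    "Polynomial3",
    "eval_polys",
]

LMAX = 4


def lm_list(lmax: int, lmin: int = 0):
    """Ordered (l, m) pairs; m < 0 are the sine-type real harmonics."""
    return [(l, m) for l in range(lmin, lmax + 1) for m in range(-l, l + 1)]


def _real_sph_direct(l: int, m: int, theta, phi):
    """Orthonormal real spherical harmonic via scipy complex harmonics."""
    if m == 0:
        return np.real(special.sph_harm_y(l, 0, theta, phi))
    ylm = special.sph_harm_y(l, abs(m), theta, phi)
    fac = np.sqrt(2.0) * (-1.0) ** abs(m)
    return fac * (np.real(ylm) if m > 0 else np.imag(ylm))


class Polynomial3:
    """Sparse polynomial in three variables: sum_k c_k x^i y^j z^k."""

    def __init__(self, exponents: np.ndarray, coeffs: np.ndarray):
        self.exponents = np.asarray(exponents, dtype=int).reshape(-1, 3)
        self.coeffs = np.asarray(coeffs, dtype=float)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = np.zeros(pts.shape[0])
        for (i, j, k), c in zip(self.exponents, self.coeffs):
            if c != 0.0:
                out += c * pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k
        return out

    def diff(self, axis: int) -> "Polynomial3":
        exps = self.exponents.copy()
        coeffs = self.coeffs * exps[:, axis]
        exps[:, axis] = np.maximum(exps[:, axis] - 1, 0)
        keep = coeffs != 0.0
        if not np.any(keep):
            return Polynomial3(np.zeros((1, 3), dtype=int), np.zeros(1))
        return Polynomial3(exps[keep], coeffs[keep])


def eval_polys(polys, pts: np.ndarray) -> list:
    """Evaluate several sparse polynomials at the same points, sharing the
    monomial values (the solid harmonics up to l=4 reuse ~30 monomials)."""
    pts = np.atleast_2d(pts)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    cache = {}

    def monomial(i, j, k):
        key = (i, j, k)
        if key not in cache:
            v = None
            for base, e in ((x, i), (y, j), (z, k)):
                if e:
                    t = base if e == 1 else base ** e
                    v = t if v is None else v * t
            cache[key] = np.ones(len(pts)) if v is None else v
        return cache[key]

    out = []
    for p in polys:
        acc = np.zeros(len(pts))
        for (i, j, k), c in zip(p.exponents, p.coeffs):
            if c != 0.0:
                acc += c * monomial(i, j, k)
        out.append(acc)
    return out


def _monomial_exponents(l: int) -> np.ndarray:
    return np.array(
        [(i, j, l - i - j) for i in range(l + 1) for j in range(l - i + 1)], dtype=int
    )


@lru_cache(maxsize=None)
def solid_harmonic(l: int, m: int) -> Polynomial3:
    """Regular real solid harmonic y_lm(r-hat) * r^l as an exact polynomial."""
    exps = _monomial_exponents(l)
    rng = np.random.default_rng(20240917)
    npts = max(4 * len(exps), 64)
    v = rng.normal(size=(npts, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    target = _real_sph_direct(l, m, theta, phi)
    basis = np.stack(
        [v[:, 0] ** i * v[:, 1] ** j * v[:, 2] ** k for i, j, k in exps], axis=1
    )
    coeffs, *_ = np.linalg.lstsq(basis, target, rcond=None)
    coeffs[np.abs(coeffs) < 1e-12] = 0.0
    return Polynomial3(exps, coeffs)


def _theta_part(l: int, m: int):
    """y_lm = g(cos theta) * {cos|m|phi, sin|m|phi, 1}; returns g."""
    am = abs(m)
    norm = np.sqrt(
        (2 * l + 1) / (4 * np.pi) * special.gamma(l - am + 1) / special.gamma(l + am + 1)
    )
    if m != 0:
        norm *= np.sqrt(2.0) * (-1.0) ** am

    def g(c):
        return norm * special.lpmv(am, l, c)

    return g


@lru_cache(maxsize=None)
def density_norm_constant(l: int, m: int) -> float:
    """D_lm with d_lm = y_lm / D_lm density-normalized.

    For l >= 1, D_lm = (1/2) integral |y_lm| dOmega; for l = 0,
    D_00 = integral y_00 dOmega = sqrt(4 pi) so that d_00 = 1/(4 pi).
    """
    if l == 0:
        return float(np.sqrt(4.0 * np.pi))
    g = _theta_part(l, m)
    # locate sign changes of the theta part, then integrate |g| piecewise
    cs = np.linspace(-1.0, 1.0, 2001)
    vals = g(cs)
    roots = []
    for i in range(len(cs) - 1):
        if vals[i] == 0.0:
            roots.append(cs[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(optimize.brentq(g, cs[i], cs[i + 1]))
    pts = sorted(set([-1.0] + [float(r) for r in roots] + [1.0]))
    theta_int = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(lambda c: abs(g(c)), a, b, limit=200)
        theta_int += val
    am = abs(m)
    phi_int = 2.0 * np.pi if am == 0 else 4.0
    return 0.5 * theta_int * phi_int


def eval_real_sph(l: int, m: int, unit_vectors: np.ndarray) -> np.ndarray:
    """Orthonormal real harmonic at unit direction vectors, shape (N, 3)."""
    return solid_harmonic(l, m)(unit_vectors)


def eval_density_normalized(l: int, m: int, unit_vectors: np.ndarray) -> np.ndarray:
    return eval_real_sph(l, m, unit_vectors) / density_norm_constant(l, m)
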