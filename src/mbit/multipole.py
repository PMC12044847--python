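"""Hansen-Coppens multipole model densities in real space.

An atom's charge density is

    rho(r) = Pc rho_core(r) + Pv kappa^3 rho_val(kappa r)
             + sum_{l=1}^{lmax} kappa'^3 R_l(kappa' r)
               sum_m P_lm d_lm(theta, phi)

with the angles taken in the atom's local Cartesian frame, R_l normalized
Slater functions and d_lm density-normalized real spherical harmonics.  The
core and valence spherical densities are built from the same Slater shell
model (see :mod:`mbit.elements`): rho_core integrates to the number of core
electrons times Pc/Pc... more precisely both rho_core and rho_val are unit
normalized, so the atom integrates to Pc + Pv electrons (the l >= 1 terms
carry no net charge).

Every term is of the form c * r^m * exp(-a r) * Q(u) with Q a homogeneous
solid-harmonic polynomial of the local coordinates u, which makes analytic
gradients and Hessians straightforward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import harmonics
from .cells import CrystalStructure
from .elements import BOHR, ElementData, get_element
from .errors import ConfigurationError

__all__ = [
    "AtomMultipoles",
    "MultipoleParameterSet",
    "AtomDensity",
    "CrystalDensity",
    "eval_atom_density",
    "density_on_grid",
]

KAPPA_GUARD = (0.5, 2.0)


@dataclass
class AtomMultipoles:
    """Multipole parameters of one pseudoatom (populations in electrons)."""

    pc: float
    pv: float
    kappa: float = 1.0
    kappa_prime: float = 1.0
    lmax: int = 3
    plm: dict = field(default_factory=dict)
    def_zeta: float | None = None  # deformation exponent override, bohr^-1
    n_l: tuple | None = None  # deformation radial powers override

    def __post_init__(self):
        self.pc = float(self.pc)
        self.pv = float(self.pv)
        self.kappa = float(self.kappa)
        self.kappa_prime = float(self.kappa_prime)
        if self.lmax > harmonics.LMAX:
            raise ConfigurationError(f"lmax {self.lmax} exceeds supported {harmonics.LMAX}")
        self.check_guards()

    def check_guards(self):
        for name, k in (("kappa", self.kappa), ("kappa_prime", self.kappa_prime)):
            if not KAPPA_GUARD[0] <= k <= KAPPA_GUARD[1]:
                raise ConfigurationError(
                    f"{name}={k} outside guard range {KAPPA_GUARD}"
                )

    def get_plm(self, l: int, m: int) -> float:
        return float(self.plm.get((l, m), 0.0))

    def copy(self) -> "AtomMultipoles":
        return AtomMultipoles(
            pc=self.pc, pv=self.pv, kappa=self.kappa, kappa_prime=self.kappa_prime,
            lmax=self.lmax, plm=dict(self.plm), def_zeta=self.def_zeta, n_l=self.n_l,
        )


class MultipoleParameterSet:
    """Per-atom multipole parameters keyed by atom label."""

    def __init__(self, atoms: dict):
        self.atoms = atoms

    def __getitem__(self, label: str) -> AtomMultipoles:
        return self.atoms[label]

    def __contains__(self, label):
        return label in self.atoms

    def labels(self):
        return list(self.atoms)

    def copy(self) -> "MultipoleParameterSet":
        return MultipoleParameterSet({k: v.copy() for k, v in self.atoms.items()})

    @classmethod
    def neutral(cls, structure: CrystalStructure, lmax_heavy: int = 3,
                lmax_h: int = 1) -> "MultipoleParameterSet":
        """Spherical neutral-atom start: Pv = valence electron count, all
        P_lm = 0, kappa = kappa' = 1.  The lmax defaults follow common
        multipole practice: octupoles on non-hydrogen atoms, a bond-directed
        dipole level on hydrogen."""
        atoms = {}
        for s in structure.sites:
            el = get_element(s.element)
            lmax = lmax_h if s.element == "H" else lmax_heavy
            atoms[s.label] = AtomMultipoles(pc=el.n_core, pv=el.n_valence, lmax=lmax)
        return cls(atoms)

    def electron_count(self, structure: CrystalStructure) -> float:
        """F(000): electrons per unit cell implied by the populations."""
        images = structure.expand_to_p1()
        total = 0.0
        for i, _k, _x, _u in images:
            s = structure.sites[i]
            m = self.atoms[s.label]
            total += s.occupancy * (m.pc + m.pv)
        return total

    def to_dict(self) -> dict:
        out = {}
        for label, m in self.atoms.items():
            entry = {
                "Pc": m.pc, "Pv": m.pv, "kappa": m.kappa,
                "kappa_prime": m.kappa_prime, "lmax": m.lmax,
                "Plm": {f"{l},{mm}": v for (l, mm), v in sorted(m.plm.items()) if v != 0.0},
            }
            if m.def_zeta is not None:
                entry["def_zeta"] = m.def_zeta
            if m.n_l is not None:
                entry["n_l"] = list(m.n_l)
            out[label] = entry
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MultipoleParameterSet":
        atoms = {}
        for label, e in d.items():
            plm = {}
            for key, v in e.get("Plm", {}).items():
                l, mm = (int(t) for t in key.split(","))
                plm[(l, mm)] = float(v)
            atoms[label] = AtomMultipoles(
                pc=float(e["Pc"]), pv=float(e["Pv"]), kappa=float(e["kappa"]),
                kappa_prime=float(e["kappa_prime"]), lmax=int(e["lmax"]), plm=plm,
                def_zeta=e.get("def_zeta"), n_l=None if "n_l" not in e else tuple(e["n_l"]),
            )
        return cls(atoms)


def _slater_norm(n: int, zeta: float) -> float:
    """Normalization N of R(r) = N r^n exp(-zeta r) with int R r^2 dr = 1."""
    return zeta ** (n + 3) / math.factorial(n + 2)


def deformation_radial(element: ElementData, mult: AtomMultipoles, l: int):
    """(n_l, zeta in A^-1, norm) of the deformation radial for order l."""
    n_l = (mult.n_l or element.n_l)[l - 1]
    zeta = (mult.def_zeta or element.def_zeta) / BOHR
    return n_l, zeta, _slater_norm(n_l, zeta)


class AtomDensity:
    """One pseudoatom's density and derivatives in its local frame."""

    def __init__(self, element: ElementData, mult: AtomMultipoles):
        self.element = element
        self.mult = mult
        sph = []  # (c, m, alpha)
        for w, p, alpha in element.density_terms("core"):
            sph.append((mult.pc * w * alpha ** (p + 3) / (4 * np.pi * math.factorial(p + 2)), p, alpha))
        k = mult.kappa
        for w, p, alpha in element.density_terms("valence"):
            sph.append((mult.pv * w * (alpha * k) ** (p + 3) / (4 * np.pi * math.factorial(p + 2)), p, alpha * k))
        self.sph = [t for t in sph if t[0] != 0.0]
        kp = mult.kappa_prime
        self.asph = []  # (c, m_pow, alpha, poly, dpolys, ddpolys)
        for l in range(1, mult.lmax + 1):
            n_l, zeta, norm = deformation_radial(element, mult, l)
            for mm in range(-l, l + 1):
                p_lm = mult.get_plm(l, mm)
                if p_lm == 0.0:
                    continue
                c = p_lm * kp ** (n_l + 3) * norm / harmonics.density_norm_constant(l, mm)
                poly = harmonics.solid_harmonic(l, mm)
                dpolys = [poly.diff(i) for i in range(3)]
                ddpolys = [[dpolys[i].diff(j) for j in range(3)] for i in range(3)]
                self.asph.append((c, n_l - l, zeta * kp, poly, dpolys, ddpolys))

    def density(self, u: np.ndarray) -> np.ndarray:
        """Density (e A^-3) at local Cartesian offsets u, shape (N, 3)."""
        u = np.atleast_2d(u)
        r = np.linalg.norm(u, axis=1)
        out = np.zeros(len(u))
        radial = {}
        for c, m, a in self.sph:
            key = (m, a)
            if key not in radial:
                radial[key] = r ** m * np.exp(-a * r)
            out += c * radial[key]
        for c, m, a, poly, _d, _dd in self.asph:
            key = (m, a)
            if key not in radial:
                radial[key] = r ** m * np.exp(-a * r)
            out += c * radial[key] * poly(u)
        return out

    def grad_hess(self, u: np.ndarray):
        """(rho, grad, hess) in local frame; units e A^-3, e A^-4, e A^-5."""
        u = np.atleast_2d(u)
        n = len(u)
        r = np.linalg.norm(u, axis=1)
        uhat = u / r[:, None]
        rho = np.zeros(n)
        grad = np.zeros((n, 3))
        hess = np.zeros((n, 3, 3))
        eye = np.eye(3)

        def add(c, m, a, q, dq, ddq):
            e = np.exp(-a * r)
            phi = c * r ** m * e
            dphi = c * e * (m * r ** (m - 1) - a * r ** m)
            ddphi = c * e * (m * (m - 1) * r ** (m - 2) - 2 * a * m * r ** (m - 1) + a * a * r ** m)
            rho_t = phi * q
            rho[:] += rho_t
            grad[:] += (dphi * q)[:, None] * uhat + phi[:, None] * dq
            coef = (ddphi - dphi / r) * q
            hess[:] += coef[:, None, None] * np.einsum("ni,nj->nij", uhat, uhat)
            hess[:] += ((dphi / r) * q)[:, None, None] * eye
            cross = np.einsum("ni,nj->nij", uhat, dq) * dphi[:, None, None]
            hess[:] += cross + cross.transpose(0, 2, 1)
            hess[:] += phi[:, None, None] * ddq

        zero3 = np.zeros((n, 3))
        zero33 = np.zeros((n, 3, 3))
        for c, m, a in self.sph:
            add(c, m, a, np.ones(n), zero3, zero33)
        for c, m, a, poly, dpolys, ddpolys in self.asph:
            q = poly(u)
            dq = np.stack([p(u) for p in dpolys], axis=1)
            ddq = np.empty((n, 3, 3))
            for i in range(3):
                for j in range(3):
                    ddq[:, i, j] = ddpolys[i][j](u)
            add(c, m, a, q, dq, ddq)
        return rho, grad, hess

    def split_core(self):
        """Two partial models sharing this atom's terms: (core-only, rest).

        The core terms are far sharper than the grid resolution used for
        maps, so the sampler integrates them on a finer subgrid.
        """
        core = object.__new__(AtomDensity)
        rest = object.__new__(AtomDensity)
        for part in (core, rest):
            part.element = self.element
            part.mult = self.mult
            part.asph = []
            part.sph = []
        n_core = len(self.element.density_terms("core"))
        core.sph = self.sph[:n_core]
        rest.sph = self.sph[n_core:]
        rest.asph = self.asph
        return core, rest

    def cutoff_radius(self, eps: float = 1e-9, rmax: float = 9.0) -> float:
        """Radius beyond which every term magnitude falls below eps."""
        rc = 0.5
        terms = [(c, m, a) for c, m, a in self.sph]
        # |Q| on the unit sphere is bounded by ~1.5 for the normalized harmonics
        terms += [(1.5 * c, m, a) for c, m, a, *_rest in self.asph]
        for c, m, a in terms:
            amp = abs(c)
            if amp == 0:
                continue
            r = 1.0
            while r < rmax and amp * r ** m * np.exp(-a * r) >= eps:
                r += 0.25
            rc = max(rc, r)
        return min(rc, rmax)


def eval_atom_density(element: str | ElementData, mult: AtomMultipoles,
                      points: np.ndarray, frame: np.ndarray | None = None,
                      center: np.ndarray | None = None) -> np.ndarray:
    """Density of a single pseudoatom at Cartesian points (A), in e A^-3.

    `frame` is the 3x3 local-axes matrix (columns = local x, y, z in global
    coordinates); `center` the nuclear position.  The density has a cusp at
    the nucleus; it is finite everywhere but the point r = 0 itself must be
    avoided.
    """
    el = get_element(element) if isinstance(element, str) else element
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if center is not None:
        pts = pts - np.asarray(center, dtype=float)
    if frame is not None:
        pts = pts @ frame  # u = M^T v
    return AtomDensity(el, mult).density(pts)


class CrystalDensity:
    """Periodic multipole density: symmetry- and lattice-summed pseudoatoms."""

    def __init__(self, structure: CrystalStructure, mmps: MultipoleParameterSet,
                 cutoff: float = 8.0):
        self.structure = structure
        self.mmps = mmps
        self.cutoff = cutoff
        cell = structure.cell
        a = cell.frac_to_cart
        frames = structure.local_frames()
        self.models = {}
        self.images = []  # (label, frac xyz, frame 3x3, occupancy)
        for i, k, x, _u6 in structure.expand_to_p1():
            s = structure.sites[i]
            if s.label not in self.models:
                self.models[s.label] = AtomDensity(get_element(s.element), mmps[s.label])
            rc_op = a @ structure.ops[k].rot_array @ np.linalg.inv(a)
            self.images.append((s.label, x, rc_op @ frames[s.label], s.occupancy))

    def _translated_centers(self, pts_cart: np.ndarray):
        """All (label, center_cart, frame, occ) lattice copies within cutoff of pts."""
        cell = self.structure.cell
        a = cell.frac_to_cart
        inv = cell.cart_to_frac
        f = pts_cart @ inv.T
        lo = np.floor(f.min(axis=0) - self.cutoff * cell.reciprocal_lengths) - 0
        hi = np.ceil(f.max(axis=0) + self.cutoff * cell.reciprocal_lengths)
        copies = []
        for label, x, frame, occ in self.images:
            for n1 in range(int(lo[0] - 1), int(hi[0] + 1)):
                for n2 in range(int(lo[1] - 1), int(hi[1] + 1)):
                    for n3 in range(int(lo[2] - 1), int(hi[2] + 1)):
                        xc = a @ (x + np.array([n1, n2, n3], dtype=float))
                        copies.append((label, xc, frame, occ))
        return copies

    def density(self, pts_cart: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_cart, dtype=float))
        out = np.zeros(len(pts))
        for label, xc, frame, occ in self._translated_centers(pts):
            v = pts - xc
            r = np.linalg.norm(v, axis=1)
            mask = r < self.cutoff
            if not np.any(mask):
                continue
            out[mask] += occ * self.models[label].density(v[mask] @ frame)
        return out

    def gradient_hessian(self, pts_cart: np.ndarray):
        """(rho, grad, hess) at Cartesian points; hess is symmetric, its trace
        is the Laplacian (e A^-5)."""
        pts = np.atleast_2d(np.asarray(pts_cart, dtype=float))
        n = len(pts)
        rho = np.zeros(n)
        grad = np.zeros((n, 3))
        hess = np.zeros((n, 3, 3))
        for label, xc, frame, occ in self._translated_centers(pts):
            v = pts - xc
            r = np.linalg.norm(v, axis=1)
            mask = r < self.cutoff
            if not np.any(mask):
                continue
            rr, gg, hh = self.models[label].grad_hess(v[mask] @ frame)
            rho[mask] += occ * rr
            grad[mask] += occ * gg @ frame.T
            hess[mask] += occ * np.einsum("ij,njk,lk->nil", frame, hh, frame)
        return rho, grad, hess

    def local_evaluator(self, center, margin: float = 1.5) -> "_LocalEvaluator":
        return _LocalEvaluator(self, center, margin)


class _LocalEvaluator:
    """Density evaluator with a frozen neighbour list, valid for points
    within `margin` of the reference centre (used by the critical-point
    search, which probes many nearby points)."""

    def __init__(self, parent: CrystalDensity, center: np.ndarray, margin: float):
        self.parent = parent
        ref = np.atleast_2d(np.asarray(center, dtype=float))
        pad = np.array([[-margin] * 3, [margin] * 3]) + ref
        self.copies = [
            (label, xc, frame, occ)
            for label, xc, frame, occ in parent._translated_centers(pad)
            if np.linalg.norm(xc - ref[0]) < parent.cutoff + margin
        ]

    def density(self, pts_cart):
        pts = np.atleast_2d(np.asarray(pts_cart, dtype=float))
        out = np.zeros(len(pts))
        for label, xc, frame, occ in self.copies:
            v = pts - xc
            out += occ * self.parent.models[label].density(v @ frame)
        return out

    def gradient_hessian(self, pts_cart):
        pts = np.atleast_2d(np.asarray(pts_cart, dtype=float))
        n = len(pts)
        rho = np.zeros(n)
        grad = np.zeros((n, 3))
        hess = np.zeros((n, 3, 3))
        for label, xc, frame, occ in self.copies:
            v = pts - xc
            rr, gg, hh = self.parent.models[label].grad_hess(v @ frame)
            rho += occ * rr
            grad += occ * gg @ frame.T
            hess += occ * np.einsum("ij,njk,lk->nil", frame, hh, frame)
        return rho, grad, hess


def density_on_grid(structure: CrystalStructure, mmps: MultipoleParameterSet,
                    shape: tuple, eps: float = 1e-8, subsample: int = 3) -> np.ndarray:
    """Model density sampled on a fractional grid over one unit cell.

    Per-atom cutoff radii are chosen so every truncated term is below `eps`
    e A^-3; lattice copies are summed explicitly, so the grid is exactly
    periodic.  The sharp core terms are point-sampled on a `subsample`-times
    finer shifted subgrid and decimated (an exact fold), which removes the
    aliasing a 1s core would otherwise leak into every Fourier coefficient
    of the sampled map.
    """
    cell = structure.cell
    a = cell.frac_to_cart
    n1, n2, n3 = shape
    grid = np.zeros(shape)
    frames = structure.local_frames()
    models = {}
    rls = cell.reciprocal_lengths
    grid_core = np.zeros(shape)
    for i, k, x, _u6 in structure.expand_to_p1():
        s = structure.sites[i]
        if s.label not in models:
            full = AtomDensity(get_element(s.element), mmps[s.label])
            models[s.label] = full.split_core()
        core, rest = models[s.label]
        rc_op = a @ structure.ops[k].rot_array @ np.linalg.inv(a)
        frame = rc_op @ frames[s.label]
        for model, target, ss in ((core, grid_core, subsample), (rest, grid, 1)):
            if not model.sph and not model.asph:
                continue
            rc = model.cutoff_radius(eps)
            marg = rc * rls
            spans = [range(int(np.floor(-marg[d] - x[d])),
                           int(np.ceil(1 + marg[d] - x[d])) + 1) for d in range(3)]
            for t1 in spans[0]:
                for t2 in spans[1]:
                    for t3 in spans[2]:
                        x0 = x + np.array([t1, t2, t3], dtype=float)
                        _accumulate(target, cell, x0, model, frame, rc,
                                    s.occupancy, ss)
    if subsample > 1 and np.any(grid_core):
        # the shifted-average fold low-passes the principal term by a
        # Dirichlet kernel per axis; deconvolve it exactly in Fourier space
        spec = np.fft.fftn(grid_core)
        for axis, n_ax in enumerate(shape):
            h = np.fft.fftfreq(n_ax) * n_ax  # signed integer frequencies
            d_axis = np.mean(
                [np.exp(2j * np.pi * h * o / (subsample * n_ax))
                 for o in range(subsample)], axis=0)
            sl = [None, None, None]
            sl[axis] = slice(None)
            spec /= d_axis[tuple(sl)]
        grid += np.real(np.fft.ifftn(spec))
    else:
        grid += grid_core
    return grid


def _accumulate(grid, cell, x0, model, frame, rc, occ, subsample: int = 1):
    n = np.array(grid.shape)
    marg = rc * cell.reciprocal_lengths
    idx = []
    for d in range(3):
        i0 = int(np.ceil((x0[d] - marg[d]) * n[d]))
        i1 = int(np.floor((x0[d] + marg[d]) * n[d]))
        if i1 - i0 + 1 >= n[d]:
            i0, i1 = 0, n[d] - 1
        if i1 < i0:
            return
        idx.append(np.arange(i0, i1 + 1))
    # box entirely outside the cell -> no overlap with grid representatives
    for d in range(3):
        if idx[d][-1] < 0 or idx[d][0] > n[d] - 1:
            return
        keep = (idx[d] >= 0) & (idx[d] <= n[d] - 1)
        idx[d] = idx[d][keep]
        if idx[d].size == 0:
            return
    a = cell.frac_to_cart
    dxs = [idx[d] / n[d] - x0[d] for d in range(3)]
    # Cartesian offsets by broadcasting the three cell axes
    vx = (dxs[0][:, None, None] * a[0, 0] + dxs[1][None, :, None] * a[0, 1]
          + dxs[2][None, None, :] * a[0, 2])
    vy = (dxs[0][:, None, None] * a[1, 0] + dxs[1][None, :, None] * a[1, 1]
          + dxs[2][None, None, :] * a[1, 2])
    vz = (dxs[0][:, None, None] * a[2, 0] + dxs[1][None, :, None] * a[2, 1]
          + dxs[2][None, None, :] * a[2, 2])
    r2 = vx * vx + vy * vy + vz * vz
    mask = r2 < rc * rc
    if not np.any(mask):
        return
    if subsample == 1:
        v = np.stack([vx[mask], vy[mask], vz[mask]], axis=1)
        vals = occ * model.density(v @ frame)
        sub = np.zeros(mask.shape)
        sub[mask] = vals
        grid[np.ix_(idx[0], idx[1], idx[2])] += sub
        return
    # shifted finer-grid sampling, folded back by averaging (exact decimation)
    sub = np.zeros(mask.shape)
    offsets = [a @ (np.array([o1, o2, o3]) / (subsample * n))
               for o1 in range(subsample) for o2 in range(subsample)
               for o3 in range(subsample)]
    base = np.stack([vx[mask], vy[mask], vz[mask]], axis=1)
    acc = np.zeros(int(mask.sum()))
    for off in offsets:
        acc += model.density((base + off) @ frame)
    sub[mask] = occ * acc / len(offsets)
    grid[np.ix_(idx[0], idx[1], idx[2])] += sub
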