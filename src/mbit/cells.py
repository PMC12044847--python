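"""Crystallographic geometry: unit cells, metric tensors, symmetry and ADP frames.

Conventions used throughout the package:

* fractional coordinates, wrapped to [0, 1);
* anisotropic displacement parameters stored as U^ij referred to the
  reciprocal basis (the CIF ``_atom_site_aniso_U`` / SHELXL convention),
  order (U11, U22, U33, U12, U13, U23) in A^2;
* the Debye-Waller exponent is 2 pi^2 sum_ij U^ij h_i h_j a*_i a*_j.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import gemmi
import numpy as np

from .errors import InvalidCellError, SymmetryError

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "LocalAxes",
    "AtomSite",
    "CrystalStructure",
    "u_cif_to_cart",
    "u_cart_to_cif",
    "u_equiv",
    "SPACE_GROUP_OPS",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit cell, lengths in Angstrom and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise InvalidCellError("degenerate cell: angle combination gives non-positive volume")

    @property
    def frac_to_cart(self) -> np.ndarray:
        """3x3 matrix A with basis vectors a, b, c as columns; x_cart = A @ x_frac."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def cart_to_frac(self) -> np.ndarray:
        return np.linalg.inv(self.frac_to_cart)

    @property
    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G = A^T A (A^2)."""
        a = self.frac_to_cart
        return a.T @ a

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric)))

    @property
    def reciprocal_basis(self) -> np.ndarray:
        """Columns are the reciprocal basis vectors a*, b*, c* in A^-1."""
        return np.linalg.inv(self.frac_to_cart).T

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        """(a*, b*, c*) lengths in A^-1."""
        return np.linalg.norm(self.reciprocal_basis, axis=0)

    def d_spacing(self, hkl) -> np.ndarray | float:
        """Resolution d = 1/|h*| in A for one or many integer reflections."""
        h = np.asarray(hkl, dtype=float)
        scalar = h.ndim == 1
        h = np.atleast_2d(h)
        if np.any(np.all(h == 0, axis=1)):
            raise InvalidCellError("d-spacing undefined for the (0,0,0) reflection")
        q2 = np.einsum("ni,ij,nj->n", h, self.reciprocal_metric, h)
        d = 1.0 / np.sqrt(q2)
        return float(d[0]) if scalar else d

    def scattering_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Cartesian reciprocal vectors q = B* h (A^-1), |q| = 1/d."""
        return np.atleast_2d(hkl) @ self.reciprocal_basis.T


def _frac_to_fraction(x: float) -> Fraction:
    return Fraction(round(float(x) * 24), 24)


@dataclass(frozen=True)
class SymmetryOp:
    """Symmetry operator x' = R x + t with integer rotation and fractional translation."""

    rot: tuple
    tran: tuple

    @classmethod
    def from_arrays(cls, rot, tran) -> "SymmetryOp":
        rot = np.asarray(rot, dtype=int)
        if round(abs(np.linalg.det(rot))) != 1:
            raise SymmetryError("rotation part must have determinant +/-1")
        t = tuple(_frac_to_fraction(x) % 1 for x in np.asarray(tran, dtype=float))
        return cls(rot=tuple(map(tuple, rot.tolist())), tran=t)

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        return cls.from_arrays(np.rint(rot).astype(int), tran)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls.from_arrays(np.eye(3, dtype=int), np.zeros(3))

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.tran])

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (self.rot_array @ np.asarray(xyz, dtype=float) + self.tran_array) % 1.0

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        r = self.rot_array @ other.rot_array
        t = self.rot_array @ other.tran_array + self.tran_array
        return SymmetryOp.from_arrays(r, t)

    def to_xyz(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(v) * gemmi.Op.DEN for v in row] for row in self.rot]
        op.tran = [int(round(float(t) * gemmi.Op.DEN)) for t in self.tran]
        return op.triplet()


#: Built-in operator lists for the symmetries exercised by the package.
SPACE_GROUP_OPS = {
    "P1": ["x,y,z"],
    "P-1": ["x,y,z", "-x,-y,-z"],
    "P21/c": ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"],
    "P212121": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
}


@dataclass
class LocalAxes:
    """Atom-local Cartesian frame: z toward `ref_z`, x in the plane of `ref_x`."""

    ref_z: str
    ref_x: str


@dataclass
class AtomSite:
    label: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    uiso: float | None = None
    u_cif: np.ndarray | None = None  # (U11, U22, U33, U12, U13, U23)
    local_axes: LocalAxes | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float) % 1.0
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        if self.u_cif is not None:
            self.u_cif = np.asarray(self.u_cif, dtype=float)

    @property
    def is_anisotropic(self) -> bool:
        return self.u_cif is not None

    def copy(self) -> "AtomSite":
        return AtomSite(
            label=self.label,
            element=self.element,
            xyz=self.xyz.copy(),
            occupancy=self.occupancy,
            uiso=self.uiso,
            u_cif=None if self.u_cif is None else self.u_cif.copy(),
            local_axes=None if self.local_axes is None else dataclasses.replace(self.local_axes),
        )


def _u6_to_mat(u6: np.ndarray) -> np.ndarray:
    u11, u22, u33, u12, u13, u23 = u6
    return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])


def _mat_to_u6(m: np.ndarray) -> np.ndarray:
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


def u_cif_to_cart(cell: UnitCell, u6: np.ndarray) -> np.ndarray:
    """CIF U^ij (reciprocal-basis referred) -> Cartesian displacement tensor (A^2)."""
    n = np.diag(cell.reciprocal_lengths)
    a = cell.frac_to_cart
    return a @ n @ _u6_to_mat(u6) @ n @ a.T


def u_cart_to_cif(cell: UnitCell, u_cart: np.ndarray) -> np.ndarray:
    n_inv = np.diag(1.0 / cell.reciprocal_lengths)
    a_inv = cell.cart_to_frac
    return _mat_to_u6(n_inv @ a_inv @ u_cart @ a_inv.T @ n_inv)


def u_equiv(cell: UnitCell, u6: np.ndarray) -> float:
    """Equivalent isotropic U: one third of the trace of the Cartesian tensor."""
    return float(np.trace(u_cif_to_cart(cell, u6)) / 3.0)


@dataclass
class CrystalStructure:
    cell: UnitCell
    ops: list
    sites: list
    name: str = ""

    def __post_init__(self):
        if not self.ops:
            self.ops = [SymmetryOp.identity()]
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise ValueError("atom labels must be unique")

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            ops=list(self.ops),
            sites=[s.copy() for s in self.sites],
            name=self.name,
        )

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def check_ops_closed(self) -> None:
        keyed = {(op.rot, op.tran) for op in self.ops}
        for op1 in self.ops:
            for op2 in self.ops:
                c = op1.compose(op2)
                if (c.rot, c.tran) not in keyed:
                    raise SymmetryError(
                        f"operator set not closed: {op1.to_xyz()} o {op2.to_xyz()}"
                    )

    def coordinates_cart(self) -> np.ndarray:
        a = self.cell.frac_to_cart
        return np.array([a @ s.xyz for s in self.sites])

    def expand_to_p1(self, merge_tol: float = 1e-4):
        """All symmetry images of the asymmetric unit.

        Returns a list of (site_index, op_index, xyz_frac, u_cif or None) tuples with
        duplicate images (special positions) merged at `merge_tol` fractional distance.
        """
        self.check_ops_closed()
        a = self.cell.frac_to_cart
        out = []
        for i, s in enumerate(self.sites):
            seen = []
            for k, op in enumerate(self.ops):
                x = op.apply(s.xyz)
                dup = False
                for xs in seen:
                    d = x - xs
                    d -= np.rint(d)
                    if np.linalg.norm(d) < merge_tol:
                        dup = True
                        break
                if dup:
                    continue
                seen.append(x)
                if s.u_cif is not None:
                    rc = a @ op.rot_array @ np.linalg.inv(a)
                    uc = u_cif_to_cart(self.cell, s.u_cif)
                    u6 = u_cart_to_cif(self.cell, rc @ uc @ rc.T)
                else:
                    u6 = None
                out.append((i, k, x, u6))
        return out

    def local_frames(self) -> dict:
        """Right-handed Cartesian frame per atom from its local-axes references.

        z points toward the `ref_z` neighbour; x lies in the (ref_z, ref_x) plane.
        Atoms without axes get the identity frame (a spherical atom does not
        need one).
        """
        a = self.cell.frac_to_cart
        pos = {s.label: s.xyz for s in self.sites}

        def mi_vector(frm, to):
            d = pos[to] - pos[frm]
            d -= np.rint(d)  # minimum-image: reference the nearest copy
            return a @ d

        frames = {}
        for s in self.sites:
            if s.local_axes is None:
                frames[s.label] = np.eye(3)
                continue
            ax = s.local_axes
            for ref in (ax.ref_z, ax.ref_x):
                if ref not in pos:
                    raise SymmetryError(
                        f"local axes of {s.label} reference missing atom {ref}"
                    )
            v1 = mi_vector(s.label, ax.ref_z)
            v2 = mi_vector(s.label, ax.ref_x)
            ez = v1 / np.linalg.norm(v1)
            ex = v2 - (v2 @ ez) * ez
            nrm = np.linalg.norm(ex)
            if nrm < 1e-8:
                raise SymmetryError(f"local axes of {s.label} are collinear")
            ex /= nrm
            ey = np.cross(ez, ex)
            frames[s.label] = np.column_stack([ex, ey, ez])
        return frames
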