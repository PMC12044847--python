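"""Charge-density diagnostics: difference Fourier maps, Henn-Meindl residual
fractal analysis, deformation density and QTAIM critical-point properties.

The QTAIM search finds stationary points of the static multipole density by
Newton-Raphson on the analytic gradient, classifies them by the Hessian
signature and reports the standard bond-critical-point table: rho_CP
(e A^-3), the Laplacian and its eigenvalues (e A^-5), the bond ellipticity
epsilon = lambda1/lambda2 - 1 (|lambda1| >= |lambda2|), and the distances
D1, D2 from the critical point to the two flanking nuclei with D their
internuclear distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import CrystalStructure
from .errors import CriticalPointError, DataError
from .multipole import CrystalDensity, MultipoleParameterSet
from .scattering import ReflectionSet

__all__ = [
    "DensityMap3D",
    "fourier_map",
    "FractalAnalysis",
    "henn_meindl",
    "plot_fractal",
    "CriticalPoint",
    "find_critical_point",
    "qtaim_report",
]


@dataclass
class DensityMap3D:
    """Density values (e A^-3) on a fractional grid over one unit cell."""

    values: np.ndarray
    cell: object
    kind: str = "model"  # residual | deformation | model

    def __post_init__(self):
        if min(self.values.shape) < 32:
            raise DataError("analysis maps need at least 32 grid points per axis")
        if not np.all(np.isfinite(self.values)):
            raise DataError("map contains non-finite values")

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size


def _expand_coefficients(structure: CrystalStructure, refl: ReflectionSet,
                         coeff: np.ndarray):
    """Spread coefficients of the unique list over the full sphere.

    Uses F(R^T h) = exp(-2 pi i h.t) F(h) for the model-phase relation and
    Friedel completion F(-h) = conj(F(h)); duplicate images are written once.
    """
    sums = {}
    counts = {}
    for i, h in enumerate(refl.hkl):
        for op in structure.ops:
            hp = tuple(int(v) for v in (h @ op.rot_array))
            ph = np.exp(-2j * np.pi * float(h @ op.tran_array))
            for key, val in ((hp, coeff[i] * ph),
                             (tuple(-v for v in hp), np.conj(coeff[i] * ph))):
                sums[key] = sums.get(key, 0.0) + val
                counts[key] = counts.get(key, 0) + 1
    # averaging over the orbit projects the coefficients onto the
    # symmetry-consistent subspace (phase-restricted and absent reflections
    # whose images disagree are symmetrized, not double-counted)
    return {k: sums[k] / counts[k] for k in sums}


def fourier_map(structure: CrystalStructure, refl: ReflectionSet,
                kind: str = "residual", grid: tuple = (64, 64, 64),
                scale: float = 1.0, fc_reference: np.ndarray | None = None) -> DensityMap3D:
    """Difference Fourier synthesis over the symmetry-completed sphere.

    kind='residual': coefficients (|Fo|/k - |Fc|) exp(i phi_c) from the
    set's Fo^2 and complex Fc.  kind='deformation': (Fc - Fc_reference),
    with `fc_reference` the spherical-model amplitudes (both static or both
    dynamic, caller's choice).  The map is the inverse Fourier sum divided
    by the cell volume, evaluated by zero-padded FFT on `grid`.
    """
    if refl.fc is None:
        raise DataError("fourier_map needs model amplitudes Fc")
    if kind == "residual":
        if refl.fo2 is None:
            raise DataError("residual map needs observed intensities")
        fo = np.sqrt(np.maximum(refl.fo2, 0.0)) / scale
        phases = refl.fc / np.maximum(np.abs(refl.fc), 1e-300)
        coeff = (fo - np.abs(refl.fc)) * phases
    elif kind == "deformation":
        if fc_reference is None:
            raise DataError("deformation map needs reference amplitudes")
        coeff = refl.fc - np.asarray(fc_reference, dtype=complex)
    else:
        raise DataError(f"unknown map kind {kind!r}")
    table = _expand_coefficients(structure, refl, coeff)
    n1, n2, n3 = grid
    spec = np.zeros(grid, dtype=complex)
    for (h, k, l), val in table.items():
        spec[h % n1, k % n2, l % n3] += val
    # rho(x) = (1/V) sum_h F_h exp(-2 pi i h.x)  ->  plain forward FFT
    rho = np.real(np.fft.fftn(spec)) / structure.cell.volume
    return DensityMap3D(values=rho, cell=structure.cell, kind=kind)


@dataclass
class FractalAnalysis:
    """Fractal-dimension curve of residual-density isosurfaces."""

    rho0: np.ndarray  # abscissa values, e A^-3
    df: np.ndarray  # fractal dimension d^f(rho0), in [0, 3]
    egross: float  # integrated residual density, e
    rho_min: float
    rho_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho0": self.rho0, "df": self.df})


def _isosurface_voxels(values: np.ndarray, rho0: float) -> np.ndarray:
    """Voxels where the map crosses rho0 against any face neighbour
    (periodic boundaries)."""
    above = values >= rho0
    cross = np.zeros(values.shape, dtype=bool)
    for axis in range(3):
        nb = np.roll(above, 1, axis=axis)
        cross |= above != nb
        cross |= np.roll(above != nb, -1, axis=axis)
    return cross


def _box_count_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of a voxel set: unweighted LSQ slope of
    log N(b) vs log(1/b) over dyadic box edges b = 2 .. n/4."""
    n1, n2, n3 = mask.shape
    sizes = []
    counts = []
    b = 2
    while b <= min(mask.shape) // 4:
        if n1 % b == 0 and n2 % b == 0 and n3 % b == 0:
            m = mask.reshape(n1 // b, b, n2 // b, b, n3 // b, b)
            occupied = m.any(axis=(1, 3, 5)).sum()
            if occupied > 0:
                sizes.append(b)
                counts.append(occupied)
        b *= 2
    if len(sizes) < 2:
        return float("nan")
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def henn_meindl(dmap: DensityMap3D, n_bins: int = 50) -> FractalAnalysis:
    """Residual-density fractal analysis.

    For each residual value rho0 the voxel set crossing the rho0 isosurface
    is box-counted; the log-log slope over dyadic box sizes is the fractal
    dimension d^f(rho0).  egross = (1/2) sum |rho| dV is the integrated
    residual density in electrons.  A flat map yields egross = 0 and an
    empty curve rather than an error.
    """
    v = dmap.values
    egross = 0.5 * float(np.sum(np.abs(v))) * dmap.voxel_volume
    rho_min, rho_max = float(v.min()), float(v.max())
    if rho_max - rho_min < 1e-15:
        return FractalAnalysis(rho0=np.array([]), df=np.array([]),
                               egross=egross, rho_min=rho_min, rho_max=rho_max)
    rho0 = np.linspace(rho_min, rho_max, n_bins + 2)[1:-1]
    df = np.array([_box_count_dimension(_isosurface_voxels(v, r)) for r in rho0])
    return FractalAnalysis(rho0=rho0, df=df, egross=egross,
                           rho_min=rho_min, rho_max=rho_max)


def plot_fractal(analysis: FractalAnalysis, ax=None, label: str | None = None):
    """Henn-Meindl plot: d^f against rho0 (the standard parabola-shaped
    residual diagnostic).  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    ax.plot(analysis.rho0, analysis.df, marker=".", label=label)
    ax.set_xlabel(r"$\rho_0$ (e $\AA^{-3}$)")
    ax.set_ylabel(r"$d^f(\rho_0)$")
    ax.set_ylim(0, 3.1)
    if label:
        ax.legend()
    return ax


@dataclass
class CriticalPoint:
    position: np.ndarray  # fractional
    rank: int
    signature: int
    rho: float  # e A^-3
    laplacian: float  # e A^-5
    eigenvalues: np.ndarray  # ascending, e A^-5
    ellipticity: float | None
    grad_norm: float
    d1: float | None = None  # CP -> attractor 1, A
    d2: float | None = None  # CP -> attractor 2, A
    d: float | None = None  # attractor-attractor distance, A
    flag: str = ""

    @property
    def label(self) -> str:
        return f"({self.rank},{self.signature:+d})"

    @property
    def is_bcp(self) -> bool:
        return self.rank == 3 and self.signature == -1


def find_critical_point(structure: CrystalStructure, mmps: MultipoleParameterSet,
                        seed_cart: np.ndarray, max_steps: int = 200,
                        grad_tol: float = 1e-8, step_cap: float = 0.3,
                        density: CrystalDensity | None = None) -> CriticalPoint:
    """Newton-Raphson search for a stationary point of the crystal density.

    Convergence requires |grad rho| < 1e-8 e A^-4.  A point that converges
    onto a density maximum (a nucleus) is reported as (3,-3), not an error.
    """
    dens = density or CrystalDensity(structure, mmps)
    x = np.asarray(seed_cart, dtype=float).copy()
    local = dens.local_evaluator(x, margin=1.5)
    for _ in range(max_steps):
        rho, g, h = local.gradient_hessian(x[None])
        gnorm = float(np.linalg.norm(g[0]))
        if gnorm < grad_tol:
            break
        try:
            step = -np.linalg.solve(h[0], g[0])
        except np.linalg.LinAlgError:
            step = -g[0]
        nrm = np.linalg.norm(step)
        if nrm > step_cap:
            step *= step_cap / nrm
        x = x + step
        if np.linalg.norm(x - np.asarray(seed_cart, dtype=float)) > 1.2:
            local = dens.local_evaluator(x, margin=1.5)
            seed_cart = x.copy()
    else:
        raise CriticalPointError(
            f"no convergence in {max_steps} Newton steps (|grad|={gnorm:.2e})")
    rho, g, h = local.gradient_hessian(x[None])
    eig = np.linalg.eigvalsh(h[0])
    nz = np.abs(eig) > 1e-10
    rank = int(nz.sum())
    signature = int(np.sign(eig[nz]).sum())
    ell = None
    if rank == 3 and signature == -1:
        lam = np.sort(eig)  # lam[0] <= lam[1] < 0 < lam[2]
        l1, l2 = sorted(lam[:2], key=abs, reverse=True)
        ell = float(l1 / l2 - 1.0)
    return CriticalPoint(
        position=structure.cell.cart_to_frac @ x,
        rank=rank, signature=signature, rho=float(rho[0]),
        laplacian=float(np.trace(h[0])), eigenvalues=eig,
        ellipticity=ell, grad_norm=float(np.linalg.norm(g[0])))


def _nearest_image(cell, frac_from, frac_to):
    d = np.asarray(frac_to) - np.asarray(frac_from)
    d -= np.rint(d)
    return np.asarray(frac_from) + d


def qtaim_report(structure: CrystalStructure, mmps: MultipoleParameterSet,
                 pairs: list, density: CrystalDensity | None = None) -> pd.DataFrame:
    """Bond-critical-point table for a list of atom pairs.

    Each pair is (label1, label2) or (label1, label2, op_index, (t1,t2,t3))
    selecting a symmetry image of the second atom; without an explicit image
    the nearest periodic image is used, so intermolecular contacts resolve
    naturally.  Pairs whose search fails or yields a non-(3,-1) point are
    flagged, never dropped.
    """
    dens = density or CrystalDensity(structure, mmps)
    a = structure.cell.frac_to_cart
    rows = []
    for pair in pairs:
        lbl1, lbl2 = pair[0], pair[1]
        x1 = structure.site(lbl1).xyz
        if len(pair) >= 4:
            op = structure.ops[pair[2]]
            x2 = op.apply(structure.site(lbl2).xyz) + np.asarray(pair[3], dtype=float)
        else:
            # nearest image over all symmetry operators and translations
            best = None
            for op in structure.ops:
                cand = _nearest_image(structure.cell, x1,
                                      op.apply(structure.site(lbl2).xyz))
                dist = np.linalg.norm(a @ (cand - x1))
                if best is None or dist < best[0]:
                    best = (dist, cand)
            x2 = best[1]
        c1, c2 = a @ x1, a @ np.asarray(x2, dtype=float)
        seed = 0.5 * (c1 + c2)
        row = {"bond": f"{lbl1}-{lbl2}", "D": float(np.linalg.norm(c2 - c1))}
        try:
            cp = find_critical_point(structure, mmps, seed, density=dens)
            xc = a @ cp.position
            # place the CP image nearest to the pair midpoint
            dfrac = cp.position - structure.cell.cart_to_frac @ seed
            dfrac -= np.rint(dfrac)
            xc = seed + a @ dfrac
            lam = np.sort(cp.eigenvalues)
            row.update({
                "D1": float(np.linalg.norm(xc - c1)),
                "D2": float(np.linalg.norm(xc - c2)),
                "CP": cp.label,
                "rho_cp": cp.rho,
                "lap_cp": cp.laplacian,
                "lambda1": float(lam[0]),
                "lambda2": float(lam[1]),
                "lambda3": float(lam[2]),
                "epsilon": cp.ellipticity,
                "flag": "" if cp.is_bcp else "non-bcp",
            })
        except CriticalPointError as exc:
            row.update({"D1": None, "D2": None, "CP": None, "rho_cp": None,
                        "lap_cp": None, "lambda1": None, "lambda2": None,
                        "lambda3": None, "epsilon": None, "flag": f"failed: {exc}"})
        rows.append(row)
    cols = ["bond", "D", "D1", "D2", "CP", "rho_cp", "lap_cp",
            "lambda1", "lambda2", "lambda3", "epsilon", "flag"]
    return pd.DataFrame(rows, columns=cols)
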