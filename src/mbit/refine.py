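"""Weighted least-squares refinement on F².

Minimizes sum_h w (Fo² - k² Fc²_corr)² over staged sets of free parameters
(scale, coordinates, ADPs, multipole populations, kappas, extinction) by
Levenberg-Marquardt-damped Gauss-Newton.  Derivatives are analytic for
scale, xyz, U and the (linear) multipole populations; central differences
are used for kappa and kappa', whose transform derivatives are unwieldy.

The weighting scheme is the SHELXL one,

    P = (max(Fo², 0) + 2 Fc²) / 3,   w = 1 / (sigma² + (aP)² + bP),

with fixed constants (a, b) taken from the protocol (no automatic
re-optimization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cells import CrystalStructure, u_equiv, u_cart_to_cif
from .errors import DataError, NonConvergenceError, RefinementError
from .multipole import MultipoleParameterSet
from .scattering import MO_KALPHA, ReflectionSet, SFCalculator

__all__ = [
    "Stage",
    "RefinementProtocol",
    "FitStatistics",
    "shelxl_weight",
    "fit_statistics",
    "optimal_scale",
    "extinction_correct",
    "extinction_kernel",
    "lsq_refine",
    "RefinementResult",
    "three_step_tmmp_protocol",
    "three_step_coordinate_protocol",
    "iam_protocol",
]


def shelxl_weight(fo2, sigma, fc2, a: float, b: float) -> np.ndarray:
    """SHELXL weights for refinement on F²; fc2 on the observed scale."""
    fo2 = np.asarray(fo2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise DataError("sigma must be positive")
    p = (np.maximum(fo2, 0.0) + 2.0 * np.asarray(fc2, dtype=float)) / 3.0
    return 1.0 / (sigma ** 2 + (a * p) ** 2 + b * p)


def optimal_scale(fo2, fc2, w) -> float:
    """k² minimizing sum w (Fo² - k² Fc²)²."""
    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    w = np.asarray(w, dtype=float)
    k2 = float(np.sum(w * fo2 * fc2) / np.sum(w * fc2 ** 2))
    return math.sqrt(max(k2, 1e-12))


def extinction_kernel(cell, hkl, wavelength: float = MO_KALPHA) -> np.ndarray:
    """Angular kernel q = 0.001 lambda^3 / sin(2 theta) of the isotropic
    secondary-extinction correction (SHELXL-style, after Larsen)."""
    s = 1.0 / cell.d_spacing(hkl)
    sin_t = np.clip(wavelength * s / 2.0, 0.0, 1.0)
    sin_2t = 2.0 * sin_t * np.sqrt(1.0 - sin_t ** 2)
    return 0.001 * wavelength ** 3 / np.maximum(sin_2t, 1e-6)


def extinction_correct(fc2, x: float, q) -> np.ndarray:
    """Fc²_corr = Fc² (1 + x q Fc²)^(-1/2); x = 0 is the identity."""
    if x < 0:
        raise DataError("extinction parameter must be non-negative")
    fc2 = np.asarray(fc2, dtype=float)
    return fc2 / np.sqrt(1.0 + x * np.asarray(q) * fc2)


@dataclass
class FitStatistics:
    r1: float  # %, on |F|
    wr2: float  # %, on F^2
    goof: float
    n_obs: int
    n_param: int
    shift_norms: list = field(default_factory=list)

    def __str__(self):
        return (f"R1={self.r1:.3f}% wR2={self.wr2:.3f}% GooF={self.goof:.3f} "
                f"({self.n_obs} obs / {self.n_param} par)")


def fit_statistics(fo2, sigma, fc, scale: float, a: float = 0.0, b: float = 0.0,
                   n_param: int = 1, ext_x: float = 0.0, ext_q=None,
                   i_over_sig: float | None = None) -> FitStatistics:
    """Agreement factors with |Fo| and Fo² brought onto the model scale.

    R1 uses all reflections by default; pass ``i_over_sig=2`` for the
    conventional I > 2 sigma subset.
    """
    fo2 = np.asarray(fo2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    fc2 = np.abs(np.asarray(fc)) ** 2
    if len(fo2) == 0:
        raise DataError("empty reflection set")
    fc2_corr = extinction_correct(fc2, ext_x, ext_q) if ext_x > 0 else fc2
    model = scale ** 2 * fc2_corr
    w = shelxl_weight(fo2, sigma, model, a, b)
    sel = np.ones(len(fo2), dtype=bool)
    if i_over_sig is not None:
        sel = fo2 > i_over_sig * sigma
    fo_amp = np.sqrt(np.maximum(fo2[sel], 0.0)) / scale
    fc_amp = np.sqrt(fc2_corr[sel])
    r1 = float(np.sum(np.abs(fo_amp - fc_amp)) / np.sum(fo_amp))
    wr2 = float(np.sqrt(np.sum(w * (fo2 - model) ** 2) / np.sum(w * fo2 ** 2)))
    dof = max(len(fo2) - n_param, 1)
    goof = float(np.sqrt(np.sum(w * (fo2 - model) ** 2) / dof))
    return FitStatistics(r1=100 * r1, wr2=100 * wr2, goof=goof,
                         n_obs=int(sel.sum()), n_param=n_param)


@dataclass
class Stage:
    """Mask of free parameters for one least-squares stage.

    The scale factor is refined in every stage (a protocol invariant);
    `uiso`/`uaniso` select the ADP treatment per atom for this stage, and the
    site is converted to the matching representation on entry.
    """

    name: str = ""
    xyz: tuple = ()
    uaniso: tuple = ()
    uiso: tuple = ()
    pv: tuple = ()
    plm: tuple = ()
    kappa: tuple = ()
    kappa_prime: tuple = ()
    extinction: bool = False
    max_cycles: int = 40
    shift_esd_tol: float = 0.005
    #: refine this stage against the d >= d_min_data subset only (a
    #: low-resolution pre-stage widens the convergence basin)
    d_min_data: float | None = None
    #: use pure 1/sigma^2 weights in this stage regardless of (a, b); the
    #: locator pre-stages want the strong structure-defining amplitudes to
    #: dominate, not the relative weighting of the final statistical fit
    sigma_weights_only: bool = False


@dataclass
class RefinementProtocol:
    stages: list
    weight_a: float = 0.01
    weight_b: float = 0.0

    def validate(self, structure: CrystalStructure):
        labels = {s.label for s in structure.sites}
        for st in self.stages:
            for kind in ("xyz", "uaniso", "uiso", "pv", "plm", "kappa", "kappa_prime"):
                bad = set(getattr(st, kind)) - labels
                if bad:
                    raise RefinementError(f"stage {st.name!r}: unknown atoms {sorted(bad)}")
            if set(st.uiso) & set(st.uaniso):
                raise RefinementError(f"stage {st.name!r}: atom both iso and aniso")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    mmps: MultipoleParameterSet
    scale: float
    ext_x: float
    stats: FitStatistics
    esds: dict
    stage_logs: list
    fc: np.ndarray | None = None


class _ParamVector:
    """Maps a stage's free parameters to/from a flat vector."""

    def __init__(self, structure, mmps, stage: Stage, use_extinction: bool):
        self.entries = [("scale", None, None)]
        if use_extinction and stage.extinction:
            self.entries.append(("ext", None, None))
        for lbl in stage.xyz:
            for i in range(3):
                self.entries.append(("xyz", lbl, i))
        for lbl in stage.uaniso:
            for i in range(6):
                self.entries.append(("uaniso", lbl, i))
        for lbl in stage.uiso:
            self.entries.append(("uiso", lbl, None))
        for lbl in stage.pv:
            self.entries.append(("pv", lbl, None))
        for lbl in stage.plm:
            m = mmps[lbl]
            for l in range(1, m.lmax + 1):
                for mm in range(-l, l + 1):
                    self.entries.append(("plm", lbl, (l, mm)))
        for lbl in stage.kappa:
            self.entries.append(("kappa", lbl, None))
        for lbl in stage.kappa_prime:
            self.entries.append(("kappa_prime", lbl, None))

    def __len__(self):
        return len(self.entries)

    def get(self, structure, mmps, scale, ext_x) -> np.ndarray:
        out = np.empty(len(self.entries))
        for i, (kind, lbl, comp) in enumerate(self.entries):
            if kind == "scale":
                out[i] = scale
            elif kind == "ext":
                out[i] = ext_x
            elif kind == "xyz":
                out[i] = structure.site(lbl).xyz[comp]
            elif kind == "uaniso":
                out[i] = structure.site(lbl).u_cif[comp]
            elif kind == "uiso":
                out[i] = structure.site(lbl).uiso
            elif kind == "pv":
                out[i] = mmps[lbl].pv
            elif kind == "plm":
                out[i] = mmps[lbl].get_plm(*comp)
            elif kind == "kappa":
                out[i] = mmps[lbl].kappa
            elif kind == "kappa_prime":
                out[i] = mmps[lbl].kappa_prime
        return out

    def set(self, vec, structure, mmps):
        scale = ext_x = None
        for i, (kind, lbl, comp) in enumerate(self.entries):
            v = float(vec[i])
            if kind == "scale":
                scale = v
            elif kind == "ext":
                ext_x = max(v, 0.0)
            elif kind == "xyz":
                structure.site(lbl).xyz[comp] = v % 1.0
            elif kind == "uaniso":
                structure.site(lbl).u_cif[comp] = v
            elif kind == "uiso":
                structure.site(lbl).uiso = v
            elif kind == "pv":
                mmps[lbl].pv = v
            elif kind == "plm":
                mmps[lbl].plm[comp] = v
            elif kind == "kappa":
                mmps[lbl].kappa = float(np.clip(v, 0.5, 2.0))
            elif kind == "kappa_prime":
                mmps[lbl].kappa_prime = float(np.clip(v, 0.5, 2.0))
        return scale, ext_x


def _prepare_adp_representation(structure, stage: Stage):
    """Convert sites to the ADP representation the stage refines."""
    cell = structure.cell
    for lbl in stage.uiso:
        s = structure.site(lbl)
        if s.u_cif is not None:
            s.uiso = u_equiv(cell, s.u_cif)
            s.u_cif = None
        elif s.uiso is None:
            s.uiso = 0.02
    for lbl in stage.uaniso:
        s = structure.site(lbl)
        if s.u_cif is None:
            u = s.uiso if s.uiso is not None else 0.02
            s.u_cif = u_cart_to_cif(cell, u * np.eye(3))
            s.uiso = None


def _model_and_jacobian(structure, mmps, pv_map, hkl, scale, ext_x, ext_q,
                        model, dispersion, static, kappa_step=2e-4):
    """Fc², model intensities and the Jacobian of the model w.r.t. pv_map."""
    calc = SFCalculator(structure, mmps, model=model, dispersion=dispersion)
    deriv_kinds = set()
    labels_by_kind = {}
    for kind, lbl, _ in pv_map.entries:
        if kind in ("xyz", "uaniso", "uiso", "pv", "plm"):
            deriv_kinds.add({"uaniso": "adp", "uiso": "adp"}.get(kind, kind))
            labels_by_kind.setdefault(kind, set()).add(lbl)
    labels = set().union(*labels_by_kind.values()) if labels_by_kind else set()
    fc, dmap = calc.compute(hkl, static=static, derivs=tuple(deriv_kinds), labels=labels) \
        if deriv_kinds else (calc.compute(hkl, static=static), {})
    fc2 = np.abs(fc) ** 2
    g = 1.0 / np.sqrt(1.0 + ext_x * ext_q * fc2) if ext_x > 0 else np.ones_like(fc2)
    m_model = scale ** 2 * fc2 * g
    # d(model)/d(fc2) including the extinction chain
    if ext_x > 0:
        dg = -0.5 * ext_x * ext_q * (1.0 + ext_x * ext_q * fc2) ** (-1.5)
        dmodel_dfc2 = scale ** 2 * (g + fc2 * dg)
    else:
        dmodel_dfc2 = np.full_like(fc2, scale ** 2)
    jac = np.zeros((len(fc2), len(pv_map)))
    kappa_cache = {}
    for j, (kind, lbl, comp) in enumerate(pv_map.entries):
        if kind == "scale":
            jac[:, j] = 2.0 * fc2 * g * scale
        elif kind == "ext":
            jac[:, j] = scale ** 2 * fc2 * (-0.5) * ext_q * fc2 * (1.0 + ext_x * ext_q * fc2) ** (-1.5)
        elif kind in ("xyz", "uaniso", "uiso", "pv", "plm"):
            d = dmap[lbl]
            if kind == "xyz":
                dfc = d["xyz"][:, comp]
            elif kind in ("uaniso", "uiso"):
                dfc = d["adp"][:, comp if kind == "uaniso" else 0]
            elif kind == "pv":
                dfc = d["pv"]
            else:
                dfc = d["plm"][comp]
            jac[:, j] = dmodel_dfc2 * 2.0 * np.real(np.conj(fc) * dfc)
        elif kind in ("kappa", "kappa_prime"):
            key = (kind, lbl)
            if key not in kappa_cache:
                mm = mmps[lbl]
                orig = getattr(mm, kind)
                step = kappa_step
                setattr(mm, kind, orig + step)
                calc_p = SFCalculator(structure, mmps, model=model, dispersion=dispersion)
                fp, _ = calc_p.atom_contribution(lbl, hkl, static=static)
                setattr(mm, kind, orig - step)
                calc_m = SFCalculator(structure, mmps, model=model, dispersion=dispersion)
                fm, _ = calc_m.atom_contribution(lbl, hkl, static=static)
                setattr(mm, kind, orig)
                kappa_cache[key] = (fp - fm) / (2 * step)
            dfc = kappa_cache[key]
            jac[:, j] = dmodel_dfc2 * 2.0 * np.real(np.conj(fc) * dfc)
    return fc, fc2, m_model, jac


def lsq_refine(structure: CrystalStructure, mmps: MultipoleParameterSet | None,
               data: ReflectionSet, protocol: RefinementProtocol,
               model: str = "multipole", dispersion: bool = True,
               static: bool = False, scale0: float | None = None,
               ext0: float = 0.0, use_extinction: bool = False,
               wavelength: float = MO_KALPHA) -> RefinementResult:
    """Run the staged refinement and return the updated model.

    Works on copies; the inputs are never mutated.  Raises
    :class:`RefinementError` for under-determined or singular stages and
    :class:`NonConvergenceError` when the damping collapses without reaching
    the shift/esd cutoff.
    """
    if data.fo2 is None or data.sigma is None:
        raise DataError("refinement needs Fo^2 and sigma")
    structure = structure.copy()
    mmps = (mmps.copy() if mmps is not None
            else MultipoleParameterSet.neutral(structure))
    protocol.validate(structure)
    hkl_all = data.hkl
    fo2_all, sigma_all = data.fo2, data.sigma
    ext_q_all = extinction_kernel(structure.cell, hkl_all, wavelength)
    d_all = structure.cell.d_spacing(hkl_all)
    a_w, b_w = protocol.weight_a, protocol.weight_b

    calc = SFCalculator(structure, mmps, model=model, dispersion=dispersion)
    fc0 = calc.compute(hkl_all, static=static)
    if scale0 is None:
        w0 = 1.0 / sigma_all ** 2
        scale = optimal_scale(fo2_all, np.abs(fc0) ** 2, w0)
    else:
        scale = scale0
    ext_x = ext0

    stage_logs = []
    esds = {}
    last_stats = None
    n_param_total = 0
    fc = fc0
    for stage in protocol.stages:
        if stage.d_min_data is not None:
            sel = d_all >= stage.d_min_data
            hkl, fo2, sigma, ext_q = (hkl_all[sel], fo2_all[sel],
                                      sigma_all[sel], ext_q_all[sel])
        else:
            hkl, fo2, sigma, ext_q = hkl_all, fo2_all, sigma_all, ext_q_all
        if stage.sigma_weights_only:
            a_st, b_st = 0.0, 0.0
        else:
            a_st, b_st = a_w, b_w
        _prepare_adp_representation(structure, stage)
        pv = _ParamVector(structure, mmps, stage, use_extinction)
        n_par = len(pv)
        n_param_total = n_par
        if len(fo2) < n_par:
            raise RefinementError(
                f"stage {stage.name!r}: {len(fo2)} observations < {n_par} parameters")
        log = {"stage": stage.name, "cycles": []}
        lam = 1e-5
        fc, fc2, m_model, jac = _model_and_jacobian(
            structure, mmps, pv, hkl, scale, ext_x, ext_q, model, dispersion, static)
        w = shelxl_weight(fo2, sigma, m_model, a_st, b_st)
        resid = fo2 - m_model
        chi2 = float(np.sum(w * resid ** 2))
        converged = False
        for cycle in range(stage.max_cycles):
            jw = jac * np.sqrt(w)[:, None]
            rw = resid * np.sqrt(w)
            nmat = jw.T @ jw
            rhs = jw.T @ rw
            diag = np.diag(nmat).copy()
            dead = diag <= 1e-25 * max(diag.max(), 1e-300)
            if np.any(dead):
                # parameters with exactly no signal (e.g. kappa' while every
                # P_lm is zero) are held fixed for this cycle; a genuinely
                # correlated singular matrix still raises below
                for i in np.where(dead)[0]:
                    nmat[i, :] = 0.0
                    nmat[:, i] = 0.0
                    nmat[i, i] = 1.0
                    rhs[i] = 0.0
                diag = np.diag(nmat).copy()
                log.setdefault("held_fixed", sorted(
                    {pv.entries[i] for i in np.where(dead)[0]}, key=str))
            accepted = False
            for _try in range(25):
                try:
                    dp = np.linalg.solve(nmat + lam * np.diag(diag), rhs)
                except np.linalg.LinAlgError:
                    cond = np.linalg.cond(nmat)
                    worst = [pv.entries[i] for i in
                             np.argsort(np.abs(np.diag(nmat)))[:3]]
                    raise RefinementError(
                        f"singular normal matrix (cond={cond:.2e}); "
                        f"suspect null-space parameters: {worst}")
                p_old = pv.get(structure, mmps, scale, ext_x)
                s_new, e_new = pv.set(p_old + dp, structure, mmps)
                scale_t = s_new if s_new is not None else scale
                ext_t = e_new if e_new is not None else ext_x
                calc_t = SFCalculator(structure, mmps, model=model, dispersion=dispersion)
                fc_t = calc_t.compute(hkl, static=static)
                fc2_t = np.abs(fc_t) ** 2
                g_t = 1.0 / np.sqrt(1.0 + ext_t * ext_q * fc2_t) if ext_t > 0 else 1.0
                m_t = scale_t ** 2 * fc2_t * g_t
                chi2_t = float(np.sum(w * (fo2 - m_t) ** 2))
                if chi2_t <= chi2 * (1 + 1e-12):
                    scale, ext_x = scale_t, ext_t
                    chi2 = chi2_t
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                pv.set(p_old, structure, mmps)
                lam *= 10.0
                if lam > 1e12:
                    break
            if not accepted:
                # stationary within numerical precision
                converged = True
                break
            fc, fc2, m_model, jac = _model_and_jacobian(
                structure, mmps, pv, hkl, scale, ext_x, ext_q, model, dispersion, static)
            w = shelxl_weight(fo2, sigma, m_model, a_st, b_st)
            resid = fo2 - m_model
            chi2 = float(np.sum(w * resid ** 2))
            dof = max(len(fo2) - n_par, 1)
            cov_diag = np.maximum(np.linalg.inv(nmat).diagonal(), 1e-300) * chi2 / dof
            esd_vec = np.sqrt(cov_diag)
            shift_esd = float(np.max(np.abs(dp) / np.maximum(esd_vec, 1e-300)))
            wr2 = float(np.sqrt(chi2 / np.sum(w * fo2 ** 2)))
            log["cycles"].append(
                {"cycle": cycle, "wR2": 100 * wr2, "max_shift_esd": shift_esd, "lambda": lam})
            if shift_esd < stage.shift_esd_tol:
                converged = True
                break
        if not converged and lam > 1e12:
            raise NonConvergenceError(
                f"stage {stage.name!r} did not reach the shift/esd cutoff")
        # esds from the undamped normal matrix at convergence
        jw = jac * np.sqrt(w)[:, None]
        nmat = jw.T @ jw
        try:
            cov = np.linalg.inv(nmat) * chi2 / max(len(fo2) - n_par, 1)
        except np.linalg.LinAlgError:
            cov = np.full((n_par, n_par), np.nan)
        for i, entry in enumerate(pv.entries):
            esds[entry] = float(np.sqrt(max(cov[i, i], 0.0)))
        stage_logs.append(log)
        fc_full = SFCalculator(structure, mmps, model=model,
                               dispersion=dispersion).compute(hkl_all, static=static)             if stage.d_min_data is not None else fc
        last_stats = fit_statistics(
            fo2_all, sigma_all, fc_full, scale, a=a_w, b=b_w, n_param=n_par,
            ext_x=ext_x, ext_q=ext_q_all)
        fc = fc_full
    return RefinementResult(structure=structure, mmps=mmps, scale=scale,
                            ext_x=ext_x, stats=last_stats, esds=esds,
                            stage_logs=stage_logs, fc=fc)


# ----------------------------------------------------------------------------
# Staged protocols
# ----------------------------------------------------------------------------

def _split_h(structure):
    h = tuple(s.label for s in structure.sites if s.element == "H")
    heavy = tuple(s.label for s in structure.sites if s.element != "H")
    return heavy, h


def three_step_tmmp_protocol(structure: CrystalStructure,
                             refine_kappa_prime: bool = True,
                             weight_a: float = 0.0,
                             weight_b: float = 0.0) -> RefinementProtocol:
    """The staged multipole fit against theoretical intensities:

    1. multipole populations of all atoms (octupole level on non-H, dipoles
       on H), kappas fixed;
    2. per-atom kappa (and kappa') with populations fixed;
    3. kappas and all populations jointly, hydrogen multipoles held fixed
       to limit correlation.

    The scale factor is free in every stage.
    """
    heavy, h = _split_h(structure)
    alla = heavy + h
    kp = alla if refine_kappa_prime else ()
    kp_heavy = heavy if refine_kappa_prime else ()
    return RefinementProtocol(
        stages=[
            Stage(name="populations", pv=alla, plm=alla),
            Stage(name="kappas", kappa=alla, kappa_prime=kp),
            Stage(name="joint", pv=heavy, plm=heavy, kappa=alla, kappa_prime=kp),
        ],
        weight_a=weight_a, weight_b=weight_b,
    )


def three_step_coordinate_protocol(structure: CrystalStructure,
                                   weight_a: float = 0.01,
                                   weight_b: float = 0.0,
                                   extinction: bool = False) -> RefinementProtocol:
    """The staged coordinate/ADP refinement against experimental intensities:

    1. coordinates and anisotropic ADPs of all non-hydrogen atoms;
    2. plus hydrogen coordinates with isotropic hydrogen ADPs;
    3. everything free, all ADPs anisotropic.
    """
    heavy, h = _split_h(structure)
    alla = heavy + h
    return RefinementProtocol(
        stages=[
            # coordinates-only pass against the low-resolution subset first:
            # the smooth low-res landscape has a wide convergence basin and
            # guides atoms (especially H) into the right wells
            Stage(name="low-res", xyz=alla, d_min_data=1.2, max_cycles=25,
                  sigma_weights_only=True),
            Stage(name="heavy", xyz=heavy, uaniso=heavy, extinction=extinction),
            Stage(name="add-H-iso", xyz=alla, uaniso=heavy, uiso=h,
                  extinction=extinction),
            # the isotropic-H approximation can push hydrogens out of their
            # (sharp) wells; a second low-resolution coordinate pass guides
            # them back before everything is freed anisotropically
            Stage(name="low-res-2", xyz=alla, d_min_data=1.2, max_cycles=25,
                  sigma_weights_only=True),
            Stage(name="all-aniso", xyz=alla, uaniso=alla,
                  extinction=extinction, max_cycles=60, shift_esd_tol=5e-4),
        ],
        weight_a=weight_a, weight_b=weight_b,
    )


def iam_protocol(structure: CrystalStructure, weight_a: float = 0.01,
                 weight_b: float = 0.0) -> RefinementProtocol:
    """Conventional spherical-atom (IAM) refinement, used for starting
    models and as the comparison baseline: anisotropic non-hydrogen atoms,
    isotropic hydrogens (the standard IAM treatment -- free anisotropic H
    ADPs would soak up the unmodelled bond density)."""
    heavy, h = _split_h(structure)
    return RefinementProtocol(
        stages=[
            Stage(name="heavy", xyz=heavy, uaniso=heavy),
            Stage(name="all-H-iso", xyz=heavy + h, uaniso=heavy, uiso=h),
        ],
        weight_a=weight_a, weight_b=weight_b,
    )
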