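"""File formats: core CIF, SHELX HKLF-4, theoretical structure-factor TSV,
and the YAML multipole-parameter schema.

The CIF reader/writer covers the core tags needed for refinement: cell,
symmetry operator strings, atom sites with fractional coordinates and
either Uiso or the six-component anisotropic U^ij (CIF convention).  HKLF-4
is the fixed-width (3I4, 2F8.2) F^2 exchange format with the all-zero
terminator line; values too wide for the fixed fields fall back to a
free-format line with a warning.
"""

from __future__ import annotations

import warnings

import gemmi
import numpy as np
import yaml

from .cells import AtomSite, CrystalStructure, LocalAxes, SymmetryOp, UnitCell
from .errors import ParseError
from .multipole import MultipoleParameterSet
from .scattering import ReflectionSet

__all__ = [
    "read_cif", "write_cif",
    "read_hklf4", "write_hklf4",
    "read_sf_tsv", "write_sf_tsv",
    "read_tmmp_yaml", "write_tmmp_yaml",
]


def write_cif(path, structure: CrystalStructure) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.name or "mbit")
    cell = structure.cell
    for tag, val in (("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
                     ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
                     ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma)):
        block.set_pair(tag, f"{val:.6f}")
    loop = block.init_loop("_space_group_symop_", ["operation_xyz"])
    for op in structure.ops:
        loop.add_row([gemmi.cif.quote(op.to_xyz())])
    loop = block.init_loop("_atom_site_", [
        "label", "type_symbol", "fract_x", "fract_y", "fract_z",
        "occupancy", "U_iso_or_equiv", "adp_type",
        "mbit_axis_ref_z", "mbit_axis_ref_x"])
    from .cells import u_equiv
    for s in structure.sites:
        if s.u_cif is not None:
            u = u_equiv(cell, s.u_cif)
            adp = "Uani"
        else:
            u = s.uiso if s.uiso is not None else 0.0
            adp = "Uiso"
        ax = s.local_axes
        loop.add_row([s.label, s.element,
                      f"{s.xyz[0]:.8f}", f"{s.xyz[1]:.8f}", f"{s.xyz[2]:.8f}",
                      f"{s.occupancy:.4f}", f"{u:.8f}", adp,
                      ax.ref_z if ax else ".", ax.ref_x if ax else "."])
    aniso = [s for s in structure.sites if s.u_cif is not None]
    if aniso:
        loop = block.init_loop("_atom_site_aniso_", [
            "label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"])
        for s in aniso:
            u = s.u_cif
            loop.add_row([s.label] + [f"{v:.8f}" for v in
                                      (u[0], u[1], u[2], u[3], u[4], u[5])])
    doc.write_file(str(path))


def read_cif(path) -> CrystalStructure:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse CIF {path}: {exc}") from exc
    block = doc.sole_block()

    def need(tag):
        v = block.find_value(tag)
        if v is None:
            raise ParseError(f"{path}: missing mandatory CIF tag {tag}")
        return float(gemmi.cif.as_number(v))

    cell = UnitCell(need("_cell_length_a"), need("_cell_length_b"),
                    need("_cell_length_c"), need("_cell_angle_alpha"),
                    need("_cell_angle_beta"), need("_cell_angle_gamma"))
    ops = []
    for tag in ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz"):
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [SymmetryOp.from_xyz(gemmi.cif.as_string(v)) for v in col]
            break
    if not ops:
        ops = [SymmetryOp.identity()]
    table = block.find("_atom_site_", ["label", "type_symbol", "fract_x",
                                       "fract_y", "fract_z"])
    if len(table) == 0:
        raise ParseError(f"{path}: missing mandatory tag _atom_site_label")
    occ_col = block.find_loop("_atom_site_occupancy")
    uiso_col = block.find_loop("_atom_site_U_iso_or_equiv")
    adp_col = block.find_loop("_atom_site_adp_type")
    axz_col = block.find_loop("_atom_site_mbit_axis_ref_z")
    axx_col = block.find_loop("_atom_site_mbit_axis_ref_x")
    sites = []
    for i, row in enumerate(table):
        s = AtomSite(
            label=row[0], element=row[1],
            xyz=[gemmi.cif.as_number(row[j]) for j in (2, 3, 4)],
            occupancy=gemmi.cif.as_number(occ_col[i]) if len(occ_col) else 1.0,
        )
        if len(uiso_col):
            adp = gemmi.cif.as_string(adp_col[i]) if len(adp_col) else "Uiso"
            if adp != "Uani":
                s.uiso = gemmi.cif.as_number(uiso_col[i])
        if len(axz_col):
            rz = gemmi.cif.as_string(axz_col[i])
            rx = gemmi.cif.as_string(axx_col[i])
            if rz != "." and rx != ".":
                s.local_axes = LocalAxes(ref_z=rz, ref_x=rx)
        sites.append(s)
    atable = block.find("_atom_site_aniso_", ["label", "U_11", "U_22", "U_33",
                                              "U_12", "U_13", "U_23"])
    by_label = {s.label: s for s in sites}
    for row in atable:
        s = by_label[row[0]]
        s.u_cif = np.array([gemmi.cif.as_number(row[j]) for j in range(1, 7)])
        s.uiso = None
    return CrystalStructure(cell=cell, ops=ops, sites=sites,
                            name=block.name if block.name != "mbit" else "")


def write_hklf4(path, refl: ReflectionSet) -> None:
    warned = False
    with open(path, "w") as fh:
        for (h, k, l), fo2, sig in zip(refl.hkl, refl.fo2, refl.sigma):
            in_range = (abs(fo2) < 1e6 and abs(sig) < 1e6
                        and all(-999 <= v <= 9999 for v in (h, k, l))
                        and round(sig, 2) > 0.0)
            if in_range:
                fh.write(f"{h:4d}{k:4d}{l:4d}{fo2:8.2f}{sig:8.2f}\n")
            else:
                if not warned:
                    warnings.warn("value outside the HKLF-4 fixed-width range; "
                                  "falling back to free-format lines")
                    warned = True
                fh.write(f"{h} {k} {l} {fo2:.8g} {sig:.8g}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hklf4(path) -> ReflectionSet:
    hkl, fo2, sig = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                break
            try:
                # fixed-width (3I4, 2F8.2) first, free-format fallback
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                f = float(line[12:20])
                s = float(line[20:28])
            except (ValueError, IndexError):
                try:
                    parts = line.split()
                    h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                    f, s = float(parts[3]), float(parts[4])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{ln}: bad HKLF-4 line {line!r}") from exc
            if h == 0 and k == 0 and l == 0:
                break
            hkl.append((h, k, l))
            fo2.append(f)
            sig.append(s)
    if not hkl:
        raise ParseError(f"{path}: no reflections before terminator")
    return ReflectionSet(hkl=np.array(hkl), fo2=np.array(fo2), sigma=np.array(sig))


def write_sf_tsv(path, hkl: np.ndarray, f: np.ndarray) -> None:
    """Theoretical static structure factors: `h k l Are Aim` columns (the
    contract a density backend's export must satisfy)."""
    with open(path, "w") as fh:
        fh.write("h\tk\tl\tAre\tAim\n")
        for (h, k, l), v in zip(np.atleast_2d(hkl), f):
            fh.write(f"{h}\t{k}\t{l}\t{v.real:.10g}\t{v.imag:.10g}\n")


def read_sf_tsv(path):
    hkl, f = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0] in ("h", "#"):
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}:{ln}: expected 'h k l Are Aim'")
            hkl.append(tuple(int(v) for v in parts[:3]))
            f.append(complex(float(parts[3]), float(parts[4])))
    return np.array(hkl), np.array(f)


def write_tmmp_yaml(path, mmps: MultipoleParameterSet) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mmps.to_dict(), fh, sort_keys=True, default_flow_style=False)


def read_tmmp_yaml(path) -> MultipoleParameterSet:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParseError(f"{path}: not a multipole parameter mapping")
    return MultipoleParameterSet.from_dict(d)
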