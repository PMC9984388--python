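"""Structure, Bragg-list, and TLS/ADP I/O.

Atomic models are read with biotite (mmCIF and PDB). Bragg intensity lists
travel as whitespace-delimited text with columns ``h k l I sigma`` (sigma
optional). TLS matrices export in the REFMAC/PDB TLS record convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_structure",
    "read_bragg_tsv",
    "write_bragg_tsv",
    "write_tls",
    "adps_to_cif_records",
]


def read_structure(path):
    """Read an mmCIF or PDB file into (asu_atoms dict, UnitCellGeometry).

    The returned dict has the arrays expected by
    :func:`~latticevibes.crystal_model.expand_to_unit_cell`. Anisotropic
    ADPs are reduced to the equivalent isotropic B. Symmetry comes from the
    file's space-group symbol (must be in the built-in table) unless the
    file is P1.
    """
    import biotite.structure.io.pdbx as pdbx
    import biotite.structure.io.pdb as pdbio
    from .crystal_model import UnitCellGeometry

    path = str(path)
    if path.endswith((".cif", ".mmcif", ".cif.gz")):
        f = pdbx.CIFFile.read(path)
        atoms = pdbx.get_structure(f, model=1, extra_fields=["occupancy",
                                                             "b_factor"])
        block = f.block
        cell_cat = block["cell"]
        cell = [float(cell_cat[k].as_item()) for k in
                ("length_a", "length_b", "length_c",
                 "angle_alpha", "angle_beta", "angle_gamma")]
        try:
            sg = block["symmetry"]["space_group_name_H-M"].as_item()
        except KeyError:
            sg = "P 1"
    else:
        f = pdbio.PDBFile.read(path)
        atoms = f.get_structure(model=1, extra_fields=["occupancy",
                                                       "b_factor"])
        box_line = None
        for line in f.lines:
            if line.startswith("CRYST1"):
                box_line = line
                break
        if box_line is None:
            raise ValueError("PDB file has no CRYST1 record")
        cell = [float(box_line[6:15]), float(box_line[15:24]),
                float(box_line[24:33]), float(box_line[33:40]),
                float(box_line[40:47]), float(box_line[47:54])]
        sg = box_line[55:66].strip() or "P 1"

    geom = UnitCellGeometry(*cell, space_group=sg)
    asu = {
        "element": np.array([e.capitalize() for e in atoms.element],
                            dtype=object),
        "xyz": np.asarray(atoms.coord, dtype=float),
        "occupancy": np.asarray(atoms.occupancy, dtype=float),
        "b_iso": np.asarray(atoms.b_factor, dtype=float),
        "residue_id": np.asarray(atoms.res_id, dtype=int),
        "residue_name": np.array(atoms.res_name, dtype=object),
        "chain_id": np.array(atoms.chain_id, dtype=object),
    }
    return asu, geom


def read_bragg_tsv(path):
    """Read a Bragg list (columns h k l I [sigma]) into a DataFrame."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want in ("h", "k", "l"):
        rename[cols[want]] = want
    for want, targets in (("I", ("i", "intensity")), ("sigma", ("sigma", "sigi", "sig"))):
        for t in targets:
            if t in cols:
                rename[cols[t]] = want
                break
    df = df.rename(columns=rename)
    if "sigma" not in df:
        df["sigma"] = np.sqrt(np.abs(df["I"]))
    return df[["h", "k", "l", "I", "sigma"]]


def write_bragg_tsv(path, h, intensities, sigmas=None):
    h = np.atleast_2d(np.asarray(h, dtype=int))
    I = np.asarray(intensities, dtype=float)
    if sigmas is None:
        sigmas = np.sqrt(np.abs(I))
    df = pd.DataFrame({"h": h[:, 0], "k": h[:, 1], "l": h[:, 2],
                       "I": I, "sigma": sigmas})
    df.to_csv(path, sep="\t", index=False)


def write_tls(path, tls_list, origins, units="deg2"):
    """Write TLS groups as REFMAC-style TLSIN text.

    ``tls_list`` is a sequence of (T, L, S) with L in rad^2; the L and S
    records convert to deg^2 / deg when ``units == "deg2"`` (REFMAC
    convention).
    """
    r2d = (180.0 / np.pi)
    with open(path, "w") as fh:
        fh.write("REFMAC\n\n")
        for i, ((T, L, S), o) in enumerate(zip(tls_list, origins), start=1):
            if units == "deg2":
                Lw = L * r2d**2
                Sw = S * r2d
            elif units == "rad2":
                Lw, Sw = L, S
            else:
                raise ValueError("units must be 'deg2' or 'rad2'")
            fh.write(f"TLS  group {i}\n")
            fh.write("ORIGIN  %9.4f %9.4f %9.4f\n" % tuple(o))
            fh.write("T   %9.4f %9.4f %9.4f %9.4f %9.4f %9.4f\n" % (
                T[0, 0], T[1, 1], T[2, 2], T[0, 1], T[0, 2], T[1, 2]))
            fh.write("L   %9.4f %9.4f %9.4f %9.4f %9.4f %9.4f\n" % (
                Lw[0, 0], Lw[1, 1], Lw[2, 2], Lw[0, 1], Lw[0, 2], Lw[1, 2]))
            fh.write("S   %9.4f %9.4f %9.4f %9.4f %9.4f %9.4f %9.4f %9.4f\n" % (
                Sw[1, 0], Sw[0, 1], Sw[0, 2], Sw[1, 2], Sw[2, 0], Sw[2, 1],
                Sw[0, 0] - Sw[1, 1], Sw[1, 1] - Sw[2, 2]))
        fh.write("\n")


def adps_to_cif_records(crystal, adps):
    """Anisotropic U records (mmCIF ``atom_site_anisotrop`` style rows).

    Returns a DataFrame with atom indexing and the six unique Cartesian U
    components in A^2.
    """
    rows = []
    i = 0
    for k, g in enumerate(crystal.groups):
        for j in range(g.n_atoms):
            U = adps.U[i]
            rows.append({
                "group": k, "atom": j, "element": str(g.elements[j]),
                "residue_id": int(g.residue_ids[j]),
                "U11": U[0, 0], "U22": U[1, 1], "U33": U[2, 2],
                "U12": U[0, 1], "U13": U[0, 2], "U23": U[1, 2],
                "B_eq": 8 * np.pi**2 * np.trace(U) / 3,
            })
            i += 1
    return pd.DataFrame(rows)
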