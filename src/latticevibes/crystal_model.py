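"""Crystal geometry, rigid groups, and inter-group spring networks.

This module turns an asymmetric-unit atomic model into a unit cell of rigid
bodies connected by harmonic springs:

* :class:`UnitCellGeometry` — cell parameters, symmetry operators, and the
  orthogonalization/fractionalization transforms.
* :func:`expand_to_unit_cell` — apply symmetry operators to build one rigid
  group per chain image.
* :func:`find_contacts` — KD-tree search for inter-group atom pairs within a
  hard distance cutoff, including pairs across cell boundaries.
* :func:`group_springs` — partition contacts into symmetry-enforced parameter
  groups (global / per-interface / per-residue-pair).
* :func:`force_constant_block` — the 3x3 force-constant matrix of a hybrid
  (Gaussian + parallel) spring.

All coordinates are Cartesian in Angstrom; fractional coordinates appear only
at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ATOMIC_MASSES",
    "UnitCellGeometry",
    "RigidGroup",
    "RigidGroupCrystal",
    "SpringContact",
    "SpringParameterSet",
    "parse_symop",
    "symop_to_string",
    "expand_to_unit_cell",
    "find_contacts",
    "group_springs",
    "force_constant_block",
]

# Standard atomic masses (u) for elements common in macromolecular models.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904, "X": 12.011,
}

# Residue names treated as solvent/buffer when building rigid groups.
SOLVENT_RESIDUES = frozenset({
    "HOH", "WAT", "DOD", "SOL", "NA", "CL", "K", "MG", "CA", "ZN", "SO4",
    "PO4", "GOL", "EDO", "ACT", "ACY", "NO3", "IOD", "BR",
})

_SPACE_GROUPS = {
    "P 1": ["x,y,z"],
    "P 1 21 1": ["x,y,z", "-x,y+1/2,-z"],
    "P 21 21 21": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
    "P 43 21 2": [
        "x,y,z",
        "-x,-y,z+1/2",
        "-y+1/2,x+1/2,z+3/4",
        "y+1/2,-x+1/2,z+1/4",
        "-x+1/2,y+1/2,-z+3/4",
        "x+1/2,-y+1/2,-z+1/4",
        "y,x,-z",
        "-y,-x,-z+1/2",
    ],
}
# Accept compact aliases like "P212121".
_SPACE_GROUP_ALIASES = {k.replace(" ", ""): k for k in _SPACE_GROUPS}


def parse_symop(text):
    """Parse an ``x,y,z``-style symmetry operator string.

    Returns ``(R, t)`` where ``R`` is a 3x3 integer rotation and ``t`` a
    fractional translation 3-vector.
    """
    rows = text.lower().replace(" ", "").split(",")
    if len(rows) != 3:
        raise ValueError(f"bad symmetry operator: {text!r}")
    R = np.zeros((3, 3), dtype=int)
    t = np.zeros(3)
    axes = {"x": 0, "y": 1, "z": 2}
    for i, row in enumerate(rows):
        # tokenize into signed terms
        terms = row.replace("-", "+-").split("+")
        for term in terms:
            if not term:
                continue
            sign = 1
            if term.startswith("-"):
                sign, term = -1, term[1:]
            if term in axes:
                R[i, axes[term]] += sign
            else:
                t[i] += sign * float(Fraction(term))
    return R, t % 1.0


def symop_to_string(R, t):
    """Inverse of :func:`parse_symop` (canonical form, e.g. ``-x,y+1/2,-z``)."""
    parts = []
    for i in range(3):
        s = ""
        for j, ax in enumerate("xyz"):
            c = int(R[i, j])
            if c == 1:
                s += ("+" if s else "") + ax
            elif c == -1:
                s += "-" + ax
            elif c != 0:
                s += f"{c:+d}*{ax}"
        frac = Fraction(t[i] % 1.0).limit_denominator(24)
        if frac != 0:
            s += f"+{frac}"
        parts.append(s)
    return ",".join(parts)


class UnitCellGeometry:
    """Unit-cell parameters plus space-group symmetry.

    Parameters
    ----------
    a, b, c : float
        Cell edge lengths in Angstrom.
    alpha, beta, gamma : float
        Cell angles in degrees.
    operators : sequence of (R, t) or str, optional
        Symmetry operators as ``(rotation, translation)`` pairs or
        ``x,y,z`` strings. Mutually exclusive with ``space_group``.
    space_group : str, optional
        Hermann-Mauguin symbol from the built-in table (``P 1``,
        ``P 1 21 1``, ``P 21 21 21``, ``P 43 21 2``).
    """

    def __init__(self, a, b, c, alpha=90.0, beta=90.0, gamma=90.0,
                 operators=None, space_group=None):
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.alpha, self.beta, self.gamma = float(alpha), float(beta), float(gamma)
        if operators is None:
            symbol = space_group or "P 1"
            key = _SPACE_GROUP_ALIASES.get(symbol.replace(" ", ""))
            if key is None:
                raise ValueError(f"unknown space group symbol: {symbol!r}")
            operators = _SPACE_GROUPS[key]
            self.space_group = key
        else:
            self.space_group = space_group
        ops = []
        for op in operators:
            if isinstance(op, str):
                ops.append(parse_symop(op))
            else:
                R, t = op
                ops.append((np.asarray(R, dtype=int), np.asarray(t, dtype=float) % 1.0))
        self.operators = ops
        self._build_transforms()
        self._check_closure()

    # -- transforms ------------------------------------------------------
    def _build_transforms(self):
        al, be, ga = np.deg2rad([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sg = np.sin(ga)
        v = np.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
        # PDB convention: a along x, b in the x-y plane.
        self.orth = np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])
        self.frac = np.linalg.inv(self.orth)
        self.volume = float(np.linalg.det(self.orth))
        # Columns of recip are the reciprocal-cell vectors (2*pi convention):
        # q(h) = recip @ h, with a_i . b_j = 2*pi*delta_ij.
        self.recip = 2 * np.pi * self.frac.T

    def _check_closure(self):
        keys = {self._op_key(R, t) for R, t in self.operators}
        for R1, t1 in self.operators:
            for R2, t2 in self.operators:
                R, t = R1 @ R2, (R1 @ t2 + t1) % 1.0
                if self._op_key(R, t) not in keys:
                    raise ValueError("symmetry operators do not form a closed group")

    @staticmethod
    def _op_key(R, t):
        return (tuple(np.asarray(R, dtype=int).ravel()),
                tuple(np.round(np.asarray(t) % 1.0, 6) % 1.0))

    # -- coordinate helpers ---------------------------------------------
    def to_cartesian(self, x_frac):
        return np.asarray(x_frac, dtype=float) @ self.orth.T

    def to_fractional(self, x_cart):
        return np.asarray(x_cart, dtype=float) @ self.frac.T

    def q_cartesian(self, h):
        """Scattering vector (2*pi convention, 1/A) for fractional Miller h."""
        return np.asarray(h, dtype=float) @ self.recip.T

    def d_spacing(self, h):
        q = np.linalg.norm(self.q_cartesian(h), axis=-1)
        with np.errstate(divide="ignore"):
            return 2 * np.pi / q

    def apply_operator(self, index, x_cart):
        """Apply symmetry operator ``index`` to Cartesian coordinates."""
        R, t = self.operators[index]
        xf = self.to_fractional(x_cart)
        return self.to_cartesian(xf @ R.T + t)

    @property
    def n_operators(self):
        return len(self.operators)

    def __repr__(self):
        sg = self.space_group or f"{len(self.operators)} ops"
        return (f"UnitCellGeometry({self.a:g}, {self.b:g}, {self.c:g}, "
                f"{self.alpha:g}, {self.beta:g}, {self.gamma:g}, {sg})")


@dataclass
class RigidGroup:
    """A rigid body: a set of atoms moving with 6 generalized DOF.

    Rotations are taken about the group origin ``origin`` (the mass-weighted
    mean position).
    """

    elements: np.ndarray          # (n,) str
    xyz: np.ndarray               # (n, 3) Cartesian, Angstrom
    occupancies: np.ndarray       # (n,)
    b_iso: np.ndarray             # (n,) isotropic B, A^2
    residue_ids: np.ndarray       # (n,) int
    chain_id: str = "A"
    operator_index: int = 0       # generating symmetry operator
    occupancy_weighting: bool = False
    masses: np.ndarray = field(default=None, repr=False)
    origin: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.b_iso = np.asarray(self.b_iso, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.masses is None:
            m = np.array([ATOMIC_MASSES.get(str(e).upper(), 12.011)
                          for e in self.elements])
            if self.occupancy_weighting:
                m = m * self.occupancies
            self.masses = m
        if self.origin is None:
            self.origin = np.average(self.xyz, axis=0, weights=self.masses)

    @property
    def n_atoms(self):
        return len(self.xyz)

    @property
    def total_mass(self):
        return float(self.masses.sum())

    @property
    def inertia_tensor(self):
        """3x3 inertia tensor about the group origin."""
        x = self.xyz - self.origin
        r2 = np.einsum("ij,ij->i", x, x)
        I = np.einsum("i,ij,ik->jk", self.masses, x, x)
        return np.eye(3) * np.einsum("i,i->", self.masses, r2) - I


class RigidGroupCrystal:
    """A full unit cell of rigid groups with symmetry bookkeeping."""

    def __init__(self, geometry: UnitCellGeometry, groups: list[RigidGroup],
                 asu_group_indices=None):
        self.geometry = geometry
        self.groups = list(groups)
        # indices of the groups generated by the identity operator
        if asu_group_indices is None:
            asu_group_indices = [i for i, g in enumerate(self.groups)
                                 if g.operator_index == 0]
        self.asu_group_indices = list(asu_group_indices)

    @property
    def n_groups(self):
        return len(self.groups)

    @property
    def n_atoms(self):
        return sum(g.n_atoms for g in self.groups)

    def all_atoms(self):
        """Concatenate coordinates over groups; returns (xyz, group_index)."""
        xyz = np.concatenate([g.xyz for g in self.groups])
        gi = np.concatenate([np.full(g.n_atoms, i) for i, g in enumerate(self.groups)])
        return xyz, gi

    def __repr__(self):
        return f"RigidGroupCrystal({self.n_groups} groups, {self.n_atoms} atoms)"


@dataclass
class SpringContact:
    """An inter-group atom pair within the contact cutoff.

    The contact connects atom ``atom_i`` of group ``group_i`` in the reference
    cell to atom ``atom_j`` of group ``group_j`` in the cell displaced by
    ``offset`` (integer cell triplet). Stored once per unordered pair; the
    Hessian assembly adds both directions.
    """

    group_i: int
    atom_i: int
    group_j: int
    atom_j: int
    offset: tuple
    vector: np.ndarray   # Cartesian, from atom_i to atom_j (+offset)
    length: float
    interface_id: int = -1
    residue_pair_id: int = -1
    parameter_id: int = -1


@dataclass
class SpringParameterSet:
    """Spring constants shared across symmetry-enforced parameter groups.

    ``gamma_g`` and ``gamma_p`` are arrays of length ``n_groups`` holding the
    Gaussian and parallel stiffness of each parameter group, in units of
    kT/A^2. ``level`` is one of ``global``, ``interface``, ``residue``.
    """

    level: str
    n_groups: int
    gamma_g: np.ndarray = None
    gamma_p: np.ndarray = None

    def __post_init__(self):
        if self.gamma_g is None:
            self.gamma_g = np.zeros(self.n_groups)
        if self.gamma_p is None:
            self.gamma_p = np.zeros(self.n_groups)
        self.gamma_g = np.asarray(self.gamma_g, dtype=float)
        self.gamma_p = np.asarray(self.gamma_p, dtype=float)
        if np.any(self.gamma_g < 0) or np.any(self.gamma_p < 0):
            raise ValueError("spring constants must be non-negative")

    def per_contact(self, contacts):
        """Return per-contact (gamma_g, gamma_p) arrays."""
        ids = np.array([c.parameter_id for c in contacts])
        return self.gamma_g[ids], self.gamma_p[ids]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def expand_to_unit_cell(asu_atoms, geometry, exclude_hydrogen=True,
                        exclude_solvent=True, occupancy_weighting=False):
    """Expand an asymmetric-unit model to a unit cell of rigid groups.

    Parameters
    ----------
    asu_atoms : dict
        Arrays ``element``, ``xyz`` (Cartesian A), ``occupancy``, ``b_iso``,
        ``residue_id``, ``chain_id`` describing the ASU.
    geometry : UnitCellGeometry
    exclude_hydrogen, exclude_solvent : bool
        Filter flags applied before group construction.
    occupancy_weighting : bool
        If True, atomic masses are weighted by occupancy.

    Returns
    -------
    RigidGroupCrystal
        One rigid group per (chain, symmetry operator) image.
    """
    elem = np.asarray(asu_atoms["element"], dtype=object)
    xyz = np.asarray(asu_atoms["xyz"], dtype=float)
    occ = np.asarray(asu_atoms.get("occupancy", np.ones(len(xyz))), dtype=float)
    biso = np.asarray(asu_atoms.get("b_iso", np.zeros(len(xyz))), dtype=float)
    resid = np.asarray(asu_atoms.get("residue_id", np.zeros(len(xyz), dtype=int)))
    resname = np.asarray(asu_atoms.get("residue_name", np.array(["UNK"] * len(xyz))),
                         dtype=object)
    chain = np.asarray(asu_atoms.get("chain_id", np.array(["A"] * len(xyz))),
                       dtype=object)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("ASU coordinates contain non-finite values")

    keep = np.ones(len(xyz), dtype=bool)
    if exclude_hydrogen:
        keep &= np.array([str(e).upper() not in ("H", "D") for e in elem])
    if exclude_solvent:
        keep &= np.array([str(r).upper() not in SOLVENT_RESIDUES for r in resname])
    if not np.any(keep):
        raise ValueError("no atoms remain in the ASU after filtering")

    elem, xyz, occ, biso = elem[keep], xyz[keep], occ[keep], biso[keep]
    resid, chain = resid[keep], chain[keep]

    groups = []
    chains = sorted(set(chain))
    for iop in range(geometry.n_operators):
        for ch in chains:
            sel = chain == ch
            groups.append(RigidGroup(
                elements=elem[sel],
                xyz=geometry.apply_operator(iop, xyz[sel]),
                occupancies=occ[sel],
                b_iso=biso[sel],
                residue_ids=resid[sel],
                chain_id=str(ch),
                operator_index=iop,
                occupancy_weighting=occupancy_weighting,
            ))
    return RigidGroupCrystal(geometry, groups)


def find_contacts(crystal, cutoff=4.0):
    """Find all inter-group atom pairs within ``cutoff`` Angstrom.

    Pairs are searched between the reference unit cell and cells at integer
    offsets (range extended automatically when the cutoff exceeds a cell-face
    spacing). Intra-group pairs within the same cell are excluded. Each
    unordered pair is stored once: contacts to cells with lexicographically
    positive offsets, plus in-cell pairs with ``(group, atom)_i < (group,
    atom)_j``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    geom = crystal.geometry
    if cutoff > 0.5 * min(geom.a, geom.b, geom.c):
        raise ValueError("cutoff exceeds half the shortest cell edge; "
                         "periodic images would be ambiguous")
    xyz, gidx = crystal.all_atoms()
    # local atom index within each group
    local = np.concatenate([np.arange(g.n_atoms) for g in crystal.groups])

    # face spacings: distance between lattice planes normal to each cell face
    inv = np.linalg.inv(geom.orth)
    face = 1.0 / np.linalg.norm(inv, axis=1)
    nmax = np.maximum(1, np.ceil(cutoff / face).astype(int))

    tree0 = cKDTree(xyz)
    contacts = []
    offsets = [(n1, n2, n3)
               for n1 in range(-nmax[0], nmax[0] + 1)
               for n2 in range(-nmax[1], nmax[1] + 1)
               for n3 in range(-nmax[2], nmax[2] + 1)]
    for off in offsets:
        if off < (0, 0, 0):
            continue  # unordered storage: keep non-negative lexicographic offsets
        shift = geom.to_cartesian(np.array(off, dtype=float))
        tree1 = cKDTree(xyz + shift)
        pairs = tree0.query_ball_tree(tree1, cutoff)
        for i, js in enumerate(pairs):
            for j in js:
                if off == (0, 0, 0):
                    if i >= j or gidx[i] == gidx[j]:
                        continue
                vec = xyz[j] + shift - xyz[i]
                contacts.append(SpringContact(
                    group_i=int(gidx[i]), atom_i=int(local[i]),
                    group_j=int(gidx[j]), atom_j=int(local[j]),
                    offset=tuple(int(o) for o in off),
                    vector=vec, length=float(np.linalg.norm(vec)),
                ))
    return contacts


def _group_image_table(crystal):
    """For each (operator g, group kappa): the image group and lattice shift.

    Returns ``image[g][kappa] = (kappa2, shift)`` such that applying operator
    ``g`` to group ``kappa`` lands on group ``kappa2`` displaced by the
    integer lattice vector ``shift``.
    """
    geom = crystal.geometry
    ops = geom.operators
    # key groups by (chain, rotation, fractional translation mod 1)
    lookup = {}
    for k2, g in enumerate(crystal.groups):
        R, t = ops[g.operator_index]
        lookup[(g.chain_id, UnitCellGeometry._op_key(R, t))] = (k2, t)
    table = []
    for Rg, tg in ops:
        row = []
        for g in crystal.groups:
            Rk, tk = ops[g.operator_index]
            R, t = Rg @ Rk, Rg @ tk + tg
            k2, t2 = lookup[(g.chain_id, UnitCellGeometry._op_key(R, t))]
            shift = np.round(t - t2).astype(int)
            row.append((k2, shift))
        table.append(row)
    return table


def _canonical_pair(ki, kj, off):
    """Canonical orientation of an unordered (group_i, group_j, offset) key."""
    a = (ki, kj, off)
    b = (kj, ki, tuple(-o for o in off))
    return (a, False) if a <= b else (b, True)


def group_springs(contacts, crystal, level="interface"):
    """Assign symmetry-enforced parameter groups to contacts (in place).

    Two contacts related by a space-group operator share a parameter group.
    ``level`` controls the refinement granularity:

    * ``global`` — one group for all springs;
    * ``interface`` — one group per unique protein-protein interface, i.e.
      per orbit of (group, group, cell offset) under the space group;
    * ``residue`` — per residue-residue interaction within an interface.

    Returns a :class:`SpringParameterSet` skeleton with zero stiffness, and
    fills ``interface_id``, ``residue_pair_id``, ``parameter_id`` on each
    contact.
    """
    if not contacts:
        raise ValueError("contact list is empty")
    if level not in ("global", "interface", "residue"):
        raise ValueError(f"unknown grouping level: {level!r}")

    table = _group_image_table(crystal)
    ops = crystal.geometry.operators

    # orbit of each unordered (ki, kj, offset) triple under the space group
    interface_of = {}
    n_interfaces = 0
    for c in contacts:
        key, _ = _canonical_pair(c.group_i, c.group_j, c.offset)
        if key in interface_of:
            continue
        orbit = set()
        for g, (Rg, _) in enumerate(ops):
            k2i, si = table[g][key[0]]
            k2j, sj = table[g][key[1]]
            off2 = Rg @ np.array(key[2]) + sj - si
            k, _ = _canonical_pair(k2i, k2j, tuple(int(o) for o in off2))
            orbit.add(k)
        for k in orbit:
            interface_of[k] = n_interfaces
        n_interfaces += 1

    residue_of = {}
    for c in contacts:
        key, swapped = _canonical_pair(c.group_i, c.group_j, c.offset)
        c.interface_id = interface_of[key]
        gi = crystal.groups[c.group_i]
        gj = crystal.groups[c.group_j]
        ri = int(gi.residue_ids[c.atom_i])
        rj = int(gj.residue_ids[c.atom_j])
        rkey = (c.interface_id, (rj, ri) if swapped else (ri, rj))
        if rkey not in residue_of:
            residue_of[rkey] = len(residue_of)
        c.residue_pair_id = residue_of[rkey]

    if level == "global":
        n_params = 1
        for c in contacts:
            c.parameter_id = 0
    elif level == "interface":
        n_params = n_interfaces
        for c in contacts:
            c.parameter_id = c.interface_id
    else:
        n_params = len(residue_of)
        for c in contacts:
            c.parameter_id = c.residue_pair_id
    return SpringParameterSet(level=level, n_groups=n_params)


def force_constant_block(contact, gamma_g, gamma_p):
    """3x3 force-constant matrix of a hybrid spring.

    ``gamma_g * I + gamma_p * (u u^T)`` with ``u`` the unit contact vector:
    the Gaussian term restores any displacement direction equally, while the
    parallel term only restores the component along the contact.
    """
    if gamma_g < 0 or gamma_p < 0:
        raise ValueError("spring constants must be non-negative")
    if contact.length <= 0:
        raise ValueError("contact has zero length")
    u = contact.vector / contact.length
    return gamma_g * np.eye(3) + gamma_p * np.outer(u, u)


def contacts_to_records(contacts):
    """Serialize contacts to plain dicts (for JSON/tabular export)."""
    return [
        {
            "group_i": c.group_i, "atom_i": c.atom_i,
            "group_j": c.group_j, "atom_j": c.atom_j,
            "offset": list(c.offset), "length": c.length,
            "interface_id": c.interface_id,
            "residue_pair_id": c.residue_pair_id,
            "parameter_id": c.parameter_id,
        }
        for c in contacts
    ]


def write_spring_network(path, contacts, params=None):
    """Write the spring network (and optional parameters) as JSON."""
    payload = {"contacts": contacts_to_records(contacts)}
    if params is not None:
        payload["parameters"] = {
            "level": params.level,
            "gamma_g": params.gamma_g.tolist(),
            "gamma_p": params.gamma_p.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
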