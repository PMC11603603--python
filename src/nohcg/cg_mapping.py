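"""No-hydrogen coarse-graining: topology, bead typing, mapping and force aggregation.

The coarse-grained (CG) representation keeps one bead per heavy atom and deletes
hydrogens (and, implicitly, solvent).  Each bead inherits

* the coordinates of its heavy atom (the map is a pure selection),
* the aggregated force — the force on the heavy atom plus the forces on all
  hydrogens bonded to it,
* an integer embedding derived from ``(element, number of bonded hydrogens)``;
  over the 20 standard amino acids at standard protonation exactly 12 such
  classes occur,
* a mass equal to the heavy-atom mass plus the masses of its hydrogens.

Force aggregation conserves the total force exactly: summing bead forces equals
summing all-atom forces, because the hydrogen sets partition the hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ELEMENT_MASSES, PROTEIN_ELEMENTS

__all__ = [
    "TopologyError",
    "BeadTypingError",
    "Atom",
    "Topology",
    "AllAtomFrame",
    "CGFrame",
    "BeadTypeTable",
    "CGMap",
    "build_noh_map",
    "map_coordinates",
    "aggregate_forces",
    "enumerate_bead_types",
    "bead_masses",
    "residue_topology",
    "standard_residue_names",
    "topology_from_pdb",
    "infer_hydrogen_bonds",
]


class TopologyError(ValueError):
    """Raised for malformed topologies (bad bond indices, unbonded hydrogens...)."""


class BeadTypingError(ValueError):
    """Raised when an ``(element, n_H)`` pair has no entry in the bead-type table."""


# ---------------------------------------------------------------------------
# Topology and frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of the fine-grained system."""

    element: str
    res_index: int
    res_name: str
    name: str


@dataclass
class Topology:
    """All-atom connectivity: atoms plus a bond list (0-based index pairs).

    Elements are restricted to {C, N, O, S, H}; anything else is rejected so
    that bead typing stays within the protein alphabet.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a in self.atoms:
            if a.element not in PROTEIN_ELEMENTS:
                raise TopologyError(
                    f"element {a.element!r} (atom {a.name!r}) is outside the "
                    f"protein alphabet {sorted(PROTEIN_ELEMENTS)}"
                )
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i}, {j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def hydrogen_attachments(self) -> dict[int, int]:
        """Map hydrogen index -> index of its unique bonded heavy atom.

        Raises :class:`TopologyError` if any hydrogen has zero or several
        bonded heavy atoms.
        """
        partners: dict[int, list[int]] = {
            i: [] for i, a in enumerate(self.atoms) if a.element == "H"
        }
        for i, j in self.bonds:
            ei, ej = self.atoms[i].element, self.atoms[j].element
            if ei == "H" and ej != "H":
                partners[i].append(j)
            elif ej == "H" and ei != "H":
                partners[j].append(i)
            elif ei == "H" and ej == "H":
                raise TopologyError(f"hydrogen-hydrogen bond ({i}, {j})")
        out = {}
        for h, heavy in partners.items():
            if len(heavy) != 1:
                raise TopologyError(
                    f"hydrogen {h} ({self.atoms[h].name!r}) has {len(heavy)} bonded "
                    "heavy atoms; exactly one is required"
                )
            out[h] = heavy[0]
        return out


@dataclass
class AllAtomFrame:
    """Coordinates (A) and optionally forces (kcal/mol/A) of one conformation."""

    coords: np.ndarray
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coords.shape:
                raise ValueError(
                    f"forces shape {self.forces.shape} != coords shape {self.coords.shape}"
                )
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("forces contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class CGFrame:
    """One coarse-grained conformation: bead coordinates, types and forces."""

    coords: np.ndarray
    bead_types: np.ndarray
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.bead_types = np.asarray(self.bead_types, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.bead_types.shape != (self.coords.shape[0],):
            raise ValueError("bead_types length must equal number of beads")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coords.shape:
                raise ValueError("forces shape must equal coords shape")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# Bead types
# ---------------------------------------------------------------------------

@dataclass
class BeadTypeTable:
    """Injective mapping ``(element, n_bonded_H) -> integer id`` plus masses.

    Ids are contiguous from 0, assigned by sorting on ``(element, n_H)``.  In
    strict mode, pairs outside the table raise; in permissive mode
    :func:`build_noh_map` can extend a copy on the fly (useful for terminal or
    unusual protonation variants on nonstandard inputs).
    """

    entries: dict[tuple[str, int], int]
    element_masses: dict[str, float] = field(default_factory=lambda: dict(ELEMENT_MASSES))

    def __post_init__(self) -> None:
        ids = sorted(self.entries.values())
        if ids != list(range(len(ids))):
            raise ValueError("bead-type ids must be contiguous from 0 and injective")

    @property
    def n_types(self) -> int:
        return len(self.entries)

    def type_id(self, element: str, n_h: int) -> int:
        try:
            return self.entries[(element, n_h)]
        except KeyError:
            raise BeadTypingError(
                f"no bead type for (element={element!r}, n_H={n_h}); "
                f"known pairs: {sorted(self.entries)}"
            ) from None

    def bead_mass(self, element: str, n_h: int) -> float:
        """Combined mass of the heavy atom and its bonded hydrogens (a.m.u.)."""
        return self.element_masses[element] + n_h * self.element_masses["H"]

    def label(self, type_id: int) -> str:
        """Human-readable label like ``'C3'`` for a type id."""
        for (el, n_h), tid in self.entries.items():
            if tid == type_id:
                return f"{el}{n_h}"
        raise KeyError(type_id)

    @classmethod
    def standard_protein(cls) -> "BeadTypeTable":
        """The canonical table enumerated over the 20 standard amino acids (12 types)."""
        residues = [residue_topology(name) for name in standard_residue_names()]
        return enumerate_bead_types(residues)


# ---------------------------------------------------------------------------
# The CG map
# ---------------------------------------------------------------------------

@dataclass
class CGMap:
    """The linear no-hydrogen map: heavy-atom selection plus hydrogen bookkeeping.

    ``heavy_indices`` are strictly increasing all-atom indices (bead order is
    ascending heavy-atom index); ``hydrogen_sets[i]`` lists the all-atom indices
    of hydrogens bonded to bead ``i``.  The hydrogen sets are pairwise disjoint
    and jointly cover every hydrogen, which is what makes force aggregation
    exactly conservative.
    """

    heavy_indices: np.ndarray
    hydrogen_sets: list[list[int]]
    bead_types: np.ndarray
    bead_masses: np.ndarray

    def __post_init__(self) -> None:
        self.heavy_indices = np.asarray(self.heavy_indices, dtype=np.int64)
        self.bead_types = np.asarray(self.bead_types, dtype=np.int64)
        self.bead_masses = np.asarray(self.bead_masses, dtype=float)
        if len(self.heavy_indices) and np.any(np.diff(self.heavy_indices) <= 0):
            raise ValueError("heavy_indices must be strictly increasing")
        if not (
            len(self.hydrogen_sets)
            == len(self.bead_types)
            == len(self.bead_masses)
            == len(self.heavy_indices)
        ):
            raise ValueError("per-bead arrays must have equal length")
        if np.any(self.bead_masses <= 0):
            raise ValueError("bead masses must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.heavy_indices)


def build_noh_map(
    topology: Topology,
    table: BeadTypeTable,
    strict_types: bool = True,
) -> CGMap:
    """Build the no-hydrogen CG map from an all-atom topology.

    One bead per heavy atom, in ascending all-atom order.  Each bead records
    the hydrogens bonded to its heavy atom, its ``(element, n_H)`` bead type
    from *table*, and its aggregated mass.

    With ``strict_types=False``, pairs absent from *table* extend a private
    copy of the table (ids appended in order of first occurrence) instead of
    raising; the extended table is attached as ``map.type_table``.
    """
    attachments = topology.hydrogen_attachments()
    heavy = [i for i, a in enumerate(topology.atoms) if a.element != "H"]
    h_sets: dict[int, list[int]] = {i: [] for i in heavy}
    for h, parent in sorted(attachments.items()):
        h_sets[parent].append(h)

    entries = dict(table.entries)
    types, masses = [], []
    for i in heavy:
        el = topology.atoms[i].element
        n_h = len(h_sets[i])
        key = (el, n_h)
        if key not in entries:
            if strict_types:
                raise BeadTypingError(
                    f"no bead type for (element={el!r}, n_H={n_h}) at atom "
                    f"{topology.atoms[i].name!r}; known pairs: {sorted(entries)}"
                )
            entries[key] = len(entries)
        types.append(entries[key])
        masses.append(table.bead_mass(el, n_h))

    cg_map = CGMap(
        heavy_indices=np.array(heavy, dtype=np.int64),
        hydrogen_sets=[h_sets[i] for i in heavy],
        bead_types=np.array(types, dtype=np.int64),
        bead_masses=np.array(masses, dtype=float),
    )
    cg_map.type_table = (
        table if entries == table.entries
        else BeadTypeTable(entries, dict(table.element_masses))
    )
    return cg_map


def map_coordinates(frame: AllAtomFrame, cg_map: CGMap) -> CGFrame:
    """Apply the selection map: bead coordinates are the heavy-atom coordinates."""
    _check_frame(frame, cg_map)
    return CGFrame(
        coords=frame.coords[cg_map.heavy_indices].copy(),
        bead_types=cg_map.bead_types.copy(),
    )


def aggregate_forces(frame: AllAtomFrame, cg_map: CGMap) -> CGFrame:
    """Map coordinates and aggregate forces onto beads.

    The force on bead *i* is the force on its heavy atom plus the sum of the
    forces on the hydrogens bonded to it.  Because the hydrogen sets partition
    the hydrogens, the total force is conserved exactly.
    """
    if frame.forces is None:
        raise ValueError("frame has no forces to aggregate")
    _check_frame(frame, cg_map)
    bead_forces = frame.forces[cg_map.heavy_indices].copy()
    for i, h_set in enumerate(cg_map.hydrogen_sets):
        if h_set:
            bead_forces[i] += frame.forces[h_set].sum(axis=0)
    return CGFrame(
        coords=frame.coords[cg_map.heavy_indices].copy(),
        bead_types=cg_map.bead_types.copy(),
        forces=bead_forces,
    )


def _check_frame(frame: AllAtomFrame, cg_map: CGMap) -> None:
    n_mapped = cg_map.n_beads + sum(len(s) for s in cg_map.hydrogen_sets)
    if frame.n_atoms != n_mapped:
        raise ValueError(
            f"frame has {frame.n_atoms} atoms but the map covers {n_mapped}"
        )


def bead_masses(cg_map: CGMap, table: BeadTypeTable) -> np.ndarray:
    """Per-bead masses: heavy-atom mass plus bonded-hydrogen masses (a.m.u.)."""
    inverse = {tid: key for key, tid in getattr(cg_map, "type_table", table).entries.items()}
    return np.array(
        [table.bead_mass(*inverse[t]) for t in cg_map.bead_types], dtype=float
    )


# ---------------------------------------------------------------------------
# Bead-type enumeration over residue topologies
# ---------------------------------------------------------------------------

def enumerate_bead_types(residue_set: list[Topology]) -> BeadTypeTable:
    """Enumerate the distinct ``(element, n_bonded_H)`` pairs realized.

    Ids are assigned deterministically by sorting on element symbol then
    hydrogen count.  Over the 20 standard amino acids at standard protonation
    this yields 12 classes: C0-C3, N0-N3, O0, O1, S0, S1.
    """
    pairs: set[tuple[str, int]] = set()
    for topo in residue_set:
        attachments = topo.hydrogen_attachments()
        counts: dict[int, int] = {}
        for _, parent in attachments.items():
            counts[parent] = counts.get(parent, 0) + 1
        for i, atom in enumerate(topo.atoms):
            if atom.element != "H":
                pairs.add((atom.element, counts.get(i, 0)))
    entries = {pair: idx for idx, pair in enumerate(sorted(pairs))}
    return BeadTypeTable(entries)


# ---------------------------------------------------------------------------
# Standard residue templates
# ---------------------------------------------------------------------------
# Heavy atoms of the 20 standard amino acids (mid-chain form, standard
# protonation at pH 7: ASP/GLU deprotonated, LYS/ARG protonated, HIS neutral
# ND1 tautomer) as (atom name, element, number of bonded hydrogens).

_BACKBONE = [("N", "N", 1), ("CA", "C", 1), ("C", "C", 0), ("O", "O", 0)]

_SIDE_CHAINS: dict[str, list[tuple[str, str, int]]] = {
    "ALA": [("CB", "C", 3)],
    "ARG": [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2), ("NE", "N", 1),
            ("CZ", "C", 0), ("NH1", "N", 2), ("NH2", "N", 2)],
    "ASN": [("CB", "C", 2), ("CG", "C", 0), ("OD1", "O", 0), ("ND2", "N", 2)],
    "ASP": [("CB", "C", 2), ("CG", "C", 0), ("OD1", "O", 0), ("OD2", "O", 0)],
    "CYS": [("CB", "C", 2), ("SG", "S", 1)],
    "GLN": [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 0), ("OE1", "O", 0),
            ("NE2", "N", 2)],
    "GLU": [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 0), ("OE1", "O", 0),
            ("OE2", "O", 0)],
    "GLY": [],
    "HIS": [("CB", "C", 2), ("CG", "C", 0), ("ND1", "N", 1), ("CD2", "C", 1),
            ("CE1", "C", 1), ("NE2", "N", 0)],
    "ILE": [("CB", "C", 1), ("CG1", "C", 2), ("CG2", "C", 3), ("CD1", "C", 3)],
    "LEU": [("CB", "C", 2), ("CG", "C", 1), ("CD1", "C", 3), ("CD2", "C", 3)],
    "LYS": [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2), ("CE", "C", 2),
            ("NZ", "N", 3)],
    "MET": [("CB", "C", 2), ("CG", "C", 2), ("SD", "S", 0), ("CE", "C", 3)],
    "PHE": [("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("CD2", "C", 1),
            ("CE1", "C", 1), ("CE2", "C", 1), ("CZ", "C", 1)],
    "PRO": [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2)],
    "SER": [("CB", "C", 2), ("OG", "O", 1)],
    "THR": [("CB", "C", 1), ("OG1", "O", 1), ("CG2", "C", 3)],
    "TRP": [("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("CD2", "C", 0),
            ("NE1", "N", 1), ("CE2", "C", 0), ("CE3", "C", 1), ("CZ2", "C", 1),
            ("CZ3", "C", 1), ("CH2", "C", 1)],
    "TYR": [("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("CD2", "C", 1),
            ("CE1", "C", 1), ("CE2", "C", 1), ("CZ", "C", 0), ("OH", "O", 1)],
    "VAL": [("CB", "C", 1), ("CG1", "C", 3), ("CG2", "C", 3)],
}


def standard_residue_names() -> list[str]:
    """The 20 standard amino-acid three-letter codes."""
    return sorted(_SIDE_CHAINS)


def residue_topology(res_name: str, res_index: int = 0) -> Topology:
    """Build a single-residue topology with explicit hydrogens.

    Proline's backbone nitrogen carries no hydrogen; glycine's CA carries two.
    Hydrogens are named after their heavy atom (``HCB1`` etc.) and bonded to it.
    """
    name = res_name.upper()
    if name not in _SIDE_CHAINS:
        raise KeyError(f"unknown residue {res_name!r}")
    heavy = [list(t) for t in _BACKBONE] + [list(t) for t in _SIDE_CHAINS[name]]
    if name == "PRO":
        heavy[0][2] = 0  # backbone N bonded into the ring, no amide H
    if name == "GLY":
        heavy[1][2] = 2  # no side chain: two HA
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    for atom_name, element, n_h in heavy:
        parent = len(atoms)
        atoms.append(Atom(element, res_index, name, atom_name))
        for k in range(n_h):
            atoms.append(Atom("H", res_index, name, f"H{atom_name}{k + 1}"))
            bonds.append((parent, len(atoms) - 1))
    return Topology(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def infer_hydrogen_bonds(
    elements: list[str], coords: np.ndarray, cutoff: float = 1.2
) -> list[tuple[int, int]]:
    """Attach each hydrogen to its nearest heavy atom within *cutoff* (A).

    Used when a structure file carries no connectivity; 1.2 A comfortably
    covers all covalent X-H bond lengths (0.96-1.09 A) while excluding
    hydrogen-bond contacts (>= 1.5 A).
    """
    coords = np.asarray(coords, dtype=float)
    heavy_idx = np.array([i for i, e in enumerate(elements) if e != "H"], dtype=int)
    if heavy_idx.size == 0:
        raise TopologyError("structure contains no heavy atoms")
    bonds = []
    for h in (i for i, e in enumerate(elements) if e == "H"):
        d = np.linalg.norm(coords[heavy_idx] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] > cutoff:
            raise TopologyError(
                f"hydrogen {h} has no heavy atom within {cutoff} A (nearest {d[j]:.2f} A)"
            )
        bonds.append((int(heavy_idx[j]), h))
    return bonds


def topology_from_pdb(path) -> tuple[Topology, AllAtomFrame]:
    """Read a PDB file into a :class:`Topology` and coordinate frame.

    CONECT-derived bonds are used when present; otherwise hydrogen attachment
    is inferred from distances (see :func:`infer_hydrogen_bonds`).  Water and
    non-protein elements are rejected.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    structure = pdb_file.get_structure(model=1)
    elements = [str(e).capitalize() if len(str(e)) > 1 else str(e).upper()
                for e in structure.element]
    elements = [e if e != "h" else "H" for e in elements]
    atoms = [
        Atom(
            element=elements[i],
            res_index=int(structure.res_id[i]),
            res_name=str(structure.res_name[i]),
            name=str(structure.atom_name[i]),
        )
        for i in range(structure.array_length())
    ]
    coords = np.asarray(structure.coord, dtype=float)
    bonds: list[tuple[int, int]] = []
    if structure.bonds is not None and structure.bonds.get_bond_count() > 0:
        bonds = [(int(i), int(j)) for i, j, _ in structure.bonds.as_array()]
    else:
        bonds = infer_hydrogen_bonds(elements, coords)
    return Topology(atoms=atoms, bonds=bonds), AllAtomFrame(coords=coords)
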