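"""All-atom / coarse-grained structure containers and PDB input-output.

The coarse-grained (CG) representation uses five beads per nucleotide:

* ``P``  — placed on the phosphorus atom; summarizes the phosphate group.
* ``S``  — placed on C4'; summarizes the ribose.
* ``B1`` — mass-weighted center of the Watson-Crick edge of the base.
* ``B2`` — mass-weighted center of the Hoogsteen (purine) / C-H (pyrimidine) edge.
* ``B3`` — mass-weighted center of the sugar edge.

The three base groups partition the heavy atoms of each base so that the three
interacting edges of the nucleobase are preserved.  Hydrogens are ignored
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    InvalidCoordinateError,
    MappingError,
    UnsupportedResidueError,
)

# ---------------------------------------------------------------------------
# Atom tables
# ---------------------------------------------------------------------------

#: Heavy-atom masses in g/mol; hydrogens are ignored by convention.
ATOMIC_MASSES: Dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
}

#: Accepted residue-name aliases -> canonical one-letter base.
RESIDUE_ALIASES: Dict[str, str] = {
    "A": "A", "RA": "A", "ADE": "A", "A3": "A", "A5": "A",
    "C": "C", "RC": "C", "CYT": "C", "C3": "C", "C5": "C",
    "G": "G", "RG": "G", "GUA": "G", "G3": "G", "G5": "G",
    "U": "U", "RU": "U", "URA": "U", "URI": "U", "U3": "U", "U5": "U",
}

#: Base heavy-atom group partition, version 1.  Three groups per base keep the
#: three-edge semantics: group 1 = Watson-Crick edge, group 2 = Hoogsteen edge
#: (purines) / C5-C4 edge (pyrimidines), group 3 = sugar edge.  The groups are
#: disjoint and their union is the full heavy-atom set of the base.
BASE_GROUPS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...], Tuple[str, ...]]] = {
    "A": (("N1", "C2", "C6", "N6"), ("N7", "C8", "N9"), ("N3", "C4", "C5")),
    "G": (("N1", "C2", "N2", "C6", "O6"), ("N7", "C8", "N9"), ("N3", "C4", "C5")),
    "C": (("N3", "C2", "O2"), ("C4", "N4", "C5"), ("C6", "N1")),
    "U": (("N3", "C2", "O2"), ("C4", "O4", "C5"), ("C6", "N1")),
}

#: Atoms whose mass is accounted to the P bead (when present).
P_GROUP = ("P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'")
#: Atoms whose mass is accounted to the S bead (when present).
S_GROUP = ("C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

BEAD_KINDS = ("P", "S", "B1", "B2", "B3")


def _element_of(atom_name: str) -> str:
    """Infer the element from a PDB atom name (heavy atoms only)."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper()


def atom_mass(atom_name: str) -> float:
    elem = _element_of(atom_name)
    return ATOMIC_MASSES.get(elem, 0.0)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    number: int
    base: str  # one of A/C/G/U
    atoms: Dict[str, np.ndarray]  # atom name -> xyz (Å)


@dataclass
class AllAtomStructure:
    """Ordered list of RNA residues with named heavy-atom coordinates."""

    residues: List[Residue]
    chain_id: str = "A"

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AllAtomStructure":
        new = []
        for r in self.residues:
            atoms = {n: rotation @ p + translation for n, p in r.atoms.items()}
            new.append(Residue(r.number, r.base, atoms))
        return AllAtomStructure(new, self.chain_id)


@dataclass
class CGBead:
    kind: str  # P, S, B1, B2, B3
    position: np.ndarray
    nt_index: int  # 1-based
    mass: float


@dataclass
class CGChain:
    """Five-bead-per-nucleotide coarse-grained chain.

    Beads are stored flat in the fixed order P, S, B1, B2, B3 per nucleotide;
    ``coords`` has shape (5*N, 3) and ``masses`` shape (5*N,).  ``circular``
    marks whether the backbone closes between nucleotide N and nucleotide 1
    (the back-splicing junction of a circular RNA).
    """

    sequence: str
    coords: np.ndarray
    masses: np.ndarray
    circular: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.sequence)
        if self.coords.shape != (5 * n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with {n} nt "
                f"(expected {(5 * n, 3)})"
            )
        if self.masses.shape != (5 * n,):
            raise ValueError("masses shape inconsistent with bead count")
        if np.any(self.masses <= 0):
            raise ValueError("bead masses must be positive")

    @property
    def n_nt(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return 5 * len(self.sequence)

    @staticmethod
    def bead_index(nt_index: int, kind: str) -> int:
        """Flat bead index for 1-based nucleotide ``nt_index`` and bead kind."""
        return 5 * (nt_index - 1) + BEAD_KINDS.index(kind)

    @property
    def beads(self) -> List[CGBead]:
        out = []
        for i in range(self.n_nt):
            for k, kind in enumerate(BEAD_KINDS):
                idx = 5 * i + k
                out.append(CGBead(kind, self.coords[idx], i + 1, float(self.masses[idx])))
        return out

    def with_coords(self, coords: np.ndarray) -> "CGChain":
        return CGChain(self.sequence, np.array(coords, dtype=float),
                       self.masses.copy(), self.circular)

    def copy(self) -> "CGChain":
        return self.with_coords(self.coords.copy())

    def end_separation(self) -> float:
        """Distance (Å) between bead P of nt 1 and bead S of nt N."""
        p1 = self.coords[self.bead_index(1, "P")]
        sn = self.coords[self.bead_index(self.n_nt, "S")]
        return float(np.linalg.norm(p1 - sn))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb(text: str) -> AllAtomStructure:
    """Parse fixed-column PDB ``ATOM`` records into an :class:`AllAtomStructure`.

    Hydrogens are dropped.  Alternate locations keep the highest-occupancy
    copy; insertion codes are rejected.  Residue names must be standard RNA
    (A/C/G/U or common aliases).
    """
    # (resnum) -> base, atom name -> (occupancy, altloc, xyz)
    residues: Dict[int, Residue] = {}
    best: Dict[Tuple[int, str], Tuple[float, str]] = {}
    chain_id = "A"
    n_atom_records = 0
    order: List[int] = []

    for line in text.splitlines():
        if not line.startswith("ATOM") and not line.startswith("HETATM"):
            continue
        if len(line) < 54:
            raise FormatError(f"truncated ATOM record: {line!r}")
        n_atom_records += 1
        atom_name = line[12:16].strip()
        altloc = line[16:17]
        res_name = line[17:20].strip().upper()
        chain_id = line[21:22].strip() or "A"
        try:
            res_num = int(line[22:26])
        except ValueError as exc:
            raise FormatError(f"bad residue number in record: {line!r}") from exc
        icode = line[26:27]
        if icode.strip():
            raise FormatError(
                f"insertion code {icode!r} at residue {res_num} not supported"
            )
        if res_name not in RESIDUE_ALIASES:
            raise UnsupportedResidueError(
                f"residue {res_name!r} (number {res_num}) is not a standard ribonucleotide"
            )
        base = RESIDUE_ALIASES[res_name]
        elem = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not elem:
            elem = _element_of(atom_name)
        if elem == "H":
            continue
        try:
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            occ = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
        except ValueError as exc:
            raise FormatError(f"bad numeric field in record: {line!r}") from exc

        if res_num not in residues:
            residues[res_num] = Residue(res_num, base, {})
            order.append(res_num)
        elif residues[res_num].base != base:
            raise FormatError(f"residue {res_num} has conflicting residue names")

        key = (res_num, atom_name)
        if atom_name in residues[res_num].atoms:
            prev_occ, prev_alt = best[key]
            if altloc.strip() == "" and prev_alt.strip() == "":
                raise FormatError(
                    f"duplicate atom {atom_name!r} in residue {res_num}"
                )
            if occ > prev_occ:
                residues[res_num].atoms[atom_name] = xyz
                best[key] = (occ, altloc)
        else:
            residues[res_num].atoms[atom_name] = xyz
            best[key] = (occ, altloc)

    if n_atom_records == 0:
        raise EmptyInputError("no ATOM records found")
    if order != sorted(order):
        raise FormatError("residue numbers are not strictly increasing")
    return AllAtomStructure([residues[n] for n in order], chain_id)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom(serial: int, name: str, res_name: str, chain: str, res_num: int,
                 xyz: np.ndarray, element: str) -> str:
    if not np.all(np.isfinite(xyz)):
        raise InvalidCoordinateError(f"non-finite coordinate for atom {name!r}")
    for v in xyz:
        if v > 9999.999 or v < -999.999:
            raise InvalidCoordinateError(
                f"coordinate {v:.3f} does not fit the 8-column PDB field"
            )
    # Atom-name column convention: 1-2 char element names start in column 14.
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{res_name:>3s} {chain:1s}"
        f"{res_num:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def write_pdb(structure: Union[AllAtomStructure, CGChain]) -> str:
    """Render a structure as fixed-width PDB text (``ATOM``/``TER``/``END``).

    CG chains are emitted as pseudo-atoms named P, S, B1, B2, B3 with the
    residue name set to the base identity.
    """
    lines: List[str] = []
    serial = 1
    if isinstance(structure, CGChain):
        if structure.n_nt == 0:
            raise EmptyInputError("cannot write an empty chain")
        elements = {"P": "P", "S": "C", "B1": "N", "B2": "N", "B3": "N"}
        for i in range(structure.n_nt):
            base = structure.sequence[i]
            for k, kind in enumerate(BEAD_KINDS):
                xyz = structure.coords[5 * i + k]
                lines.append(_format_atom(serial, kind, base, "A", i + 1, xyz,
                                          elements[kind]))
                serial += 1
        lines.append(f"TER   {serial:>5d}      {structure.sequence[-1]:>3s} A"
                     f"{structure.n_nt:>4d}")
    else:
        if len(structure.residues) == 0:
            raise EmptyInputError("cannot write an empty structure")
        chain = structure.chain_id[:1] or "A"
        for res in structure.residues:
            for name, xyz in res.atoms.items():
                lines.append(_format_atom(serial, name, res.base, chain,
                                          res.number, xyz, _element_of(name)))
                serial += 1
        last = structure.residues[-1]
        lines.append(f"TER   {serial:>5d}      {last.base:>3s} {chain:1s}{last.number:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# All-atom -> CG mapping
# ---------------------------------------------------------------------------

def _group_center(res: Residue, group: Sequence[str], what: str) -> Tuple[np.ndarray, float]:
    """Mass-weighted center and total mass of an atom group (all atoms required)."""
    missing = [a for a in group if a not in res.atoms]
    if missing:
        raise MappingError(
            f"residue {res.number} ({res.base}) missing base atom(s) {missing} for {what}"
        )
    masses = np.array([atom_mass(a) for a in group])
    pos = np.array([res.atoms[a] for a in group])
    total = float(masses.sum())
    return (masses[:, None] * pos).sum(axis=0) / total, total


def _optional_group_mass(res: Residue, group: Sequence[str]) -> float:
    return float(sum(atom_mass(a) for a in group if a in res.atoms))


def map_to_cg(structure: AllAtomStructure, circular: bool = False) -> CGChain:
    """Map an all-atom RNA structure onto the five-bead CG representation.

    Bead P sits exactly on atom P (5'-terminal residues without a phosphate
    fall back to O5', then to an extrapolation past C5'); bead S sits exactly
    on C4'; B1/B2/B3 are mass-weighted centers of the three base edge groups.
    Bead masses are the summed heavy-atom masses of the groups they represent.
    """
    n = len(structure.residues)
    if n == 0:
        raise EmptyInputError("cannot map an empty structure")
    coords = np.zeros((5 * n, 3))
    masses = np.zeros(5 * n)
    for i, res in enumerate(structure.residues):
        if res.base not in BASE_GROUPS:
            raise UnsupportedResidueError(f"residue {res.number}: base {res.base!r}")
        # P bead
        if "P" in res.atoms:
            p_pos = res.atoms["P"]
        elif i == 0:
            if "O5'" in res.atoms:
                p_pos = res.atoms["O5'"]
            elif "C5'" in res.atoms and "C4'" in res.atoms:
                d = res.atoms["C5'"] - res.atoms["C4'"]
                p_pos = res.atoms["C5'"] + 1.44 * d / np.linalg.norm(d)
            else:
                raise MappingError(
                    f"residue {res.number}: no P, O5' or C5' to place the P bead"
                )
            warnings.warn(
                f"residue {res.number} lacks a 5'-phosphate; P bead placed from O5'/C5'",
                stacklevel=2,
            )
        else:
            raise MappingError(f"residue {res.number}: missing atom P")
        if "C4'" not in res.atoms:
            raise MappingError(f"residue {res.number}: missing atom C4'")

        p_mass = _optional_group_mass(res, P_GROUP) or ATOMIC_MASSES["P"]
        s_mass = _optional_group_mass(res, S_GROUP) or ATOMIC_MASSES["C"]
        coords[5 * i + 0] = p_pos
        masses[5 * i + 0] = p_mass
        coords[5 * i + 1] = res.atoms["C4'"]
        masses[5 * i + 1] = s_mass
        for g, group in enumerate(BASE_GROUPS[res.base]):
            center, gmass = _group_center(res, group, f"B{g + 1}")
            coords[5 * i + 2 + g] = center
            masses[5 * i + 2 + g] = gmass
    return CGChain(structure.sequence, coords, masses, circular)
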