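"""Structure I/O, bond perception, and rigid superposition.

Reads and writes PDB files (ATOM/HETATM/CONECT/TER/END), assigns molecule
roles (protein / ligand / cobinder / water / ion), perceives covalent bonds
from interatomic distances, and computes least-squares rigid superpositions
(Kabsch) so that search-zone coordinates defined in a reference frame are
meaningful for any input complex.

Conventions: coordinates in Å, serials 1-based as in the PDB format, the
first alternate-location conformer is kept, insertion codes are ignored with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger("abfekit")

ROLES = ("protein", "ligand", "cobinder", "water", "ion")

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM", "ACE", "NME",
}
_WATERS = {"HOH", "WAT", "TIP", "TIP3", "TP3", "SPC", "OPC", "T4E"}
_IONS = {"NA", "CL", "K", "MG", "CA2", "ZN", "NA+", "CL-", "K+", "BR", "IOD", "CS", "LI", "RB", "F"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable Structure."""


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``serial`` is the 1-based PDB serial; ``position`` is in Å.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered collection of atoms with roles and covalent bonds.

    ``roles`` maps each atom serial to one of :data:`ROLES`; ``bonds`` holds
    unordered serial pairs stored as sorted tuples. Multiple protein chains
    and cobinders are supported.
    """

    atoms: list[Atom]
    roles: dict[int, str] = field(default_factory=dict)
    bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials must be unique within a Structure")
        self._by_serial = {a.serial: a for a in self.atoms}
        for i, j in self.bonds:
            if i not in self._by_serial or j not in self._by_serial:
                raise ValueError(f"bond ({i}, {j}) references a nonexistent serial")

    # -- access helpers -------------------------------------------------
    def atom(self, serial: int) -> Atom:
        try:
            return self._by_serial[serial]
        except KeyError:
            raise KeyError(f"no atom with serial {serial}") from None

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self, serials: Sequence[int] | None = None) -> np.ndarray:
        if serials is None:
            return np.array([a.position for a in self.atoms])
        return np.array([self.atom(s).position for s in serials])

    def role(self, serial: int) -> str:
        return self.roles.get(serial, "ligand")

    def serials_with_role(self, role: str) -> list[int]:
        return [a.serial for a in self.atoms if self.role(a.serial) == role]

    def ligand_atoms(self, heavy_only: bool = False) -> list[Atom]:
        out = [a for a in self.atoms if self.role(a.serial) == "ligand"]
        if heavy_only:
            out = [a for a in out if not a.is_hydrogen]
        return out

    def neighbors(self, serial: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == serial:
                out.append(j)
            elif j == serial:
                out.append(i)
        return sorted(out)

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("cannot bond an atom to itself")
        self.atom(i), self.atom(j)
        self.bonds.add((min(i, j), max(i, j)))

    def with_positions(self, new_positions: np.ndarray) -> "Structure":
        """Copy of this structure with every atom position replaced (same order)."""
        if new_positions.shape != (len(self.atoms), 3):
            raise ValueError("position array shape mismatch")
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, new_positions)]
        return Structure(atoms=atoms, roles=dict(self.roles), bonds=set(self.bonds))


@dataclass(frozen=True)
class Superposition:
    """A rigid transform (rotation then translation) fitted by least squares."""

    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # Å
    rmsd: float               # Å over the fitted mapping
    atom_mapping: tuple[tuple[int, int], ...]  # (mobile serial, reference serial)

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3) or abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper 3x3 rotation matrix (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of positions."""
        return np.asarray(positions) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def _default_role(residue_name: str, is_hetatm: bool) -> str:
    name = residue_name.strip().upper()
    if name in _WATERS:
        return "water"
    if name in _IONS:
        return "ion"
    if name in _AMINO_ACIDS:
        return "protein"
    # HETATM that is not water defaults to ligand (BAT-style behaviour);
    # unknown ATOM residues are treated as protein (modified residues).
    return "ligand" if is_hetatm else "protein"


def assign_roles(
    structure: Structure,
    role_hints: Mapping[str, str] | None = None,
    hetatm_serials: Iterable[int] = (),
) -> None:
    """Assign a role to every atom, in place.

    ``role_hints`` keys are residue names (e.g. ``{"MOL": "ligand"}``) or
    chain selectors prefixed with ``chain:`` (e.g. ``{"chain:B": "cobinder"}``).
    Explicit hints win over the built-in defaults.
    """
    hints = dict(role_hints or {})
    for role in hints.values():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; must be one of {ROLES}")
    het = set(hetatm_serials)
    for atom in structure.atoms:
        role = hints.get(f"chain:{atom.chain_id}") or hints.get(atom.residue_name.strip())
        if role is None:
            role = _default_role(atom.residue_name, atom.serial in het)
        structure.roles[atom.serial] = role


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_conect(path: Path) -> set[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("CONECT"):
                continue
            fields = line[6:].rstrip("\n")
            try:
                serials = [int(fields[i:i + 5]) for i in range(0, len(fields.rstrip()), 5)]
            except ValueError:
                raise PDBParseError(f"{path}:{lineno}: malformed CONECT record: {line.rstrip()!r}")
            if len(serials) >= 2:
                first = serials[0]
                for other in serials[1:]:
                    bonds.add((min(first, other), max(first, other)))
    return bonds


def read_pdb(path: str | Path, role_hints: Mapping[str, str] | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Serials are preserved, CONECT records populate ``bonds``, roles come from
    ``role_hints`` with HETATM-not-water defaulting to ligand. Only the first
    alternate-location conformer is kept; insertion codes are ignored with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()

    hetatm_serials: set[int] = set()
    for lineno, line in enumerate(open(path), 1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except (ValueError, IndexError):
                raise PDBParseError(f"{path}:{lineno}: malformed coordinate columns: {line.rstrip()!r}")
            if line.startswith("HETATM"):
                try:
                    hetatm_serials.add(int(line[6:11]))
                except ValueError:
                    raise PDBParseError(f"{path}:{lineno}: malformed serial: {line.rstrip()!r}")

    atoms: list[Atom] = []
    warned_icode = False
    for model in st:
        for chain in model:
            for res in chain:
                if res.seqid.icode not in ("", " ") and not warned_icode:
                    logger.warning("%s: insertion codes present; they are ignored", path)
                    warned_icode = True
                for at in res:
                    element = at.element.name if at.element else ""
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        element=element,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hydrogen=(element.upper() in ("H", "D")),
                    ))
        break  # first model only

    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    structure = Structure(atoms=atoms, bonds=_parse_conect(path))
    assign_roles(structure, role_hints, hetatm_serials)
    return structure


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ATOM/HETATM, TER, CONECT and END records.

    Sufficient for fixtures and restraint visualisation: occupancy 1.00,
    B-factor 0.00, non-protein/water roles emitted as HETATM.
    """
    lines: list[str] = []
    for atom in structure.atoms:
        record = "ATOM  " if structure.role(atom.serial) in ("protein", "water") else "HETATM"
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"{record}{atom.serial:5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain_id[:1] or 'A'}{atom.residue_number:4d}    "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )
    partners: dict[int, list[int]] = {}
    for i, j in sorted(structure.bonds):
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    for serial in sorted(partners):
        plist = sorted(partners[serial])
        for start in range(0, len(plist), 4):
            chunk = plist[start:start + 4]
            lines.append("CONECT" + f"{serial:5d}" + "".join(f"{p:5d}" for p in chunk))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def covalent_radius(element: str) -> float:
    """Covalent radius in Å from gemmi's element table."""
    el = gemmi.Element(element.capitalize() if element else "X")
    radius = el.covalent_r
    if not element or el.name == "X" or radius <= 0:
        raise ValueError(f"no covalent radius known for element {element!r}")
    return radius


def perceive_bonds(structure: Structure, tolerance: float = 0.4) -> Structure:
    """Add bonds where distance <= sum of covalent radii + ``tolerance`` (Å).

    Existing (e.g. CONECT-derived) bonds are preserved. Uses a KD-tree for
    the pair search; equivalent to the exhaustive O(N^2) scan.
    """
    from scipy.spatial import cKDTree

    radii = np.array([covalent_radius(a.element) for a in structure.atoms])
    pos = structure.positions()
    serials = [a.serial for a in structure.atoms]
    tree = cKDTree(pos)
    cutoff = 2.0 * radii.max() + tolerance
    bonds = set(structure.bonds)
    for i, j in tree.query_pairs(cutoff):
        dist = np.linalg.norm(pos[i] - pos[j])
        if dist <= radii[i] + radii[j] + tolerance:
            bonds.add((min(serials[i], serials[j]), max(serials[i], serials[j])))
    return Structure(atoms=list(structure.atoms), roles=dict(structure.roles), bonds=bonds)


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def _default_mapping(mobile: Structure, reference: Structure, selection: Sequence[str]) -> list[tuple[int, int]]:
    ref_index = {
        (a.chain_id, a.residue_number, a.name): a.serial
        for a in reference.atoms if a.name in selection
    }
    mapping = []
    for a in mobile.atoms:
        if a.name in selection:
            key = (a.chain_id, a.residue_number, a.name)
            if key in ref_index:
                mapping.append((a.serial, ref_index[key]))
    return mapping


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: Sequence[str] = ("CA",),
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are mapped by matching chain id, residue number and atom name over
    the ``selection`` name filter (default: alpha carbons). Requires at least
    three non-collinear mapped pairs. A consistent chain/residue numbering
    between mobile and reference is assumed.
    """
    mapping = _default_mapping(mobile, reference, selection)
    if len(mapping) < 3:
        raise ValueError(
            f"superposition needs >=3 mapped atom pairs; found {len(mapping)} "
            f"for selection {tuple(selection)}"
        )
    mob = mobile.positions([m for m, _ in mapping])
    ref = reference.positions([r for _, r in mapping])
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    mob0, ref0 = mob - mob_c, ref - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("mapped atoms are collinear; superposition is underdetermined")
    rot, _ = Rotation.align_vectors(ref0, mob0)
    Q = rot.as_matrix()
    translation = ref_c - Q @ mob_c
    fitted = mob @ Q.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return Superposition(rotation=Q, translation=translation, rmsd=rmsd,
                         atom_mapping=tuple((m, r) for m, r in mapping))


def apply_superposition(structure: Structure, sp: Superposition) -> Structure:
    """Return a copy of ``structure`` with all positions transformed by ``sp``."""
    return structure.with_positions(sp.apply(structure.positions()))
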