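"""Construction and evaluation of the three restraint classes.

Translational/rotational (TR, Boresch-style) restraints tie the ligand's
rigid-body pose to three protein anchors through six coordinates: the P1-L1
distance r, the angles θ = P2-P1-L1 and Θ = P1-L1-L2, and the dihedrals
φ = P3-P2-P1-L1, Φ = P2-P1-L1-L2, Ψ = P1-L1-L2-L3. Conformational restraints
hold every heavy-atom dihedral of the ligand and/or the protein backbone
φ/ψ dihedrals in declared residue ranges. Centre-of-mass (COM) restraints
fix the reference frame only and contribute no free-energy component.

All restraints are harmonic. Force constants follow the AMBER convention:
kcal·mol⁻¹·Å⁻² for distances, kcal·mol⁻¹·rad⁻² for angles and dihedrals.
Reference values are reported in degrees; dihedral differences are wrapped
to (−180°, 180°] before squaring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .anchors import AnchorSet
from .structio import Structure, logger

DEFAULT_K_R = 10.0        # kcal/mol/Å², TR distance
DEFAULT_K_ANGLE = 100.0   # kcal/mol/rad², TR angles and dihedrals
DEFAULT_K_CONF = 30.0     # kcal/mol/rad², conformational dihedrals
DEFAULT_K_COM = 10.0      # kcal/mol/Å², centre-of-mass tether


def wrap_degrees(delta: float) -> float:
    """Wrap an angular difference in degrees to (−180, 180]."""
    wrapped = ((delta + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _vec(structure: Structure, serial: int) -> np.ndarray:
    return structure.atom(serial).position


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise ValueError("coincident points: angle undefined")
    return math.degrees(math.acos(float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (−180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n2 = np.linalg.norm(b2)
    if n2 < 1e-10:
        raise ValueError("coincident points: dihedral undefined")
    m1 = np.cross(b1, b2)
    m2 = np.cross(b2, b3)
    if np.linalg.norm(m1) < 1e-10 or np.linalg.norm(m2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    x = float(np.dot(m1, m2))
    y = float(np.dot(np.cross(m1, b2 / n2), m2))
    return wrap_degrees(math.degrees(math.atan2(y, x)))


#: Order of the six TR coordinates everywhere in the package.
TR_COORD_NAMES = ("r", "theta", "Theta", "phi", "Phi", "Psi")


def measure_tr_coordinates(structure: Structure, anchors: AnchorSet) -> tuple[float, ...]:
    """Measure (r, θ, Θ, φ, Φ, Ψ) from anchor positions.

    Distances in Å, angles and dihedrals in degrees (dihedrals in
    (−180°, 180°]). Raises on coincident consecutive anchors.
    """
    p1, p2, p3 = (_vec(structure, s) for s in anchors.protein_serials)
    l1, l2, l3 = (_vec(structure, s) for s in anchors.ligand_serials)
    r = distance(p1, l1)
    if r < 1e-10:
        raise ValueError("P1 and L1 coincide: TR geometry undefined")
    return (
        r,
        angle_deg(p2, p1, l1),
        angle_deg(p1, l1, l2),
        dihedral_deg(p3, p2, p1, l1),
        dihedral_deg(p2, p1, l1, l2),
        dihedral_deg(p1, l1, l2, l3),
    )


# ---------------------------------------------------------------------------
# Restraint types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRRestraint:
    """Harmonic restraints on the six TR coordinates.

    ``anchors`` records the defining atoms; reference values are degrees for
    the angular coordinates, Å for r.
    """

    anchors: AnchorSet
    r0: float
    theta0: float
    Theta0: float
    phi0: float
    Phi0: float
    Psi0: float
    k_r: float = DEFAULT_K_R
    k_theta: float = DEFAULT_K_ANGLE
    k_Theta: float = DEFAULT_K_ANGLE
    k_phi: float = DEFAULT_K_ANGLE
    k_Phi: float = DEFAULT_K_ANGLE
    k_Psi: float = DEFAULT_K_ANGLE

    def __post_init__(self):
        for name in ("k_r", "k_theta", "k_Theta", "k_phi", "k_Phi", "k_Psi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("theta0", "Theta0"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"{name} must lie strictly inside (0°, 180°)")
        for name in ("phi0", "Phi0", "Psi0"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} must lie in (−180°, 180°], got {v}")

    @property
    def references(self) -> tuple[float, ...]:
        return (self.r0, self.theta0, self.Theta0, self.phi0, self.Phi0, self.Psi0)

    @property
    def force_constants(self) -> tuple[float, ...]:
        return (self.k_r, self.k_theta, self.k_Theta, self.k_phi, self.k_Phi, self.k_Psi)

    def scaled(self, factor: float) -> "TRRestraint":
        ks = [k * factor for k in self.force_constants]
        return TRRestraint(self.anchors, *self.references, *ks)


@dataclass(frozen=True)
class DihedralRestraint:
    """One harmonic dihedral restraint: four serials, reference (deg), k (kcal/mol/rad²)."""

    serials: tuple[int, int, int, int]
    reference: float
    k: float

    def __post_init__(self):
        if len(set(self.serials)) != 4:
            raise ValueError(f"dihedral serials must be distinct: {self.serials}")
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")


@dataclass(frozen=True)
class ConformationalRestraints:
    """A set of dihedral restraints on the ligand or the protein backbone."""

    dihedrals: tuple[DihedralRestraint, ...]
    target: str  # "ligand" | "protein_backbone"

    def __post_init__(self):
        if self.target not in ("ligand", "protein_backbone"):
            raise ValueError(f"unknown conformational target {self.target!r}")

    def __len__(self) -> int:
        return len(self.dihedrals)

    def references(self) -> list[float]:
        return [d.reference for d in self.dihedrals]


@dataclass(frozen=True)
class COMRestraint:
    """Harmonic tether on a selection's centre of mass. No free-energy term."""

    serials: tuple[int, ...]
    reference_center: np.ndarray
    k: float = DEFAULT_K_COM

    def __post_init__(self):
        if not self.serials:
            raise ValueError("COM restraint selection must be non-empty")
        center = np.asarray(self.reference_center, dtype=float)
        if center.shape != (3,):
            raise ValueError("reference center must be a 3-vector")
        object.__setattr__(self, "reference_center", center)


@dataclass(frozen=True)
class RestraintSchedule:
    """Ordered multiplicative λ factors applied to a component's force constants.

    ``mode`` is "attach" (nondecreasing) or "release" (nonincreasing);
    ``samples_per_window`` is the per-window sampling plan.
    """

    factors: tuple[float, ...]
    mode: str = "attach"
    samples_per_window: int = 1000

    def __post_init__(self):
        if self.mode not in ("attach", "release"):
            raise ValueError(f"mode must be 'attach' or 'release', got {self.mode!r}")
        f = np.asarray(self.factors, dtype=float)
        if f.size < 2 or np.any(f < 0) or np.any(f > 1):
            raise ValueError("factors must be >=2 values in [0, 1]")
        diffs = np.diff(f)
        if self.mode == "attach" and np.any(diffs < 0):
            raise ValueError("attach factors must be nondecreasing")
        if self.mode == "release" and np.any(diffs > 0):
            raise ValueError("release factors must be nonincreasing")
        lo, hi = (f[0], f[-1]) if self.mode == "attach" else (f[-1], f[0])
        if not (lo == 0.0 and hi == 1.0):
            raise ValueError("schedule must span the end states 0 and 1")


@dataclass(frozen=True)
class RestraintBundle:
    """Everything :func:`build_restraints` produces for one pose."""

    tr: TRRestraint
    ligand_conf: ConformationalRestraints
    protein_conf: ConformationalRestraints
    com: tuple[COMRestraint, ...]


# ---------------------------------------------------------------------------
# Building restraints from a structure
# ---------------------------------------------------------------------------

def enumerate_ligand_dihedrals(structure: Structure) -> list[tuple[int, int, int, int]]:
    """Every bonded heavy-atom quadruple i-j-k-l of the ligand, one per
    distinct quadruple (both walk directions identified)."""
    heavy = {a.serial for a in structure.ligand_atoms(heavy_only=True)}
    seen: set[tuple[int, int, int, int]] = set()
    out: list[tuple[int, int, int, int]] = []
    for j, k in sorted(structure.bonds):
        if j not in heavy or k not in heavy:
            continue
        for jj, kk in ((j, k), (k, j)):
            for i in structure.neighbors(jj):
                if i == kk or i not in heavy:
                    continue
                for l in structure.neighbors(kk):
                    if l == jj or l == i or l not in heavy:
                        continue
                    quad = (i, jj, kk, l)
                    canon = min(quad, quad[::-1])
                    if canon not in seen:
                        seen.add(canon)
                        out.append(canon)
    return sorted(out)


def _backbone_index(structure: Structure) -> dict[tuple[str, int, str], int]:
    return {
        (a.chain_id, a.residue_number, a.name): a.serial
        for a in structure.atoms
        if structure.role(a.serial) == "protein" and a.name in ("N", "CA", "C")
    }


def enumerate_backbone_phi_psi(
    structure: Structure,
    residue_ranges: Sequence[tuple[str, int, int]],
) -> list[tuple[int, int, int, int]]:
    """φ/ψ backbone dihedral quadruples for residues in the declared ranges.

    φ(i) = C(i−1)-N(i)-CA(i)-C(i); ψ(i) = N(i)-CA(i)-C(i)-N(i+1). Dihedrals
    whose flanking residues are missing are skipped.
    """
    idx = _backbone_index(structure)
    quads = []
    for chain, first, last in residue_ranges:
        if last < first:
            raise ValueError(f"invalid residue range {first}..{last} on chain {chain}")
        for resnum in range(first, last + 1):
            phi = [(chain, resnum - 1, "C"), (chain, resnum, "N"),
                   (chain, resnum, "CA"), (chain, resnum, "C")]
            psi = [(chain, resnum, "N"), (chain, resnum, "CA"),
                   (chain, resnum, "C"), (chain, resnum + 1, "N")]
            for quad in (phi, psi):
                if all(key in idx for key in quad):
                    quads.append(tuple(idx[key] for key in quad))
    return quads


def _atomic_mass(element: str) -> float:
    return gemmi.Element(element.capitalize() or "X").weight


def center_of_mass(structure: Structure, serials: Sequence[int]) -> np.ndarray:
    masses = np.array([_atomic_mass(structure.atom(s).element) for s in serials])
    pos = structure.positions(serials)
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()


def build_restraints(
    structure: Structure,
    anchors: AnchorSet,
    k_r: float = DEFAULT_K_R,
    k_angle: float = DEFAULT_K_ANGLE,
    k_ligand_conf: float = DEFAULT_K_CONF,
    k_protein_conf: float = DEFAULT_K_CONF,
    k_com: float = DEFAULT_K_COM,
    protein_residue_ranges: Sequence[tuple[str, int, int]] = (),
) -> RestraintBundle:
    """Construct TR, conformational and COM restraints for one pose.

    TR references are measured from the input conformation, so the restrained
    minimum is the conformation itself. Ligand dihedrals cover every bonded
    heavy-atom quadruple (hydrogens excluded); an empty list is allowed for a
    rigid ligand, with a warning. Protein φ/ψ restraints are built only for
    the declared residue ranges.
    """
    coords = measure_tr_coordinates(structure, anchors)
    tr = TRRestraint(anchors, *coords, k_r=k_r, k_theta=k_angle, k_Theta=k_angle,
                     k_phi=k_angle, k_Phi=k_angle, k_Psi=k_angle)

    lig_quads = enumerate_ligand_dihedrals(structure)
    if not lig_quads:
        logger.warning("ligand has no heavy-atom dihedrals (rigid ligand); "
                       "conformational restraint set is empty")
    lig_dihedrals = tuple(
        DihedralRestraint(q, dihedral_deg(*(_vec(structure, s) for s in q)), k_ligand_conf)
        for q in lig_quads
    )
    prot_quads = enumerate_backbone_phi_psi(structure, protein_residue_ranges)
    prot_dihedrals = tuple(
        DihedralRestraint(q, dihedral_deg(*(_vec(structure, s) for s in q)), k_protein_conf)
        for q in prot_quads
    )

    backbone = [a.serial for a in structure.atoms
                if structure.role(a.serial) == "protein" and a.name in ("N", "CA", "C", "O")]
    lig_heavy = [a.serial for a in structure.ligand_atoms(heavy_only=True)]
    com = []
    if backbone:
        com.append(COMRestraint(tuple(backbone), center_of_mass(structure, backbone), k_com))
    if lig_heavy:
        com.append(COMRestraint(tuple(lig_heavy), center_of_mass(structure, lig_heavy), k_com))

    return RestraintBundle(
        tr=tr,
        ligand_conf=ConformationalRestraints(lig_dihedrals, "ligand"),
        protein_conf=ConformationalRestraints(prot_dihedrals, "protein_backbone"),
        com=tuple(com),
    )


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

def tr_restraint_energy(values: Sequence[float], tr: TRRestraint, scale: float = 1.0) -> float:
    """Harmonic TR energy u = scale · Σ ½k(x − x₀)², kcal/mol.

    ``values`` are (r, θ, Θ, φ, Φ, Ψ) with angles in degrees; angular terms
    are converted to radians and dihedral differences wrapped to (−180°, 180°].
    """
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"scale must lie in [0, 1], got {scale}")
    if len(values) != 6:
        raise ValueError("expected six TR coordinate values")
    r, th, Th, ph, Ph, Ps = values
    refs = tr.references
    energy = 0.5 * tr.k_r * (r - refs[0]) ** 2
    for val, ref, k in ((th, refs[1], tr.k_theta), (Th, refs[2], tr.k_Theta)):
        energy += 0.5 * k * math.radians(val - ref) ** 2
    for val, ref, k in ((ph, refs[3], tr.k_phi), (Ph, refs[4], tr.k_Phi), (Ps, refs[5], tr.k_Psi)):
        energy += 0.5 * k * math.radians(wrap_degrees(val - ref)) ** 2
    return scale * energy


def conformational_energy(
    values: Sequence[float],
    conf: ConformationalRestraints,
    scale: float = 1.0,
) -> float:
    """Harmonic dihedral-set energy with wrapped differences, kcal/mol."""
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"scale must lie in [0, 1], got {scale}")
    if len(values) != len(conf.dihedrals):
        raise ValueError("one value per restrained dihedral required")
    energy = 0.0
    for val, dih in zip(values, conf.dihedrals):
        energy += 0.5 * dih.k * math.radians(wrap_degrees(val - dih.reference)) ** 2
    return scale * energy


def restraint_energy(values, restraint, scale: float = 1.0) -> float:
    """Dispatch on restraint type: TR six-coordinate or conformational set."""
    if isinstance(restraint, TRRestraint):
        return tr_restraint_energy(values, restraint, scale)
    if isinstance(restraint, ConformationalRestraints):
        return conformational_energy(values, restraint, scale)
    raise TypeError(f"cannot evaluate restraint of type {type(restraint).__name__}")


def measure_conformational(structure: Structure, conf: ConformationalRestraints) -> list[float]:
    """Current values (degrees) of a conformational restraint set."""
    return [dihedral_deg(*(_vec(structure, s) for s in d.serials)) for d in conf.dihedrals]


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def manifest_dict(bundle: RestraintBundle) -> dict:
    tr = bundle.tr
    return {
        "anchors": tr.anchors.to_dict(),
        "tr": {
            "references": dict(zip(TR_COORD_NAMES, tr.references)),
            "force_constants": {
                "k_r": tr.k_r, "k_theta": tr.k_theta, "k_Theta": tr.k_Theta,
                "k_phi": tr.k_phi, "k_Phi": tr.k_Phi, "k_Psi": tr.k_Psi,
            },
        },
        "ligand_conf": [
            {"serials": list(d.serials), "reference": d.reference, "k": d.k}
            for d in bundle.ligand_conf.dihedrals
        ],
        "protein_conf": [
            {"serials": list(d.serials), "reference": d.reference, "k": d.k}
            for d in bundle.protein_conf.dihedrals
        ],
        "com": [
            {"serials": list(c.serials), "center": c.reference_center.tolist(), "k": c.k}
            for c in bundle.com
        ],
    }


def write_manifest(bundle: RestraintBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest_dict(bundle), indent=2) + "\n")


def read_manifest(path: str | Path) -> RestraintBundle:
    d = json.loads(Path(path).read_text())
    anchor_set = AnchorSet.from_dict(d["anchors"])
    refs = d["tr"]["references"]
    ks = d["tr"]["force_constants"]
    tr = TRRestraint(anchor_set, refs["r"], refs["theta"], refs["Theta"],
                     refs["phi"], refs["Phi"], refs["Psi"],
                     k_r=ks["k_r"], k_theta=ks["k_theta"], k_Theta=ks["k_Theta"],
                     k_phi=ks["k_phi"], k_Phi=ks["k_Phi"], k_Psi=ks["k_Psi"])
    lig = ConformationalRestraints(
        tuple(DihedralRestraint(tuple(e["serials"]), e["reference"], e["k"])
              for e in d["ligand_conf"]), "ligand")
    prot = ConformationalRestraints(
        tuple(DihedralRestraint(tuple(e["serials"]), e["reference"], e["k"])
              for e in d["protein_conf"]), "protein_backbone")
    com = tuple(COMRestraint(tuple(e["serials"]), np.asarray(e["center"]), e["k"])
                for e in d["com"])
    return RestraintBundle(tr=tr, ligand_conf=lig, protein_conf=prot, com=com)


def write_disang(bundle: RestraintBundle, path: str | Path) -> None:
    """AMBER NMR-restraint (DISANG) text with one &rst block per restraint."""
    tr = bundle.tr
    a = tr.anchors
    lines = ["# TR restraints"]

    def rst(iat, ref, k, width):
        iat_s = ",".join(str(i) for i in iat)
        return (f" &rst iat={iat_s}, r1={ref - width:.3f}, r2={ref:.3f}, "
                f"r3={ref:.3f}, r4={ref + width:.3f}, rk2={k:.3f}, rk3={k:.3f}, &end")

    lines.append(rst((a.P1, a.L1), tr.r0, tr.k_r, 99.0))
    lines.append(rst((a.P2, a.P1, a.L1), tr.theta0, tr.k_theta, 180.0))
    lines.append(rst((a.P1, a.L1, a.L2), tr.Theta0, tr.k_Theta, 180.0))
    lines.append(rst((a.P3, a.P2, a.P1, a.L1), tr.phi0, tr.k_phi, 180.0))
    lines.append(rst((a.P2, a.P1, a.L1, a.L2), tr.Phi0, tr.k_Phi, 180.0))
    lines.append(rst((a.P1, a.L1, a.L2, a.L3), tr.Psi0, tr.k_Psi, 180.0))
    for label, conf in (("ligand", bundle.ligand_conf), ("protein backbone", bundle.protein_conf)):
        if conf.dihedrals:
            lines.append(f"# {label} conformational restraints")
            for d in conf.dihedrals:
                lines.append(rst(d.serials, d.reference, d.k, 180.0))
    Path(path).write_text("\n".join(lines) + "\n")
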