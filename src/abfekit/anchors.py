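"""Anchor-atom selection for translational/rotational (Boresch) restraints.

Three user-chosen protein backbone atoms (P1, P2, P3) and three automatically
selected ligand heavy atoms (L1, L2, L3) define the six restrained rigid-body
coordinates. L1 is the ligand atom closest to the centre of a spherical
search zone given in the reference frame; L2 is the in-range atom whose
P1-L1-L2 angle is closest to 90°, and L3 follows the same rule on L2-L3
distance and the L1-L2-L3 angle. If no ligand atom lies inside the search
zone the pose is flagged unstable — a defined workflow outcome, not an
error — since the ligand has left the binding site.

All selections are deterministic: candidates are non-hydrogen ligand atoms
and ties are broken by smallest serial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import Structure


class UnstablePose:
    """Distinguished outcome: no ligand atom inside the search zone."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "UNSTABLE_POSE"

    def __bool__(self):
        return False


#: Singleton returned by :func:`find_l1` when the ligand left the site.
UNSTABLE_POSE = UnstablePose()

_BACKBONE_NAMES = {"N", "CA", "C", "O"}

DEFAULT_DIST_RANGE = (2.5, 5.0)   # Å, L1-L2 and L2-L3 windows
DEFAULT_MIN_DIST = 5.0            # Å, protein anchor separation
DEFAULT_ANGLE_WINDOW = 25.0       # degrees away from 0°/180° for P1-P2-P3


@dataclass(frozen=True)
class SearchZone:
    """Spherical L1 search region, centre in the reference frame (Å)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise ValueError("search-zone center must be a finite 3-vector")
        if self.radius <= 0:
            raise ValueError("search-zone radius must be positive")
        object.__setattr__(self, "center", center)


@dataclass(frozen=True)
class AnchorSet:
    """The six anchor atoms and the selection parameters that produced them."""

    P1: int
    P2: int
    P3: int
    L1: int
    L2: int
    L3: int
    zone: SearchZone
    l1l2_range: tuple[float, float] = DEFAULT_DIST_RANGE
    l2l3_range: tuple[float, float] = DEFAULT_DIST_RANGE

    def __post_init__(self):
        serials = (self.P1, self.P2, self.P3, self.L1, self.L2, self.L3)
        if len(set(serials)) != 6:
            raise ValueError(f"anchor serials must be distinct, got {serials}")

    @property
    def protein_serials(self) -> tuple[int, int, int]:
        return (self.P1, self.P2, self.P3)

    @property
    def ligand_serials(self) -> tuple[int, int, int]:
        return (self.L1, self.L2, self.L3)

    def validate_roles(self, structure: Structure) -> None:
        """Check role and element invariants against ``structure``."""
        for s in self.protein_serials:
            if structure.role(s) != "protein":
                raise ValueError(f"anchor {s} is not a protein atom")
        for s in self.ligand_serials:
            if structure.role(s) != "ligand":
                raise ValueError(f"anchor {s} is not a ligand atom")
            if structure.atom(s).is_hydrogen:
                raise ValueError(f"ligand anchor {s} is a hydrogen")

    def to_dict(self) -> dict:
        return {
            "P1": self.P1, "P2": self.P2, "P3": self.P3,
            "L1": self.L1, "L2": self.L2, "L3": self.L3,
            "zone": {"center": self.zone.center.tolist(), "radius": self.zone.radius},
            "l1l2_range": list(self.l1l2_range),
            "l2l3_range": list(self.l2l3_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorSet":
        zone = SearchZone(np.asarray(d["zone"]["center"]), d["zone"]["radius"])
        return cls(P1=d["P1"], P2=d["P2"], P3=d["P3"], L1=d["L1"], L2=d["L2"],
                   L3=d["L3"], zone=zone,
                   l1l2_range=tuple(d.get("l1l2_range", DEFAULT_DIST_RANGE)),
                   l2l3_range=tuple(d.get("l2l3_range", DEFAULT_DIST_RANGE)))


@dataclass
class ValidationReport:
    """Per-rule pass/fail record for protein anchor choices."""

    rules: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, rule: str, passed: bool, detail: str = "") -> None:
        self.rules.append((rule, passed, detail))

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.rules)

    def failures(self) -> list[str]:
        return [f"{rule}: {detail}" for rule, passed, detail in self.rules if not passed]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise ValueError("coincident points: angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def validate_protein_anchors(
    structure: Structure,
    p1: int,
    p2: int,
    p3: int,
    min_dist: float = DEFAULT_MIN_DIST,
    angle_window: float = DEFAULT_ANGLE_WINDOW,
) -> ValidationReport:
    """Check the qualitative rules for protein anchor placement.

    Anchors should be backbone atoms (N, CA, C, O), mutually separated by at
    least ``min_dist`` Å, with a P1-P2-P3 angle at least ``angle_window``
    degrees away from 0° and 180° (gimbal-lock avoidance).
    """
    report = ValidationReport()
    atoms = [structure.atom(s) for s in (p1, p2, p3)]  # raises on bad serial

    for atom in atoms:
        if structure.role(atom.serial) != "protein" or atom.name not in _BACKBONE_NAMES:
            report.add("backbone", False,
                       f"atom {atom.serial} ({atom.name}) is not a protein backbone atom")
    if not report.rules or report.ok:
        report.add("backbone", True, "all anchors are protein backbone atoms")

    pos = [a.position for a in atoms]
    pairs = [(p1, p2, 0, 1), (p1, p3, 0, 2), (p2, p3, 1, 2)]
    dist_ok = True
    for sa, sb, ia, ib in pairs:
        d = float(np.linalg.norm(pos[ia] - pos[ib]))
        if d < min_dist:
            dist_ok = False
            report.add("distance", False, f"{sa}-{sb} distance {d:.2f} Å < {min_dist} Å")
    if dist_ok:
        report.add("distance", True, f"all pairwise distances >= {min_dist} Å")

    try:
        ang = _angle_deg(pos[0], pos[1], pos[2])
    except ValueError:
        report.add("angle", False, "coincident anchors: P1-P2-P3 angle undefined")
    else:
        if angle_window <= ang <= 180.0 - angle_window:
            report.add("angle", True, f"P1-P2-P3 angle {ang:.1f}°")
        else:
            report.add("angle", False,
                       f"P1-P2-P3 angle {ang:.1f}° outside [{angle_window}, {180 - angle_window}]°")
    return report


def find_l1(structure: Structure, zone: SearchZone) -> int | UnstablePose:
    """L1: the non-hydrogen ligand atom closest to the search-zone centre.

    The structure must already be superposed onto the reference frame. If no
    ligand heavy atom lies within ``zone.radius`` of the centre, returns
    :data:`UNSTABLE_POSE`.
    """
    candidates = structure.ligand_atoms(heavy_only=True)
    if not candidates:
        raise ValueError("structure has no ligand heavy atoms")
    best: tuple[float, int] | None = None
    for atom in candidates:
        dist = float(np.linalg.norm(atom.position - zone.center))
        if dist <= zone.radius and (best is None or (dist, atom.serial) < best):
            best = (dist, atom.serial)
    if best is None:
        return UNSTABLE_POSE
    return best[1]


def select_anchor_chain(
    structure: Structure,
    prev_a: int,
    prev_b: int,
    dist_range: tuple[float, float] = DEFAULT_DIST_RANGE,
) -> int:
    """Next ligand anchor: in-range atom with angle(prev_a, prev_b, x) closest to 90°.

    For L2, ``prev_a``/``prev_b`` are P1/L1; for L3 they are L1/L2. Candidates
    are non-hydrogen ligand atoms distinct from both previous anchors whose
    distance to ``prev_b`` lies within ``dist_range``. Ties break by smallest
    serial.
    """
    lo, hi = dist_range
    if lo <= 0 or hi <= lo:
        raise ValueError(f"invalid distance range {dist_range}")
    pa = structure.atom(prev_a).position
    pb = structure.atom(prev_b).position
    best: tuple[float, int] | None = None
    n_in_range = 0
    for atom in structure.ligand_atoms(heavy_only=True):
        if atom.serial in (prev_a, prev_b):
            continue
        d = float(np.linalg.norm(atom.position - pb))
        if not (lo <= d <= hi):
            continue
        n_in_range += 1
        dev = abs(_angle_deg(pa, pb, atom.position) - 90.0)
        if best is None or (dev, atom.serial) < best:
            best = (dev, atom.serial)
    if best is None:
        raise ValueError(
            f"no ligand heavy atom within {dist_range} Å of atom {prev_b}; "
            "widen the anchor distance range in the run configuration"
        )
    return best[1]


def select_anchors(
    structure: Structure,
    p1: int,
    p2: int,
    p3: int,
    zone: SearchZone,
    l1l2_range: tuple[float, float] = DEFAULT_DIST_RANGE,
    l2l3_range: tuple[float, float] = DEFAULT_DIST_RANGE,
) -> AnchorSet | UnstablePose:
    """Full anchor selection: L1 by zone proximity, then L2 and L3 by geometry.

    Returns :data:`UNSTABLE_POSE` when the ligand is outside the search zone.
    The same operation serves re-selection after equilibration, applied to the
    equilibrated (re-superposed) structure.
    """
    l1 = find_l1(structure, zone)
    if isinstance(l1, UnstablePose):
        return UNSTABLE_POSE
    l2 = select_anchor_chain(structure, p1, l1, l1l2_range)
    l3 = select_anchor_chain(structure, l1, l2, l2l3_range)
    anchor_set = AnchorSet(P1=p1, P2=p2, P3=p3, L1=l1, L2=l2, L3=l3, zone=zone,
                           l1l2_range=l1l2_range, l2l3_range=l2l3_range)
    anchor_set.validate_roles(structure)
    return anchor_set
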