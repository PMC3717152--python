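"""Geometric quality checks and the knowledge-based interaction checklist.

Two kinds of checks live here. The generic screens (Ramachandran
classification, cis-peptide detection, steric clash screen, disulfide
detection) ask whether a model contains obvious construction errors. The
interaction checklist asks a receptor-specific question: are the conserved
inter-helical hydrogen bonds / salt bridges that stabilize muscarinic
receptors (e.g. Ser64-Asn113 between TM II and TM IV, the Arg121-Glu382
ionic lock between TM III and TM VI) actually formed in the model, formed
with an alternative partner, or absent?

Hydrogen-bond geometry is judged by donor-acceptor distance and, when
explicit hydrogens are present, the D-H...A angle; crystal structures and
most models lack hydrogens, so a heavy-atom-only distance criterion is the
fallback.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, Structure, packaged_data_path

__all__ = [
    "HBondCriteria",
    "HBond",
    "ChecklistEntry",
    "ChecklistResult",
    "QCReport",
    "detect_hbonds",
    "run_checklist",
    "ramachandran_classify",
    "detect_cis_prolines",
    "detect_clashes",
    "check_disulfides",
    "load_default_checklist",
    "run_qc",
]

logger = logging.getLogger(__name__)

# Side-chain donor / acceptor heavy atoms per residue type. Backbone N (donor)
# and O (acceptor) are added for every residue. Histidine nitrogens are listed
# as both (protonation unknown without hydrogens).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
_ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}


class QCError(ValueError):
    pass


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_da_distance`` and ``min_dha_angle`` apply when explicit hydrogens
    are available; ``heavy_only_distance`` replaces both when they are not.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0
    heavy_only_distance: float = 3.5
    salt_bridge_distance: float = 4.5

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.heavy_only_distance <= 0:
            raise ValueError("distances must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("angle must be in (0, 180]")


@dataclass
class HBond:
    donor: tuple[Residue, Atom]
    acceptor: tuple[Residue, Atom]
    distance: float
    angle: float | None = None

    def __repr__(self) -> str:  # compact, for logs and reports
        d_res, d_at = self.donor
        a_res, a_at = self.acceptor
        return (
            f"HBond({d_res.name}{d_res.seq_number}:{d_at.name} -> "
            f"{a_res.name}{a_res.seq_number}:{a_at.name}, {self.distance:.2f} A)"
        )


@dataclass
class ChecklistEntry:
    label: str
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    alternatives: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError(f"{self.label}: checklist residues must be distinct")
        if len(self.alternatives) != len(set(self.alternatives)):
            raise ValueError(f"{self.label}: duplicate alternative partners")


@dataclass
class ChecklistVerdict:
    entry: ChecklistEntry
    status: Literal["present", "absent", "alternative", "unresolvable"]
    partner: tuple[str, int] | None = None
    evidence: list[HBond] = field(default_factory=list)


@dataclass
class ChecklistResult:
    verdicts: list[ChecklistVerdict]

    @property
    def counts(self) -> dict[str, int]:
        out = {"present": 0, "absent": 0, "alternative": 0, "unresolvable": 0}
        for v in self.verdicts:
            out[v.status] += 1
        return out

    def status_of(self, residue_a: tuple[str, int], residue_b: tuple[str, int]) -> str:
        for v in self.verdicts:
            if v.entry.residue_a == residue_a and v.entry.residue_b == residue_b:
                return v.status
        raise KeyError(f"no checklist entry {residue_a}-{residue_b}")


@dataclass
class QCReport:
    rama_counts: dict[str, int] = field(default_factory=dict)
    disallowed: list[tuple[str, int, str]] = field(default_factory=list)
    cis_prolines: list[tuple[str, int]] = field(default_factory=list)
    clashes: list[tuple[str, str, float]] = field(default_factory=list)
    disulfides: list[tuple[int, int, float]] = field(default_factory=list)


def _collect(structure: Structure, table: dict[str, tuple[str, ...]], backbone_atom: str):
    """(residue, atom) pairs for the given side-chain table + backbone atom."""
    out: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        wanted = set(table.get(res.name, ())) | {backbone_atom}
        for at in res.heavy_atoms():
            if at.name in wanted:
                out.append((res, at))
    return out


def _has_hydrogens(structure: Structure) -> bool:
    return any(a.is_hydrogen for res in structure.residues() for a in res.atoms)


def _attached_hydrogens(res: Residue, donor: Atom) -> list[Atom]:
    return [
        a
        for a in res.atoms
        if a.is_hydrogen and np.linalg.norm(a.coords - donor.coords) < 1.25
    ]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    structure: Structure,
    criteria: HBondCriteria | None = None,
    donors: dict[str, tuple[str, ...]] | None = None,
    acceptors: dict[str, tuple[str, ...]] | None = None,
    sidechain_only: bool = False,
) -> list[HBond]:
    """All inter-residue hydrogen bonds satisfying the geometric criteria.

    With explicit hydrogens: D-A distance and D-H...A angle; without: the
    heavy-atom distance only. Output is sorted by distance.
    """
    criteria = criteria or HBondCriteria()
    donors = donors or SIDECHAIN_DONORS
    acceptors = acceptors or SIDECHAIN_ACCEPTORS
    don = _collect(structure, donors, "" if sidechain_only else "N")
    acc = _collect(structure, acceptors, "" if sidechain_only else "O")
    if not don or not acc:
        return []
    use_h = _has_hydrogens(structure)
    cutoff = criteria.max_da_distance if use_h else criteria.heavy_only_distance
    acc_tree = cKDTree(np.array([a.coords for _, a in acc]))
    bonds: list[HBond] = []
    for d_res, d_at in don:
        for j in acc_tree.query_ball_point(d_at.coords, cutoff):
            a_res, a_at = acc[j]
            if a_res.key == d_res.key:
                continue  # no self-bonds
            dist = float(np.linalg.norm(d_at.coords - a_at.coords))
            angle = None
            if use_h:
                hydrogens = _attached_hydrogens(d_res, d_at)
                if hydrogens:
                    angle = max(
                        _angle(d_at.coords, h.coords, a_at.coords) for h in hydrogens
                    )
                    if angle < criteria.min_dha_angle:
                        continue
            bonds.append(HBond(donor=(d_res, d_at), acceptor=(a_res, a_at), distance=dist, angle=angle))
    bonds.sort(key=lambda b: b.distance)
    return bonds


def _pair_hbonds(res_a: Residue, res_b: Residue, criteria: HBondCriteria) -> list[HBond]:
    """Side-chain hydrogen bonds between two specific residues."""
    mini = Structure(id="pair")
    # clone into separate chains so identical seq numbers cannot collide
    a = Residue(res_a.name, res_a.seq_number, "a", list(res_a.atoms), res_a.icode)
    b = Residue(res_b.name, res_b.seq_number, "b", list(res_b.atoms), res_b.icode)
    mini.chains = {"a": [a], "b": [b]}
    return detect_hbonds(mini, criteria, sidechain_only=True)


def _salt_bridge(res_a: Residue, res_b: Residue, criteria: HBondCriteria) -> list[HBond]:
    """Charged-pair contact: any side-chain N-O within the salt-bridge cutoff."""
    for acidic, basic in ((res_a, res_b), (res_b, res_a)):
        if acidic.name in _ACIDIC and basic.name in _BASIC:
            hits = []
            for o_name in _ACIDIC[acidic.name]:
                if not acidic.has_atom(o_name):
                    continue
                for n_name in _BASIC[basic.name]:
                    if not basic.has_atom(n_name):
                        continue
                    d = float(
                        np.linalg.norm(acidic.atom(o_name).coords - basic.atom(n_name).coords)
                    )
                    if d <= criteria.salt_bridge_distance:
                        hits.append(
                            HBond(
                                donor=(basic, basic.atom(n_name)),
                                acceptor=(acidic, acidic.atom(o_name)),
                                distance=d,
                            )
                        )
            return sorted(hits, key=lambda h: h.distance)
    return []


def _interacts(res_a: Residue, res_b: Residue, criteria: HBondCriteria) -> list[HBond]:
    evidence = _pair_hbonds(res_a, res_b, criteria)
    if not evidence:
        evidence = _salt_bridge(res_a, res_b, criteria)
    return evidence


def load_default_checklist() -> list[ChecklistEntry]:
    """The packaged muscarinic inter-helical interaction checklist."""
    data = json.loads(packaged_data_path("m2_checklist.json").read_text())
    return [
        ChecklistEntry(
            label=e["label"],
            residue_a=(e["residue_a"][0], int(e["residue_a"][1])),
            residue_b=(e["residue_b"][0], int(e["residue_b"][1])),
            alternatives=[(n, int(i)) for n, i in e["alternatives"]],
        )
        for e in data["entries"]
    ]


def run_checklist(
    structure: Structure,
    checklist: list[ChecklistEntry] | None = None,
    criteria: HBondCriteria | None = None,
) -> ChecklistResult:
    """Evaluate each interaction entry as present / alternative / absent.

    An entry is *present* when at least one side-chain hydrogen bond (or,
    for acidic-basic pairs, a salt bridge) links its two residues;
    otherwise each listed alternative partner is scanned in order and the
    first interacting one yields an *alternative(partner)* verdict.
    """
    checklist = checklist if checklist is not None else load_default_checklist()
    criteria = criteria or HBondCriteria()
    verdicts: list[ChecklistVerdict] = []
    for entry in checklist:
        try:
            res_a = structure.find_by_name(*entry.residue_a)
            res_b = structure.find_by_name(*entry.residue_b)
        except KeyError:
            verdicts.append(ChecklistVerdict(entry=entry, status="unresolvable"))
            continue
        evidence = _interacts(res_a, res_b, criteria)
        if evidence:
            verdicts.append(
                ChecklistVerdict(entry=entry, status="present", partner=entry.residue_b, evidence=evidence)
            )
            continue
        alt_hit = None
        for alt in entry.alternatives:
            try:
                res_alt = structure.find_by_name(*alt)
            except KeyError:
                continue
            alt_evidence = _interacts(res_a, res_alt, criteria)
            if alt_evidence:
                alt_hit = ChecklistVerdict(
                    entry=entry, status="alternative", partner=alt, evidence=alt_evidence
                )
                break
        verdicts.append(alt_hit or ChecklistVerdict(entry=entry, status="absent"))
    return ChecklistResult(verdicts=verdicts)


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


_RAMA_REGIONS = None


def _rama_regions() -> dict:
    global _RAMA_REGIONS
    if _RAMA_REGIONS is None:
        _RAMA_REGIONS = json.loads(packaged_data_path("rama_regions.json").read_text())["classes"]
    return _RAMA_REGIONS


def _rama_class(res: Residue, next_res: Residue | None) -> str:
    if res.name == "GLY":
        return "glycine"
    if res.name == "PRO":
        return "proline"
    if next_res is not None and next_res.name == "PRO":
        return "preproline"
    return "general"


def _in_boxes(phi: float, psi: float, boxes: list[list[float]]) -> bool:
    return any(lo_f <= phi <= hi_f and lo_s <= psi <= hi_s for lo_f, hi_f, lo_s, hi_s in boxes)


def _backbone_ok(res: Residue) -> bool:
    return all(res.has_atom(n) for n in ("N", "CA", "C"))


def _contiguous(prev: Residue, res: Residue) -> bool:
    if not (prev.has_atom("CA") and res.has_atom("CA")):
        return False
    return float(np.linalg.norm(prev.atom("CA").coords - res.atom("CA").coords)) <= 4.5


def ramachandran_classify(structure: Structure) -> QCReport:
    """Classify each interior residue as favored / allowed / disallowed.

    phi/psi are computed from the backbone; classification uses the packaged
    rectangular region masks per residue class (general, glycine, proline,
    pre-proline). Chain termini and residues flanking a chain break
    (Calpha-Calpha > 4.5 A) are left unclassified.
    """
    counts = {"favored": 0, "allowed": 0, "disallowed": 0}
    disallowed: list[tuple[str, int, str]] = []
    regions = _rama_regions()
    for chain_name, residues in structure.chains.items():
        for i in range(1, len(residues) - 1):
            prev, res, nxt = residues[i - 1], residues[i], residues[i + 1]
            if not (_backbone_ok(prev) and _backbone_ok(res) and _backbone_ok(nxt)):
                continue
            if not (_contiguous(prev, res) and _contiguous(res, nxt)):
                logger.warning(
                    "chain break around %s%d in chain %s: residue unclassified",
                    res.name, res.seq_number, chain_name,
                )
                continue
            phi = _dihedral(prev.atom("C").coords, res.atom("N").coords,
                            res.atom("CA").coords, res.atom("C").coords)
            psi = _dihedral(res.atom("N").coords, res.atom("CA").coords,
                            res.atom("C").coords, nxt.atom("N").coords)
            cls = regions[_rama_class(res, nxt)]
            if _in_boxes(phi, psi, cls["favored"]):
                counts["favored"] += 1
            elif _in_boxes(phi, psi, cls["allowed"]):
                counts["allowed"] += 1
            else:
                counts["disallowed"] += 1
                disallowed.append((res.name, res.seq_number, f"phi={phi:.0f},psi={psi:.0f}"))
    report = QCReport(rama_counts=counts, disallowed=disallowed)
    return report


def detect_cis_prolines(structure: Structure) -> list[tuple[str, int]]:
    """Prolines whose preceding peptide bond is cis (|omega| < 30 deg)."""
    out = []
    for residues in structure.chains.values():
        for prev, res in zip(residues, residues[1:]):
            if res.name != "PRO":
                continue
            needed = prev.has_atom("CA") and prev.has_atom("C") and res.has_atom("N") and res.has_atom("CA")
            if not needed or not _contiguous(prev, res):
                continue
            omega = _dihedral(prev.atom("CA").coords, prev.atom("C").coords,
                              res.atom("N").coords, res.atom("CA").coords)
            if abs(omega) < 30.0:
                out.append((res.name, res.seq_number))
    return out


_VDW = None


def _vdw_radius(element: str) -> float:
    global _VDW
    if _VDW is None:
        _VDW = json.loads(packaged_data_path("vdw_radii.json").read_text())
    return _VDW["radii"].get(element.upper(), _VDW["default"])


def check_disulfides(structure: Structure, max_ss_distance: float = 2.5) -> list[tuple[int, int, float]]:
    """Cysteine pairs whose SG-SG distance is within disulfide range."""
    cys = [r for r in structure.residues() if r.name == "CYS" and r.has_atom("SG")]
    out = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].atom("SG").coords - cys[j].atom("SG").coords))
            if d <= max_ss_distance:
                out.append((cys[i].seq_number, cys[j].seq_number, d))
    return out


def detect_clashes(
    structure: Structure,
    overlap_factor: float = 0.6,
    criteria: HBondCriteria | None = None,
) -> list[tuple[str, str, float]]:
    """Non-bonded heavy-atom pairs closer than ``overlap_factor`` x (r1+r2).

    Pairs within a residue, between bonded backbone neighbors (and their 1-3
    environment), across detected disulfides and between hydrogen-bond
    partners are excluded.
    """
    atoms: list[tuple[Residue, Atom, int]] = []  # residue, atom, position index in chain
    index = 0
    order: dict[tuple, int] = {}
    for residues in structure.chains.values():
        for pos, res in enumerate(residues):
            order[res.key] = pos
            for at in res.heavy_atoms():
                atoms.append((res, at, index))
        index += 1000  # chain offset so neighbors never span chains
    coords = np.array([a.coords for _, a, _ in atoms])
    if len(coords) < 2:
        return []
    ss_pairs = {frozenset((a, b)) for a, b, _ in check_disulfides(structure)}
    hb_pairs = {
        frozenset((b.donor[0].key, b.acceptor[0].key))
        for b in detect_hbonds(structure, criteria)
    }
    tree = cKDTree(coords)
    clashes = []
    for i, j in tree.query_pairs(r=2.0 * 1.9 * overlap_factor + 0.5):
        res_i, at_i, _ = atoms[i]
        res_j, at_j, _ = atoms[j]
        if res_i.key == res_j.key:
            continue
        bonded = (
            res_i.chain == res_j.chain
            and abs(order[res_i.key] - order[res_j.key]) == 1
            and abs(res_i.seq_number - res_j.seq_number) == 1
        )
        if bonded:
            continue  # peptide-linked neighbors: 1-2/1-3 contacts are not clashes
        if frozenset((res_i.seq_number, res_j.seq_number)) in ss_pairs:
            continue
        if frozenset((res_i.key, res_j.key)) in hb_pairs:
            continue
        d = float(np.linalg.norm(at_i.coords - at_j.coords))
        limit = overlap_factor * (_vdw_radius(at_i.element) + _vdw_radius(at_j.element))
        if d < limit:
            label_i = f"{res_i.name}{res_i.seq_number}:{at_i.name}"
            label_j = f"{res_j.name}{res_j.seq_number}:{at_j.name}"
            clashes.append((label_i, label_j, d))
    clashes.sort(key=lambda c: c[2])
    return clashes


def run_qc(structure: Structure, criteria: HBondCriteria | None = None) -> QCReport:
    """Full geometric QC: Ramachandran, cis-prolines, clashes, disulfides."""
    report = ramachandran_classify(structure)
    report.cis_prolines = detect_cis_prolines(structure)
    report.clashes = detect_clashes(structure, criteria=criteria)
    report.disulfides = check_disulfides(structure)
    return report
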