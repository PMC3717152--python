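"""Synthetic inputs for every stage of the evaluation pipeline.

Nothing here pretends to be a real receptor: the generators produce the
*geometric situations* the pipeline must recognize, with known ground truth
and no external files.

* :func:`make_bundle` builds an idealized transmembrane helix bundle:
  ideal alpha-helices (phi = -57 deg, psi = -47 deg, 1.5 A rise per
  residue) stood on a circle, carrying the M2-numbered landmark residues
  (the 10 orthosteric pocket residues with their functional atoms facing
  the bundle axis, plus the checklist residues) as backbone + Cbeta +
  named functional pseudo-atoms.
* :func:`perturb` makes decoys: a rigid transform plus per-coordinate
  Gaussian noise, globally or restricted to a region, so the true
  deviation is known by construction.
* :func:`make_poses` places a rigid mock ligand (cationic nitrogen, ester
  oxygen, two ring dummies) correctly in the pocket, flipped 180 degrees
  about the pocket axis, or displaced out of the site.
* :func:`make_score_table` builds metric tables whose Spearman correlation
  to a generated RMSD vector is prescribed.

All generators are deterministic for a fixed seed and record it in their
output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pose_analysis import LigandAtom, PoseRecord
from .structure_io import Atom, BWMap, MetricTable, Residue, Structure, load_default_bw_map

__all__ = [
    "BundleSpec",
    "PerturbSpec",
    "make_bundle",
    "perturb",
    "displace_residues",
    "make_poses",
    "make_score_table",
]

# ideal backbone internal coordinates (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0

# default seven-helix layout: residue ranges and axial offsets chosen so the
# pocket residues' functional atoms cluster near the bundle mid-plane
_DEFAULT_RANGES: list[tuple[int, int, float]] = [
    (20, 50, 0.0),     # TM1
    (55, 85, -6.0),    # TM2: Ser64, Asp69, Ser76
    (92, 122, 4.0),    # TM3: Cys96, Asp97, Trp99, Asp103, Tyr104, Asn108 ... Arg121
    (140, 170, 0.0),   # TM4: Trp148, Ser151, Trp155, Gln163, Arg169
    (172, 202, 0.0),   # TM5: Cys176, Gln179, Thr187, Thr190
    (380, 410, -12.0), # TM6: Glu382, Tyr403, Asn404
    (412, 442, 0.0),   # TM7: Tyr426, Tyr430, Ser433, Asn436, Tyr440
]

_SPECIAL_RESIDUES: dict[int, str] = {
    64: "SER", 69: "ASP", 76: "SER",
    96: "CYS", 97: "ASP", 99: "TRP", 103: "ASP", 104: "TYR", 108: "ASN",
    113: "ASN", 118: "SER", 120: "ASP", 121: "ARG",
    148: "TRP", 151: "SER", 155: "TRP", 163: "GLN", 169: "ARG",
    176: "CYS", 179: "GLN", 187: "THR", 190: "THR",
    382: "GLU", 403: "TYR", 404: "ASN",
    426: "TYR", 430: "TYR", 433: "SER", 436: "ASN", 440: "TYR",
}

# functional pseudo-atom layout per special residue type:
# (branch atom or None, tip atom names, reach of branch point from CA)
_FUNCTIONAL: dict[str, tuple[str | None, tuple[str, ...], float]] = {
    "SER": (None, ("OG",), 2.5),
    "THR": (None, ("OG1",), 2.5),
    "CYS": (None, ("SG",), 2.6),
    "TYR": (None, ("OH",), 4.0),
    "TRP": (None, ("NE1",), 3.4),
    "ASN": ("CG", ("OD1", "ND2"), 2.5),
    "ASP": ("CG", ("OD1", "OD2"), 2.5),
    "GLN": ("CD", ("OE1", "NE2"), 3.2),
    "GLU": ("CD", ("OE1", "OE2"), 3.2),
    "ARG": ("CZ", ("NH1", "NH2"), 4.0),
}

_PATTERN = ("ALA", "LEU", "VAL", "LEU", "GLY", "ILE", "PHE", "LEU")


class SyntheticError(ValueError):
    pass


@dataclass
class BundleSpec:
    n_helices: int = 7
    residues_per_helix: int = 31
    bundle_radius: float = 11.0
    helix_tilt: float = 0.0  # degrees, tilt of each helix axis from vertical
    seed: int = 0
    phi: float = _HELIX_PHI
    psi: float = _HELIX_PSI
    with_special_residues: bool = True

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise SyntheticError("need at least one helix")
        if self.residues_per_helix < 4:
            raise SyntheticError("need at least 4 residues per helix")
        if self.n_helices > 1 and self.bundle_radius < 8.0:
            raise SyntheticError("bundle radius below 8 A would clash helices")

    def ranges(self) -> list[tuple[int, int, float]]:
        if self.n_helices == 7 and self.residues_per_helix == 31 and self.with_special_residues:
            return list(_DEFAULT_RANGES)
        out = []
        start = 20
        for _ in range(self.n_helices):
            out.append((start, start + self.residues_per_helix - 1, 0.0))
            start += self.residues_per_helix + 10
        return out


@dataclass
class PerturbSpec:
    noise_sigma: float = 0.0  # angstrom, per coordinate
    rigid_rotation: float = 0.0  # degrees
    rigid_translation: float = 0.0  # angstrom
    region: Literal["global", "site", "nonsite"] = "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SyntheticError("noise sigma must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from frame (a, b, c), bond c-d, angle b-c-d, torsion a-b-c-d."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = length * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard virtual-Cbeta construction from backbone frame
    b = ca - n
    c_ = c - ca
    a = np.cross(b, c_)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_ + ca


def _build_backbone(
    n_res: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    overrides: dict[int, dict[str, float]] | None = None,
) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O, CB) for an ideal chain; per-residue phi/psi/omega
    overrides are keyed by 0-based residue index."""
    overrides = overrides or {}

    def tors(i: int, name: str, default: float) -> float:
        return overrides.get(i, {}).get(name, default)

    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, tors(i - 1, "psi", psi))
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, tors(i, "omega", omega))
        c_i = _nerf(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, tors(i, "phi", phi))
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            res["O"] = _nerf(
                res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O,
                tors(i, "psi", psi) + 180.0,
            )
        else:
            res["O"] = _nerf(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, 0.0)
        res["CB"] = _cbeta(res["N"], res["CA"], res["C"])
    return residues


def build_helix(
    n_res: int,
    phi: float = _HELIX_PHI,
    psi: float = _HELIX_PSI,
    overrides: dict[int, dict[str, float]] | None = None,
) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone, axis-aligned to +z and centered."""
    residues = _build_backbone(n_res, phi, psi, overrides=overrides)
    cas = np.array([r["CA"] for r in residues])
    center = cas.mean(axis=0)
    # principal axis of the CA trace, oriented first -> last
    u, s, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        c = float(np.dot(axis, z))
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    out = []
    for res in residues:
        out.append({k: rot @ (v_ - center) for k, v_ in res.items()})
    return out


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, float))
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def _functional_atoms(resname: str, ca: np.ndarray, inward: np.ndarray) -> list[Atom]:
    branch, tips, reach = _FUNCTIONAL[resname]
    atoms: list[Atom] = []
    if branch is None:
        tip = tips[0]
        element = tip[0] if tip[0] in ("O", "N", "S") else "C"
        atoms.append(Atom(tip, element, ca + reach * inward))
        return atoms
    base = ca + reach * inward
    atoms.append(Atom(branch, "C", base))
    perp = _unit(np.cross(inward, np.array([0.0, 0.0, 1.0])))
    for tip, sign in zip(tips, (1.0, -1.0)):
        element = tip[0] if tip[0] in ("O", "N", "S") else "C"
        direction = _unit(0.82 * inward + sign * 0.57 * perp)
        atoms.append(Atom(tip, element, base + 1.25 * direction))
    return atoms


def make_bundle(spec: BundleSpec | None = None) -> Structure:
    """Idealized transmembrane bundle carrying the landmark residues.

    Helices are placed on a circle of ``bundle_radius`` around the z axis;
    functional atoms of special residues face the axis. The output passes
    the clean-structure QC suite (all classified residues favored, no
    clashes, no cis-prolines).
    """
    spec = spec or BundleSpec()
    structure = Structure(id=f"bundle_seed{spec.seed}")
    structure.metadata = {"generator": "make_bundle", "seed": spec.seed}
    chain: list[Residue] = []
    ranges = spec.ranges()
    for k, (start, end, z_off) in enumerate(ranges):
        n_res = end - start + 1
        helix = build_helix(n_res, phi=spec.phi, psi=spec.psi)
        azimuth = 2.0 * math.pi * k / max(len(ranges), 1)
        origin = spec.bundle_radius * np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
        origin = origin + np.array([0.0, 0.0, z_off])
        tilt = _rotation_about(np.array([math.cos(azimuth + math.pi / 2),
                                         math.sin(azimuth + math.pi / 2), 0.0]),
                               spec.helix_tilt)
        for i, res_atoms in enumerate(helix):
            seq = start + i
            name = _SPECIAL_RESIDUES.get(seq) if spec.with_special_residues else None
            name = name or _PATTERN[i % len(_PATTERN)]
            coords = {at: tilt @ pos + origin for at, pos in res_atoms.items()}
            atoms = [Atom(at, at[0], xyz) for at, xyz in coords.items()]
            if spec.with_special_residues and seq in _SPECIAL_RESIDUES:
                ca = coords["CA"]
                inward = _unit(np.array([-ca[0], -ca[1], 0.0]))
                atoms.extend(_functional_atoms(name, ca, inward))
            chain.append(Residue(name=name, seq_number=seq, chain="A", atoms=atoms))
    structure.chains["A"] = chain
    return structure.validate()


def _region_mask(structure: Structure, region: str, bw_map: BWMap | None) -> set:
    if region == "global":
        return {r.key for r in structure.residues()}
    bw_map = bw_map or load_default_bw_map()
    site_nums = {num for _, num in (bw_map.entries[c] for c in bw_map.binding_site)}
    site = {r.key for r in structure.residues() if r.seq_number in site_nums}
    if region == "site":
        return site
    if region == "nonsite":
        return {r.key for r in structure.residues()} - site
    raise SyntheticError(f"unknown region {region!r}")


def perturb(structure: Structure, spec: PerturbSpec, bw_map: BWMap | None = None) -> Structure:
    """Decoy: rigid transform followed by i.i.d. Gaussian coordinate noise.

    Noise is applied only to the selected region; atom count, residue
    identity and topology are untouched. The spec is recorded in the
    output's metadata.
    """
    rng = np.random.default_rng(spec.seed)
    out = structure.copy()
    out.id = f"{structure.id}_decoy"
    out.metadata = dict(structure.metadata)
    out.metadata["perturb"] = {
        "noise_sigma": spec.noise_sigma,
        "rigid_rotation": spec.rigid_rotation,
        "rigid_translation": spec.rigid_translation,
        "region": spec.region,
        "seed": spec.seed,
    }
    all_coords = out.coords()
    centroid = all_coords.mean(axis=0)
    R = _rotation_about(rng.normal(size=3), spec.rigid_rotation)
    t = spec.rigid_translation * _unit(rng.normal(size=3)) if spec.rigid_translation else np.zeros(3)
    mask = _region_mask(out, spec.region, bw_map)
    for res in out.residues():
        noisy = res.key in mask
        for atom in res.atoms:
            atom.coords = R @ (atom.coords - centroid) + centroid + t
            if noisy and spec.noise_sigma > 0:
                atom.coords = atom.coords + rng.normal(0.0, spec.noise_sigma, size=3)
    for _, atoms in out.ligands:
        for atom in atoms:
            atom.coords = R @ (atom.coords - centroid) + centroid + t
    return out


def displace_residues(
    structure: Structure, seq_numbers: Sequence[int], translation: Sequence[float]
) -> Structure:
    """Copy with the given residues rigidly displaced (loop-decoy helper)."""
    out = structure.copy()
    out.id = f"{structure.id}_displaced"
    t = np.asarray(translation, float)
    wanted = set(seq_numbers)
    for res in out.residues():
        if res.seq_number in wanted:
            for atom in res.atoms:
                atom.coords = atom.coords + t
    return out


def _pocket_landmarks(receptor: Structure, bw_map: BWMap):
    from .pose_analysis import site_center

    asp_name, asp_num = bw_map.entries["3.32"]
    asn_name, asn_num = bw_map.entries["6.52"]
    asp = receptor.find_by_name(asp_name, asp_num)
    asn = receptor.find_by_name(asn_name, asn_num)
    ox = [asp.atom(n).coords for n in ("OD1", "OD2") if asp.has_atom(n)]
    if not ox:
        raise SyntheticError("receptor 3.32 residue lacks carboxylate oxygens")
    amide = asn.atom("ND2").coords if asn.has_atom("ND2") else asn.atom("OD1").coords
    return np.mean(ox, axis=0), amide, site_center(receptor, bw_map)


def make_poses(
    receptor: Structure,
    kind: Literal["correct", "flipped", "displaced"],
    seed: int = 0,
    ligand_id: str = "MOCK",
    pose_id: str | None = None,
    bw_map: BWMap | None = None,
) -> PoseRecord:
    """Mock rigid ligand pose with known classification.

    ``correct`` satisfies both pharmacophore contacts inside the pocket;
    ``flipped`` is the same ligand rotated 180 degrees about the vertical
    pocket axis (cation contact lost); ``displaced`` is moved 15 A out of
    the site.
    """
    if kind not in ("correct", "flipped", "displaced"):
        raise SyntheticError(f"unknown pose kind {kind!r}")
    bw_map = bw_map or load_default_bw_map()
    rng = np.random.default_rng(seed)
    ox_mid, amide, center = _pocket_landmarks(receptor, bw_map)
    u = _unit(center - ox_mid)
    v = _unit(center - amide)
    n_pos = ox_mid + 3.5 * u
    o_pos = amide + 2.9 * v
    mid = 0.5 * (n_pos + o_pos)
    atoms = [
        LigandAtom("N1", "N", n_pos, formal_charge=1, n_heavy_neighbors=4),
        LigandAtom("C1", "C", mid + np.array([0.0, 0.0, 0.7])),
        LigandAtom("C2", "C", mid - np.array([0.0, 0.0, 0.7])),
        LigandAtom("O1", "O", o_pos),
    ]
    jitter = rng.normal(0.0, 0.05, size=(len(atoms), 3))
    for atom, dx in zip(atoms, jitter):
        atom.coords = atom.coords + dx
    if kind == "flipped":
        flip = _rotation_about(np.array([0.0, 0.0, 1.0]), 180.0)
        for atom in atoms:
            atom.coords = flip @ (atom.coords - center) + center
    elif kind == "displaced":
        shift = 15.0 * _unit(np.array([center[0] + 1.0, center[1] + 1.0, 0.0]) - center)
        for atom in atoms:
            atom.coords = atom.coords + shift
    return PoseRecord(
        ligand_id=ligand_id,
        pose_id=pose_id or f"{ligand_id}_{kind}_{seed}",
        atoms=atoms,
    )


def make_score_table(
    n_models: int,
    target_rho: float | dict[str, float],
    seed: int = 0,
    rmsd_range: tuple[float, float] = (2.8, 5.6),
    n_candidates: int = 32,
) -> MetricTable:
    """Metric table with prescribed Spearman correlation to its RMSD column.

    Each metric column is a rank blend ``rho * z(rank(RMSD)) + sqrt(1-rho^2)
    * noise``; among ``n_candidates`` seeded draws the one whose realized
    rho is closest to the target is kept (exact at |rho| = 1).
    """
    from scipy import stats as sps

    if n_models < 4:
        raise SyntheticError("need at least 4 models")
    targets = target_rho if isinstance(target_rho, dict) else {"metric": float(target_rho)}
    for name, rho in targets.items():
        if not -1.0 <= rho <= 1.0:
            raise SyntheticError(f"{name}: |target rho| must be <= 1")
    rng = np.random.default_rng(seed)
    lo, hi = rmsd_range
    rmsd = np.sort(rng.uniform(lo, hi, size=n_models))
    z_rank = sps.zscore(sps.rankdata(rmsd))
    data = {"RMSD": rmsd}
    for name, rho in targets.items():
        if abs(rho) == 1.0:
            data[name] = math.copysign(1.0, rho) * rmsd
            continue
        best_col, best_err = None, np.inf
        for _ in range(n_candidates):
            noise = rng.normal(size=n_models)
            col = rho * z_rank + math.sqrt(1.0 - rho * rho) * sps.zscore(noise)
            realized = float(sps.spearmanr(col, rmsd).statistic)
            err = abs(realized - rho)
            if err < best_err:
                best_col, best_err = col, err
        data[name] = best_col
    df = pd.DataFrame(data, index=[f"model{i:03d}" for i in range(1, n_models + 1)])
    return MetricTable(
        data=df,
        rmsd_column="RMSD",
        directions={name: "positive_better" for name in targets},
    )
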