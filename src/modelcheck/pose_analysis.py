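"""Docking-pose triage for muscarinic-receptor models.

Orthosteric muscarinic ligands share two essential contacts (the classic
two-point pharmacophore): the cationic/quaternary nitrogen head-group pairs
with the conserved TM III aspartate (BW 3.32) and an electronegative part of
the ligand accepts a hydrogen bond from the TM VI asparagine amide (BW 6.52).
A docking pose is *good* when it sits inside the orthosteric pocket and makes
both contacts; otherwise it is *bad*, with every failed condition recorded.

Because the two rescoring functions disagree on different RMSD regimes, the
*best* pose per ligand/model is chosen by a dual-score consensus: among the
top-scoring poses by the MM/GBSA-style energy (more negative = better), take
the one with the highest binding-energy-function score (more positive =
better).

Experimental dissociation constants are converted to binding free-energy
magnitudes with dG = -R T ln(Kd / 1 M); only *relative* predicted energies
are ever compared to these (absolute rescoring energies neglect entropy and
overshoot severely).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_qc import HBondCriteria
from .structure_io import Atom, BWMap, Structure, load_default_bw_map, select_residues

__all__ = [
    "PoseRecord",
    "PharmacophoreRules",
    "AffinityRecord",
    "classify_pose",
    "select_best",
    "kd_to_dG",
    "rank_agreement",
    "energy_rmsd_split",
    "read_poses_sdf",
    "read_pose_energies",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class LigandAtom:
    name: str
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    n_heavy_neighbors: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)


@dataclass
class PoseRecord:
    ligand_id: str
    pose_id: str
    atoms: list[LigandAtom] = field(default_factory=list)
    prime_energy: float | None = None   # kcal/mol, more negative = better
    yasara_energy: float | None = None  # kcal/mol, more positive = better
    autodock_energy: float | None = None
    rmsd_to_ref: float | None = None
    label: Literal["good", "bad", "unset"] = "unset"
    reasons: list[str] = field(default_factory=list)
    best: bool = False

    def __post_init__(self) -> None:
        for e in (self.prime_energy, self.yasara_energy, self.autodock_energy):
            if e is not None and not math.isfinite(e):
                raise ValueError(f"pose {self.pose_id}: non-finite energy")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.element.upper() != "H"])

    def cationic_nitrogens(self) -> list[LigandAtom]:
        """Nitrogens counted as cationic: formally charged, or quaternary."""
        return [
            a
            for a in self.atoms
            if a.element.upper() == "N" and (a.formal_charge > 0 or a.n_heavy_neighbors >= 4)
        ]

    def acceptor_atoms(self) -> list[LigandAtom]:
        return [a for a in self.atoms if a.element.upper() in ("O", "N")]


@dataclass
class PharmacophoreRules:
    cation_partner: str = "3.32"
    cation_max_distance: float = 4.5
    acceptor_partner: str = "6.52"
    acceptor_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    site_radius: float = 8.0
    site_codes: list[str] | None = None  # default: BW map binding site

    def __post_init__(self) -> None:
        if self.cation_max_distance <= 0 or self.site_radius <= 0:
            raise ValueError("distances must be positive")


@dataclass
class AffinityRecord:
    ligand_id: str
    kd: float  # molar
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"{self.ligand_id}: Kd must be positive")

    @property
    def dG(self) -> float:
        return kd_to_dG(self.kd, self.temperature)


_CARBOXYLATE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_AMIDE = {"ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2")}


def site_center(receptor: Structure, bw_map: BWMap, codes: list[str] | None = None) -> np.ndarray:
    """Heavy-atom centroid of the binding-site residues."""
    residues = select_residues(receptor, codes or bw_map.binding_site, bw_map)
    coords = np.array([a.coords for r in residues for a in r.heavy_atoms()])
    return coords.mean(axis=0)


def classify_pose(
    pose: PoseRecord,
    receptor: Structure,
    rules: PharmacophoreRules | None = None,
    bw_map: BWMap | None = None,
) -> PoseRecord:
    """Label a pose good/bad against the two-point muscarinic pharmacophore.

    Good requires all of: (a) ligand centroid inside the pocket sphere,
    (b) a cationic ligand nitrogen within ``cation_max_distance`` of the
    midpoint of the 3.32 carboxylate oxygens, (c) at least one ligand O/N
    within hydrogen-bond range of the 6.52 side-chain amide. Failed
    conditions are appended to ``pose.reasons``.
    """
    rules = rules or PharmacophoreRules()
    bw_map = bw_map or load_default_bw_map()
    (asp_res,) = select_residues(receptor, [rules.cation_partner], bw_map)
    (asn_res,) = select_residues(receptor, [rules.acceptor_partner], bw_map)
    if asp_res.name not in _CARBOXYLATE:
        raise ValueError(f"cation partner {asp_res.name}{asp_res.seq_number} has no carboxylate")
    if asn_res.name not in _AMIDE:
        raise ValueError(f"acceptor partner {asn_res.name}{asn_res.seq_number} has no amide")

    reasons: list[str] = []
    heavy = pose.heavy_coords()
    if heavy.size == 0:
        raise ValueError(f"pose {pose.pose_id}: no heavy atoms")
    center = site_center(receptor, bw_map, rules.site_codes)
    if np.linalg.norm(heavy.mean(axis=0) - center) > rules.site_radius:
        reasons.append("outside binding site")

    ox_names = [n for n in _CARBOXYLATE[asp_res.name] if asp_res.has_atom(n)]
    if not ox_names:
        raise ValueError(f"{asp_res.name}{asp_res.seq_number}: carboxylate oxygens missing")
    ox_mid = np.mean([asp_res.atom(n).coords for n in ox_names], axis=0)
    cations = pose.cationic_nitrogens()
    if not cations:
        reasons.append("no cationic nitrogen in ligand")
    elif min(np.linalg.norm(a.coords - ox_mid) for a in cations) > rules.cation_max_distance:
        reasons.append(f"cation contact to {rules.cation_partner} failed")

    amide_names = [n for n in _AMIDE[asn_res.name] if asn_res.has_atom(n)]
    if not amide_names:
        raise ValueError(f"{asn_res.name}{asn_res.seq_number}: amide atoms missing")
    cutoff = rules.acceptor_criteria.heavy_only_distance
    amide_coords = [asn_res.atom(n).coords for n in amide_names]
    contact = any(
        np.linalg.norm(a.coords - ac) <= cutoff
        for a in pose.acceptor_atoms()
        for ac in amide_coords
    )
    if not contact:
        reasons.append(f"hydrogen bond to {rules.acceptor_partner} failed")

    pose.label = "good" if not reasons else "bad"
    pose.reasons = reasons
    return pose


def select_best(poses: Sequence[PoseRecord], top_n: int = 10) -> PoseRecord:
    """Dual-score consensus: max binding-energy-function score among the
    ``top_n`` poses by MM/GBSA-style energy.

    Ties are broken by pose_id, so the result is independent of input order.
    """
    scored = [p for p in poses if p.prime_energy is not None and p.yasara_energy is not None]
    if not scored:
        raise ValueError("select_best needs at least one pose with both energies")
    top = sorted(scored, key=lambda p: (p.prime_energy, p.pose_id))[:top_n]
    best = max(top, key=lambda p: (p.yasara_energy, _neg_id(p.pose_id)))
    for p in poses:
        p.best = p is best
    return best


def _neg_id(pose_id: str) -> tuple:
    # max() with lexicographically *smallest* id on yasara ties
    return tuple(-ord(c) for c in pose_id)


def kd_to_dG(kd: float, temperature: float = 298.15) -> float:
    """Binding free-energy magnitude -R T ln(Kd / 1 M), kcal/mol.

    Reported as a positive number for sub-molar Kd (the usual convention
    when quoting 'binding energies' of high-affinity ligands).
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -GAS_CONSTANT_KCAL * temperature * math.log(kd)


def rank_agreement(
    best_poses: dict[str, PoseRecord] | Sequence[PoseRecord],
    affinities: Sequence[AffinityRecord],
    score: Literal["prime", "yasara"] = "yasara",
) -> dict:
    """Spearman agreement between predicted best-pose energies and
    experimental binding energies.

    Predicted energies are direction-corrected (prime: more negative =
    stronger; yasara: more positive = stronger) so that perfect agreement
    with the experimental affinity order gives rho = +1.
    """
    if not isinstance(best_poses, dict):
        best_poses = {p.ligand_id: p for p in best_poses}
    aff = {a.ligand_id: a for a in affinities}
    shared = [lig for lig in aff if lig in best_poses]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ligands, got {len(shared)}")
    if score == "prime":
        predicted = [-best_poses[lig].prime_energy for lig in shared]
    elif score == "yasara":
        predicted = [best_poses[lig].yasara_energy for lig in shared]
    else:
        raise ValueError(f"unknown score {score!r}")
    experimental = [aff[lig].dG for lig in shared]
    rho = float(sps.spearmanr(predicted, experimental).statistic)
    return {
        "spearman_rho": rho,
        "concordant": bool(rho > 1 - 1e-9),
        "n": len(shared),
        "ligands": shared,
    }


def energy_rmsd_split(
    poses: Sequence[PoseRecord],
    energy: Literal["prime", "yasara", "autodock"] = "prime",
    threshold: float = 3.0,
) -> dict:
    """Pearson correlation of pose energy vs RMSD, on all poses and on the
    near-native subset (rmsd < threshold).

    A coefficient whose subset has fewer than 3 points is reported as None.
    """
    attr = f"{energy}_energy"
    pts = [
        (p.rmsd_to_ref, getattr(p, attr))
        for p in poses
        if p.rmsd_to_ref is not None and getattr(p, attr) is not None
    ]
    if len(pts) < 3:
        raise ValueError("need >= 3 poses with RMSD and energy")
    rmsd = np.array([x for x, _ in pts])
    en = np.array([y for _, y in pts])

    def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return None
        return float(sps.pearsonr(x, y).statistic)

    below = rmsd < threshold
    return {
        "r_all": _pearson(rmsd, en),
        "r_below": _pearson(rmsd[below], en[below]),
        "n_all": int(len(rmsd)),
        "n_below": int(below.sum()),
        "threshold": threshold,
        "energy": energy,
    }


def read_poses_sdf(path: str | Path) -> list[PoseRecord]:
    """Read ligand poses from an SDF file (rdkit), one pose per molecule.

    ``ligand_id``/``pose_id`` are taken from molecule properties when
    present, else from the title or running index.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    poses: list[PoseRecord] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable molecule at index {i}")
        conf = mol.GetConformer()
        atoms = []
        for at in mol.GetAtoms():
            pos = conf.GetAtomPosition(at.GetIdx())
            atoms.append(
                LigandAtom(
                    name=f"{at.GetSymbol()}{at.GetIdx() + 1}",
                    element=at.GetSymbol(),
                    coords=np.array([pos.x, pos.y, pos.z]),
                    formal_charge=at.GetFormalCharge(),
                    n_heavy_neighbors=sum(
                        1 for nb in at.GetNeighbors() if nb.GetAtomicNum() > 1
                    ),
                )
            )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        lig = mol.GetProp("ligand_id") if mol.HasProp("ligand_id") else name
        pid = mol.GetProp("pose_id") if mol.HasProp("pose_id") else f"{name}_{i}"
        poses.append(PoseRecord(ligand_id=lig, pose_id=pid, atoms=atoms))
    return poses


def read_pose_energies(path: str | Path) -> pd.DataFrame:
    """Read the externally computed per-pose energy table.

    Columns: ligand_id, pose_id, prime_energy, yasara_energy
    [, autodock_energy, rmsd_to_ref].
    """
    df = pd.read_csv(path)
    required = {"ligand_id", "pose_id", "prime_energy", "yasara_energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def attach_energies(poses: Sequence[PoseRecord], energies: pd.DataFrame) -> list[PoseRecord]:
    """Join an energy table onto pose records by (ligand_id, pose_id)."""
    table = energies.set_index(["ligand_id", "pose_id"])
    for pose in poses:
        key = (pose.ligand_id, pose.pose_id)
        if key not in table.index:
            continue
        row = table.loc[key]
        pose.prime_energy = float(row["prime_energy"])
        pose.yasara_energy = float(row["yasara_energy"])
        if "autodock_energy" in row and pd.notna(row.get("autodock_energy")):
            pose.autodock_energy = float(row["autodock_energy"])
        if "rmsd_to_ref" in row and pd.notna(row.get("rmsd_to_ref")):
            pose.rmsd_to_ref = float(row["rmsd_to_ref"])
    return list(poses)
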