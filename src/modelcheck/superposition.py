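"""Rigid-body superposition and the four subset RMSD flavors.

Model-vs-reference deviation is reported four ways, mirroring how homology
models of a receptor are usually compared to a crystal structure:

* ``whole``        — Calpha atoms of all sequence-paired residues;
* ``aligned``      — Calpha atoms of the structurally conserved core, found
                     by iteratively trimming pairs whose Calpha-Calpha
                     distance exceeds a cutoff after re-superposition;
* ``binding_site`` — heavy atoms of the orthosteric-site residues,
                     superposed on those same atoms;
* ``ligand``       — ligand heavy atoms after binding-site superposition,
                     with no re-fit on the ligand itself.

The optimal rotation is the Kabsch/SVD solution with the reflection branch
excluded (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from Bio import Align

from .structure_io import BWMap, Residue, Structure, load_default_bw_map

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "kabsch",
    "pair_by_sequence",
    "structurally_aligned_set",
    "subset_rmsd",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


class SuperpositionError(ValueError):
    pass


@dataclass
class Correspondence:
    pairs: list[tuple[Residue, Residue]]
    mode: Literal["sequence", "structural"] = "sequence"

    def __post_init__(self) -> None:
        a_keys = [p[0].key for p in self.pairs]
        b_keys = [p[1].key for p in self.pairs]
        if len(a_keys) != len(set(a_keys)) or len(b_keys) != len(set(b_keys)):
            raise SuperpositionError("correspondence is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def ca_coords(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = [(a, b) for a, b in self.pairs if a.has_atom("CA") and b.has_atom("CA")]
        xa = np.array([a.atom("CA").coords for a, _ in pairs])
        xb = np.array([b.atom("CA").coords for _, b in pairs])
        return xa, xb


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, angstrom
    rmsd: float
    n_pairs: int
    atom_mode: Literal["CA", "heavy"] = "CA"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise SuperpositionError("rotation is not a proper orthonormal matrix")
        if self.rmsd < 0 or self.n_pairs < 3:
            raise SuperpositionError("invalid superposition result")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray, atom_mode: str = "CA") -> SuperpositionResult:
    """Least-squares fit of ``coords_a`` onto ``coords_b`` (Kabsch, SVD).

    Returns the proper rotation R and translation t minimizing
    ``|| a @ R.T + t - b ||``; reflections are excluded by flipping the sign
    of the smallest singular vector when det would be negative.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError(f"coordinate shapes differ or are not Nx3: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    for pts in (a0, b0):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise SuperpositionError("degenerate (collinear) point set")
    H = a0.T @ b0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((a0 @ R.T - b0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n, atom_mode=atom_mode)


def _sequence_of(residues: list[Residue]) -> str:
    return "".join(_THREE_TO_ONE.get(r.name, "X") for r in residues)


def pair_by_sequence(model: Structure, ref: Structure) -> Correspondence:
    """Pair residues of a model with a reference.

    When both structures use the same author numbering the pairing is by
    (chain, seq_number, icode); otherwise chains are paired in order and a
    global alignment of one-letter sequences (identity scoring) is used.
    """
    if model.n_residues == 0 or ref.n_residues == 0:
        raise SuperpositionError("cannot pair residues of an empty structure")
    ref_index = {r.key: r for r in ref.residues()}
    pairs = [(r, ref_index[r.key]) for r in model.residues() if r.key in ref_index]
    # identical-numbering fast path; fall back to alignment when overlap is poor
    if len(pairs) < max(3, min(model.n_residues, ref.n_residues) // 2):
        pairs = _pair_by_alignment(model, ref)
    if len(pairs) < 3:
        raise SuperpositionError(
            f"fewer than 3 pairable residues between {model.id!r} and {ref.id!r}"
        )
    return Correspondence(pairs=pairs, mode="sequence")


def _pair_by_alignment(model: Structure, ref: Structure) -> list[tuple[Residue, Residue]]:
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0, open_gap_score=-1, extend_gap_score=-0.5
    )
    pairs: list[tuple[Residue, Residue]] = []
    for chain_m, chain_r in zip(model.chains.values(), ref.chains.values()):
        aln = aligner.align(_sequence_of(chain_m), _sequence_of(chain_r))[0]
        for (ms, me), (rs, re_) in zip(*aln.aligned):
            for i, j in zip(range(ms, me), range(rs, re_)):
                if chain_m[i].name == chain_r[j].name:
                    pairs.append((chain_m[i], chain_r[j]))
    return pairs


def structurally_aligned_set(
    model: Structure,
    ref: Structure,
    cutoff: float = 3.5,
    max_iter: int = 10,
) -> tuple[Correspondence, SuperpositionResult]:
    """Structurally conserved core by iterative Calpha trimming.

    Starting from the sequence pairing, superpose on the current pair set,
    drop pairs whose Calpha-Calpha distance exceeds ``cutoff``, and repeat
    until no pair is dropped or ``max_iter`` is reached. Deterministic, and
    the pair count never increases across iterations.
    """
    corr = pair_by_sequence(model, ref)
    pairs = [(a, b) for a, b in corr.pairs if a.has_atom("CA") and b.has_atom("CA")]
    result: SuperpositionResult | None = None
    for _ in range(max_iter):
        if len(pairs) < 3:
            raise SuperpositionError("structural core shrank below 3 residues")
        xa = np.array([a.atom("CA").coords for a, _ in pairs])
        xb = np.array([b.atom("CA").coords for _, b in pairs])
        result = kabsch(xa, xb)
        dists = np.linalg.norm(result.apply(xa) - xb, axis=1)
        keep = dists <= cutoff
        if keep.all():
            break
        pairs = [p for p, k in zip(pairs, keep) if k]
    else:
        xa = np.array([a.atom("CA").coords for a, _ in pairs])
        xb = np.array([b.atom("CA").coords for _, b in pairs])
        result = kabsch(xa, xb)
    if len(pairs) < 3 or result is None:
        raise SuperpositionError("structural core shrank below 3 residues")
    return Correspondence(pairs=pairs, mode="structural"), result


def _paired_heavy_atoms(pairs: list[tuple[Residue, Residue]]) -> tuple[np.ndarray, np.ndarray]:
    xa, xb = [], []
    for a, b in pairs:
        b_atoms = {at.name: at for at in b.heavy_atoms()}
        for at in a.heavy_atoms():
            if at.name in b_atoms:
                xa.append(at.coords)
                xb.append(b_atoms[at.name].coords)
    return np.array(xa), np.array(xb)


def _binding_site_pairs(
    model: Structure, ref: Structure, bw_map: BWMap, codes: list[str] | None
) -> list[tuple[Residue, Residue]]:
    codes = codes or bw_map.binding_site
    pairs = []
    missing = []
    for code in codes:
        name, num = bw_map.entries[code]
        try:
            pairs.append((model.find_by_name(name, num), ref.find_by_name(name, num)))
        except KeyError:
            missing.append(f"{name}{num} ({code})")
    if missing:
        raise SuperpositionError(f"binding-site residues missing: {', '.join(missing)}")
    return pairs


def subset_rmsd(
    model: Structure,
    ref: Structure,
    subset: Literal["whole", "aligned", "binding_site", "ligand"],
    bw_map: BWMap | None = None,
    binding_site_codes: list[str] | None = None,
    cutoff: float = 3.5,
    max_iter: int = 10,
    whole_atom_mode: Literal["CA", "heavy"] = "CA",
) -> tuple[float, SuperpositionResult]:
    """RMSD of one subset after the subset-appropriate superposition.

    Returns (rmsd, superposition used). For ``ligand`` the superposition is
    computed on the binding-site heavy atoms and the ligand RMSD is measured
    under that transform without re-fitting; ligand atoms are matched by
    position in the atom list (fixed ordering, no symmetry expansion).
    """
    if subset == "whole":
        corr = pair_by_sequence(model, ref)
        if whole_atom_mode == "CA":
            xa, xb = corr.ca_coords()
        else:
            xa, xb = _paired_heavy_atoms(corr.pairs)
        res = kabsch(xa, xb, atom_mode=whole_atom_mode)
        return res.rmsd, res
    if subset == "aligned":
        _, res = structurally_aligned_set(model, ref, cutoff=cutoff, max_iter=max_iter)
        return res.rmsd, res
    bw_map = bw_map or load_default_bw_map()
    pairs = _binding_site_pairs(model, ref, bw_map, binding_site_codes)
    xa, xb = _paired_heavy_atoms(pairs)
    if len(xa) < 3:
        raise SuperpositionError("fewer than 3 matched binding-site heavy atoms")
    site = kabsch(xa, xb, atom_mode="heavy")
    if subset == "binding_site":
        return site.rmsd, site
    if subset == "ligand":
        if not model.ligands or not ref.ligands:
            raise SuperpositionError("both structures must carry a ligand for ligand RMSD")
        la = [a.coords for a in model.ligands[0][1] if not a.is_hydrogen]
        lb = [a.coords for a in ref.ligands[0][1] if not a.is_hydrogen]
        if len(la) != len(lb):
            raise SuperpositionError(
                f"ligand heavy-atom counts differ: {len(la)} vs {len(lb)}"
            )
        moved = site.apply(np.array(la))
        rmsd = float(np.sqrt(np.mean(np.sum((moved - np.array(lb)) ** 2, axis=1))))
        return rmsd, site
    raise ValueError(f"unknown subset {subset!r}")
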