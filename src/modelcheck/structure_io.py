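"""Structure and score-table I/O for receptor-model evaluation.

The in-memory model is a deliberately small hierarchy (:class:`Atom`,
:class:`Residue`, :class:`Structure`) carrying author (PDB) numbering and
coordinates in angstrom. Parsing and writing of PDB files is delegated to
gemmi; this module only maps between gemmi's hierarchy and ours, partitions
protein from ligand records, and attaches Ballesteros-Weinstein (BW) generic
numbering through a :class:`BWMap`.

BW codes ("helix.position", e.g. ``3.32`` for the conserved TM III aspartate)
let binding-site definitions be written once per receptor family and resolved
to sequence numbers per receptor; the packaged default map covers the human
M2 muscarinic receptor's orthosteric site and checklist residues.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "BWMap",
    "MetricTable",
    "STANDARD_AMINO_ACIDS",
    "read_structure",
    "write_structure",
    "select_residues",
    "bw_lookup",
    "read_score_table",
    "load_default_bw_map",
    "default_binding_site_codes",
    "packaged_data_path",
]

#: Three-letter codes treated as protein when partitioning ATOM/HETATM records.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

_BW_CODE_RE = re.compile(r"^\d\.\d{1,2}$")


class StructureError(ValueError):
    """Raised for unreadable, empty or internally inconsistent structures."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    name: str
    seq_number: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    bw_code: str | None = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name}{self.seq_number}: duplicate atom names"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.seq_number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    """One protein structure plus any ligands, author numbering preserved."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[tuple[str, list[Atom]]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "Structure":
        if self.n_residues == 0:
            raise StructureError(f"structure {self.id!r} contains no protein residues")
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise StructureError(
                    f"structure {self.id!r}: duplicate residue "
                    f"(chain {res.chain!r}, {res.seq_number}{res.icode})"
                )
            seen.add(res.key)
        return self

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def find_residue(self, chain: str | None, seq_number: int) -> Residue:
        pools = [self.chains[chain]] if chain is not None else self.chains.values()
        for pool in pools:
            for res in pool:
                if res.seq_number == seq_number:
                    return res
        where = f"chain {chain!r}" if chain is not None else "any chain"
        raise KeyError(f"residue {seq_number} not found in {where} of {self.id!r}")

    def find_by_name(self, name: str, seq_number: int) -> Residue:
        for res in self.residues():
            if res.seq_number == seq_number and res.name == name.upper():
                return res
        raise KeyError(f"residue {name}{seq_number} not found in {self.id!r}")

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms: list[np.ndarray] = []
        for res in self.residues():
            pool = res.heavy_atoms() if heavy_only else res.atoms
            atoms.extend(a.coords for a in pool)
        for _, lig_atoms in self.ligands:
            atoms.extend(a.coords for a in lig_atoms if not (heavy_only and a.is_hydrogen))
        return np.array(atoms, dtype=float)

    def copy(self) -> "Structure":
        new = Structure(id=self.id, metadata=dict(self.metadata))
        for cname, residues in self.chains.items():
            new.chains[cname] = [
                Residue(
                    name=r.name,
                    seq_number=r.seq_number,
                    chain=r.chain,
                    atoms=[Atom(a.name, a.element, a.coords.copy(), a.is_hydrogen) for a in r.atoms],
                    icode=r.icode,
                    bw_code=r.bw_code,
                )
                for r in residues
            ]
        new.ligands = [
            (name, [Atom(a.name, a.element, a.coords.copy(), a.is_hydrogen) for a in atoms])
            for name, atoms in self.ligands
        ]
        return new

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> x @ R.T + t`` applied to every atom."""
        new = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for res in new.residues():
            for a in res.atoms:
                a.coords = R @ a.coords + t
        for _, atoms in new.ligands:
            for a in atoms:
                a.coords = R @ a.coords + t
        return new


@dataclass
class BWMap:
    """Bijection between BW generic codes and (residue name, sequence number)."""

    entries: dict[str, tuple[str, int]]
    receptor: str = ""
    binding_site: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = list(self.entries.values())
        if len(values) != len(set(values)):
            raise ValueError("BW map is not bijective: duplicate residue assignments")
        for code in self.entries:
            if not _BW_CODE_RE.match(code):
                raise ValueError(f"malformed BW code {code!r}")
        missing = [c for c in self.binding_site if c not in self.entries]
        if missing:
            raise ValueError(f"binding-site codes missing from BW map: {missing}")

    @classmethod
    def from_json(cls, path: str | Path) -> "BWMap":
        data = json.loads(Path(path).read_text())
        entries = {code: (name.upper(), int(num)) for code, (name, num) in data["entries"].items()}
        return cls(
            entries=entries,
            receptor=data.get("receptor", ""),
            binding_site=list(data.get("binding_site", [])),
        )


@dataclass
class MetricTable:
    """Models x quality metrics, with per-metric 'better' direction."""

    data: pd.DataFrame  # index: model ids; columns numeric
    rmsd_column: str = "RMSD"
    directions: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 4:
            raise ValueError("metric table needs at least 4 rows")
        for col, direction in self.directions.items():
            if direction not in (None, "positive_better", "negative_better"):
                raise ValueError(f"column {col!r}: unknown direction {direction!r}")

    @property
    def metric_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != self.rmsd_column]


def packaged_data_path(name: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(resources.files("modelcheck").joinpath("data", name))


def load_default_bw_map() -> BWMap:
    """The packaged M2 muscarinic receptor BW map."""
    return BWMap.from_json(packaged_data_path("m2_bw_map.json"))


def default_binding_site_codes() -> list[str]:
    """BW codes of the 10 orthosteric binding-site residues."""
    return list(load_default_bw_map().binding_site)


def _from_gemmi(st: gemmi.Structure, structure_id: str | None = None) -> Structure:
    if len(st) == 0:
        raise StructureError("structure contains no models")
    model = st[0]  # first model only
    out = Structure(id=structure_id or st.name or "structure")
    for chain in model:
        for res in chain:
            atoms: list[Atom] = []
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                el = at.element.name.upper() if at.element else ""
                atoms.append(
                    Atom(
                        name=at.name,
                        element=el or at.name[:1],
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hydrogen=(el in ("H", "D")),
                    )
                )
            if not atoms:
                continue
            resname = res.name.upper()
            if resname in STANDARD_AMINO_ACIDS:
                out.chains.setdefault(chain.name, []).append(
                    Residue(
                        name=resname,
                        seq_number=res.seqid.num,
                        chain=chain.name,
                        atoms=atoms,
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
            else:
                if resname == "HOH":
                    continue
                out.ligands.append((resname, atoms))
    return out.validate()


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a structure file into the package's hierarchy.

    Only the first model of multi-model files is read and only altloc ""/"A"
    atoms are kept. Records are partitioned into protein residues (standard
    amino-acid names) and ligands; waters are dropped.
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, structure_id=path.stem)


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write the structure as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cname, residues in structure.chains.items():
        chain = gemmi.Chain(cname)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.seq_number, res.icode or " ")
            for a in res.atoms:
                g_at = gemmi.Atom()
                g_at.name = a.name
                g_at.element = gemmi.Element(a.element)
                g_at.pos = gemmi.Position(*a.coords)
                g_res.add_atom(g_at)
            chain.add_residue(g_res)
        model.add_chain(chain)
    if structure.ligands:
        lig_chain = gemmi.Chain("X")
        for i, (name, atoms) in enumerate(structure.ligands, start=1):
            g_res = gemmi.Residue()
            g_res.name = name
            g_res.seqid = gemmi.SeqId(i, " ")
            g_res.het_flag = "H"
            for a in atoms:
                g_at = gemmi.Atom()
                g_at.name = a.name
                g_at.element = gemmi.Element(a.element)
                g_at.pos = gemmi.Position(*a.coords)
                g_res.add_atom(g_at)
            lig_chain.add_residue(g_res)
        model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def bw_lookup(bw_map: BWMap, code: str) -> tuple[str, int]:
    """Resolve a BW generic code to (residue name, sequence number)."""
    if not _BW_CODE_RE.match(code):
        raise ValueError(f"malformed BW code {code!r} (expected 'T.NN')")
    try:
        return bw_map.entries[code]
    except KeyError:
        raise KeyError(f"BW code {code!r} not present in map for {bw_map.receptor!r}") from None


def select_residues(
    structure: Structure,
    spec: Sequence[str | tuple[str | None, int]],
    bw_map: BWMap | None = None,
) -> list[Residue]:
    """Resolve a mixed list of BW codes and (chain, seq_number) to residues.

    Residues are returned in request order; every item must resolve or a
    single error listing all unresolved items is raised.
    """
    out: list[Residue] = []
    unresolved: list[str] = []
    for item in spec:
        try:
            if isinstance(item, str):
                if bw_map is None:
                    raise KeyError(f"BW code {item!r} given but no BW map supplied")
                name, num = bw_lookup(bw_map, item)
                out.append(structure.find_by_name(name, num))
            else:
                chain, num = item
                out.append(structure.find_residue(chain, num))
        except KeyError:
            unresolved.append(str(item))
    if unresolved:
        raise KeyError(f"unresolved residues in {structure.id!r}: {', '.join(unresolved)}")
    return out


def read_score_table(
    path: str | Path,
    sidecar: str | Path | None = None,
    rmsd_column: str | None = None,
) -> MetricTable:
    """Read a models-x-metrics CSV plus its JSON direction sidecar.

    The first column holds model/pose ids; all other columns must be numeric.
    The sidecar (default: same path with ``.json`` suffix) declares, per
    column, the direction in which the score improves and its units.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty score table")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(f"{path}: non-numeric or missing cell at row {row!r}, column {col!r}")
        df[col] = numeric
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    directions: dict[str, str] = {}
    units: dict[str, str] = {}
    side_rmsd = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        side_rmsd = meta.get("rmsd_column")
        for col, info in meta.get("columns", {}).items():
            if info.get("direction"):
                directions[col] = info["direction"]
            if info.get("units"):
                units[col] = info["units"]
    return MetricTable(
        data=df,
        rmsd_column=rmsd_column or side_rmsd or "RMSD",
        directions=directions,
        units=units,
    )
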