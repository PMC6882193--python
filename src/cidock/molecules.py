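"""Molecule and pose containers plus readers/writers for the common docking formats.

The pipeline treats a molecule as an ordered list of atoms (element, 3-D
coordinates in Å, formal charge) plus a bond list — enough structure for pose
clustering, RMSD and empirical rescoring.  Protonation, partial charges and
any other preparation chemistry are deliberately out of scope.

RDKit backs SDF, PDB and SMILES; TRIPOS MOL2 and AutoDock PDBQT are parsed
directly (RDKit writes neither).  Atom order is the canonical correspondence
between poses of one ligand; molecular-symmetry handling lives in
:mod:`cidock.geometry`, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .errors import (
    ContentError,
    FormatError,
    MissingScoreError,
    TopologyError,
    ValidationError,
)

BondOrder = object  # 1 | 2 | 3 | "ar"

_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "HD": "H", "HS": "H", "H": "H", "P": "P", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "MG": "Mg", "ZN": "Zn", "MN": "Mn",
    "CA": "Ca", "FE": "Fe",
}

_SDF_SCORE_KEYS = ("score", "SCORE", "Score", "engine_score", "ENERGY",
                   "minimizedAffinity", "vina_score", "docking_score")


@dataclass
class Molecule:
    """A small molecule or receptor: ordered atoms, bonds, 3-D coordinates (Å)."""

    name: str
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, BondOrder]] = field(default_factory=list)
    charges: list[int] | None = None
    is_receptor: bool = False
    needs_embedding: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.elements), 3)
        if self.charges is None:
            self.charges = [0] * len(self.elements)
        if not self.needs_embedding and not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"molecule {self.name!r} has non-finite coordinates")
        n = len(self.elements)
        seen: set[frozenset[int]] = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValidationError(f"invalid bond ({i}, {j}) in molecule {self.name!r}")
            key = frozenset((i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond ({i}, {j}) in molecule {self.name!r}")
            seen.add(key)
        if self.n_heavy < 1:
            raise ContentError(f"molecule {self.name!r} has no heavy atoms")

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    @property
    def n_heavy(self) -> int:
        return int(len(self.heavy_indices))

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices]

    @property
    def heavy_elements(self) -> list[str]:
        return [self.elements[i] for i in self.heavy_indices]

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float),
                       name=self.name if name is None else name)

    def translated(self, shift: Sequence[float]) -> "Molecule":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def strip_hydrogens(self) -> "Molecule":
        """Heavy-atom-only copy with bonds reindexed; the pose template."""
        idx = self.heavy_indices
        remap = {int(old): new for new, old in enumerate(idx)}
        bonds = [(remap[i], remap[j], o) for i, j, o in self.bonds
                 if i in remap and j in remap]
        return Molecule(self.name, [self.elements[i] for i in idx], self.coords[idx],
                        bonds, [self.charges[i] for i in idx],
                        self.is_receptor, self.needs_embedding)

    def heavy_graph(self) -> nx.Graph:
        """Heavy-atom molecular graph; node attr ``element``, edge attr ``order``."""
        heavy = set(int(i) for i in self.heavy_indices)
        g = nx.Graph()
        for i in heavy:
            g.add_node(i, element=self.elements[i])
        for i, j, o in self.bonds:
            if i in heavy and j in heavy:
                g.add_edge(i, j, order=o)
        return g

    def heavy_topology_key(self) -> tuple:
        """Hashable key identifying the heavy-atom topology (order-sensitive)."""
        idx = self.heavy_indices
        remap = {int(old): new for new, old in enumerate(idx)}
        bonds = frozenset(
            (min(remap[i], remap[j]), max(remap[i], remap[j]), str(o))
            for i, j, o in self.bonds if i in remap and j in remap)
        return (tuple(self.elements[i] for i in idx), bonds)


@dataclass
class Pose:
    """One docked conformation of the query ligand with engine provenance.

    ``engine_score`` is normalized so that lower is always better,
    independent of the engine's native polarity.
    """

    molecule: Molecule
    engine_id: str
    engine_score: float
    pose_index: int

    @property
    def pose_id(self) -> str:
        return f"{self.engine_id}:{self.pose_index}"

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.molecule.heavy_coords


@dataclass
class PoseEnsemble:
    """All poses one engine produced for one ligand-target pair."""

    ligand_id: str
    target_id: str
    engine_id: str
    poses: list[Pose]
    max_poses: int = 100

    def __post_init__(self) -> None:
        if not 1 <= len(self.poses) <= self.max_poses:
            raise ValidationError(
                f"ensemble {self.engine_id} has {len(self.poses)} poses; "
                f"expected 1..{self.max_poses}")
        key = self.poses[0].molecule.heavy_topology_key()
        for p in self.poses:
            if p.engine_id != self.engine_id:
                raise ValidationError("mixed engine ids inside one ensemble")
            if p.molecule.heavy_topology_key() != key:
                raise TopologyError(
                    f"pose {p.pose_index} topology differs within ensemble {self.engine_id}")

    def __len__(self) -> int:
        return len(self.poses)

    def pose_by_id(self, pose_id: str) -> Pose:
        for p in self.poses:
            if p.pose_id == pose_id:
                return p
        raise KeyError(pose_id)


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

_RD_ORDER = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
             Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: "ar"}
_TO_RD_ORDER = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}


def _mol_from_rdkit(rdmol: Chem.Mol, name: str, *, is_receptor: bool = False,
                    needs_embedding: bool = False) -> Molecule:
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in rdmol.GetAtoms()]
    if rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    else:
        coords = np.zeros((len(elements), 3))
        needs_embedding = True
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RD_ORDER.get(b.GetBondType(), 1))
             for b in rdmol.GetBonds()]
    return Molecule(name, elements, coords, bonds, charges,
                    is_receptor=is_receptor, needs_embedding=needs_embedding)


def _rdkit_from_mol(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for el, q in zip(mol.elements, mol.charges):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(q))
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, o in mol.bonds:
        rw.AddBond(int(i), int(j), _TO_RD_ORDER[o])
        if o == "ar":
            rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
    conf = Chem.Conformer(mol.n_atoms)
    for k, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
    rw.AddConformer(conf)
    out = rw.GetMol()
    out.SetProp("_Name", mol.name)
    return out


def embed_3d(mol: Molecule, seed: int = 2025) -> Molecule:
    """Generate 3-D coordinates for a SMILES-derived molecule (ETKDG)."""
    rd = Chem.MolFromSmiles(Chem.MolToSmiles(_rdkit_from_mol_topology(mol)))
    if rd is None:
        raise ContentError(f"cannot re-derive a sanitizable molecule from {mol.name!r}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise ContentError(f"3-D embedding failed for {mol.name!r}")
    rd = Chem.RemoveHs(rd)
    out = _mol_from_rdkit(rd, mol.name)
    out.needs_embedding = False
    return out


def _rdkit_from_mol_topology(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for el, q in zip(mol.elements, mol.charges):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(q))
        rw.AddAtom(a)
    for i, j, o in mol.bonds:
        rw.AddBond(int(i), int(j), _TO_RD_ORDER[o])
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    return m


# ---------------------------------------------------------------------------
# MOL2 (TRIPOS)
# ---------------------------------------------------------------------------

_MOL2_ORDER = {"1": 1, "2": 2, "3": 3, "ar": "ar", "am": 1, "du": 1, "un": 1, "nc": 1}
_TO_MOL2_ORDER = {1: "1", 2: "2", 3: "3", "ar": "ar"}


def _parse_mol2_block(lines: list[str], start_line: int) -> Molecule:
    section = None
    name = "mol"
    atoms: list[tuple[str, float, float, float]] = []
    bonds: list[tuple[int, int, BondOrder]] = []
    header: list[str] = []
    for off, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            continue
        if not line.strip() or line.startswith("#"):
            continue
        try:
            if section == "MOLECULE":
                header.append(line.strip())
                if len(header) == 1:
                    name = header[0] or name
            elif section == "ATOM":
                parts = line.split()
                sym = parts[5].split(".")[0]
                sym = sym[0].upper() + sym[1:].lower() if sym else "C"
                atoms.append((sym, float(parts[2]), float(parts[3]), float(parts[4])))
            elif section == "BOND":
                parts = line.split()
                order = _MOL2_ORDER.get(parts[3].lower())
                if order is None:
                    raise ValueError(f"unknown bond type {parts[3]!r}")
                bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, order))
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"MOL2 parse error at line {start_line + off + 1}: {exc}") from exc
    if not atoms:
        raise FormatError(f"MOL2 block starting at line {start_line + 1} has no atoms")
    elements = [a[0] for a in atoms]
    coords = np.array([a[1:] for a in atoms], dtype=float)
    return Molecule(name, elements, coords, bonds)


def _read_mol2_blocks(path: Path) -> list[Molecule]:
    text = path.read_text()
    lines = text.splitlines()
    starts = [i for i, l in enumerate(lines) if l.startswith("@<TRIPOS>MOLECULE")]
    if not starts:
        raise FormatError(f"{path}: no @<TRIPOS>MOLECULE record found")
    mols = []
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else len(lines)
        mols.append(_parse_mol2_block(lines[s:e], s))
    return mols


def _mol2_block(mol: Molecule) -> str:
    out = ["@<TRIPOS>MOLECULE", mol.name,
           f"{mol.n_atoms} {len(mol.bonds)} 0 0 0", "SMALL", "NO_CHARGES", "",
           "@<TRIPOS>ATOM"]
    for k, (el, (x, y, z)) in enumerate(zip(mol.elements, mol.coords), start=1):
        out.append(f"{k:>7} {el}{k:<4} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
                   f"{el:<5} 1 LIG1 0.0000")
    out.append("@<TRIPOS>BOND")
    for k, (i, j, o) in enumerate(mol.bonds, start=1):
        out.append(f"{k:>6} {i + 1:>5} {j + 1:>5} {_TO_MOL2_ORDER[o]:>4}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDBQT (AutoDock dialect) — coordinates and scores only; charges ignored
# ---------------------------------------------------------------------------

def _pdbqt_element(line: str) -> str:
    ad_type = line[77:79].strip().upper() if len(line) > 77 else ""
    if ad_type in _PDBQT_TYPE_TO_ELEMENT:
        return _PDBQT_TYPE_TO_ELEMENT[ad_type]
    atom_name = line[12:16].strip()
    sym = re.sub(r"[^A-Za-z]", "", atom_name)[:2]
    if sym[:1].upper() in {"C", "N", "O", "S", "P", "H", "F", "I"} and \
            sym.upper() not in {"CL", "BR"}:
        return sym[:1].upper()
    return sym[0].upper() + sym[1:].lower() if sym else "C"


def _read_pdbqt_models(path: Path) -> list[tuple[Molecule, float | None, str]]:
    models: list[tuple[Molecule, float | None, str]] = []
    cur: list[tuple[str, float, float, float]] = []
    score: float | None = None
    model_no = 0
    in_model = False

    def flush() -> None:
        nonlocal cur, score
        if cur:
            elements = [a[0] for a in cur]
            coords = np.array([a[1:] for a in cur], dtype=float)
            name = f"{path.stem}_m{len(models) + 1}"
            models.append((Molecule(name, elements, coords, []), score, name))
        cur, score = [], None

    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            flush()
            in_model = True
            model_no += 1
        elif rec == "ENDMDL":
            flush()
            in_model = False
        elif raw.startswith("REMARK VINA RESULT:"):
            try:
                score = float(raw.split(":", 1)[1].split()[0])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{ln}: malformed VINA RESULT remark") from exc
        elif rec in ("ATOM", "HETATM"):
            try:
                cur.append((_pdbqt_element(raw), float(raw[30:38]),
                            float(raw[38:46]), float(raw[46:54])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad PDBQT atom record") from exc
    flush()
    if not models:
        raise FormatError(f"{path}: no atoms found in PDBQT file")
    return models


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------

_SUFFIX_FORMAT = {".mol2": "mol2", ".sdf": "sdf", ".sd": "sdf", ".mol": "sdf",
                  ".pdb": "pdb", ".pdbqt": "pdbqt", ".smi": "smiles", ".smiles": "smiles"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"cannot infer format from suffix of {path}") from None


def read_molecule(path: str | Path, format: str | None = None) -> Molecule:
    """Read one molecule from ``path``.

    SMILES input yields a molecule flagged ``needs_embedding`` with zeroed
    coordinates; PDB input is flagged as a receptor.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mol2":
        return _read_mol2_blocks(path)[0]
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for rd in supplier:
            if rd is None:
                raise FormatError(f"{path}: first SDF record failed to parse")
            name = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") \
                else path.stem
            return _mol_from_rdkit(rd, name)
        raise FormatError(f"{path}: empty SDF file")
    if fmt == "pdb":
        rd = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False,
                                 proximityBonding=False)
        if rd is None:
            raise FormatError(f"{path}: PDB parse failed")
        return _mol_from_rdkit(rd, path.stem, is_receptor=True)
    if fmt == "pdbqt":
        return _read_pdbqt_models(path)[0][0]
    if fmt == "smiles":
        first = path.read_text().strip().splitlines()
        if not first:
            raise FormatError(f"{path}: empty SMILES file")
        tokens = first[0].split()
        rd = Chem.MolFromSmiles(tokens[0])
        if rd is None:
            raise FormatError(f"{path}: line 1: invalid SMILES {tokens[0]!r}")
        name = tokens[1] if len(tokens) > 1 else path.stem
        return _mol_from_rdkit(rd, name, needs_embedding=True)
    raise FormatError(f"unsupported format {fmt!r}")


def molecule_from_smiles(smiles: str, name: str = "ligand") -> Molecule:
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise FormatError(f"invalid SMILES {smiles!r}")
    return _mol_from_rdkit(rd, name, needs_embedding=True)


def write_molecule(mol: Molecule, path: str | Path, format: str | None = None) -> None:
    """Write a molecule as MOL2 or SDF (coordinates to 1e-4 Å)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mol2":
        path.write_text(_mol2_block(mol))
    elif fmt == "sdf":
        path.write_text(Chem.MolToMolBlock(_rdkit_from_mol(mol), kekulize=False) + "$$$$\n")
    else:
        raise FormatError(f"unsupported output format {fmt!r}")


def write_pose_ensemble(ensemble: PoseEnsemble, path: str | Path,
                        format: str = "sdf") -> None:
    """Multi-model SDF or MOL2 with per-pose score records."""
    path = Path(path)
    if format == "sdf":
        chunks = []
        for p in ensemble.poses:
            rd = _rdkit_from_mol(p.molecule.with_coords(
                p.molecule.coords, name=p.pose_id))
            block = Chem.MolToMolBlock(rd, kekulize=False)
            chunks.append(f"{block}>  <score>\n{p.engine_score:.4f}\n\n$$$$\n")
        path.write_text("".join(chunks))
    elif format == "mol2":
        path.write_text("".join(
            _mol2_block(p.molecule.with_coords(p.molecule.coords, name=p.pose_id))
            for p in ensemble.poses))
        sidecar = path.with_suffix(path.suffix + ".scores")
        sidecar.write_text("".join(
            f"{p.pose_id}\t{p.engine_score:.4f}\n" for p in ensemble.poses))
    else:
        raise FormatError(f"unsupported ensemble format {format!r}")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Two-column tab-separated sidecar: pose-name, score."""
    scores: dict[str, float] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected 'name<TAB>score'")
        try:
            scores[parts[0].strip()] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric score {parts[1]!r}") from exc
    return scores


def _read_sdf_models(path: Path) -> list[tuple[Molecule, float | None, str]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    models = []
    for k, rd in enumerate(supplier):
        if rd is None:
            raise FormatError(f"{path}: SDF record {k + 1} failed to parse")
        name = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") \
            else f"{path.stem}_m{k + 1}"
        score = None
        props = rd.GetPropsAsDict()
        for key in _SDF_SCORE_KEYS:
            if key in props:
                try:
                    score = float(props[key])
                except (TypeError, ValueError):
                    continue
                break
        models.append((_mol_from_rdkit(rd, name), score, name))
    if not models:
        raise FormatError(f"{path}: empty SDF file")
    return models


def read_pose_ensemble(path: str | Path, format: str | None, engine_id: str,
                       ligand: Molecule, *, ligand_id: str | None = None,
                       target_id: str = "", score_table: str | Path | None = None,
                       score_polarity: str = "lower_better",
                       max_poses: int = 100) -> PoseEnsemble:
    """Read a multi-model pose file as a :class:`PoseEnsemble`.

    Every model must match the query ligand's heavy-atom topology (element
    sequence; bond set too when the dialect records bonds).  Scores come from
    the dialect's native score records when present, else from a two-column
    sidecar ``score_table`` keyed by pose name.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        models = _read_sdf_models(path)
    elif fmt == "mol2":
        models = [(m, None, m.name) for m in _read_mol2_blocks(path)]
    elif fmt == "pdbqt":
        models = _read_pdbqt_models(path)
    else:
        raise FormatError(f"unsupported ensemble format {fmt!r}")

    template = ligand.strip_hydrogens()
    t_elements = template.elements
    t_bondset = {(min(i, j), max(i, j), str(o)) for i, j, o in template.bonds}
    sidecar = read_score_table(score_table) if score_table is not None else None

    poses: list[Pose] = []
    for k, (model, native_score, name) in enumerate(models):
        mheavy = model.strip_hydrogens()
        if mheavy.elements != t_elements:
            raise TopologyError(
                f"{path}: model {k + 1} heavy-atom elements do not match ligand "
                f"{ligand.name!r} ({len(mheavy.elements)} vs {len(t_elements)} atoms)")
        if mheavy.bonds:
            mset = {(min(i, j), max(i, j), str(o)) for i, j, o in mheavy.bonds}
            if mset != t_bondset:
                raise TopologyError(f"{path}: model {k + 1} bond list does not match ligand")
        if sidecar is not None:
            if name not in sidecar:
                raise MissingScoreError(f"{path}: no sidecar score for pose {name!r}")
            score = sidecar[name]
        elif native_score is not None:
            score = native_score
        else:
            raise MissingScoreError(
                f"{path}: model {k + 1} carries no score and no sidecar table was given")
        if score_polarity == "higher_better":
            score = -score
        elif score_polarity != "lower_better":
            raise ValidationError(f"unknown score polarity {score_polarity!r}")
        poses.append(Pose(template.with_coords(mheavy.coords, name=name),
                          engine_id, float(score), k))
    return PoseEnsemble(ligand_id or ligand.name, target_id, engine_id, poses,
                        max_poses=max(max_poses, len(poses)))


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def count_rotatable_bonds(mol: Molecule) -> int:
    """Number of rotatable bonds: acyclic single non-amide bonds between heavy
    atoms that each have ≥ 2 heavy neighbours.

    This is the common cheminformatics convention (terminal and ring bonds are
    rigid; amide C–N barely rotates); used as the ligand-flexibility proxy and
    as the rotor count of the deformation term in rescoring.
    """
    g = mol.heavy_graph()
    if g.number_of_edges() == 0:
        return 0
    bridges = {frozenset(e) for e in nx.bridges(g)}
    double_bonded_o: set[int] = set()
    for i, j, o in mol.bonds:
        if o == 2:
            if mol.elements[j] == "O":
                double_bonded_o.add(i)
            if mol.elements[i] == "O":
                double_bonded_o.add(j)

    def is_amide(i: int, j: int) -> bool:
        for c, n_ in ((i, j), (j, i)):
            if mol.elements[c] == "C" and mol.elements[n_] == "N" and c in double_bonded_o:
                return True
        return False

    count = 0
    for i, j, o in mol.bonds:
        if o != 1 or not (g.has_node(i) and g.has_node(j)):
            continue
        if frozenset((i, j)) not in bridges:  # ring bond
            continue
        if g.degree[i] < 2 or g.degree[j] < 2:
            continue
        if is_amide(i, j):
            continue
        count += 1
    return count
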