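"""Structure data model and PDB input/output.

The toolkit works on a light-weight in-memory model — :class:`Atom`,
:class:`Residue`, :class:`Structure`, :class:`Ligand`, :class:`Trajectory` —
backed by gemmi for reading and writing PDB files (including multi-model
trajectory files) and biotite for solvent-accessible surface areas.

Conventions:

* coordinates are in Å; author residue numbering is preserved;
* for alternate conformations only the highest-occupancy conformer is kept;
* waters are never treated as ligands;
* a multi-MODEL file is returned as a :class:`Trajectory` whose frame
  spacing must be supplied by the caller (PDB files carry no time axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import biotite.structure as _bts
from Bio.Align import PairwiseAligner

from .errors import (
    InvalidInputError,
    MissingChainError,
    ParseError,
)

# Van der Waals radii (Å) used for SASA; Bondi-style values.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

# Theoretical maximum accessible surface areas per residue (Å²),
# used for the relative-SASA surface criterion.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ASA = 200.0

AMINO_ACIDS_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

NUCLEIC_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}

#: residue key: (chain_id, author number, insertion code)
ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    """A single atom: name, element, position and PDB bookkeeping fields."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise InvalidInputError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise InvalidInputError(f"atom {self.name}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.occupancy, self.b_factor)


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""
    is_hetero: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return AMINO_ACIDS_3TO1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)

    def centroid(self) -> np.ndarray:
        return self.coords(heavy_only=True).mean(axis=0)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.number, self.name,
                       [a.copy() for a in self.atoms],
                       self.insertion_code, self.is_hetero)


@dataclass
class Ligand:
    """A hetero group (or hetero polymer) bound to a structure.

    ``kind`` is one of ``nucleic``, ``peptide``, ``small-molecule``, ``ion``.
    Polymeric ligands keep their per-residue substructure in ``residues``;
    ``atoms`` always exposes the flat atom list.
    """

    het_code: str
    residues: list[Residue]
    source_structure: str = ""
    kind: str = "small-molecule"

    def __post_init__(self) -> None:
        if not self.residues or not any(r.atoms for r in self.residues):
            raise InvalidInputError("ligand with no atoms")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if not a.is_hydrogen],
                        dtype=float).reshape(-1, 3)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Ligand":
        lig = self.copy()
        for res in lig.residues:
            for a in res.atoms:
                a.coord = rotation @ a.coord + translation
        return lig

    def copy(self) -> "Ligand":
        return Ligand(self.het_code, [r.copy() for r in self.residues],
                      self.source_structure, self.kind)


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    ligands: list[Ligand] = field(default_factory=list)
    frame_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for r in self.residues:
            if r.key in seen:
                raise InvalidInputError(f"duplicate residue key {r.key} in {self.id}")
            seen.add(r.key)

    def residue(self, key: ResidueKey) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if not r.is_hetero)

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        """Flat (n_atoms, 3) coordinates in residue/atom order (ligands excluded)."""
        return np.array([a.coord for a in self.all_atoms()], dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        atoms = self.all_atoms()
        if len(atoms) != len(coords):
            raise InvalidInputError("coordinate array does not match atom count")
        for a, c in zip(atoms, coords):
            a.coord = np.asarray(c, dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.all_atoms() if not a.is_hydrogen],
                        dtype=float).reshape(-1, 3)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply ``x -> R x + t`` in place to all atoms, ligands included."""
        for a in self.all_atoms():
            a.coord = rotation @ a.coord + translation
        for lig in self.ligands:
            for res in lig.residues:
                for a in res.atoms:
                    a.coord = rotation @ a.coord + translation

    def copy(self) -> "Structure":
        return Structure(self.id, [r.copy() for r in self.residues],
                         [l.copy() for l in self.ligands],
                         self.frame_index, dict(self.metadata))


@dataclass
class Trajectory:
    """An ordered sequence of identically laid-out structure frames."""

    frames: list[Structure]
    dt_ps: float = 1.0
    t0_ps: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt_ps <= 0:
            raise InvalidInputError("dt_ps must be positive")
        counts = {len(f.all_atoms()) for f in self.frames}
        if len(counts) > 1:
            raise InvalidInputError(f"frames differ in atom count: {sorted(counts)}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return self.t0_ps + self.dt_ps * np.arange(self.n_frames)

    @property
    def span_ps(self) -> float:
        return self.dt_ps * (self.n_frames - 1)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _classify_polymer(residues: list[Residue]) -> str:
    names = {r.name for r in residues}
    if names <= NUCLEIC_RESIDUES:
        return "nucleic"
    if names <= set(AMINO_ACIDS_3TO1):
        return "peptide"
    return "small-molecule"


def _ligand_kind(residues: list[Residue]) -> str:
    if len(residues) > 1:
        return _classify_polymer(residues)
    res = residues[0]
    if res.name in NUCLEIC_RESIDUES:
        return "nucleic"
    if res.name in AMINO_ACIDS_3TO1:
        return "peptide"
    if len(res.heavy_atoms()) == 1:
        return "ion"
    return "small-molecule"


def _group_ligands(het_residues: list[Residue], source_id: str) -> list[Ligand]:
    """Group hetero residues into ligands.

    Consecutive hetero residues of nucleic or amino-acid type in the same
    chain are merged into one polymeric ligand; every other hetero residue
    becomes its own ligand.
    """
    ligands: list[Ligand] = []
    run: list[Residue] = []

    def flush_run() -> None:
        nonlocal run
        if not run:
            return
        kind = _classify_polymer(run)
        code = run[0].name if len(run) == 1 else ("NUC" if kind == "nucleic" else "PEP")
        ligands.append(Ligand(code, run, source_id, _ligand_kind(run)))
        run = []

    prev: Residue | None = None
    for res in het_residues:
        polymeric = res.name in NUCLEIC_RESIDUES or res.name in AMINO_ACIDS_3TO1
        contiguous = (prev is not None and res.chain_id == prev.chain_id
                      and polymeric
                      and (prev.name in NUCLEIC_RESIDUES or prev.name in AMINO_ACIDS_3TO1))
        if polymeric and (not run or contiguous):
            run.append(res)
        else:
            flush_run()
            if polymeric:
                run.append(res)
            else:
                ligands.append(Ligand(res.name, [res], source_id, _ligand_kind([res])))
        prev = res
    flush_run()
    return ligands


def _convert_model(model: gemmi.Model, struct_id: str, chain: str | None,
                   frame_index: int | None) -> Structure:
    residues: list[Residue] = []
    het: list[Residue] = []
    found_chain = False
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        found_chain = True
        for res in ch:
            if res.name in WATER_RESIDUES:
                continue
            atoms = [Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                          a.occ, a.b_iso) for a in res]
            if not atoms:
                continue
            r = Residue(ch.name, res.seqid.num, res.name, atoms,
                        res.seqid.icode.strip(), res.het_flag == "H")
            (het if r.is_hetero else residues).append(r)
    if chain is not None and not found_chain:
        raise MissingChainError(f"chain {chain!r} not found in {struct_id}")
    return Structure(struct_id, residues, _group_ligands(het, struct_id), frame_index)


def read_structure(path: str | Path, chain: str | None = None,
                   dt_ps: float = 1.0, t0_ps: float = 0.0) -> Structure | Trajectory:
    """Read a PDB file; multi-MODEL files yield a :class:`Trajectory`.

    ``dt_ps``/``t0_ps`` set the time axis of a returned trajectory (the PDB
    format itself records no times).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()
    struct_id = path.stem if not chain else f"{path.stem}.{chain}"
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if len(st) == 1:
        return _convert_model(st[0], struct_id, chain, None)
    frames = [_convert_model(m, struct_id, chain, i) for i, m in enumerate(st)]
    return Trajectory(frames, dt_ps=dt_ps, t0_ps=t0_ps)


def read_trajectory(path: str | Path, chain: str | None = None,
                    dt_ps: float = 1.0, t0_ps: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (single model -> 1 frame)."""
    result = read_structure(path, chain=chain, dt_ps=dt_ps, t0_ps=t0_ps)
    if isinstance(result, Structure):
        return Trajectory([result], dt_ps=dt_ps, t0_ps=t0_ps)
    return result


def _populate_gemmi_model(model: gemmi.Model, structure: Structure) -> None:
    chains: dict[str, gemmi.Chain] = {}

    def chain_for(name: str) -> gemmi.Chain:
        if name not in chains:
            model.add_chain(gemmi.Chain(name))
            chains[name] = model[len(model) - 1]
        return chains[name]

    def add_residue(res: Residue, hetero: bool) -> None:
        g = gemmi.Residue()
        g.name = res.name
        g.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
        g.het_flag = "H" if hetero else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            g.add_atom(ga)
        chain_for(res.chain_id).add_residue(g)

    for res in structure.residues:
        add_residue(res, res.is_hetero)
    for lig in structure.ligands:
        for res in lig.residues:
            add_residue(res, True)


def write_structure(obj: Structure | Trajectory, path: str | Path,
                    remarks: Sequence[str] = ()) -> None:
    """Write a structure or trajectory to a PDB file."""
    st = gemmi.Structure()
    st.name = obj.id if isinstance(obj, Structure) else "trajectory"
    frames = [obj] if isinstance(obj, Structure) else obj.frames
    for i, frame in enumerate(frames):
        model = gemmi.Model(i + 1)
        _populate_gemmi_model(model, frame)
        st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK 300 {line}\n" for line in remarks)
        text = header + text
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _to_biotite(structure: Structure) -> tuple[_bts.AtomArray, list[ResidueKey], np.ndarray]:
    atoms = []
    for res in structure.residues:
        for a in res.atoms:
            atoms.append((res, a))
    arr = _bts.AtomArray(len(atoms))
    keys: list[ResidueKey] = []
    radii = np.empty(len(atoms))
    for i, (res, a) in enumerate(atoms):
        arr.coord[i] = a.coord
        arr.chain_id[i] = res.chain_id[:4]
        arr.res_id[i] = res.number
        arr.res_name[i] = res.name[:5]
        arr.atom_name[i] = a.name[:6]
        arr.element[i] = a.element[:2]
        arr.hetero[i] = res.is_hetero
        keys.append(res.key)
        radii[i] = VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS)
    return arr, keys, radii


def atom_sasa(structure: Structure, probe_radius: float = 1.4,
              point_number: int = 300) -> np.ndarray:
    """Shrake-Rupley SASA per atom (Å²), in structure atom order."""
    if probe_radius <= 0:
        raise InvalidInputError("probe_radius must be positive")
    if not structure.residues:
        return np.empty(0)
    arr, _, radii = _to_biotite(structure)
    values = _bts.sasa(arr, probe_radius=probe_radius, vdw_radii=radii,
                       point_number=point_number, ignore_ions=False)
    return np.nan_to_num(values, nan=0.0)


def residue_sasa(structure: Structure, probe_radius: float = 1.4,
                 point_number: int = 300) -> dict[ResidueKey, float]:
    """SASA per residue (Å²): sum of its atoms' Shrake-Rupley areas."""
    if not structure.residues:
        return {}
    values = atom_sasa(structure, probe_radius, point_number)
    _, keys, _ = _to_biotite(structure)
    out: dict[ResidueKey, float] = {}
    for key, v in zip(keys, values):
        out[key] = out.get(key, 0.0) + float(v)
    return out


def surface_residues(structure: Structure, rel_cutoff: float = 0.05,
                     probe_radius: float = 1.4) -> set[ResidueKey]:
    """Residues whose relative SASA is at least ``rel_cutoff`` of the
    residue-type maximum (default 5%)."""
    sasa = residue_sasa(structure, probe_radius)
    out: set[ResidueKey] = set()
    for res in structure.residues:
        if res.is_hetero:
            continue
        max_asa = MAX_ASA.get(res.name, DEFAULT_MAX_ASA)
        if sasa.get(res.key, 0.0) >= rel_cutoff * max_asa:
            out.add(res.key)
    return out


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global (Needleman-Wunsch) sequence identity.

    Scoring: match 1, mismatch 0, linear gap -1.  Identity is the number of
    identical aligned positions divided by the alignment length (gaps
    included), hence in [0, 1].
    """
    if not seq_a or not seq_b:
        raise InvalidInputError("sequence_identity: empty sequence")
    aligner = PairwiseAligner(mode="global", match_score=1.0, mismatch_score=0.0,
                              open_gap_score=-1.0, extend_gap_score=-1.0)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


# ---------------------------------------------------------------------------
# Ligand legitimacy
# ---------------------------------------------------------------------------

def load_exclusion_list(path: str | Path | None = None) -> set[str]:
    """Load a het-code exclusion list (one code per line, '#' comments).

    With no argument the bundled non-specific-ligand list is used.
    """
    if path is None:
        text = (resources.files("bsfp") / "data" / "nonspecific_ligands.txt").read_text()
    else:
        text = Path(path).read_text()
    codes: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            codes.add(line.upper())
    return codes


def _min_distance_to_protein(ligand: Ligand, protein_coords: np.ndarray) -> float:
    lig_coords = ligand.heavy_coords()
    if len(lig_coords) == 0 or len(protein_coords) == 0:
        return math.inf
    diff = lig_coords[:, None, :] - protein_coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def extract_legitimate_ligands(structure: Structure,
                               exclusion_list: set[str] | None = None,
                               covalent_cutoff: float = 1.8) -> list[Ligand]:
    """Ligands that are plausibly functionally bound.

    Excluded: het codes on the non-specific list; hetero groups that are
    modified amino-acid residues; groups covalently linked to the protein
    (any heavy-atom pair closer than ``covalent_cutoff``, the glycan /
    modified-residue test).  Polymeric nucleic or peptide ligands are
    always kept.
    """
    if exclusion_list is None:
        exclusion_list = load_exclusion_list()
    protein_coords = structure.heavy_coords()
    kept: list[Ligand] = []
    for lig in structure.ligands:
        if lig.kind in ("nucleic", "peptide") and len(lig.residues) > 1:
            kept.append(lig)
            continue
        if lig.het_code.upper() in exclusion_list:
            continue
        if lig.kind == "peptide":  # single modified amino-acid residue
            continue
        if _min_distance_to_protein(lig, protein_coords) < covalent_cutoff:
            continue
        kept.append(lig)
    return kept


def resolve_region(structure: Structure,
                   region: Iterable[ResidueKey | tuple[str, int]]) -> set[ResidueKey]:
    """Normalize a residue region to full residue keys of ``structure``.

    Accepts ``(chain, number)`` or ``(chain, number, icode)`` tuples.
    """
    by_short: dict[tuple[str, int], list[ResidueKey]] = {}
    keys = {r.key for r in structure.residues}
    for r in structure.residues:
        by_short.setdefault((r.chain_id, r.number), []).append(r.key)
    out: set[ResidueKey] = set()
    for item in region:
        if len(item) == 3 and item in keys:
            out.add(item)  # type: ignore[arg-type]
        elif (item[0], item[1]) in by_short:
            out.update(by_short[(item[0], item[1])])
    return out
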