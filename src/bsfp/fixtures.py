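"""Deterministic synthetic structures, libraries and trajectories.

Every module of the toolkit is testable offline against structures built
here.  The generator produces a *pseudo-fold*: an expanded helical backbone
(radius 8 Å, 45° turn and 2.2 Å rise per residue) carrying one stub atom
per functional-point typing row, spaced so that no two heavy atoms come
closer than 2 Å.  Geometric testability — exact placement, reproducibility,
known ground truth — is the goal; physical realism is not.

A :class:`MotifSpec` plants a rigid cluster of residues whose primary
functional atoms sit exactly at the requested relative geometry (plus
optional Gaussian jitter), recorded as ground truth in the structure
metadata.  Carrier/decoy libraries and noisy trajectories with planted
hydrogen bonds build on this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .core_model import Atom, Ligand, Residue, Structure, Trajectory
from .errors import GenerationError, InvalidInputError
from .sitegraph import typing_table
from .traj_analysis import AtomRef

_MIN_SPACING = 2.0  # Å, generator self-avoidance contract

_HELIX_RADIUS = 8.0
_HELIX_TURN = np.radians(45.0)
_HELIX_RISE = 2.2

# residues drawn for random positions (one typing row each keeps stubs small)
_RESIDUE_POOL = ("ALA", "SER", "THR", "LEU", "VAL", "LYS", "ARG", "ASP",
                 "GLU", "PHE", "GLY", "MET", "ILE", "PRO", "CYS", "TRP")


@dataclass
class MotifSpec:
    """A rigid arrangement of residues to plant into a structure.

    ``geometry`` holds the target positions of each residue's primary
    functional atom (first typing-table row), relative to an arbitrary
    origin; the cluster is translated as a whole when planted.
    """

    residue_types: tuple[str, ...]
    geometry: np.ndarray
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 3)
        if len(self.residue_types) != len(self.geometry):
            raise InvalidInputError("residue_types and geometry differ in length")
        if self.jitter_sd < 0:
            raise InvalidInputError("jitter_sd must be >= 0")

    def __len__(self) -> int:
        return len(self.residue_types)

    def transformed(self, rotation: np.ndarray) -> "MotifSpec":
        return MotifSpec(self.residue_types, self.geometry @ rotation.T,
                         self.jitter_sd, self.seed)


def _typing_rows(resname: str) -> list[tuple[str, str, list[str]]]:
    return [row for row in typing_table() if row[0] == resname]


def _perpendicular(v: np.ndarray) -> np.ndarray:
    trial = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(trial) < 1e-6:
        trial = np.cross(v, [1.0, 0.0, 0.0])
    return trial / np.linalg.norm(trial)


#: default helix parameters: (radius Å, turn rad, rise Å, phase rad)
_DEFAULT_HELIX = (_HELIX_RADIUS, _HELIX_TURN, _HELIX_RISE, 0.0)


def random_helix_params(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Helix parameters varied within self-avoiding bounds, for building
    structures whose peripheral folds do not align with each other."""
    return (float(rng.uniform(8.0, 10.0)),
            float(np.radians(rng.uniform(44.0, 55.0))),
            float(rng.uniform(2.0, 2.6)),
            float(rng.uniform(0.0, 2 * np.pi)))


def _helix_residue(index: int, resname: str, chain_id: str,
                   jitter: np.ndarray,
                   helix: tuple[float, float, float, float] = _DEFAULT_HELIX
                   ) -> Residue:
    radius, turn, rise, phase = helix
    angle = phase + turn * index
    ca = np.array([radius * np.cos(angle),
                   radius * np.sin(angle),
                   rise * index]) + jitter
    radial = np.array([np.cos(angle), np.sin(angle), 0.0])
    tangent_raw = np.array([-np.sin(angle), np.cos(angle), 0.0]) * radius \
        * turn + np.array([0.0, 0.0, rise])
    tangent = tangent_raw / np.linalg.norm(tangent_raw)
    atoms = [Atom("CA", "C", ca),
             Atom("N", "N", ca - 2.05 * tangent),
             Atom("C", "C", ca + 2.05 * tangent),
             Atom("O", "O", ca + 2.05 * tangent + 2.05 * radial)]
    names_taken = {a.name for a in atoms}
    for k, (_, _ptype, atom_names) in enumerate(_typing_rows(resname)):
        name = atom_names[0]
        if name in names_taken:  # GLY row references CA, already present
            continue
        element = name[0] if name[0] in "CNOS" else "C"
        atoms.append(Atom(name, element, ca + (2.4 + 2.0 * k) * radial))
        names_taken.add(name)
    return Residue(chain_id, index + 1, resname, atoms)


def _motif_residue(number: int, resname: str, chain_id: str,
                   anchor: np.ndarray, outward: np.ndarray) -> Residue:
    """A residue whose primary functional atom sits exactly at ``anchor``."""
    ca = anchor - 2.4 * outward
    atoms = [Atom("CA", "C", ca)]
    for k, (_, _ptype, atom_names) in enumerate(_typing_rows(resname)):
        name = atom_names[0]
        if name == "CA":
            continue
        element = name[0] if name[0] in "CNOS" else "C"
        atoms.append(Atom(name, element, ca + (2.4 + 2.0 * k) * outward))
    return Residue(chain_id, number, resname, atoms)


def _min_heavy_spacing(structure: Structure) -> float:
    coords = structure.heavy_coords()
    ligand_coords = [lig.heavy_coords() for lig in structure.ligands]
    if ligand_coords:
        coords = np.vstack([coords] + ligand_coords)
    if len(coords) < 2:
        return np.inf
    return float(pdist(coords).min())


def make_toy_protein(n_res: int, motif: MotifSpec | None = None,
                     seed: int = 0, struct_id: str | None = None,
                     chain_id: str = "A", max_retries: int = 20,
                     helix: tuple[float, float, float, float] | None = None
                     ) -> Structure:
    """A self-avoiding pseudo-fold with an optional planted motif.

    The motif occupies the last ``len(motif)`` residues; its residues'
    primary functional atoms realize the motif geometry exactly (up to the
    requested jitter), translated as a rigid cluster to just outside the
    helix.  Ground truth is stored in ``metadata["motif_residues"]``.
    """
    if motif is not None and n_res < len(motif):
        raise InvalidInputError("n_res smaller than motif length")
    rng = np.random.default_rng(seed)
    helix_params = helix if helix is not None else _DEFAULT_HELIX
    radius, _turn, rise, _phase = helix_params
    n_helix = n_res - (len(motif) if motif else 0)
    names = [str(_RESIDUE_POOL[i]) for i in
             rng.integers(0, len(_RESIDUE_POOL), size=n_helix)]
    for attempt in range(max_retries):
        jitter_sd = 0.1
        residues = [
            _helix_residue(i, names[i], chain_id,
                           rng.normal(0.0, jitter_sd, size=3), helix_params)
            for i in range(n_helix)
        ]
        motif_keys = []
        if motif is not None:
            jrng = np.random.default_rng(motif.seed + attempt)
            anchors = motif.geometry.copy()
            if motif.jitter_sd > 0:
                anchors = anchors + jrng.normal(0.0, motif.jitter_sd,
                                                size=anchors.shape)
            center = anchors.mean(axis=0)
            z_mid = 0.5 * rise * max(n_helix - 1, 0)
            shift = np.array([radius + 12.0, 0.0, z_mid]) - center
            anchors = anchors + shift
            # a constant outward axis keeps motif CA spacing equal to the
            # anchor spacing (per-residue directions would cluster the CAs)
            outward = np.array([1.0, 0.0, 0.0])
            for m, resname in enumerate(motif.residue_types):
                res = _motif_residue(n_helix + m + 1, resname, chain_id,
                                     anchors[m], outward)
                residues.append(res)
                motif_keys.append(res.key)
        structure = Structure(struct_id or f"toy{seed}", residues)
        structure.metadata = {"seed": seed, "motif_residues": motif_keys}
        if _min_heavy_spacing(structure) >= _MIN_SPACING:
            return structure
    raise GenerationError(
        f"could not place atoms >= {_MIN_SPACING} Å apart in {max_retries} attempts")


def plant_ligand(structure: Structure, n_anchors: int = 4,
                 distance: float = 2.7, het_code: str = "LIG") -> Ligand:
    """Attach a small-molecule ligand next to the planted motif.

    One ligand atom is placed ``distance`` Å (default 2.7: inside the
    strict < 3 Å binding-site rule, outside the 2.5 Å clash cutoff) from
    the primary functional atom of each of the first ``n_anchors`` motif
    residues, offset perpendicular to the residue's side-chain direction,
    so the ligand defines a binding site containing those residues without
    triggering the covalent-link test (> 1.8 Å from every protein atom).
    """
    motif_keys = structure.metadata.get("motif_residues") or []
    if len(motif_keys) < n_anchors:
        raise InvalidInputError("structure has no (or too few) motif residues")
    anchors = []
    for key in motif_keys[:n_anchors]:
        res = structure.residue(tuple(key))
        primary = next(a for a in res.atoms if a.name != "CA")
        outward = primary.coord - res.atom("CA").coord
        anchors.append((primary.coord, outward / np.linalg.norm(outward)))
    protein = structure.heavy_coords()
    # try several offset directions around the side-chain axis until the
    # ligand clears both the protein and itself; clearance stays above the
    # 2.5 Å clash cutoff (the anchors themselves sit at `distance`)
    clearance = min(2.55, distance - 1e-9)
    base = _perpendicular(anchors[0][1])
    number = max(r.number for r in structure.residues) + 100
    for angle in np.arange(0.0, 2 * np.pi, np.pi / 8):
        rot = Rotation.from_rotvec(angle * anchors[0][1]).as_matrix()
        direction = rot @ base
        coords = np.array([p + distance * direction for p, _ in anchors])
        if cdist(coords, protein).min() < clearance:
            continue
        if len(coords) > 1 and pdist(coords).min() < _MIN_SPACING:
            continue
        atoms = [Atom(f"C{k + 1}", "C", c) for k, c in enumerate(coords)]
        res = Residue(structure.residues[0].chain_id, number, het_code, atoms,
                      is_hetero=True)
        ligand = Ligand(het_code, [res], structure.id, "small-molecule")
        structure.ligands.append(ligand)
        return ligand
    raise GenerationError("could not place a clash-free ligand on the motif")


def make_decoy_db(n_total: int, n_carriers: int, motif: MotifSpec,
                  seed: int = 0, n_res: int = 40,
                  with_ligands: bool = True,
                  decoy_subset: int = 3,
                  decoy_jitter: float = 0.8
                  ) -> tuple[list[Structure], list[str]]:
    """A structure library with motif carriers hidden among decoys.

    Carriers embed a rigidly rotated copy of the full motif (rotation seeded
    per carrier) and, when ``with_ligands``, a planted ligand defining a
    binding site on the motif.  Decoys carry only a heavily jittered
    ``decoy_subset``-residue fragment of the motif and no ligand: real
    template libraries show broad weak background similarity to any query,
    and that background is what Z-score standardization measures full
    matches against.  Returns the structures and the carrier ids (also in
    each structure's metadata as ``is_carrier``).
    """
    if n_carriers > n_total:
        raise InvalidInputError("n_carriers > n_total")
    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    carrier_ids: list[str] = []
    for i in range(n_total):
        sub_seed = int(rng.integers(0, 2 ** 31))
        sub_rng = np.random.default_rng(sub_seed)
        rotation = Rotation.random(rng=sub_rng).as_matrix()
        if i < n_carriers:
            planted = MotifSpec(motif.residue_types, motif.geometry @ rotation.T,
                                motif.jitter_sd, sub_seed)
            struct_id = f"carrier_{i:02d}"
            s = make_toy_protein(n_res, planted, seed=sub_seed, struct_id=struct_id)
            if with_ligands:
                plant_ligand(s)
            s.metadata["is_carrier"] = True
            carrier_ids.append(struct_id)
        else:
            struct_id = f"decoy_{i - n_carriers:02d}"
            chosen = sorted(sub_rng.choice(len(motif), size=min(decoy_subset,
                                                                len(motif)),
                                           replace=False))
            fragment = MotifSpec(
                tuple(motif.residue_types[c] for c in chosen),
                motif.geometry[chosen] @ rotation.T,
                decoy_jitter, sub_seed)
            s = make_toy_protein(n_res, fragment, seed=sub_seed,
                                 struct_id=struct_id)
            s.metadata["is_carrier"] = False
        structures.append(s)
    return structures, carrier_ids


def make_toy_trajectory(base: Structure, n_frames: int, dt_ps: float = 1.0,
                        noise_sd: float = 0.0,
                        planted_hbonds: list[tuple[AtomRef, AtomRef, float]]
                        | None = None,
                        seed: int = 0) -> Trajectory:
    """Gaussian-noise frames around a base structure.

    ``planted_hbonds`` is a list of (donor atom ref, acceptor atom ref,
    occupancy fraction): in exactly ``round(fraction * n_frames)`` frames
    the acceptor is held 2.9 Å from the donor (inside the default H-bond
    criterion), 5.5 Å otherwise, so the resulting occupancy is exact.
    Ground truth is recorded in the trajectory metadata.
    """
    if n_frames < 1:
        raise InvalidInputError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    planted_hbonds = planted_hbonds or []
    frames = []
    for f in range(n_frames):
        frame = base.copy()
        frame.frame_index = f
        if noise_sd > 0:
            for atom in frame.all_atoms():
                atom.coord = atom.coord + rng.normal(0.0, noise_sd, size=3)
            for lig in frame.ligands:
                for res in lig.residues:
                    for atom in res.atoms:
                        atom.coord = atom.coord + rng.normal(0.0, noise_sd, size=3)
        lookup = {(res.chain_id, res.number, res.insertion_code, a.name): a
                  for res in frame.residues for a in res.atoms}
        for donor_ref, acceptor_ref, fraction in planted_hbonds:
            donor = lookup[tuple(donor_ref)]
            acceptor = lookup[tuple(acceptor_ref)]
            direction = acceptor.coord - donor.coord
            direction /= np.linalg.norm(direction)
            bound = f < round(fraction * n_frames)
            acceptor.coord = donor.coord + (2.9 if bound else 5.5) * direction
        frames.append(frame)
    traj = Trajectory(frames, dt_ps=dt_ps)
    traj.metadata = {"seed": seed, "noise_sd": noise_sd,
                     "planted_hbonds": list(planted_hbonds)}
    return traj


def default_motif(jitter_sd: float = 0.0, seed: int = 0) -> MotifSpec:
    """A six-residue motif with distinctive types and geometry, used across
    the test fixtures and the worked examples."""
    geometry = np.array([
        [0.0, 0.0, 0.0],     # ARG  donor
        [5.2, 0.0, 0.0],     # ASP  acceptor
        [2.6, 4.8, 0.0],     # SER  mixed
        [1.8, 1.9, 4.6],     # PHE  aromatic
        [6.4, 4.4, 3.1],     # LEU  aliphatic
        [-2.9, 4.1, 2.5],    # LYS  donor
    ])
    return MotifSpec(("ARG", "ASP", "SER", "PHE", "LEU", "LYS"),
                     geometry, jitter_sd, seed)
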