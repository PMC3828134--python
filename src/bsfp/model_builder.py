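"""Receptor-ligand complex models by binding-site superimposition.

The receptor's predicted site is locally aligned to a template's known
site; the resulting rigid transform (template -> receptor frame, so the
receptor never moves) is applied to the template's ligand, whose
coordinates are then copied next to the receptor.  Steric quality is
quantified as the number of heavy-atom receptor-ligand pairs closer than a
clash cutoff (default 2.5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import Ligand, ResidueKey, Structure, write_structure
from .errors import ModelFailureError
from .sitegraph import CompareParams, Hit, compare_sites

#: (residue key, atom name) pair references for clashing atoms
AtomRef = tuple[ResidueKey, str]


@dataclass
class ComplexModel:
    receptor: Structure
    ligand: Ligand
    rotation: np.ndarray
    translation: np.ndarray
    hit: Hit
    clash_count: int
    clash_pairs: list[tuple[AtomRef, int, float]]


def count_clashes(receptor: Structure, ligand: Ligand,
                  cutoff: float = 2.5) -> tuple[int, list[tuple[AtomRef, int, float]]]:
    """Heavy-atom receptor-ligand pairs with distance < ``cutoff`` Å.

    Pairs are reported as ((residue key, atom name), ligand atom index,
    distance).
    """
    rec_atoms: list[tuple[AtomRef, np.ndarray]] = []
    for res in receptor.residues:
        for atom in res.atoms:
            if not atom.is_hydrogen:
                rec_atoms.append(((res.key, atom.name), atom.coord))
    lig_coords = ligand.heavy_coords()
    if not rec_atoms or not len(lig_coords):
        return 0, []
    rec_coords = np.array([c for _, c in rec_atoms])
    dist = cdist(rec_coords, lig_coords)
    pairs = [
        (rec_atoms[i][0], int(j), float(dist[i, j]))
        for i, j in zip(*np.nonzero(dist < cutoff))
    ]
    pairs.sort(key=lambda p: p[2])
    return len(pairs), pairs


def build_complex(receptor: Structure, receptor_site: set[ResidueKey],
                  template: Structure, template_site: set[ResidueKey],
                  ligand: Ligand,
                  params: CompareParams = CompareParams(),
                  clash_cutoff: float = 2.5) -> ComplexModel:
    """Transpose a template ligand onto the receptor via site superimposition.

    The template site is aligned onto the receptor site (the receptor stays
    fixed); the same transform carries the ligand.  Raises
    :class:`ModelFailureError` when no site correspondence exists,
    distinguishing a missing clique from degenerate geometry.
    """
    hit = compare_sites(receptor, receptor_site, template, params,
                        target_region=template_site)
    if hit is None:
        # compare_sites logs degenerate-geometry cases before returning None;
        # distinguish the two failure modes for the caller
        probe = compare_sites(receptor, receptor_site, template,
                              CompareParams(params.d_max, params.epsilon,
                                            params.extend_cutoff, 1),
                              target_region=template_site)
        if probe is None:
            raise ModelFailureError(
                f"no common clique between {receptor.id} site and "
                f"{template.id} site")
        raise ModelFailureError(
            f"site correspondence of {receptor.id} vs {template.id} is "
            f"degenerate or below min_clique={params.min_clique}")
    moved = ligand.transformed(hit.rotation, hit.translation)
    moved.source_structure = template.id
    count, pairs = count_clashes(receptor, moved, clash_cutoff)
    return ComplexModel(receptor, moved, hit.rotation, hit.translation,
                        hit, count, pairs)


def write_complex(model: ComplexModel, path: str | Path,
                  ligand_chain: str = "X") -> None:
    """Write receptor + transposed ligand as one PDB; the ligand becomes a
    new chain and the applied transform is logged in REMARK records."""
    complexed = model.receptor.copy()
    lig = model.ligand.copy()
    for i, res in enumerate(lig.residues):
        res.chain_id = ligand_chain
        res.is_hetero = True
    complexed.ligands.append(lig)
    remarks = ["transposed ligand %s from %s as chain %s" %
               (model.ligand.het_code, model.ligand.source_structure, ligand_chain)]
    for row in model.rotation:
        remarks.append("rotation  %9.6f %9.6f %9.6f" % tuple(row))
    remarks.append("translation %9.4f %9.4f %9.4f" % tuple(model.translation))
    remarks.append(f"clash_count {model.clash_count}")
    write_structure(complexed, path, remarks=remarks)
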