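"""From raw substructure hits to functional annotations.

A matched substructure anywhere on a library protein is not yet evidence of
function; it must coincide with a *binding site*.  Binding sites are defined
by ligands — either co-crystallized with the library protein itself or
transposed from its close (>30% sequence identity) homologs after
superimposition.  A site is the set of residues with a heavy atom strictly
closer than 3 Å to any ligand heavy atom.  Hits whose correspondence
overlaps a site (fraction >= min_overlap) are retained and classified by
ligand type, mirroring a ranked DNA/RNA/nucleotide/peptide/other table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import (
    Ligand,
    ResidueKey,
    Structure,
    extract_legitimate_ligands,
    sequence_identity,
    surface_residues,
)
from .errors import InvalidInputError
from .sitegraph import CompareParams, Hit, compare_sites

logger = logging.getLogger(__name__)


@dataclass
class BindingSite:
    ligand: Ligand
    residues: set[ResidueKey]
    cutoff: float


@dataclass
class AnnotatedHit:
    hit: Hit
    matched_sites: list[BindingSite]
    overlap_fraction: float
    ligand_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise InvalidInputError("overlap_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# Ligand classification
# ---------------------------------------------------------------------------

_NUCLEOTIDE_CODES: set[str] | None = None


def _nucleotide_codes() -> set[str]:
    global _NUCLEOTIDE_CODES
    if _NUCLEOTIDE_CODES is None:
        text = (resources.files("bsfp") / "data" / "ligand_classes.tsv").read_text()
        codes = set()
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                code, cls = line.split("\t")
                if cls == "nucleotide":
                    codes.add(code.upper())
        _NUCLEOTIDE_CODES = codes
    return _NUCLEOTIDE_CODES


def classify_ligand(ligand: Ligand) -> str:
    """One of DNA, RNA, nucleotide, peptide, other."""
    if ligand.kind == "nucleic":
        names = {r.name for r in ligand.residues}
        if names & {"DA", "DC", "DG", "DT", "DI", "DU"}:
            return "DNA"
        return "RNA"
    if ligand.kind == "peptide":
        return "peptide"
    if ligand.het_code.upper() in _nucleotide_codes():
        return "nucleotide"
    return "other"


# ---------------------------------------------------------------------------
# Ligand transposition from homologs
# ---------------------------------------------------------------------------

def transpose_ligands(target: Structure,
                      homologs: list[tuple[Structure, float | None]],
                      min_identity: float = 0.30,
                      params: CompareParams = CompareParams(),
                      merge_cutoff: float = 2.0) -> list[Ligand]:
    """Copy ligands from >min_identity homologs onto the target's frame.

    Each qualifying homolog is superimposed onto the target through a
    whole-surface local alignment; the resulting rigid transform is applied
    to the homolog's legitimate ligands.  Duplicates (same het code,
    centroids within ``merge_cutoff`` Å) are merged keeping the ligand from
    the higher-identity source.
    """
    candidates: list[tuple[float, Ligand]] = []
    for homolog, identity in homologs:
        if identity is None:
            identity = sequence_identity(target.sequence, homolog.sequence)
        if identity <= min_identity:
            continue
        ligands = extract_legitimate_ligands(homolog)
        if not ligands:
            continue
        hit = compare_sites(target, surface_residues(target), homolog, params)
        if hit is None:
            logger.warning("homolog %s failed to superimpose onto %s; skipped",
                           homolog.id, target.id)
            continue
        # hit transform maps homolog coordinates into the target frame
        for lig in ligands:
            moved = lig.transformed(hit.rotation, hit.translation)
            moved.source_structure = homolog.id
            candidates.append((identity, moved))
    candidates.sort(key=lambda c: -c[0])
    merged: list[tuple[float, Ligand]] = []
    for identity, lig in candidates:
        duplicate = any(
            kept.het_code == lig.het_code
            and np.linalg.norm(kept.centroid() - lig.centroid()) < merge_cutoff
            for _, kept in merged)
        if not duplicate:
            merged.append((identity, lig))
    return [lig for _, lig in merged]


# ---------------------------------------------------------------------------
# Binding sites and hit filtering
# ---------------------------------------------------------------------------

def define_binding_site(structure: Structure, ligand: Ligand,
                        cutoff: float = 3.0) -> BindingSite:
    """Residues with any heavy atom strictly < ``cutoff`` Å from any ligand
    heavy atom.  Hydrogens are ignored on both sides."""
    lig_coords = ligand.heavy_coords()
    residues: set[ResidueKey] = set()
    for res in structure.residues:
        if res.is_hetero:
            continue
        coords = res.coords(heavy_only=True)
        if len(coords) and cdist(coords, lig_coords).min() < cutoff:
            residues.add(res.key)
    return BindingSite(ligand, residues, cutoff)


def binding_sites_for(structure: Structure,
                      homologs: list[tuple[Structure, float | None]] | None = None,
                      cutoff: float = 3.0,
                      min_identity: float = 0.30,
                      params: CompareParams = CompareParams()) -> list[BindingSite]:
    """All ligand-defined binding sites: native legitimate ligands plus
    ligands transposed from homologs."""
    ligands = list(extract_legitimate_ligands(structure))
    if homologs:
        ligands.extend(transpose_ligands(structure, homologs, min_identity, params))
    return [define_binding_site(structure, lig, cutoff) for lig in ligands]


def filter_hits_by_sites(hits: list[Hit],
                         db_structures: dict[str, Structure],
                         homolog_map: dict[str, list[tuple[Structure, float | None]]]
                         | None = None,
                         min_overlap: float = 0.5,
                         cutoff: float = 3.0,
                         params: CompareParams = CompareParams()) -> list[AnnotatedHit]:
    """Keep hits whose matched residues fall inside a known binding site.

    ``overlap_fraction`` is the share of a hit's target-side correspondence
    residues inside a site; a hit survives when some site reaches
    ``min_overlap``.  Retained hits inherit the class of the best ligand.
    """
    homolog_map = homolog_map or {}
    annotated: list[AnnotatedHit] = []
    site_cache: dict[str, list[BindingSite]] = {}
    for hit in hits:
        structure = db_structures.get(hit.target_id)
        if structure is None:
            raise InvalidInputError(f"hit references unknown structure {hit.target_id}")
        if hit.target_id not in site_cache:
            site_cache[hit.target_id] = binding_sites_for(
                structure, homolog_map.get(hit.target_id), cutoff,
                params=params)
        sites = site_cache[hit.target_id]
        target_keys = {(c, n, i) for _q, (c, n, i, _name) in hit.correspondence}
        best_overlap = 0.0
        best_site: BindingSite | None = None
        matched: list[BindingSite] = []
        for site in sites:
            overlap = len(target_keys & site.residues) / len(target_keys)
            if overlap >= min_overlap:
                matched.append(site)
            if overlap > best_overlap or best_site is None:
                best_overlap, best_site = overlap, site
        if matched:
            matched.sort(key=lambda s: -len(target_keys & s.residues))
            annotated.append(AnnotatedHit(
                hit, matched, best_overlap, classify_ligand(matched[0].ligand)))
    annotated.sort(key=lambda a: (-a.hit.z_score, a.hit.target_id))
    return annotated
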