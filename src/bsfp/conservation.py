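"""Per-residue structural conservation and binding-site prediction.

Each homolog is locally aligned to the query's surface with
:func:`bsfp.sitegraph.compare_sites`.  The raw conservation of a residue is
the fraction of successful homolog alignments whose correspondence contains
it; the fraction is mapped onto a 1-10 degree scale (deciles, ceil, minimum
1).  Residues at degree >= 8 are the putative binding site; they are grouped
into spatial patches by single-linkage clustering of residue centroids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .core_model import ResidueKey, Structure, sequence_identity, surface_residues
from .errors import InvalidInputError
from .sitegraph import CompareParams, compare_sites

logger = logging.getLogger(__name__)


@dataclass
class ConservationProfile:
    degrees: dict[ResidueKey, int]
    n_alignments: int
    centroids: dict[ResidueKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: d for k, d in self.degrees.items() if not 1 <= d <= 10}
        if bad:
            raise InvalidInputError(f"degrees outside 1..10: {bad}")


def degree_from_fraction(fraction: float) -> int:
    """Map an alignment fraction in [0, 1] to a conservation degree 1..10."""
    return min(10, max(1, math.ceil(10.0 * fraction)))


def conservation_profile(query: Structure, homologs: list[Structure],
                         params: CompareParams = CompareParams()) -> ConservationProfile:
    """Structural conservation degrees of the query's surface residues."""
    if not homologs:
        raise InvalidInputError("at least one homolog is required")
    surface = surface_residues(query)
    counts: dict[ResidueKey, int] = {key: 0 for key in surface}
    n_alignments = 0
    for homolog in homologs:
        hit = compare_sites(query, surface, homolog, params)
        if hit is None:
            logger.warning("no alignment of %s with homolog %s",
                           query.id, homolog.id)
            continue
        n_alignments += 1
        for (chain, number, icode, _name), _t in hit.correspondence:
            key = (chain, number, icode)
            if key in counts:
                counts[key] += 1
    if n_alignments == 0:
        logger.warning("no homolog of %s produced an alignment; "
                       "all degrees set to 1", query.id)
    degrees = {
        key: degree_from_fraction(counts[key] / n_alignments) if n_alignments else 1
        for key in surface
    }
    centroids = {r.key: r.centroid() for r in query.residues if r.key in surface}
    return ConservationProfile(degrees, n_alignments, centroids)


def predict_binding_site(profile: ConservationProfile, min_degree: int = 8,
                         patch_cutoff: float = 8.0) -> list[set[ResidueKey]]:
    """Residues at ``degree >= min_degree`` grouped into spatial patches.

    Single-linkage clustering at ``patch_cutoff`` Å between residue
    centroids; patches are returned largest first.  An empty list means no
    residue passed the threshold.
    """
    if not profile.degrees:
        raise InvalidInputError("empty conservation profile")
    selected = [k for k, d in profile.degrees.items() if d >= min_degree]
    if not selected:
        return []
    selected.sort()
    coords = np.array([profile.centroids[k] for k in selected])
    adjacency = cdist(coords, coords) <= patch_cutoff
    n_patches, labels = connected_components(adjacency, directed=False)
    patches: list[set[ResidueKey]] = [set() for _ in range(n_patches)]
    for key, label in zip(selected, labels):
        patches[label].add(key)
    patches.sort(key=lambda p: (-len(p), sorted(p)[0]))
    return patches


def flag_homologs(query: Structure, homologs: list[Structure],
                  lo: float = 0.20, hi: float = 0.90) -> dict[str, float]:
    """Sequence identities of homologs against the query, warning on those
    outside [lo, hi] (too distant to align or near-duplicates)."""
    out: dict[str, float] = {}
    for h in homologs:
        ident = sequence_identity(query.sequence, h.sequence)
        out[h.id] = ident
        if not lo <= ident <= hi:
            logger.warning("homolog %s has identity %.2f outside [%.2f, %.2f]",
                           h.id, ident, lo, hi)
    return out
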