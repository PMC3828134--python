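"""Protein graphs and pairwise local structural alignment.

A (sub)structure is abstracted into *functional points* — typed pseudoatoms
placed at side-chain functional-group centroids (donor / acceptor / mixed /
aromatic / aliphatic; the typing table lives in ``data/functional_points.tsv``
and is editable).  Points closer than ``d_max`` are joined by
distance-labelled edges, giving a *protein graph*.

Two protein graphs are compared on their *product graph*: vertices are
type-compatible point pairs, edges connect pairs whose intra-structure
distances agree within ``epsilon``.  A maximum clique of the product graph is
the largest geometrically consistent correspondence; its point pairs seed a
rigid superimposition, after which the correspondence is extended with
mutually nearest compatible pairs.  Hits are ranked by standardized scores
(Z-scores) within one search run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core_model import ResidueKey, Structure, resolve_region, surface_residues
from .errors import DegenerateGeometryError, EmptyRegionError, InvalidInputError

logger = logging.getLogger(__name__)

PTYPES = ("donor", "acceptor", "mixed", "aromatic", "aliphatic")

#: residue reference carried by a functional point: (chain, number, icode, name)
ResidueRef = tuple[str, int, str, str]


@dataclass(frozen=True)
class CompareParams:
    """Tunable cutoffs of the comparison pipeline (all Å except min_clique)."""

    d_max: float = 15.0
    epsilon: float = 2.0
    extend_cutoff: float = 3.0
    min_clique: int = 3

    def __post_init__(self) -> None:
        if min(self.d_max, self.epsilon, self.extend_cutoff, self.min_clique) <= 0:
            raise InvalidInputError("CompareParams fields must be positive")


@dataclass(frozen=True)
class FunctionalPoint:
    position: np.ndarray
    ptype: str
    residue_ref: ResidueRef

    def __post_init__(self) -> None:
        if self.ptype not in PTYPES:
            raise InvalidInputError(f"unknown functional point type {self.ptype!r}")


class ProteinGraph:
    """Functional points plus the distance-labelled edge set (d <= d_max)."""

    def __init__(self, points: Sequence[FunctionalPoint], d_max: float):
        self.points = list(points)
        self.d_max = d_max
        self.positions = np.array([p.position for p in self.points],
                                  dtype=float).reshape(-1, 3)
        self.ptypes = np.array([p.ptype for p in self.points])
        n = len(self.points)
        if n:
            self.distances = cdist(self.positions, self.positions)
        else:
            self.distances = np.zeros((0, 0))

    def __len__(self) -> int:
        return len(self.points)

    def has_edge(self, i: int, j: int) -> bool:
        return i != j and self.distances[i, j] <= self.d_max

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for i in range(len(self)):
            for j in range(i + 1, len(self)):
                if self.distances[i, j] <= self.d_max:
                    out.append((i, j, float(self.distances[i, j])))
        return out


class ProductGraph:
    """Compatibility graph of two protein graphs.

    Vertex ``(i, j)``: query point i and target point j share a ptype.
    Edge between ``(i, j)`` and ``(k, l)`` iff ``i != k``, ``j != l``, both
    intra-structure pairs are graph edges (<= d_max) and their distances
    agree within ``epsilon``.
    """

    def __init__(self, g_query: ProteinGraph, g_target: ProteinGraph, epsilon: float):
        self.g_query = g_query
        self.g_target = g_target
        self.epsilon = epsilon
        self.vertices: list[tuple[int, int]] = [
            (i, j)
            for i in range(len(g_query))
            for j in range(len(g_target))
            if g_query.ptypes[i] == g_target.ptypes[j]
        ]
        n = len(self.vertices)
        adj = np.zeros((n, n), dtype=bool)
        if n:
            qi = np.array([v[0] for v in self.vertices])
            tj = np.array([v[1] for v in self.vertices])
            dq = g_query.distances[np.ix_(qi, qi)]
            dt = g_target.distances[np.ix_(tj, tj)]
            adj = (
                (np.abs(dq - dt) <= epsilon)
                & (dq <= g_query.d_max)
                & (dt <= g_target.d_max)
                & (qi[:, None] != qi[None, :])
                & (tj[:, None] != tj[None, :])
            )
            np.fill_diagonal(adj, False)
        self.adjacency = adj

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class Hit:
    """A local alignment of a query region onto a target structure."""

    target_id: str
    correspondence: list[tuple[ResidueRef, ResidueRef]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    score: float
    z_score: float = 0.0
    frame_index: int | None = None


# ---------------------------------------------------------------------------
# Functional point typing
# ---------------------------------------------------------------------------

def _load_typing_table() -> list[tuple[str, str, list[str]]]:
    text = (resources.files("bsfp") / "data" / "functional_points.tsv").read_text()
    rows: list[tuple[str, str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resname, ptype, atoms = line.split("\t")
        rows.append((resname, ptype, atoms.split(",")))
    return rows


_TYPING_TABLE: list[tuple[str, str, list[str]]] | None = None


def typing_table() -> list[tuple[str, str, list[str]]]:
    global _TYPING_TABLE
    if _TYPING_TABLE is None:
        _TYPING_TABLE = _load_typing_table()
    return _TYPING_TABLE


_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def functional_points(structure: Structure,
                      region: Iterable[ResidueKey] | None = None) -> list[FunctionalPoint]:
    """Typed pseudoatoms for the given residues (default: all residues)."""
    wanted = set(region) if region is not None else None
    table = typing_table()
    points: list[FunctionalPoint] = []
    for res in structure.residues:
        if res.is_hetero:
            continue
        if wanted is not None and res.key not in wanted:
            continue
        ref: ResidueRef = (res.chain_id, res.number, res.insertion_code, res.name)
        rows = [row for row in table if row[0] == res.name]
        emitted = False
        for _, ptype, atom_names in rows:
            coords = [res.atom(a).coord for a in atom_names if res.atom(a) is not None]
            if coords:
                points.append(FunctionalPoint(np.mean(coords, axis=0), ptype, ref))
                emitted = True
        if not emitted:
            # unknown residue type or missing side chain: fall back to a
            # side-chain heavy-atom centroid (or CA) typed aliphatic
            side = [a.coord for a in res.heavy_atoms() if a.name not in _BACKBONE]
            if side:
                points.append(FunctionalPoint(np.mean(side, axis=0), "aliphatic", ref))
            elif res.atom("CA") is not None:
                points.append(FunctionalPoint(res.atom("CA").coord, "aliphatic", ref))
    return points


def build_protein_graph(structure: Structure,
                        region: Iterable[ResidueKey] | None = None,
                        params: CompareParams = CompareParams()) -> ProteinGraph:
    """Protein graph over a region (default: all surface residues)."""
    if region is not None:
        resolved = resolve_region(structure, region)
        if not resolved:
            raise EmptyRegionError(f"region resolves to no residues of {structure.id}")
    else:
        resolved = surface_residues(structure)
    return ProteinGraph(functional_points(structure, resolved), params.d_max)


def build_product_graph(g_query: ProteinGraph, g_target: ProteinGraph,
                        epsilon: float) -> ProductGraph:
    return ProductGraph(g_query, g_target, epsilon)


# ---------------------------------------------------------------------------
# Exact maximum clique (branch and bound with greedy colouring)
# ---------------------------------------------------------------------------

def max_clique(pg: ProductGraph | np.ndarray) -> list[int]:
    """Exact maximum clique of an undirected graph.

    Branch-and-bound in the style of exact clique solvers for product
    graphs: vertices are examined in a fixed order (degree descending, index
    ascending, so the result is deterministic) and a greedy colouring of the
    candidate set provides the pruning bound (a clique cannot use more
    vertices than colours).  Accepts a :class:`ProductGraph` or a boolean
    adjacency matrix; returns vertex indices (empty graph -> []; any lone
    vertex forms a clique of size 1).
    """
    adj = pg.adjacency if isinstance(pg, ProductGraph) else np.asarray(pg, dtype=bool)
    n = adj.shape[0]
    if n == 0:
        return []
    degrees = adj.sum(axis=1)
    order = sorted(range(n), key=lambda v: (-degrees[v], v))
    rank = {v: i for i, v in enumerate(order)}
    neighbors = [set(np.nonzero(adj[v])[0].tolist()) for v in range(n)]

    best: list[int] = [order[0]]

    def greedy_color(candidates: list[int]) -> list[tuple[int, int]]:
        """Colour candidates greedily; returns (vertex, colour) sorted by
        colour ascending.  Candidates must be in deterministic order."""
        color_classes: list[list[int]] = []
        colored: list[tuple[int, int]] = []
        for v in candidates:
            for c, cls in enumerate(color_classes):
                if all(u not in neighbors[v] for u in cls):
                    cls.append(v)
                    colored.append((v, c + 1))
                    break
            else:
                color_classes.append([v])
                colored.append((v, len(color_classes)))
        colored.sort(key=lambda vc: (vc[1], rank[vc[0]]))
        return colored

    def expand(current: list[int], candidates: list[int]) -> None:
        nonlocal best
        colored = greedy_color(candidates)
        ordered = [v for v, _ in colored]
        # branch from the highest colour down; vertices already branched on
        # at this level (the tail of `ordered`) are excluded from deeper calls
        for idx in range(len(colored) - 1, -1, -1):
            v, color = colored[idx]
            if len(current) + color <= len(best):
                return
            current.append(v)
            nxt = [u for u in ordered[:idx] if u in neighbors[v]]
            if nxt:
                expand(current, nxt)
            elif len(current) > len(best):
                best = list(current)
            current.pop()

    expand([], order)
    return sorted(best)


# ---------------------------------------------------------------------------
# Rigid superimposition (Kabsch via scipy)
# ---------------------------------------------------------------------------

@dataclass
class Transform:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superimpose(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Least-squares rigid superimposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R (det +1) and translation t minimizing
    ``|R x + t - y|`` over the paired points; raises
    :class:`DegenerateGeometryError` for fewer than 3 pairs or collinear
    points (no unique rotation).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise InvalidInputError("superimpose: point sets differ in size")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    # collinear (rank < 2) point sets leave a rotational degree of freedom
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear points: rotation not unique")
    rot, _rssd = Rotation.align_vectors(r0, m0)
    rotation = rot.as_matrix()
    translation = rc - rotation @ mc
    # recompute explicitly: the reported rssd loses precision near zero
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return Transform(rotation, translation, rmsd)


# ---------------------------------------------------------------------------
# Full pairwise comparison
# ---------------------------------------------------------------------------

def _point_ref(point: FunctionalPoint) -> ResidueRef:
    return point.residue_ref


def _extend_correspondence(g_query: ProteinGraph, g_target: ProteinGraph,
                           transform: Transform, cutoff: float
                           ) -> list[tuple[int, int, float]]:
    """Mutually nearest same-type point pairs within ``cutoff`` after
    moving the target into the query frame."""
    if not len(g_query) or not len(g_target):
        return []
    moved = transform.apply(g_target.positions)
    dist = cdist(g_query.positions, moved)
    type_ok = g_query.ptypes[:, None] == g_target.ptypes[None, :]
    dist = np.where(type_ok, dist, np.inf)
    pairs: list[tuple[int, int, float]] = []
    nearest_t = dist.argmin(axis=1)
    nearest_q = dist.argmin(axis=0)
    for i in range(len(g_query)):
        j = nearest_t[i]
        if np.isfinite(dist[i, j]) and dist[i, j] <= cutoff and nearest_q[j] == i:
            pairs.append((i, int(j), float(dist[i, j])))
    return pairs


def compare_sites(query: Structure, query_region: Iterable[ResidueKey],
                  target: Structure, params: CompareParams = CompareParams(),
                  target_region: Iterable[ResidueKey] | None = None) -> Hit | None:
    """Local alignment of a query region against a target structure.

    Pipeline: protein graphs -> product graph -> maximum clique ->
    superimpose the clique correspondence -> extend with mutually nearest
    compatible residue pairs within ``extend_cutoff`` -> re-superimpose on
    the extended pairing.  Score = number of aligned residue pairs.
    Returns None when the clique is smaller than ``min_clique`` or the
    geometry degenerates.
    """
    g_query = build_protein_graph(query, query_region, params)
    g_target = build_protein_graph(target, target_region, params)
    if not len(g_query) or not len(g_target):
        return None
    pg = build_product_graph(g_query, g_target, params.epsilon)
    if not len(pg):
        return None
    clique = max_clique(pg)
    if len(clique) < params.min_clique:
        return None
    qi = [pg.vertices[v][0] for v in clique]
    tj = [pg.vertices[v][1] for v in clique]
    try:
        transform = superimpose(g_target.positions[tj], g_query.positions[qi])
    except DegenerateGeometryError as exc:
        logger.warning("compare_sites %s vs %s: %s", query.id, target.id, exc)
        return None
    point_pairs = _extend_correspondence(g_query, g_target, transform,
                                         params.extend_cutoff)
    if len(point_pairs) >= 3:
        try:
            transform = superimpose(
                g_target.positions[[j for _, j, _ in point_pairs]],
                g_query.positions[[i for i, _, _ in point_pairs]])
            point_pairs = _extend_correspondence(g_query, g_target, transform,
                                                 params.extend_cutoff)
        except DegenerateGeometryError:
            pass
    # reduce point pairs to residue pairs, unique on both sides,
    # preferring closer pairs
    point_pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    used_q: set[ResidueRef] = set()
    used_t: set[ResidueRef] = set()
    correspondence: list[tuple[ResidueRef, ResidueRef]] = []
    for i, j, _ in point_pairs:
        rq = _point_ref(g_query.points[i])
        rt = _point_ref(g_target.points[j])
        if rq in used_q or rt in used_t:
            continue
        used_q.add(rq)
        used_t.add(rt)
        correspondence.append((rq, rt))
    if len(correspondence) < params.min_clique:
        return None
    correspondence.sort(key=lambda pair: pair[0])
    return Hit(target_id=target.id, correspondence=correspondence,
               rotation=transform.rotation, translation=transform.translation,
               rmsd=transform.rmsd, score=float(len(correspondence)),
               frame_index=query.frame_index)


def assign_z_scores(hits: list[Hit]) -> list[Hit]:
    """Standardize hit scores within one search run (population sd).

    Fewer than two hits or zero variance -> all z = 0.
    """
    if len(hits) < 2:
        return [replace_z(h, 0.0) for h in hits]
    scores = np.array([h.score for h in hits], dtype=float)
    sd = scores.std()
    if sd == 0:
        return [replace_z(h, 0.0) for h in hits]
    mean = scores.mean()
    return [replace_z(h, (h.score - mean) / sd) for h in hits]


def replace_z(hit: Hit, z: float) -> Hit:
    return Hit(hit.target_id, hit.correspondence, hit.rotation, hit.translation,
               hit.rmsd, hit.score, z, hit.frame_index)
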