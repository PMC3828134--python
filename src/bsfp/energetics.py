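"""MM/GBSA binding free energies over trajectory snapshots.

Single-trajectory scheme: for each complex snapshot the receptor and ligand
terms are evaluated on coordinates taken from the complex frame, so bonded
(internal) contributions cancel exactly and

    dG_bind = dE_MM + dG_sol - T*dS        (entropy term fixed at 0)
    dE_MM   = dE_internal + dE_electrostatic + dE_vdw
    dG_sol  = dG_GB + dG_SA

Molecular-mechanics terms: harmonic bonds ``k (r - r0)^2``, harmonic angles
``k (theta - theta0)^2``, cosine dihedrals ``k (1 + cos(n phi - delta))``,
Coulomb ``332.06 q_i q_j / (eps_int r)`` and 12-6 Lennard-Jones with 1-2 and
1-3 pairs excluded and 1-4 pairs scaled.  The polar solvation term is a
pairwise Generalized Born model with Hawkins-Cramer-Truhlar descreening
effective radii and the canonical smoothing function
``f_GB = sqrt(r^2 + Bi Bj exp(-r^2 / 4 Bi Bj))``; the non-polar term is
``gamma * SASA + beta``.  Parameters are supplied as a self-contained
sidecar file per structure (no force-field importer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from .core_model import Structure, Trajectory, atom_sasa
from .errors import (
    InvalidInputError,
    NumericalDegeneracyError,
    ParameterError,
    SelectionOverlapError,
)
from .traj_analysis import select_window_indices

COULOMB_CONSTANT = 332.06  # kcal Å / (mol e²)


@dataclass
class ForceFieldParams:
    """Self-contained per-structure parameter set.

    Per-atom arrays are indexed by flat atom order; bonded terms reference
    those indices.  Angle ``theta0`` and dihedral ``delta`` are in degrees;
    force constants in kcal/mol per Å² or rad² as appropriate.
    """

    charge: np.ndarray                    # e
    lj_eps: np.ndarray                    # kcal/mol
    lj_rmin: np.ndarray                   # Å (pair minimum for two like atoms)
    gb_radius: np.ndarray                 # Å
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    eps_int: float = 1.0
    eps_solv: float = 78.5
    gamma: float = 0.00542                # kcal/mol/Å²
    beta: float = 0.92                    # kcal/mol
    scale14_elec: float = 1.0
    scale14_lj: float = 1.0
    gb_scale: float = 0.8                 # HCT descreening scale factor

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_eps = np.asarray(self.lj_eps, dtype=float)
        self.lj_rmin = np.asarray(self.lj_rmin, dtype=float)
        self.gb_radius = np.asarray(self.gb_radius, dtype=float)
        n = len(self.charge)
        for name in ("lj_eps", "lj_rmin", "gb_radius"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"{name} length != charge length")
        if np.any(self.gb_radius <= 0):
            raise ParameterError("GB radii must be positive")
        if self.eps_int < 1 or self.eps_solv < 1:
            raise ParameterError("dielectrics must be >= 1")
        for term in self.bonds + self.angles + self.dihedrals:
            for idx in term[: {4: 2, 5: 3, 7: 4}[len(term)]]:
                if not 0 <= idx < n:
                    raise ParameterError(f"bonded term references atom {idx} "
                                         f"outside 0..{n - 1}")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def subset(self, indices: np.ndarray) -> "ForceFieldParams":
        """Parameters restricted to a subset of atoms.

        Bonded terms crossing the subset boundary are dropped (a valid
        receptor/ligand split has none; :func:`binding_free_energy` checks).
        """
        indices = np.asarray(indices, dtype=int)
        remap = {int(old): new for new, old in enumerate(indices)}
        keep = set(remap)

        def keep_term(term, n_idx):
            return all(i in keep for i in term[:n_idx])

        return ForceFieldParams(
            self.charge[indices], self.lj_eps[indices], self.lj_rmin[indices],
            self.gb_radius[indices],
            [(remap[i], remap[j], k, r0) for i, j, k, r0 in self.bonds
             if keep_term((i, j), 2)],
            [(remap[i], remap[j], remap[k], kt, t0)
             for i, j, k, kt, t0 in self.angles if keep_term((i, j, k), 3)],
            [(remap[i], remap[j], remap[k], remap[l], kp, n, d)
             for i, j, k, l, kp, n, d in self.dihedrals
             if keep_term((i, j, k, l), 4)],
            self.eps_int, self.eps_solv, self.gamma, self.beta,
            self.scale14_elec, self.scale14_lj, self.gb_scale)


@dataclass
class EnergyTerms:
    E_internal: float
    E_electrostatic: float
    E_vdw: float
    G_GB: float
    G_SA: float

    @property
    def E_MM(self) -> float:
        return self.E_internal + self.E_electrostatic + self.E_vdw

    @property
    def G_sol(self) -> float:
        return self.G_GB + self.G_SA

    @property
    def total(self) -> float:
        return self.E_MM + self.G_sol


@dataclass
class BindingFreeEnergy:
    per_frame: np.ndarray          # dG_bind per analyzed frame, kcal/mol
    mean: float
    sd: float
    entropy_term: float            # -T*dS, fixed 0
    components: dict[str, float]   # means of dE_internal, dE_elec, dE_vdw, dG_GB, dG_SA


# ---------------------------------------------------------------------------
# Sidecar parameter files
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = ("eps_int", "eps_solv", "gamma", "beta",
                "scale14_elec", "scale14_lj", "gb_scale")


def write_params(params: ForceFieldParams, path: str | Path) -> None:
    lines = ["[globals]"]
    for key in _GLOBAL_KEYS:
        lines.append(f"{key}\t{float(getattr(params, key))!r}")
    lines.append("[atoms]")
    lines.append("index\tcharge\tlj_eps\tlj_rmin\tgb_radius")
    for i in range(params.n_atoms):
        lines.append("%d\t%r\t%r\t%r\t%r" % (i, float(params.charge[i]),
                                             float(params.lj_eps[i]),
                                             float(params.lj_rmin[i]),
                                             float(params.gb_radius[i])))
    lines.append("[bonds]")
    for i, j, k, r0 in params.bonds:
        lines.append(f"{i}\t{j}\t{float(k)!r}\t{float(r0)!r}")
    lines.append("[angles]")
    for i, j, k, kt, t0 in params.angles:
        lines.append(f"{i}\t{j}\t{k}\t{float(kt)!r}\t{float(t0)!r}")
    lines.append("[dihedrals]")
    for i, j, k, l, kp, n, d in params.dihedrals:
        lines.append(f"{i}\t{j}\t{k}\t{l}\t{float(kp)!r}\t{n}\t{float(d)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path, n_atoms: int | None = None) -> ForceFieldParams:
    section = None
    globals_: dict[str, float] = {}
    atoms: dict[int, tuple[float, float, float, float]] = {}
    bonds, angles, dihedrals = [], [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        fields = line.split("\t")
        if section == "globals":
            globals_[fields[0]] = float(fields[1])
        elif section == "atoms":
            if fields[0] == "index":
                continue
            atoms[int(fields[0])] = tuple(float(x) for x in fields[1:5])
        elif section == "bonds":
            bonds.append((int(fields[0]), int(fields[1]),
                          float(fields[2]), float(fields[3])))
        elif section == "angles":
            angles.append((int(fields[0]), int(fields[1]), int(fields[2]),
                           float(fields[3]), float(fields[4])))
        elif section == "dihedrals":
            dihedrals.append((int(fields[0]), int(fields[1]), int(fields[2]),
                              int(fields[3]), float(fields[4]), int(fields[5]),
                              float(fields[6])))
        else:
            raise ParameterError(f"{path}: line outside a known section: {raw!r}")
    if not atoms:
        raise ParameterError(f"{path}: no [atoms] section")
    count = max(atoms) + 1
    if n_atoms is not None and count != n_atoms:
        raise ParameterError(f"{path}: parameters for {count} atoms, "
                             f"structure has {n_atoms}")
    missing = [i for i in range(count) if i not in atoms]
    if missing:
        raise ParameterError(f"{path}: missing atom parameters for indices {missing}")
    table = np.array([atoms[i] for i in range(count)])
    return ForceFieldParams(table[:, 0], table[:, 1], table[:, 2], table[:, 3],
                            bonds, angles, dihedrals, **globals_)


# ---------------------------------------------------------------------------
# Molecular mechanics terms
# ---------------------------------------------------------------------------

def _coords_of(obj: Structure | np.ndarray) -> np.ndarray:
    if isinstance(obj, Structure):
        return obj.coords()
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def _bond_path_lengths(params: ForceFieldParams) -> np.ndarray:
    """Topological distances (number of bonds) up to 3, inf beyond."""
    n = params.n_atoms
    if not params.bonds:
        return np.full((n, n), np.inf)
    rows = [i for i, j, *_ in params.bonds] + [j for i, j, *_ in params.bonds]
    cols = [j for i, j, *_ in params.bonds] + [i for i, j, *_ in params.bonds]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(graph, method="D", unweighted=True, directed=False)


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return math.atan2(y, x)


def mm_energy(structure: Structure | np.ndarray,
              params: ForceFieldParams) -> tuple[float, float, float]:
    """Gas-phase MM energy: (E_internal, E_electrostatic, E_vdw) kcal/mol."""
    coords = _coords_of(structure)
    if len(coords) != params.n_atoms:
        raise ParameterError(f"structure has {len(coords)} atoms, "
                             f"parameters cover {params.n_atoms}")
    e_internal = 0.0
    for i, j, k, r0 in params.bonds:
        r = np.linalg.norm(coords[i] - coords[j])
        e_internal += k * (r - r0) ** 2
    for i, j, k, kt, t0 in params.angles:
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cosine = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = math.acos(max(-1.0, min(1.0, cosine)))
        e_internal += kt * (theta - math.radians(t0)) ** 2
    for i, j, k, l, kp, n, d in params.dihedrals:
        phi = _dihedral_angle(coords[i], coords[j], coords[k], coords[l])
        e_internal += kp * (1.0 + math.cos(n * phi - math.radians(d)))

    n_atoms = params.n_atoms
    e_elec = 0.0
    e_vdw = 0.0
    if n_atoms > 1:
        topo = _bond_path_lengths(params)
        dist = squareform(pdist(coords))
        iu = np.triu_indices(n_atoms, 1)
        r = dist[iu]
        t = topo[iu]
        included = t >= 3.5  # 1-5 and beyond (path >= 4) or disconnected
        scaled14 = np.isclose(t, 3.0)
        qq = np.outer(params.charge, params.charge)[iu]
        elec = COULOMB_CONSTANT * qq / (params.eps_int * r)
        eps_ij = np.sqrt(np.outer(params.lj_eps, params.lj_eps))[iu]
        rmin_ij = (0.5 * (params.lj_rmin[:, None] + params.lj_rmin[None, :]))[iu]
        ratio6 = (rmin_ij / r) ** 6
        lj = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
        e_elec = float(elec[included].sum()
                       + params.scale14_elec * elec[scaled14].sum())
        e_vdw = float(lj[included].sum() + params.scale14_lj * lj[scaled14].sum())
    return float(e_internal), e_elec, e_vdw


# ---------------------------------------------------------------------------
# Generalized Born solvation
# ---------------------------------------------------------------------------

def effective_born_radii(coords: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """HCT pairwise-descreening effective radii B_i (Å).

    For an isolated atom B equals its intrinsic GB radius; neighbours
    descreen solvent and increase B.  Raises
    :class:`NumericalDegeneracyError` if the descreening sum drives an
    inverse radius to zero or below.
    """
    rho = params.gb_radius
    s = params.gb_scale
    n = len(coords)
    inv_b = 1.0 / rho
    if n > 1:
        dist = squareform(pdist(coords))
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if j == i:
                    continue
                r = dist[i, j]
                sr = s * rho[j]
                if r + sr <= rho[i]:
                    continue  # neighbour buried inside atom i
                upper = r + sr
                lower = max(rho[i], abs(r - sr))
                acc += 0.5 * (
                    1.0 / lower - 1.0 / upper
                    + (r / 4.0) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
                    + (1.0 / (2.0 * r)) * math.log(lower / upper)
                    + (sr ** 2 / (4.0 * r)) * (1.0 / lower ** 2 - 1.0 / upper ** 2)
                )
                if sr > r + rho[i]:
                    # neighbour sphere engulfs atom i entirely
                    acc += 1.0 / rho[i] - 1.0 / lower
            inv_b[i] -= acc
    if np.any(inv_b <= 0):
        bad = np.nonzero(inv_b <= 0)[0].tolist()
        raise NumericalDegeneracyError(
            f"non-positive inverse effective radius for atoms {bad}")
    return 1.0 / inv_b


def gb_energy(structure: Structure | np.ndarray, params: ForceFieldParams) -> float:
    """Polar solvation energy G_GB (kcal/mol), pairwise GB.

    ``G_GB = -1/2 (1/eps_int - 1/eps_solv) * k_C * sum_ij q_i q_j / f_GB``
    with the self term ``f_GB(i, i) = B_i`` (Born limit for a single ion).
    """
    coords = _coords_of(structure)
    if len(coords) != params.n_atoms:
        raise ParameterError("coordinate/parameter atom count mismatch")
    b = effective_born_radii(coords, params)
    tau = (1.0 / params.eps_int - 1.0 / params.eps_solv) * COULOMB_CONSTANT
    q = params.charge
    r2 = squareform(pdist(coords)) ** 2 if len(coords) > 1 else np.zeros((1, 1))
    bb = np.outer(b, b)
    f_gb = np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))
    return float(-0.5 * tau * (np.outer(q, q) / f_gb).sum())


def total_sasa(structure: Structure, probe_radius: float = 1.4,
               point_number: int = 300) -> float:
    return float(atom_sasa(structure, probe_radius, point_number).sum())


def sa_energy(structure: Structure, params: ForceFieldParams,
              probe_radius: float = 1.4) -> float:
    """Non-polar solvation energy ``G_SA = gamma * SASA + beta``."""
    return params.gamma * total_sasa(structure, probe_radius) + params.beta


def energy_terms(structure: Structure, params: ForceFieldParams) -> EnergyTerms:
    """All MM/GBSA terms of one structure snapshot."""
    e_int, e_elec, e_vdw = mm_energy(structure, params)
    return EnergyTerms(e_int, e_elec, e_vdw,
                       gb_energy(structure, params), sa_energy(structure, params))


# ---------------------------------------------------------------------------
# Binding free energy over a trajectory
# ---------------------------------------------------------------------------

def _subset_structure(frame: Structure, indices: np.ndarray) -> Structure:
    """A structure containing only the selected atoms (for SASA)."""
    wanted = set(int(i) for i in indices)
    flat = 0
    residues = []
    for res in frame.residues:
        atoms = []
        for atom in res.atoms:
            if flat in wanted:
                atoms.append(atom.copy())
            flat += 1
        if atoms:
            residues.append(type(res)(res.chain_id, res.number, res.name, atoms,
                                      res.insertion_code, res.is_hetero))
    return Structure(frame.id + ".sub", residues)


def binding_free_energy(traj: Trajectory,
                        receptor_sel: np.ndarray,
                        ligand_sel: np.ndarray,
                        params: ForceFieldParams,
                        window: tuple[float, float] | None = None) -> BindingFreeEnergy:
    """Single-trajectory MM/GBSA binding free energy.

    ``receptor_sel`` / ``ligand_sel`` are flat atom index arrays that must
    partition the complex.  For each analyzed frame the receptor and ligand
    terms are computed on coordinates taken from the complex frame, so
    dE_internal cancels exactly (asserted).  ``window`` is an optional
    ``(window_ns, stride_ps)`` pair selecting the trailing analysis window;
    default: every frame.
    """
    receptor_sel = np.asarray(sorted(int(i) for i in receptor_sel), dtype=int)
    ligand_sel = np.asarray(sorted(int(i) for i in ligand_sel), dtype=int)
    n_atoms = params.n_atoms
    overlap = set(receptor_sel) & set(ligand_sel)
    if overlap:
        raise SelectionOverlapError(f"selections share atoms {sorted(overlap)}")
    union = set(receptor_sel) | set(ligand_sel)
    if union != set(range(n_atoms)):
        raise SelectionOverlapError(
            "selections must partition the complex; missing atoms "
            f"{sorted(set(range(n_atoms)) - union)}")
    for i, j, *_ in params.bonds:
        if (i in set(receptor_sel)) != (j in set(receptor_sel)):
            raise SelectionOverlapError(
                f"bond {i}-{j} crosses the receptor/ligand partition")
    p_rec = params.subset(receptor_sel)
    p_lig = params.subset(ligand_sel)

    if window is not None:
        window_ns, stride_ps = window
        indices = select_window_indices(traj.n_frames, traj.dt_ps,
                                        window_ns, stride_ps)
        frames = [traj.frames[i] for i in indices]
    else:
        frames = list(traj.frames)
    if not frames:
        raise InvalidInputError("no frames to analyze")

    per_frame = np.empty(len(frames))
    comp_sums = dict.fromkeys(
        ("dE_internal", "dE_electrostatic", "dE_vdw", "dG_GB", "dG_SA"), 0.0)
    for idx, frame in enumerate(frames):
        coords = frame.coords()
        if len(coords) != n_atoms:
            raise ParameterError("frame atom count does not match parameters")
        t_com = energy_terms(frame, params)
        rec = _subset_structure(frame, receptor_sel)
        lig = _subset_structure(frame, ligand_sel)
        t_rec = energy_terms(rec, p_rec)
        t_lig = energy_terms(lig, p_lig)
        d_int = t_com.E_internal - t_rec.E_internal - t_lig.E_internal
        assert abs(d_int) < 1e-8, "single-trajectory dE_internal must vanish"
        d_elec = t_com.E_electrostatic - t_rec.E_electrostatic - t_lig.E_electrostatic
        d_vdw = t_com.E_vdw - t_rec.E_vdw - t_lig.E_vdw
        d_gb = t_com.G_GB - t_rec.G_GB - t_lig.G_GB
        d_sa = t_com.G_SA - t_rec.G_SA - t_lig.G_SA
        comp_sums["dE_internal"] += d_int
        comp_sums["dE_electrostatic"] += d_elec
        comp_sums["dE_vdw"] += d_vdw
        comp_sums["dG_GB"] += d_gb
        comp_sums["dG_SA"] += d_sa
        per_frame[idx] = d_int + d_elec + d_vdw + d_gb + d_sa
    n = len(frames)
    components = {k: v / n for k, v in comp_sums.items()}
    sd = float(per_frame.std(ddof=1)) if n > 1 else 0.0
    return BindingFreeEnergy(per_frame, float(per_frame.mean()), sd, 0.0, components)
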