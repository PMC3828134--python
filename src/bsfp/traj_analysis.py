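"""Trajectory post-processing: hydrogen bonds, subset RMSD, windows.

Hydrogen bonds use a geometric criterion — donor-acceptor heavy-atom
distance <= 3.5 Å, plus a D-H···A angle >= 120° whenever an explicit
hydrogen is bonded to the donor (distance-only otherwise, as for
heavy-atom-only models).  A bond's *occupancy* is the fraction of analyzed
frames satisfying the criterion; only bonds with occupancy strictly above
the threshold (default 0.5) are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import Atom, ResidueKey, Structure, Trajectory
from .errors import (
    InvalidInputError,
    SelectionMismatchError,
    WindowOutOfRangeError,
)
from .sitegraph import superimpose

#: atom reference: (chain, residue number, insertion code, atom name)
AtomRef = tuple[str, int, str, str]

#: default geometric criterion: (max D...A distance Å, min D-H...A angle °)
DEFAULT_CRITERIA = (3.5, 120.0)

_HYDROGEN_BOND_LENGTH = 1.25  # Å; covalent D-H detection radius


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    occupancy: float
    mean_distance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise InvalidInputError("occupancy outside [0, 1]")


def _atom_lookup(frame: Structure) -> dict[AtomRef, Atom]:
    out: dict[AtomRef, Atom] = {}
    for res in frame.residues:
        for atom in res.atoms:
            out[(res.chain_id, res.number, res.insertion_code, atom.name)] = atom
    return out


def _donor_hydrogens(frame: Structure, donor_ref: AtomRef,
                     lookup: dict[AtomRef, Atom]) -> list[Atom]:
    donor = lookup[donor_ref]
    chain, number, icode, _ = donor_ref
    hydrogens = []
    for res in frame.residues:
        if (res.chain_id, res.number, res.insertion_code) != (chain, number, icode):
            continue
        for atom in res.atoms:
            if atom.is_hydrogen and \
                    np.linalg.norm(atom.coord - donor.coord) <= _HYDROGEN_BOND_LENGTH:
                hydrogens.append(atom)
    return hydrogens


def _satisfied(frame: Structure, donor_ref: AtomRef, acceptor_ref: AtomRef,
               criteria: tuple[float, float],
               lookup: dict[AtomRef, Atom]) -> tuple[bool, float]:
    d_max, angle_min = criteria
    donor = lookup.get(donor_ref)
    acceptor = lookup.get(acceptor_ref)
    if donor is None or acceptor is None:
        raise InvalidInputError(f"atom not found: {donor_ref} or {acceptor_ref}")
    distance = float(np.linalg.norm(donor.coord - acceptor.coord))
    if distance > d_max:
        return False, distance
    hydrogens = _donor_hydrogens(frame, donor_ref, lookup)
    if not hydrogens:
        return True, distance  # heavy-atom model: distance-only criterion
    for h in hydrogens:
        v1 = donor.coord - h.coord
        v2 = acceptor.coord - h.coord
        cosine = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosine))))
        if angle >= angle_min:
            return True, distance
    return False, distance


def hydrogen_bonds(traj: Trajectory, donors: set[AtomRef], acceptors: set[AtomRef],
                   criteria: tuple[float, float] = DEFAULT_CRITERIA,
                   min_occupancy: float = 0.5) -> list[HBond]:
    """Persistent hydrogen bonds between donor and acceptor atom sets.

    All donor x acceptor pairs are evaluated per frame; a pair is reported
    when its occupancy is strictly greater than ``min_occupancy``.  Bonds
    are sorted by occupancy descending.
    """
    if not donors or not acceptors:
        raise InvalidInputError("donor and acceptor sets must be non-empty")
    if traj.n_frames < 1:
        raise InvalidInputError("trajectory must have at least one frame")
    pairs = [(d, a) for d in sorted(donors) for a in sorted(acceptors) if d != a]
    satisfied = np.zeros(len(pairs), dtype=int)
    distance_sum = np.zeros(len(pairs))
    for frame in traj.frames:
        lookup = _atom_lookup(frame)
        for k, (d, a) in enumerate(pairs):
            ok, distance = _satisfied(frame, d, a, criteria, lookup)
            if ok:
                satisfied[k] += 1
                distance_sum[k] += distance
    bonds = []
    for k, (d, a) in enumerate(pairs):
        occupancy = satisfied[k] / traj.n_frames
        if occupancy > min_occupancy:
            bonds.append(HBond(d, a, occupancy, distance_sum[k] / satisfied[k]))
    bonds.sort(key=lambda b: (-b.occupancy, b.donor, b.acceptor))
    return bonds


# ---------------------------------------------------------------------------
# Subset RMSD
# ---------------------------------------------------------------------------

def _select_atoms(structure: Structure, selection: str) -> list[tuple[ResidueKey, Atom]]:
    return [(res.key, atom) for res in structure.residues for atom in res.atoms
            if atom.name == selection]


def subset_rmsd(frame: Structure, reference: Structure, selection: str = "CA") -> float:
    """RMSD of a named-atom selection after optimal rigid superimposition.

    The selections of both structures must pair up one-to-one by residue;
    offenders are listed otherwise.
    """
    sel_frame = _select_atoms(frame, selection)
    sel_ref = _select_atoms(reference, selection)
    keys_frame = [k for k, _ in sel_frame]
    keys_ref = [k for k, _ in sel_ref]
    if keys_frame != keys_ref:
        only_frame = sorted(set(keys_frame) - set(keys_ref))
        only_ref = sorted(set(keys_ref) - set(keys_frame))
        raise SelectionMismatchError(
            f"selection {selection!r} mismatch; only in frame: {only_frame}; "
            f"only in reference: {only_ref}")
    coords_frame = np.array([a.coord for _, a in sel_frame])
    coords_ref = np.array([a.coord for _, a in sel_ref])
    return superimpose(coords_frame, coords_ref).rmsd


# ---------------------------------------------------------------------------
# Snapshot windows
# ---------------------------------------------------------------------------

def select_window_indices(n_frames: int, dt_ps: float,
                          window_ns: float = 20.0,
                          stride_ps: float = 1.0) -> list[int]:
    """Frame indices of the last ``window_ns`` at ``stride_ps`` spacing.

    Snapshots are counted backward from the final frame (inclusive): a
    window of W ns at stride s contains W * 1000 / s snapshots.  Raises
    :class:`WindowOutOfRangeError` if the trajectory is too short.
    """
    if dt_ps <= 0 or stride_ps <= 0 or window_ns <= 0:
        raise InvalidInputError("dt, stride and window must be positive")
    stride_frames = stride_ps / dt_ps
    if abs(stride_frames - round(stride_frames)) > 1e-9 or round(stride_frames) < 1:
        raise InvalidInputError(
            f"stride {stride_ps} ps is not a multiple of dt {dt_ps} ps")
    stride_frames = round(stride_frames)
    n_snap = round(window_ns * 1000.0 / stride_ps)
    first = (n_frames - 1) - (n_snap - 1) * stride_frames
    if first < 0:
        raise WindowOutOfRangeError(
            f"window of {window_ns} ns at stride {stride_ps} ps needs "
            f"{(n_snap - 1) * stride_frames + 1} frames, trajectory has {n_frames}")
    return list(range(first, n_frames, stride_frames))


def select_window(traj: Trajectory, window_ns: float = 20.0,
                  stride_ps: float = 1.0) -> list[Structure]:
    """Frames of the trailing analysis window (see
    :func:`select_window_indices` for the counting convention)."""
    indices = select_window_indices(traj.n_frames, traj.dt_ps, window_ns, stride_ps)
    return [traj.frames[i] for i in indices]
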