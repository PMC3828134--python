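"""Multi-frame (quenched-ensemble) binding-site search.

Snapshots are quenched from a molecular-dynamics trajectory on a segment
schedule (the default reproduces the 20 + 10 = 30 frame protocol: every
5 ps over the first 100 ps, then every 100 ps up to 1 ns).  Every frame's
binding-site region is compared against every library structure; hits are
pooled, standardized, thresholded at Z > z_min, and deduplicated keeping
the single highest-Z hit per library protein (ties -> earlier frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_model import ResidueKey, Structure, Trajectory
from .errors import InvalidInputError, ScheduleOutOfRangeError
from .sitegraph import CompareParams, Hit, assign_z_scores, compare_sites

logger = logging.getLogger(__name__)

_TIME_TOL = 1e-6


@dataclass(frozen=True)
class QuenchSchedule:
    """Sampling segments ``(t_start, t_end, interval)`` in ps.

    Each segment is half-open ``[t_start, t_end)``; in a multi-segment
    schedule the final segment additionally includes its endpoint (the
    boundary time belongs to the segment that starts there, and the very
    last boundary has no successor to own it).  This is the unique simple
    convention under which the default schedule
    ``[(0, 100, 5), (100, 1000, 100)]`` yields 0, 5, ..., 95 ps (20 frames)
    plus 100, 200, ..., 1000 ps (10 frames), while the first segment alone
    yields exactly the 20.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for t_start, t_end, interval in self.segments:
            if interval <= 0 or t_end <= t_start:
                raise InvalidInputError(f"bad segment {(t_start, t_end, interval)}")
            if prev_end is not None and t_start < prev_end:
                raise InvalidInputError("segments overlap or are out of order")
            prev_end = t_end

    def times(self) -> list[float]:
        out: list[float] = []
        for seg_idx, (t_start, t_end, interval) in enumerate(self.segments):
            closed = len(self.segments) > 1 and seg_idx == len(self.segments) - 1
            t = t_start
            while t < t_end - _TIME_TOL or (closed and t <= t_end + _TIME_TOL):
                out.append(t)
                t += interval
        return out


def default_schedule() -> QuenchSchedule:
    return QuenchSchedule(((0.0, 100.0, 5.0), (100.0, 1000.0, 100.0)))


def parse_schedule(text: str) -> QuenchSchedule:
    """Parse ``"0:100:5,100:1000:100"`` into a schedule."""
    segments = []
    for part in text.split(","):
        fields = part.split(":")
        if len(fields) != 3:
            raise InvalidInputError(f"bad schedule segment {part!r}")
        segments.append(tuple(float(x) for x in fields))
    return QuenchSchedule(tuple(segments))


def quench_frames(traj: Trajectory, schedule: QuenchSchedule) -> list[Structure]:
    """Extract the frames at the schedule's times.

    Every scheduled time must coincide with a trajectory frame time;
    otherwise a :class:`ScheduleOutOfRangeError` names the missing time.
    """
    frames: list[Structure] = []
    for t in schedule.times():
        index_f = (t - traj.t0_ps) / traj.dt_ps
        index = round(index_f)
        if abs(index_f - index) > _TIME_TOL or not 0 <= index < traj.n_frames:
            raise ScheduleOutOfRangeError(
                f"no trajectory frame at t = {t} ps "
                f"(trajectory: t0 = {traj.t0_ps} ps, dt = {traj.dt_ps} ps, "
                f"{traj.n_frames} frames)")
        frame = traj.frames[index]
        if frame.frame_index is None:
            frame.frame_index = index
        frames.append(frame)
    return frames


@dataclass
class SearchReport:
    hits: list[Hit]
    n_frames: int
    z_min: float
    per_frame_counts: dict[int, int] = field(default_factory=dict)


def ensemble_search(frames: list[Structure], region: set[ResidueKey],
                    db: list[Structure],
                    params: CompareParams = CompareParams(),
                    z_min: float = 0.5) -> SearchReport:
    """Search a region of every frame against a structure library.

    Hits from all (frame, library entry) comparisons are pooled and
    standardized together, so Z-scores share one scale across frames.  Hits
    at Z <= z_min are dropped; of the survivors, only the highest-Z hit per
    library protein is retained (ties broken toward the earlier frame).
    Retained hits are sorted by Z descending.
    """
    pooled: list[Hit] = []
    per_frame_counts: dict[int, int] = {}
    for order, frame in enumerate(frames):
        frame_id = frame.frame_index if frame.frame_index is not None else order
        count = 0
        for target in db:
            hit = compare_sites(frame, region, target, params)
            if hit is not None:
                hit.frame_index = frame_id
                pooled.append(hit)
                count += 1
        per_frame_counts[frame_id] = count
    pooled = assign_z_scores(pooled)
    retained: dict[str, Hit] = {}
    for hit in pooled:
        if hit.z_score <= z_min:
            continue
        prev = retained.get(hit.target_id)
        if (prev is None or hit.z_score > prev.z_score
                or (hit.z_score == prev.z_score
                    and (hit.frame_index or 0) < (prev.frame_index or 0))):
            retained[hit.target_id] = hit
    hits = sorted(retained.values(),
                  key=lambda h: (-h.z_score, h.frame_index or 0, h.target_id))
    logger.info("ensemble search: %d frames x %d targets -> %d pooled, %d retained",
                len(frames), len(db), len(pooled), len(hits))
    return SearchReport(hits, len(frames), z_min, per_frame_counts)
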