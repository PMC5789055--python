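"""Domain model for longitudinal dendritic-spine imaging data.

The unit of analysis is a :class:`SpineMap`: a set of animals, each carrying
dendritic segments imaged repeatedly on a fixed schedule of days relative to
the start of training (negative days = baseline sessions).  Spine positions
are 1-D path coordinates in micrometres along the segment (base-to-base
convention); all inter-spine distances are absolute coordinate differences
within a segment.  Presence is scored per session with no identity
persistence across gaps: a spine that disappears and reappears is two events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ImagingSchedule",
    "Spine",
    "SpineFate",
    "DendriteSegment",
    "AnimalRecord",
    "SpineMap",
    "SchemaError",
    "ValidationError",
    "read_spine_table",
    "write_spine_table",
    "read_behavior_table",
    "annotate_fates",
]


class SchemaError(ValueError):
    """A required column is missing or malformed in a spine table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (position bounds, duplicates...)."""


@dataclass(frozen=True)
class ImagingSchedule:
    """Ordered imaging days relative to the first training day (day 0)."""

    sessions: tuple[int, ...]

    def __post_init__(self) -> None:
        sessions = tuple(int(s) for s in self.sessions)
        object.__setattr__(self, "sessions", sessions)
        if len(sessions) < 2:
            raise ValidationError("schedule needs at least 2 sessions")
        if any(b <= a for a, b in zip(sessions, sessions[1:])):
            raise ValidationError(f"sessions must be strictly increasing: {sessions}")

    def index(self, day: int) -> int:
        try:
            return self.sessions.index(int(day))
        except ValueError:
            raise KeyError(f"day {day} not in imaging schedule {self.sessions}") from None

    def __len__(self) -> int:
        return len(self.sessions)


@dataclass(frozen=True)
class SpineFate:
    """Interval-wise fate annotation of a single spine.

    All flags refer to the three analysis days passed to
    :func:`annotate_fates`: the pre-learning baseline session ``t_pre``, the
    learning start ``t0``, and the learning end ``t_end``.
    ``new_stable`` (absent at ``t0``, present at ``t_end``) is the class the
    clustering statistics operate on.
    """

    baseline_formed: bool
    baseline_lost: bool
    baseline_stable: bool
    formed: bool       # absent at t0, present at some later session <= t_end
    lost: bool         # present at t0, absent at t_end
    new_stable: bool   # absent at t0, present at t_end

    @property
    def baseline_turnover(self) -> bool:
        """Pre-learning turnover site: formed or lost between baseline sessions."""
        return self.baseline_formed or self.baseline_lost


@dataclass
class Spine:
    spine_id: str
    position: float
    presence: np.ndarray  # bool vector aligned to the schedule
    fate: SpineFate | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 1:
            raise ValidationError(f"presence of {self.spine_id} must be 1-D")
        if not self.presence.any():
            raise ValidationError(f"spine {self.spine_id} is never present")

    def present_at(self, schedule: ImagingSchedule, day: int) -> bool:
        return bool(self.presence[schedule.index(day)])


@dataclass
class DendriteSegment:
    segment_id: str
    animal_id: str
    length: float
    spines: list[Spine] = field(default_factory=list)
    # days whose imaging is missing for the whole segment; such a segment is
    # excluded from any statistic touching that session
    missing_sessions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValidationError(f"segment {self.segment_id}: length must be > 0")
        seen: set[str] = set()
        for sp in self.spines:
            if sp.spine_id in seen:
                raise ValidationError(
                    f"duplicate spine_id {sp.spine_id!r} in segment {self.segment_id}"
                )
            seen.add(sp.spine_id)
            if not (0.0 <= sp.position <= self.length):
                raise ValidationError(
                    f"segment {self.segment_id}: spine {sp.spine_id} at "
                    f"{sp.position} um outside [0, {self.length}]"
                )


@dataclass
class AnimalRecord:
    animal_id: str
    group: str               # "trained" | "control"
    genotype: str            # "WT" | "mutant"
    schedule: ImagingSchedule
    segments: list[DendriteSegment] = field(default_factory=list)
    behavior: dict[int, float] = field(default_factory=dict)  # day -> freezing %

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"animal {self.animal_id} has no segments")
        n = len(self.schedule)
        for seg in self.segments:
            for sp in seg.spines:
                if len(sp.presence) != n:
                    raise ValidationError(
                        f"spine {sp.spine_id}: presence length {len(sp.presence)} "
                        f"!= {n} sessions"
                    )

    def all_spines(self):
        for seg in self.segments:
            yield from seg.spines


@dataclass
class SpineMap:
    """All animals of an experiment, sharing one imaging schedule."""

    animals: dict[str, AnimalRecord]

    def __post_init__(self) -> None:
        if not self.animals:
            raise ValidationError("SpineMap has no animals")
        schedules = {a.schedule.sessions for a in self.animals.values()}
        if len(schedules) != 1:
            raise ValidationError("all animals must share one imaging schedule")

    @property
    def schedule(self) -> ImagingSchedule:
        return next(iter(self.animals.values())).schedule

    def __iter__(self):
        return iter(self.animals.values())

    def __len__(self) -> int:
        return len(self.animals)


_BASE_COLUMNS = [
    "animal", "group", "genotype", "segment", "segment_length_um",
    "spine_id", "position_um",
]


def _day_column(day: int) -> str:
    return f"d{day}"


def _parse_day_columns(columns) -> list[int]:
    days = []
    for c in columns:
        if isinstance(c, str) and c.startswith("d") and c != "d":
            try:
                days.append(int(c[1:]))
            except ValueError:
                continue
    return sorted(days)


def read_spine_table(path, dialect: dict[str, str] | None = None,
                     behavior: dict | pd.DataFrame | None = None) -> SpineMap:
    """Read a delimited spine table into a validated :class:`SpineMap`.

    Parameters
    ----------
    path : str or file-like
        CSV/TSV file with columns ``animal, group, genotype, segment,
        segment_length_um, spine_id, position_um`` and one 0/1 presence
        column per imaging day, named ``d{day}`` (e.g. ``d-3, d0, d5``).
    dialect : dict, optional
        Mapping from required column names to the names actually used
        in the file.
    behavior : DataFrame or nested dict, optional
        Per-animal freezing traces (columns ``animal, day, freezing_pct``
        or mapping animal -> {day: freezing}).
    """
    sep = None
    if isinstance(path, str) and path.endswith((".tsv", ".tab")):
        sep = "\t"
    df = pd.read_csv(path, sep=sep or ",")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in _BASE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"spine table is missing required column {col!r}")
    days = _parse_day_columns(df.columns)
    if len(days) < 2:
        raise SchemaError("spine table needs >= 2 presence columns named d{day}")
    schedule = ImagingSchedule(tuple(days))
    day_cols = [_day_column(d) for d in days]

    behav_map: dict[str, dict[int, float]] = {}
    if behavior is not None:
        if isinstance(behavior, pd.DataFrame):
            for _, row in behavior.iterrows():
                behav_map.setdefault(str(row["animal"]), {})[int(row["day"])] = float(
                    row["freezing_pct"]
                )
        else:
            behav_map = {str(a): {int(d): float(v) for d, v in t.items()}
                         for a, t in behavior.items()}

    animals: dict[str, AnimalRecord] = {}
    for animal_id, adf in df.groupby("animal", sort=True):
        animal_id = str(animal_id)
        segments = []
        for segment_id, sdf in adf.groupby("segment", sort=True):
            length = float(sdf["segment_length_um"].iloc[0])
            missing = frozenset(
                d for d, col in zip(days, day_cols) if sdf[col].isna().all()
            )
            if missing:
                logger.warning(
                    "segment %s of animal %s misses sessions %s; it will be "
                    "excluded from statistics touching those days",
                    segment_id, animal_id, sorted(missing),
                )
            spines = []
            for ridx, row in sdf.iterrows():
                pos = float(row["position_um"])
                if not (0.0 <= pos <= length):
                    raise ValidationError(
                        f"row {ridx}: position {pos} um outside [0, {length}] "
                        f"on segment {segment_id}"
                    )
                vals = row[day_cols].to_numpy(dtype=float)
                presence = np.nan_to_num(vals, nan=0.0).astype(bool)
                spines.append(Spine(str(row["spine_id"]), pos, presence))
            segments.append(
                DendriteSegment(str(segment_id), animal_id, length, spines,
                                missing_sessions=missing)
            )
        animals[animal_id] = AnimalRecord(
            animal_id=animal_id,
            group=str(adf["group"].iloc[0]),
            genotype=str(adf["genotype"].iloc[0]),
            schedule=schedule,
            segments=segments,
            behavior=behav_map.get(animal_id, {}),
        )
    return SpineMap(animals)


def write_spine_table(spine_map: SpineMap, path) -> pd.DataFrame:
    """Serialize a SpineMap to tidy CSV; returns the frame written."""
    schedule = spine_map.schedule
    rows = []
    for animal in spine_map:
        for seg in animal.segments:
            for sp in seg.spines:
                row = {
                    "animal": animal.animal_id,
                    "group": animal.group,
                    "genotype": animal.genotype,
                    "segment": seg.segment_id,
                    "segment_length_um": seg.length,
                    "spine_id": sp.spine_id,
                    "position_um": sp.position,
                }
                for d, present in zip(schedule.sessions, sp.presence):
                    row[_day_column(d)] = int(present)
                rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_behavior_table(path) -> pd.DataFrame:
    """Read a behavior CSV with columns animal, day, freezing_pct."""
    df = pd.read_csv(path)
    for col in ("animal", "day", "freezing_pct"):
        if col not in df.columns:
            raise SchemaError(f"behavior table is missing column {col!r}")
    return df


def annotate_fates(spine_map: SpineMap, t_pre: int, t0: int, t_end: int) -> SpineMap:
    """Annotate every spine with its interval fates (in place; returns map).

    ``t_pre``/``t0`` bracket the pre-learning baseline interval; ``t0`` is
    the learning start and ``t_end`` the learning end.  ``new_stable`` spines
    (absent at ``t0``, present at ``t_end``) are the substrate of all
    clustering statistics.  Idempotent and order-independent.
    """
    schedule = spine_map.schedule
    i_pre, i0, i_end = (schedule.index(d) for d in (t_pre, t0, t_end))
    if not (i_pre < i0 < i_end):
        raise ValueError(f"require t_pre < t0 < t_end within schedule, got "
                         f"{t_pre}, {t0}, {t_end}")
    for animal in spine_map:
        for seg in animal.segments:
            for sp in seg.spines:
                p = sp.presence
                formed = (not p[i0]) and bool(p[i0 + 1:i_end + 1].any())
                sp.fate = SpineFate(
                    baseline_formed=bool((not p[i_pre]) and p[i0]),
                    baseline_lost=bool(p[i_pre] and (not p[i0])),
                    baseline_stable=bool(p[i_pre] and p[i0]),
                    formed=formed,
                    lost=bool(p[i0] and (not p[i_end])),
                    new_stable=bool((not p[i0]) and p[i_end]),
                )
    return spine_map
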