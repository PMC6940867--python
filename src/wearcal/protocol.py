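"""Laboratory activity protocol for tracker-validation studies in cardiac patients.

The standard protocol is a fixed sequence of 14 low-to-moderate intensity
activities: three sedentary, three household, stair ascent/descent, cycling at
three ergometer loads and treadmill walking at three speed/incline settings.
Cycling loads and walking speeds differ between the two patient groups (CAD
with preserved ejection fraction vs. HFrEF); durations do not, so the active
protocol lasts 39 min for both groups.

Recovery gaps between activities were heart-rate driven in the laboratory and
are therefore not fixed; they are modelled as explicit per-boundary durations
(default 0) and the segment timeline is derived from durations plus gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "ActivityCategory",
    "PatientGroup",
    "Activity",
    "Segment",
    "ActivityProtocol",
    "build_standard_protocol",
    "total_duration",
]


class ActivityCategory(str, Enum):
    SEDENTARY = "sedentary"
    HOUSEHOLD = "household"
    STAIRS = "stairs"
    CYCLING = "cycling"
    WALKING = "walking"


class PatientGroup(str, Enum):
    """The two admissible patient groups.

    CAD: coronary artery disease with preserved ejection fraction.
    HFrEF: heart failure with reduced ejection fraction (lower workloads,
    slower oxygen-uptake kinetics).
    """

    CAD = "CAD"
    HFREF = "HFrEF"


def _as_group(group: "PatientGroup | str") -> PatientGroup:
    if isinstance(group, PatientGroup):
        return group
    try:
        return PatientGroup(group)
    except ValueError:
        names = ", ".join(g.value for g in PatientGroup)
        raise ValueError(f"unknown patient group {group!r}; expected one of: {names}") from None


@dataclass(frozen=True)
class Activity:
    """One protocol activity.

    ``load_w`` is set for cycling only, ``speed_kmh``/``incline_pct`` for
    walking only; other categories carry neither.
    """

    id: str
    label: str
    category: ActivityCategory
    duration_s: float
    load_w: Optional[float] = None
    speed_kmh: Optional[float] = None
    incline_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"activity {self.id!r}: duration must be > 0, got {self.duration_s}")
        cat = ActivityCategory(self.category)
        object.__setattr__(self, "category", cat)
        if cat is ActivityCategory.CYCLING:
            if self.load_w is None or self.load_w < 0:
                raise ValueError(f"cycling activity {self.id!r} requires a load_w >= 0")
        elif self.load_w is not None:
            raise ValueError(f"activity {self.id!r}: load_w only valid for cycling")
        if cat is ActivityCategory.WALKING:
            if self.speed_kmh is None or self.speed_kmh <= 0:
                raise ValueError(f"walking activity {self.id!r} requires a speed_kmh > 0")
            incline = 0.0 if self.incline_pct is None else self.incline_pct
            if incline < 0:
                raise ValueError(f"activity {self.id!r}: incline_pct must be >= 0")
            object.__setattr__(self, "incline_pct", incline)
        elif self.speed_kmh is not None or self.incline_pct is not None:
            raise ValueError(f"activity {self.id!r}: speed/incline only valid for walking")


@dataclass(frozen=True)
class Segment:
    """Half-open window [start_s, end_s) on the protocol clock."""

    activity_id: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ActivityProtocol:
    group: PatientGroup
    activities: tuple[Activity, ...]
    rest_gaps_s: tuple[float, ...] = field(default=())
    segments: tuple[Segment, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", _as_group(self.group))
        acts = tuple(self.activities)
        object.__setattr__(self, "activities", acts)
        n_bound = max(len(acts) - 1, 0)
        gaps = tuple(self.rest_gaps_s) if self.rest_gaps_s else (0.0,) * n_bound
        if len(gaps) != n_bound:
            raise ValueError(
                f"expected {n_bound} rest gaps (one per inter-activity boundary), got {len(gaps)}"
            )
        if any(g < 0 for g in gaps):
            raise ValueError("rest gaps must be non-negative")
        object.__setattr__(self, "rest_gaps_s", gaps)
        segs = []
        t = 0.0
        for i, act in enumerate(acts):
            segs.append(Segment(act.id, t, t + act.duration_s))
            t += act.duration_s
            if i < n_bound:
                t += gaps[i]
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def end_s(self) -> float:
        """End of the last activity on the protocol clock (rest included)."""
        return self.segments[-1].end_s if self.segments else 0.0

    def activity(self, activity_id: str) -> Activity:
        for act in self.activities:
            if act.id == activity_id:
                return act
        raise KeyError(f"no activity {activity_id!r} in protocol")

    def segment(self, activity_id: str) -> Segment:
        for seg in self.segments:
            if seg.activity_id == activity_id:
                return seg
        raise KeyError(f"no segment for activity {activity_id!r}")


# (id, label, category, duration_min) for the 14 standard activities;
# group-specific loads/speeds are filled in by build_standard_protocol.
_STANDARD_ROWS = [
    ("sitting", "Sitting", ActivityCategory.SEDENTARY, 5),
    ("standing", "Standing", ActivityCategory.SEDENTARY, 2),
    ("typing", "Typing", ActivityCategory.SEDENTARY, 3),
    ("table_cleaning", "Table cleaning", ActivityCategory.HOUSEHOLD, 3),
    ("dishwasher", "(Un)loading the dishwasher", ActivityCategory.HOUSEHOLD, 3),
    ("vacuuming", "Vacuuming", ActivityCategory.HOUSEHOLD, 3),
    ("stairs_up", "Ascending stairs", ActivityCategory.STAIRS, 1),
    ("stairs_down", "Descending stairs", ActivityCategory.STAIRS, 1),
    ("cycling_low", "Cycling, unloaded", ActivityCategory.CYCLING, 3),
    ("cycling_mid", "Cycling, moderate load", ActivityCategory.CYCLING, 3),
    ("cycling_high", "Cycling, higher load", ActivityCategory.CYCLING, 3),
    ("walking_slow", "Walking, base speed", ActivityCategory.WALKING, 3),
    ("walking_fast", "Walking, faster speed", ActivityCategory.WALKING, 3),
    ("walking_incline", "Walking, base speed at 5% slope", ActivityCategory.WALKING, 3),
]

# Group-specific ergometer loads (W) and treadmill speeds (km/h); the third
# walking setting reuses the base speed at a 5% grade.
_GROUP_LOADS_W = {PatientGroup.CAD: (0.0, 40.0, 70.0), PatientGroup.HFREF: (0.0, 25.0, 50.0)}
_GROUP_SPEEDS_KMH = {PatientGroup.CAD: (4.0, 5.5, 4.0), PatientGroup.HFREF: (3.0, 4.5, 3.0)}
_WALK_INCLINES_PCT = (0.0, 0.0, 5.0)


def build_standard_protocol(
    group: "PatientGroup | str",
    rest_gaps_s: Optional[Sequence[float]] = None,
) -> ActivityProtocol:
    """Build the 14-activity standard protocol for a patient group.

    Parameters
    ----------
    group
        ``"CAD"`` or ``"HFrEF"``; selects cycling loads (0/40/70 W vs
        0/25/50 W) and walking speeds (4/5.5/4@5% vs 3/4.5/3@5% km/h).
    rest_gaps_s
        Optional recovery gap per inter-activity boundary (13 entries),
        seconds; defaults to zero gaps.
    """
    grp = _as_group(group)
    loads = iter(_GROUP_LOADS_W[grp])
    speeds = iter(zip(_GROUP_SPEEDS_KMH[grp], _WALK_INCLINES_PCT))
    acts = []
    for aid, label, cat, dur_min in _STANDARD_ROWS:
        kw = {}
        if cat is ActivityCategory.CYCLING:
            kw["load_w"] = next(loads)
        elif cat is ActivityCategory.WALKING:
            speed, incline = next(speeds)
            kw["speed_kmh"] = speed
            kw["incline_pct"] = incline
        acts.append(Activity(aid, label, cat, dur_min * 60.0, **kw))
    return ActivityProtocol(group=grp, activities=tuple(acts), rest_gaps_s=tuple(rest_gaps_s or ()))


def total_duration(protocol: ActivityProtocol) -> float:
    """Total active duration in seconds (sum of activity durations, rest excluded)."""
    return float(sum(a.duration_s for a in protocol.activities))
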