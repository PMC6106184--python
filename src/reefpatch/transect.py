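"""Domain types for scored video transects and binning of annotation logs.

A drop-down camera *tow* produces a continuous video of the seabed. For
condition assessment the video is split into fixed-duration (default 5-s)
*segments*, and an analyst scores each segment: data quality, percentage
cover of *Sabellaria spinulosa* reef, and tube elevation against a laser
scale. From cover the binary *presence* variable is derived (1 iff cover
> 0), and from (cover, elevation) the ordinal reef status.

Segment intervals are half-open ``[k*d, (k+1)*d)``, 0-based and contiguous.
A trailing part-segment shorter than 1 s is dropped; otherwise it is kept.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .status import ReefStatusMatrix, StatusClass, classify_segment

__all__ = [
    "Quality",
    "SegmentRecord",
    "TransectSeries",
    "AnnotationEvent",
    "AnnotationKind",
    "BroadscaleSection",
    "derive_presence",
    "normalize_cover",
    "bin_annotations",
    "broadscale_segments",
]


class Quality(enum.Enum):
    """Data quality of one segment: usable footage or not."""

    OK = "ok"
    UNUSABLE = "unusable"

    def __str__(self) -> str:
        return self.value


def derive_presence(quality: Quality, cover_pct: float | None) -> int | None:
    """Presence value for a segment: 1 iff cover > 0, 0 iff cover = 0.

    Unusable segments have no presence value (returns ``None``). Presence is
    a pure function of quality and cover and is always re-derived, never
    trusted from storage.
    """
    if quality is Quality.UNUSABLE:
        return None
    if cover_pct is None or (isinstance(cover_pct, float) and math.isnan(cover_pct)):
        raise ValueError("quality=ok segment must have a cover estimate")
    return 1 if cover_pct > 0 else 0


@dataclass(frozen=True)
class SegmentRecord:
    """Scores for one fixed-duration video segment.

    ``presence`` and ``status`` are derived fields; use :meth:`score` to
    build a consistent record from the raw analyst measurements.
    """

    tow_id: str
    segment_index: int
    start_time_s: float
    quality: Quality
    cover_pct: float | None
    elevation_cm: float | None
    presence: int | None
    status: StatusClass
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if self.segment_index < 0:
            raise ValueError("segment_index must be non-negative")
        if self.start_time_s < 0:
            raise ValueError("start_time_s must be non-negative")
        if self.quality is Quality.UNUSABLE:
            if self.presence is not None or self.status is not StatusClass.MISSING:
                raise ValueError("unusable segment must have presence=None, status=Missing")
        else:
            if self.cover_pct is None:
                raise ValueError("usable segment must have cover_pct")
            if not 0 <= self.cover_pct <= 100:
                raise ValueError(f"cover_pct out of range: {self.cover_pct}")
            if self.presence != (1 if self.cover_pct > 0 else 0):
                raise ValueError("presence inconsistent with cover_pct")
            if self.cover_pct == 0 and self.status is not StatusClass.NO_REEF:
                raise ValueError("cover_pct=0 requires status=NoReef")
        if self.elevation_cm is not None and self.elevation_cm < 0:
            raise ValueError("elevation_cm must be non-negative")

    @classmethod
    def score(
        cls,
        tow_id: str,
        segment_index: int,
        start_time_s: float,
        quality: Quality | str = Quality.OK,
        cover_pct: float | None = None,
        elevation_cm: float | None = None,
        matrix: ReefStatusMatrix | None = None,
        lon: float | None = None,
        lat: float | None = None,
    ) -> "SegmentRecord":
        """Build a record, deriving presence and status from the scores.

        A usable segment with positive cover but no elevation estimate (no
        measurable tubes against the lasers) is scored at 0 cm, which
        classifies as Not a reef via the <2 cm band.
        """
        quality = Quality(quality)
        if quality is Quality.UNUSABLE:
            return cls(
                tow_id, segment_index, start_time_s, quality,
                cover_pct=None, elevation_cm=None, presence=None,
                status=StatusClass.MISSING, lon=lon, lat=lat,
            )
        if cover_pct is not None and cover_pct > 0 and elevation_cm is None:
            elevation_cm = 0.0
        if cover_pct is not None and cover_pct == 0:
            elevation_cm = None
        presence = derive_presence(quality, cover_pct)
        status = classify_segment(cover_pct, elevation_cm, matrix=matrix)
        return cls(
            tow_id, segment_index, start_time_s, quality,
            cover_pct=cover_pct, elevation_cm=elevation_cm,
            presence=presence, status=status, lon=lon, lat=lat,
        )


@dataclass(frozen=True)
class TransectSeries:
    """Ordered sequence of scored segments for one tow.

    ``habitats``, when present, holds one broad-scale habitat label per
    segment for use by :func:`broadscale_segments`.
    """

    tow_id: str
    segments: tuple[SegmentRecord, ...]
    study_area: str = ""
    segment_duration_s: float = 5.0
    habitats: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.segment_duration_s <= 0:
            raise ValueError("segment_duration_s must be positive")
        if not self.segments:
            raise ValueError("a transect must contain at least one segment")
        for k, seg in enumerate(self.segments):
            if seg.tow_id != self.tow_id:
                raise ValueError(f"segment {k} has tow_id {seg.tow_id!r} != {self.tow_id!r}")
            if seg.segment_index != k:
                raise ValueError("segment indices must be contiguous from 0")
        if self.habitats is not None and len(self.habitats) != len(self.segments):
            raise ValueError("habitats must have one label per segment")

    def __len__(self) -> int:
        return len(self.segments)

    def presence_values(self) -> list[int | None]:
        """Presence variable in segment order (None marks missing)."""
        return [seg.presence for seg in self.segments]

    def trim_to_first_presence(self) -> "TransectSeries":
        """Drop leading segments before the first reef observation.

        Supports survey designs where analysis starts where *S. spinulosa*
        aggregations are first observed, so that tows beginning far from the
        reef remain comparable with tows started on it.
        """
        for k, seg in enumerate(self.segments):
            if seg.presence == 1:
                break
        else:
            raise ValueError(f"tow {self.tow_id!r} contains no reef observation")
        segs = tuple(
            replace(s, segment_index=i) for i, s in enumerate(self.segments[k:])
        )
        habitats = self.habitats[k:] if self.habitats is not None else None
        return replace(self, segments=segs, habitats=habitats)


class AnnotationKind(enum.Enum):
    """Kinds of analyst annotation in a raw (pre-binning) log."""

    COVER_ESTIMATE = "cover_estimate"
    ELEVATION_ESTIMATE = "elevation_estimate"
    NEW_FIELD_OF_VIEW = "new_field_of_view"
    QUALITY_FLAG = "quality_flag"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AnnotationEvent:
    """One timestamped analyst annotation, prior to segment binning."""

    time_s: float
    kind: AnnotationKind
    value: float | str | None = None

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("annotation time must be non-negative")
        if self.kind is AnnotationKind.COVER_ESTIMATE:
            if self.value is None or not 0 <= float(self.value) <= 100:
                raise ValueError(f"cover estimate out of [0, 100]: {self.value}")
        if self.kind is AnnotationKind.ELEVATION_ESTIMATE:
            if self.value is None or float(self.value) < 0:
                raise ValueError(f"elevation estimate must be >= 0: {self.value}")


def normalize_cover(view_estimates: Sequence[float], n_new_views: int) -> float:
    """Normalize per-view cover estimates by the number of new fields of view.

    The camera's field of view drifts during a segment, so cover is estimated
    each time a new area of seabed comes into view and the total is divided
    by the number of new views. Result is clamped to [0, 100].
    """
    if n_new_views < 1:
        raise ValueError(
            "n_new_views must be >= 1; a segment with no usable view "
            "should be marked quality=unusable"
        )
    est = [float(v) for v in view_estimates]
    for v in est:
        if not 0 <= v <= 100:
            raise ValueError(f"cover estimate out of [0, 100]: {v}")
    return float(np.clip(sum(est) / n_new_views, 0.0, 100.0))


def bin_annotations(
    events: Sequence[AnnotationEvent],
    tow_duration_s: float,
    segment_duration_s: float = 5.0,
    tow_id: str = "tow",
    study_area: str = "",
    matrix: ReefStatusMatrix | None = None,
) -> TransectSeries:
    """Bin a raw annotation log into fixed-duration scored segments.

    Each event is assigned to the segment whose half-open interval
    ``[k*d, (k+1)*d)`` contains its timestamp. Within a segment, cover is
    the sum of per-view estimates divided by the number of new fields of
    view (at least 1), elevation is the mean of elevation estimates, and a
    segment with an ``unusable`` quality flag or no cover estimate at all is
    marked unusable. If the tow duration is not a whole number of segments,
    the trailing part-segment is kept when it is at least 1 s long.
    """
    if tow_duration_s <= 0:
        raise ValueError("tow_duration_s must be positive")
    if segment_duration_s <= 0:
        raise ValueError("segment_duration_s must be positive")
    times = [e.time_s for e in events]
    if any(t < 0 for t in times):
        raise ValueError("annotation times must be non-negative")
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("annotation events must be sorted by time")
    if any(t > tow_duration_s for t in times):
        raise ValueError("annotation after end of tow")

    d = segment_duration_s
    n_full, remainder = divmod(tow_duration_s, d)
    n_segments = int(n_full) + (1 if remainder >= 1.0 else 0)
    if n_segments == 0:
        raise ValueError("tow shorter than one usable segment")

    covers: list[list[float]] = [[] for _ in range(n_segments)]
    elevations: list[list[float]] = [[] for _ in range(n_segments)]
    new_views = [0] * n_segments
    unusable = [False] * n_segments
    for ev in events:
        k = int(ev.time_s // d)
        if k >= n_segments:  # inside a dropped (<1 s) tail
            continue
        if ev.kind is AnnotationKind.COVER_ESTIMATE:
            covers[k].append(float(ev.value))
        elif ev.kind is AnnotationKind.ELEVATION_ESTIMATE:
            elevations[k].append(float(ev.value))
        elif ev.kind is AnnotationKind.NEW_FIELD_OF_VIEW:
            new_views[k] += 1
        elif ev.kind is AnnotationKind.QUALITY_FLAG:
            if str(ev.value).lower() in {"unusable", "bad", "obscured"}:
                unusable[k] = True

    segments = []
    for k in range(n_segments):
        start = k * d
        if unusable[k] or not covers[k]:
            rec = SegmentRecord.score(
                tow_id, k, start, quality=Quality.UNUSABLE, matrix=matrix
            )
        else:
            cover = normalize_cover(covers[k], max(1, new_views[k]))
            elev = float(np.mean(elevations[k])) if elevations[k] else None
            rec = SegmentRecord.score(
                tow_id, k, start, quality=Quality.OK,
                cover_pct=cover, elevation_cm=elev, matrix=matrix,
            )
        segments.append(rec)
    return TransectSeries(
        tow_id=tow_id,
        segments=tuple(segments),
        study_area=study_area,
        segment_duration_s=d,
    )


@dataclass(frozen=True)
class BroadscaleSection:
    """A maximal broad-scale habitat section of a tow.

    ``start_index`` is inclusive and ``end_index`` exclusive, in segment
    units. ``incidental`` lists short habitat changes that were observed
    inside this section but, being briefer than the recording threshold,
    were not recorded as sections in their own right.
    """

    habitat: str
    start_index: int
    end_index: int
    incidental: tuple[tuple[str, int, int], ...] = ()


def broadscale_segments(
    series: TransectSeries, min_duration_s: float = 60.0
) -> list[BroadscaleSection]:
    """Broad-scale habitat sections: runs of identical habitat label.

    A habitat change is recorded as a new section only if it persists for
    at least ``min_duration_s`` (default 1 min); shorter runs are folded
    into the preceding section and noted as incidental patches. The first
    run is always kept as a section, whatever its length, since it has no
    preceding section to fold into. A segment straddling a habitat change
    carries the label of the habitat occupying the majority of it (labels
    are per-segment, so assignment is by majority time upstream).
    """
    if series.habitats is None:
        raise ValueError("series has no per-segment habitat labels")
    d = series.segment_duration_s
    labels = series.habitats

    runs: list[tuple[str, int, int]] = []  # (label, start, end)
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i

    sections: list[BroadscaleSection] = []
    for label, lo, hi in runs:
        duration = (hi - lo) * d
        if not sections:
            sections.append(BroadscaleSection(label, lo, hi))
        elif label == sections[-1].habitat:
            sections[-1] = replace(sections[-1], end_index=hi)
        elif duration < min_duration_s:
            last = sections[-1]
            sections[-1] = replace(
                last,
                end_index=hi,
                incidental=last.incidental + ((label, lo, hi),),
            )
        else:
            sections.append(BroadscaleSection(label, lo, hi))
    return sections
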