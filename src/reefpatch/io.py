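"""Readers and writers for the segment CSV schema and derived outputs.

The segment CSV is the interchange format between scoring and analysis: one
row per 5-s segment with the columns ``tow_id, segment_index, start_time_s,
quality, cover_pct, elevation_cm, presence, status, lon, lat`` (the last two
optional; empty cells mean absent). Presence and status are re-derived on
read, never trusted from the file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .patchiness import PatchinessResult, TowSummary
from .status import ReefStatusMatrix, StatusClass
from .transect import AnnotationEvent, AnnotationKind, Quality, SegmentRecord, TransectSeries

__all__ = [
    "SEGMENT_COLUMNS",
    "SUMMARY_COLUMNS",
    "read_segments_csv",
    "write_segments_csv",
    "read_annotation_log",
    "write_summary_csv",
    "summaries_to_frame",
    "write_tow_report",
    "transect_to_geojson",
    "write_geojson",
]

SEGMENT_COLUMNS = [
    "tow_id", "segment_index", "start_time_s", "quality",
    "cover_pct", "elevation_cm", "presence", "status", "lon", "lat",
]

#: Summary CSV layout: per-class percentages of the tow, patch count and
#: length statistics, and the patchiness statistic K with its p-value.
SUMMARY_COLUMNS = [
    "tow_id", "n_segments", "n_valid",
    "pct_no_reef", "pct_not_reef", "pct_low", "pct_medium", "pct_high",
    "n_patches", "mean_patch_len", "median_patch_len",
    "patch_size_min", "patch_size_max", "k", "p_value",
]


def _opt(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    value = float(value)
    return None if math.isnan(value) else value


def read_segments_csv(
    path: str | Path, matrix: ReefStatusMatrix | None = None
) -> list[TransectSeries]:
    """Read a segment CSV into one :class:`TransectSeries` per tow.

    Presence and status are re-derived from quality, cover and elevation;
    a stored status that disagrees is ignored. Tows are returned in order
    of first appearance. Schema violations raise ``ValueError`` naming the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"tow_id": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no segment rows")
    missing_cols = {"tow_id", "segment_index", "start_time_s", "quality"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")

    series_list = []
    for tow_id, group in df.groupby("tow_id", sort=False):
        group = group.sort_values("segment_index")
        segments = []
        for row in group.itertuples():
            rownum = row.Index + 1
            try:
                quality = Quality(str(row.quality).strip().lower())
                cover = _opt(getattr(row, "cover_pct", None))
                elev = _opt(getattr(row, "elevation_cm", None))
                rec = SegmentRecord.score(
                    tow_id=str(tow_id),
                    segment_index=int(row.segment_index),
                    start_time_s=float(row.start_time_s),
                    quality=quality,
                    cover_pct=cover,
                    elevation_cm=elev,
                    matrix=matrix,
                    lon=_opt(getattr(row, "lon", None)),
                    lat=_opt(getattr(row, "lat", None)),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {rownum}: {exc}") from exc
            segments.append(rec)
        try:
            series_list.append(TransectSeries(tow_id=str(tow_id), segments=tuple(segments)))
        except ValueError as exc:
            raise ValueError(f"{path}: tow {tow_id}: {exc}") from exc
    return series_list


def _series_frame(series_list: Iterable[TransectSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for seg in series.segments:
            rows.append(
                {
                    "tow_id": seg.tow_id,
                    "segment_index": seg.segment_index,
                    "start_time_s": seg.start_time_s,
                    "quality": str(seg.quality),
                    "cover_pct": seg.cover_pct,
                    "elevation_cm": seg.elevation_cm,
                    "presence": seg.presence,
                    "status": str(seg.status),
                    "lon": seg.lon,
                    "lat": seg.lat,
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments_csv(
    series_list: "TransectSeries | Iterable[TransectSeries]", path: str | Path
) -> None:
    """Write one or more transects to the segment CSV schema (UTF-8)."""
    if isinstance(series_list, TransectSeries):
        series_list = [series_list]
    df = _series_frame(series_list)
    # Int64 keeps presence an integer column despite missing entries
    df["presence"] = df["presence"].astype("Int64")
    df.to_csv(path, index=False)


def read_annotation_log(path: str | Path) -> list[AnnotationEvent]:
    """Read a raw annotation log CSV with columns time_s, kind, value."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no annotation rows")
    required = {"time_s", "kind", "value"} - set(df.columns)
    if required:
        raise ValueError(f"{path}: missing required columns {sorted(required)}")
    events = []
    for row in df.itertuples():
        try:
            kind = AnnotationKind(str(row.kind).strip().lower())
            value = row.value
            if kind in (AnnotationKind.COVER_ESTIMATE, AnnotationKind.ELEVATION_ESTIMATE):
                value = float(value)
            events.append(AnnotationEvent(float(row.time_s), kind, value))
        except ValueError as exc:
            raise ValueError(f"{path}: row {row.Index + 1}: {exc}") from exc
    return events


def summaries_to_frame(
    summaries: Sequence[TowSummary], order: str = "max_patch"
) -> pd.DataFrame:
    """Tow summaries as a DataFrame in the summary CSV layout.

    ``order='max_patch'`` sorts by descending maximum patch size (tows with
    the largest reef patches first); ``order='tow_id'`` sorts
    lexicographically; ``order='input'`` preserves the given order.
    """
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries], columns=SUMMARY_COLUMNS)
    if order == "max_patch":
        df = df.sort_values(
            ["patch_size_max", "tow_id"], ascending=[False, True], na_position="last"
        )
    elif order == "tow_id":
        df = df.sort_values("tow_id")
    elif order != "input":
        raise ValueError(f"unknown ordering {order!r}")
    return df.reset_index(drop=True)


def write_summary_csv(
    summaries: Sequence[TowSummary], path: str | Path, order: str = "max_patch"
) -> None:
    """Write the per-tow summary table (one row per tow) as CSV."""
    summaries_to_frame(summaries, order=order).to_csv(path, index=False)


def write_tow_report(
    summary: TowSummary,
    result: PatchinessResult | None,
    path: str | Path,
    patch_sizes: Sequence[int] = (),
) -> None:
    """Machine-readable JSON report for one tow."""
    payload = {
        "summary": dataclasses.asdict(summary),
        "patch_sizes": [int(s) for s in patch_sizes],
        "patchiness": dataclasses.asdict(result) if result is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def transect_to_geojson(series: TransectSeries) -> dict:
    """GeoJSON FeatureCollection for one tow with per-segment positions.

    One LineString traces the tow through the segment positions; one Point
    per positioned segment carries its status properties. Segments without
    coordinates are omitted from the geometry.
    """
    points = []
    coords = []
    for seg in series.segments:
        if seg.lon is None or seg.lat is None:
            continue
        coords.append([seg.lon, seg.lat])
        points.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [seg.lon, seg.lat]},
                "properties": {
                    "tow_id": seg.tow_id,
                    "segment_index": seg.segment_index,
                    "status": str(seg.status),
                    "cover_pct": seg.cover_pct,
                    "elevation_cm": seg.elevation_cm,
                    "presence": seg.presence,
                },
            }
        )
    if not coords:
        raise ValueError(f"tow {series.tow_id!r} has no positioned segments")
    line = {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {"tow_id": series.tow_id, "study_area": series.study_area},
    }
    return {"type": "FeatureCollection", "features": [line, *points]}


def write_geojson(series: TransectSeries, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(transect_to_geojson(series), fh)
        fh.write("\n")
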