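"""Reef structure matrix: percentage cover x tube elevation -> ordinal reef status.

The matrix assigns each scored video segment an ordinal condition class
(Not a reef < Low < Medium < High) from two analyst measurements: the
percentage of the viewed seabed covered by *Sabellaria spinulosa* reef and
the elevation of the tube structures above the surrounding seabed (cm).
Zero cover is a separate "No reef" class, and segments that could not be
scored (obscured seabed) are "Missing". The default matrix is a transcription
of the published reef structure matrix (a modification of Gubbay's cover and
elevation categories); alternative matrices can be loaded from a YAML config.

Band conventions
----------------
The published band labels ("<10, 10-20, 20-30, >30" percent cover;
"<2, 2-5, 5-10, >10" cm elevation) do not state which band owns a shared
edge. This module uses left-closed, right-open intervals, so cover 10 falls
in the 10-20% band and elevation 5 in the 5-10 cm band. The top bands are
closed above at 100% cover and unbounded for elevation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "StatusClass",
    "ReefStatusMatrix",
    "default_matrix",
    "cover_band",
    "elevation_band",
    "classify_segment",
]


class StatusClass(enum.Enum):
    """Ordinal reef-status class for one 5-s video segment.

    The five non-missing classes are totally ordered
    NoReef < NotAReef < Low < Medium < High. ``NO_REEF`` is reserved for
    segments with exactly zero cover; ``MISSING`` marks unusable segments
    and is excluded from the ordering (its :attr:`rank` raises).
    """

    NO_REEF = "NoReef"
    NOT_A_REEF = "NotAReef"
    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"
    MISSING = "Missing"

    @property
    def rank(self) -> int:
        """Position in the ordinal scale (0 = NoReef ... 4 = High)."""
        if self is StatusClass.MISSING:
            raise ValueError("Missing status has no ordinal rank")
        return _RANKS[self]

    def __str__(self) -> str:  # CSV cell representation
        return self.value


_RANKS = {
    StatusClass.NO_REEF: 0,
    StatusClass.NOT_A_REEF: 1,
    StatusClass.LOW: 2,
    StatusClass.MEDIUM: 3,
    StatusClass.HIGH: 4,
}

#: Status classes a matrix cell may contain (NoReef is the cover=0 override).
_CELL_CLASSES = frozenset(
    {StatusClass.NOT_A_REEF, StatusClass.LOW, StatusClass.MEDIUM, StatusClass.HIGH}
)


@dataclass(frozen=True)
class ReefStatusMatrix:
    """A cover-band x elevation-band lookup of status classes.

    Parameters
    ----------
    cover_edges
        Five increasing numbers partitioning [0, 100] into four left-closed
        cover bands, e.g. ``(0, 10, 20, 30, 100)``.
    elevation_edges
        Five increasing numbers partitioning [0, inf) into four left-closed
        elevation bands, e.g. ``(0, 2, 5, 10, inf)``.
    cells
        4x4 tuple of :class:`StatusClass`; ``cells[i][j]`` is the class for
        cover band ``i`` and elevation band ``j``.
    """

    cover_edges: tuple[float, ...]
    elevation_edges: tuple[float, ...]
    cells: tuple[tuple[StatusClass, ...], ...]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        cov = self.cover_edges
        ele = self.elevation_edges
        if len(cov) != 5 or len(ele) != 5:
            raise ValueError("band edges must have 5 entries (4 bands)")
        if list(cov) != sorted(cov) or len(set(cov)) != 5:
            raise ValueError("cover edges must be strictly increasing")
        if list(ele) != sorted(ele) or len(set(ele)) != 5:
            raise ValueError("elevation edges must be strictly increasing")
        if cov[0] != 0 or cov[-1] != 100:
            raise ValueError("cover bands must partition [0, 100]")
        if ele[0] != 0 or not np.isinf(ele[-1]):
            raise ValueError("elevation bands must partition [0, inf)")
        if len(self.cells) != 4 or any(len(row) != 4 for row in self.cells):
            raise ValueError("cells must be a 4x4 table")
        for row in self.cells:
            for cell in row:
                if cell not in _CELL_CLASSES:
                    raise ValueError(f"invalid matrix cell: {cell}")
        # Ordinal monotonicity along both axes: more cover or taller tubes
        # never lowers the class.
        ranks = np.array([[c.rank for c in row] for row in self.cells])
        if (np.diff(ranks, axis=0) < 0).any() or (np.diff(ranks, axis=1) < 0).any():
            raise ValueError("matrix cells must be monotone non-decreasing")

    def cover_band(self, cover_pct: float) -> int:
        """Index (0..3) of the cover band containing ``cover_pct``."""
        return _band_index(cover_pct, self.cover_edges, upper_closed=True, name="cover_pct")

    def elevation_band(self, elevation_cm: float) -> int:
        """Index (0..3) of the elevation band containing ``elevation_cm``."""
        return _band_index(
            elevation_cm, self.elevation_edges, upper_closed=False, name="elevation_cm"
        )

    def classify(self, cover_pct: float | None, elevation_cm: float | None) -> StatusClass:
        """Status class for one segment; see :func:`classify_segment`."""
        if cover_pct is None or (isinstance(cover_pct, float) and np.isnan(cover_pct)):
            return StatusClass.MISSING
        if not 0 <= cover_pct <= 100:
            raise ValueError(f"cover_pct out of range [0, 100]: {cover_pct}")
        if cover_pct == 0:
            return StatusClass.NO_REEF
        if elevation_cm is None or (isinstance(elevation_cm, float) and np.isnan(elevation_cm)):
            return StatusClass.MISSING
        i = self.cover_band(cover_pct)
        j = self.elevation_band(elevation_cm)
        return self.cells[i][j]

    # ---- config I/O -------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "ReefStatusMatrix":
        cells = tuple(
            tuple(StatusClass(c) for c in row) for row in cfg["cells"]
        )
        ele = [float(x) for x in cfg["elevation_band_edges"]]
        return cls(
            cover_edges=tuple(float(x) for x in cfg["cover_band_edges"]),
            elevation_edges=tuple(ele),
            cells=cells,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReefStatusMatrix":
        """Load and validate a matrix config from a YAML file."""
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        return {
            "cover_band_edges": list(self.cover_edges),
            "elevation_band_edges": list(self.elevation_edges),
            "cells": [[c.value for c in row] for row in self.cells],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _band_index(
    value: float, edges: Sequence[float], upper_closed: bool, name: str
) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"{name} is missing")
    if value < edges[0]:
        raise ValueError(f"{name} out of range: {value}")
    if np.isfinite(edges[-1]):
        if value > edges[-1]:
            raise ValueError(f"{name} out of range: {value}")
        if value == edges[-1] and upper_closed:
            return len(edges) - 2
    # left-closed bands: [e0,e1), [e1,e2), ...
    idx = int(np.searchsorted(np.asarray(edges[1:-1]), value, side="right"))
    return idx


_DEFAULT_MATRIX: ReefStatusMatrix | None = None


def default_matrix() -> ReefStatusMatrix:
    """The packaged reef structure matrix (loaded once from its YAML config)."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        ref = resources.files("reefpatch").joinpath("data/reef_matrix.yaml")
        cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_MATRIX = ReefStatusMatrix.from_dict(cfg)
    return _DEFAULT_MATRIX


def cover_band(cover_pct: float, matrix: ReefStatusMatrix | None = None) -> int:
    """Cover band index 0..3 for the bands <10, 10-20, 20-30, >30 percent.

    Bands are left-closed ([0,10), [10,20), [20,30), [30,100]), so 10 falls
    in band 1 and 100 in band 3.
    """
    return (matrix or default_matrix()).cover_band(cover_pct)


def elevation_band(elevation_cm: float, matrix: ReefStatusMatrix | None = None) -> int:
    """Elevation band index 0..3 for the bands <2, 2-5, 5-10, >10 cm."""
    return (matrix or default_matrix()).elevation_band(elevation_cm)


def classify_segment(
    cover_pct: float | None,
    elevation_cm: float | None,
    matrix: ReefStatusMatrix | None = None,
) -> StatusClass:
    """Reef status for one segment from its cover and elevation scores.

    Rules, in order: missing cover -> ``MISSING`` (never silently NoReef);
    cover 0 -> ``NO_REEF``; missing elevation with positive cover ->
    ``MISSING``; otherwise the matrix cell at (cover band, elevation band).
    Any cell in the <10% cover band or the <2 cm elevation band is
    ``NOT_A_REEF``: sparse or flat tube growth does not constitute reef.

    Examples
    --------
    >>> classify_segment(50, 12)
    <StatusClass.HIGH: 'High'>
    >>> classify_segment(25, 3)
    <StatusClass.LOW: 'Low'>
    >>> classify_segment(5, 12)
    <StatusClass.NOT_A_REEF: 'NotAReef'>
    >>> classify_segment(0, None)
    <StatusClass.NO_REEF: 'NoReef'>
    """
    return (matrix or default_matrix()).classify(cover_pct, elevation_cm)
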