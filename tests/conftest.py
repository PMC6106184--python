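import numpy as np
import pytest

from reefpatch import Quality, SegmentRecord, TransectSeries


def build_series(
    covers, elevations=None, tow_id="T1", quality=None, segment_duration_s=5.0,
    habitats=None,
):
    """Build a scored TransectSeries from parallel per-segment score lists.

    ``covers[i] is None`` marks an unusable segment; ``elevations`` defaults
    to no measurable tubes.
    """
    n = len(covers)
    elevations = elevations if elevations is not None else [None] * n
    quality = quality if quality is not None else [
        Quality.UNUSABLE if c is None else Quality.OK for c in covers
    ]
    segments = tuple(
        SegmentRecord.score(
            tow_id, i, i * segment_duration_s,
            quality=quality[i],
            cover_pct=covers[i],
            elevation_cm=elevations[i],
        )
        for i in range(n)
    )
    return TransectSeries(
        tow_id=tow_id, segments=segments,
        segment_duration_s=segment_duration_s, habitats=habitats,
    )


@pytest.fixture
def block_series():
    """A tow that is one solid block of Low reef after a reef-free stretch."""
    covers = [0.0] * 6 + [15.0] * 4
    elevations = [None] * 6 + [3.0] * 4
    return build_series(covers, elevations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
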