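"""Shared builders and fixtures for toy spine maps."""

from __future__ import annotations

import numpy as np
import pytest

from spinedyn.data import (AnimalRecord, DendriteSegment, ImagingSchedule,
                           Spine, SpineMap, annotate_fates)

SCHEDULE_3 = (-3, 0, 5)
SCHEDULE_5 = (-3, 0, 2, 5, 35)


def spine(sid: str, pos: float, presence) -> Spine:
    return Spine(sid, pos, np.array(presence, dtype=bool))


def make_map(segments_spec, schedule=SCHEDULE_3, group="trained",
             annotate=True) -> SpineMap:
    """Build a one-or-more-animal map from {animal: [(length, [spines])]}.

    ``segments_spec`` maps animal id to a list of (length, spines) tuples.
    """
    sched = ImagingSchedule(schedule)
    animals = {}
    for aid, segs in segments_spec.items():
        seg_objs = [
            DendriteSegment(f"{aid}_s{i}", aid, length, list(spines))
            for i, (length, spines) in enumerate(segs)
        ]
        animals[aid] = AnimalRecord(aid, group, "WT", sched, seg_objs)
    m = SpineMap(animals)
    if annotate:
        annotate_fates(m, schedule[0], schedule[1], schedule[-2] if
                       len(schedule) > 3 else schedule[-1])
    return m


@pytest.fixture(scope="session")
def synthetic_map():
    """Default-condition synthetic map with fates annotated."""
    import spinedyn as sd
    m, truth = sd.generate_map(seed=42)
    sd.annotate_fates(m, -3, 0, 5)
    return m, truth
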