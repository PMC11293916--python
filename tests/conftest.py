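"""Shared fixtures: test-side landmark constructors, independent of the
package's own synthetic generator."""

import math

import numpy as np
import pytest

from oscillocobb import LandmarkSet, Point2D, Units, VertebraCorners, View
from oscillocobb.landmark_model import VERTEBRA_LABELS


def set_from_tilts(
    tilts,
    view: View = View.CORONAL,
    width: float = 90.0,
    height: float = 65.0,
    disc: float = 22.0,
    x0: float = 800.0,
    case_id: str = "test",
) -> LandmarkSet:
    """Build a landmark set whose 34 endplate tilts are exactly ``tilts``.

    Vertebra centroids stack vertically (no lateral drift); each endplate is a
    segment of the given width rotated about the endplate midpoint.  Written
    independently of the package's spine simulator so it can serve as an
    oracle for tilt recovery.
    """
    tilts = np.asarray(tilts, dtype=float)
    assert tilts.shape == (34,)
    verts = []
    y = 100.0
    for v in range(17):
        cy = y + height / 2.0
        rows = {}
        for key_l, key_r, t, my in (
            ("ul", "ur", math.radians(tilts[2 * v]), cy - height / 2.0),
            ("ll", "lr", math.radians(tilts[2 * v + 1]), cy + height / 2.0),
        ):
            dx, dy = (width / 2.0) * math.cos(t), (width / 2.0) * math.sin(t)
            rows[key_l] = Point2D(x0 - dx, my - dy)
            rows[key_r] = Point2D(x0 + dx, my + dy)
        verts.append(VertebraCorners(VERTEBRA_LABELS[v], rows["ul"], rows["ur"], rows["ll"], rows["lr"]))
        y += height + disc
    return LandmarkSet(view=view, units=Units.PX, vertebrae=tuple(verts), case_id=case_id)


@pytest.fixture
def straight_set() -> LandmarkSet:
    """Axis-aligned rectangles: every endplate horizontal."""
    return set_from_tilts(np.zeros(34))


@pytest.fixture
def tilts_builder():
    return set_from_tilts
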