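"""Domain model for vertebral corner-point annotations.

A single radiographic view of the spine is annotated with the four corner
points of each vertebral body from T1 to L5 (17 vertebrae, 68 points).  This
module defines the validated in-memory types for such annotations, JSON/CSV
readers and writers, and case-level validation across the up-to-four views
(coronal standing, sagittal, left and right side-bending) used in scoliosis
work-up.

Coordinate convention: raster image coordinates — origin top-left, x grows
rightward, y grows *downward*.  "Left"/"right" in corner names means image
left/right; whether image-left is the patient's left or right depends on the
projection (AP vs PA) and is deliberately not asserted anywhere.  For sagittal
views the same corner keys are read as anterior/posterior.  Units may be
pixels or millimetres; all downstream angle computations are unit-invariant.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

THORACIC_LABELS = tuple(f"T{i}" for i in range(1, 13))
LUMBAR_LABELS = tuple(f"L{i}" for i in range(1, 6))
#: Vertebra labels in anatomical (cranial -> caudal) order.
VERTEBRA_LABELS: tuple[str, ...] = THORACIC_LABELS + LUMBAR_LABELS
VERTEBRA_INDEX = {label: i for i, label in enumerate(VERTEBRA_LABELS)}

N_VERTEBRAE = 17
N_CORNERS = 68
CORNER_KEYS = ("ul", "ur", "ll", "lr")


class View(str, Enum):
    """Radiographic view of a landmark set."""

    CORONAL = "coronal"
    SAGITTAL = "sagittal"
    LEFT_BENDING = "left_bending"
    RIGHT_BENDING = "right_bending"


class Units(str, Enum):
    PX = "px"
    MM = "mm"


class LandmarkError(ValueError):
    """Invalid landmark data (schema or geometric invariant violation)."""


@dataclass(frozen=True)
class Point2D:
    """A 2-D point in image coordinates (y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        # coerce numpy scalars etc. to plain floats so repr/serialization
        # round-trips exactly
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise LandmarkError(f"non-finite point coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class VertebraCorners:
    """Four corner points of one vertebral body.

    ``ul``/``ur`` are the superior (upper) endplate endpoints, ``ll``/``lr``
    the inferior ones; ``l``/``r`` refer to image left/right (anterior /
    posterior on sagittal views).
    """

    label: str
    ul: Point2D
    ur: Point2D
    ll: Point2D
    lr: Point2D

    def violations(self) -> list[str]:
        """Rule ids violated by this vertebra's geometry (empty if valid)."""
        out: list[str] = []
        if self.label not in VERTEBRA_INDEX:
            out.append("unknown-label")
            return out
        if not (self.ul.x < self.ur.x):
            out.append("corner-order-superior")
        if not (self.ll.x < self.lr.x):
            out.append("corner-order-inferior")
        if not ((self.ul.y + self.ur.y) / 2.0 < (self.ll.y + self.lr.y) / 2.0):
            out.append("superior-below-inferior")
        return out

    @property
    def centroid(self) -> Point2D:
        return Point2D(
            (self.ul.x + self.ur.x + self.ll.x + self.lr.x) / 4.0,
            (self.ul.y + self.ur.y + self.ll.y + self.lr.y) / 4.0,
        )

    def corners(self) -> Iterator[tuple[str, Point2D]]:
        for key in CORNER_KEYS:
            yield key, getattr(self, key)


@dataclass(frozen=True)
class Violation:
    """A single validation finding: where it is and which rule it breaks."""

    view: str
    vertebra: str
    rule: str
    message: str


@dataclass(frozen=True)
class LandmarkSet:
    """One view's complete annotation: 17 vertebrae, T1 first, L5 last."""

    view: View
    units: Units
    vertebrae: tuple[VertebraCorners, ...]
    case_id: str = ""

    def violations(self) -> list[Violation]:
        out: list[Violation] = []
        labels = [v.label for v in self.vertebrae]
        if len(self.vertebrae) != N_VERTEBRAE:
            out.append(
                Violation(
                    self.view.value,
                    "*",
                    "vertebra-count",
                    f"expected {N_VERTEBRAE} vertebrae, found {len(self.vertebrae)}",
                )
            )
        seen = set()
        for lab in labels:
            if lab in seen:
                out.append(
                    Violation(self.view.value, lab, "duplicate-vertebra", f"duplicate vertebra {lab}")
                )
            seen.add(lab)
        missing = [lab for lab in VERTEBRA_LABELS if lab not in seen]
        for lab in missing:
            out.append(
                Violation(self.view.value, lab, "missing-vertebra", f"missing vertebra {lab}")
            )
        in_order = [lab for lab in labels if lab in VERTEBRA_INDEX]
        if in_order != sorted(in_order, key=VERTEBRA_INDEX.__getitem__):
            out.append(
                Violation(self.view.value, "*", "vertebra-order", "vertebrae not in T1..L5 order")
            )
        for vert in self.vertebrae:
            for rule in vert.violations():
                out.append(
                    Violation(
                        self.view.value,
                        vert.label,
                        rule,
                        f"{vert.label}: {rule}",
                    )
                )
        return out

    def validate(self) -> "LandmarkSet":
        """Return self if valid, else raise :class:`LandmarkError`."""
        bad = self.violations()
        if bad:
            raise LandmarkError("; ".join(v.message for v in bad))
        return self

    def vertebra(self, label: str) -> VertebraCorners:
        return self.vertebrae[VERTEBRA_INDEX[label]]

    def points(self) -> Iterator[Point2D]:
        for vert in self.vertebrae:
            for _, pt in vert.corners():
                yield pt

    def mirrored(self, axis_x: float | None = None) -> "LandmarkSet":
        """Reflect all landmarks about a vertical axis (default: mean x).

        Corner roles are swapped (ul<->ur, ll<->lr) so the image-left corner
        stays image-left, preserving the corner-order invariant.
        """
        if axis_x is None:
            xs = [pt.x for pt in self.points()]
            axis_x = sum(xs) / len(xs)

        def refl(p: Point2D) -> Point2D:
            return Point2D(2.0 * axis_x - p.x, p.y)

        verts = tuple(
            VertebraCorners(v.label, refl(v.ur), refl(v.ul), refl(v.lr), refl(v.ll))
            for v in self.vertebrae
        )
        return replace(self, vertebrae=verts)


@dataclass
class CaseViews:
    """All available views for one patient case (coronal is mandatory)."""

    case_id: str
    coronal: LandmarkSet
    sagittal: LandmarkSet | None = None
    left_bending: LandmarkSet | None = None
    right_bending: LandmarkSet | None = None

    def present_views(self) -> dict[View, LandmarkSet]:
        out: dict[View, LandmarkSet] = {View.CORONAL: self.coronal}
        if self.sagittal is not None:
            out[View.SAGITTAL] = self.sagittal
        if self.left_bending is not None:
            out[View.LEFT_BENDING] = self.left_bending
        if self.right_bending is not None:
            out[View.RIGHT_BENDING] = self.right_bending
        return out


def validate_case(case: CaseViews) -> list[Violation]:
    """Validate every present view of a case.

    Returns violation records rather than raising: an empty list means the
    case satisfies all invariants.  Slot/tag mismatches (e.g. a set tagged
    ``sagittal`` sitting in the coronal slot) are reported per slot.
    """
    out: list[Violation] = []
    slots = {
        View.CORONAL: case.coronal,
        View.SAGITTAL: case.sagittal,
        View.LEFT_BENDING: case.left_bending,
        View.RIGHT_BENDING: case.right_bending,
    }
    for slot, lset in slots.items():
        if lset is None:
            continue
        if lset.view is not slot:
            out.append(
                Violation(
                    slot.value,
                    "*",
                    "slot-mismatch",
                    f"set tagged '{lset.view.value}' found in the {slot.value} slot",
                )
            )
        out.extend(lset.violations())
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _point_from(obj, where: str) -> Point2D:
    try:
        x, y = float(obj[0]), float(obj[1])
    except (TypeError, ValueError, IndexError, KeyError) as exc:
        raise LandmarkError(f"malformed corner at {where}: {obj!r}") from exc
    return Point2D(x, y)


def _normalize(vertebrae: dict[str, VertebraCorners], view: View, units: Units, case_id: str) -> LandmarkSet:
    missing = [lab for lab in VERTEBRA_LABELS if lab not in vertebrae]
    if missing:
        raise LandmarkError("missing vertebra " + ", ".join(missing))
    extra = [lab for lab in vertebrae if lab not in VERTEBRA_INDEX]
    if extra:
        raise LandmarkError("unknown vertebra label " + ", ".join(extra))
    ordered = tuple(vertebrae[lab] for lab in VERTEBRA_LABELS)
    return LandmarkSet(view=view, units=units, vertebrae=ordered, case_id=case_id).validate()


def parse_landmarks(content: str, format: str = "json") -> LandmarkSet:
    """Parse one view's annotation from its JSON or CSV text form.

    Vertebra order in the input is irrelevant; the returned set is always
    T1 -> L5.  Errors name the offending vertebra and field.
    """
    if format == "json":
        try:
            doc = json.loads(content)
        except json.JSONDecodeError as exc:
            raise LandmarkError(f"invalid JSON: {exc}") from exc
        try:
            view = View(doc["view"])
        except (KeyError, ValueError) as exc:
            raise LandmarkError(f"unknown or missing view tag: {doc.get('view')!r}") from exc
        units = Units(doc.get("units", "px"))
        case_id = str(doc.get("case_id", ""))
        raw = doc.get("vertebrae")
        if not isinstance(raw, dict):
            raise LandmarkError("missing 'vertebrae' mapping")
        verts: dict[str, VertebraCorners] = {}
        for lab, corners in raw.items():
            if lab in verts:
                raise LandmarkError(f"duplicate vertebra {lab}")
            pts = {}
            for key in CORNER_KEYS:
                if key not in corners:
                    raise LandmarkError(f"vertebra {lab}: missing corner '{key}'")
                pts[key] = _point_from(corners[key], f"{lab}.{key}")
            verts[lab] = VertebraCorners(lab, pts["ul"], pts["ur"], pts["ll"], pts["lr"])
        return _normalize(verts, view, units, case_id)

    if format == "csv":
        reader = csv.DictReader(io.StringIO(content))
        required = {"case_id", "view", "vertebra", "corner", "x", "y"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LandmarkError(
                f"CSV header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        rows = list(reader)
        if not rows:
            raise LandmarkError("empty CSV")
        views = {r["view"] for r in rows}
        if len(views) != 1:
            raise LandmarkError(f"CSV mixes views: {sorted(views)}")
        try:
            view = View(rows[0]["view"])
        except ValueError as exc:
            raise LandmarkError(f"unknown view tag: {rows[0]['view']!r}") from exc
        case_ids = {r["case_id"] for r in rows}
        if len(case_ids) != 1:
            raise LandmarkError(f"CSV mixes case_ids: {sorted(case_ids)}")
        units = Units(rows[0]["units"]) if "units" in (reader.fieldnames or []) and rows[0].get("units") else Units.PX
        per_vert: dict[str, dict[str, Point2D]] = {}
        for r in rows:
            lab, key = r["vertebra"], r["corner"]
            if key not in CORNER_KEYS:
                raise LandmarkError(f"vertebra {lab}: unknown corner '{key}'")
            slot = per_vert.setdefault(lab, {})
            if key in slot:
                raise LandmarkError(f"vertebra {lab}: duplicate corner '{key}'")
            slot[key] = _point_from((r["x"], r["y"]), f"{lab}.{key}")
        verts = {}
        for lab, pts in per_vert.items():
            for key in CORNER_KEYS:
                if key not in pts:
                    raise LandmarkError(f"vertebra {lab}: missing corner '{key}'")
            verts[lab] = VertebraCorners(lab, pts["ul"], pts["ur"], pts["ll"], pts["lr"])
        return _normalize(verts, view, units, rows[0]["case_id"])

    raise ValueError(f"unsupported format {format!r} (expected 'json' or 'csv')")


def write_landmarks(lset: LandmarkSet, format: str = "json") -> str:
    """Serialize a landmark set; ``parse_landmarks`` round-trips it exactly.

    Note the CSV schema carries no units column, so a millimetre-unit set
    only round-trips through JSON.
    """
    lset.validate()
    if format == "json":
        doc = {
            "case_id": lset.case_id,
            "view": lset.view.value,
            "units": lset.units.value,
            "vertebrae": {
                v.label: {key: [pt.x, pt.y] for key, pt in v.corners()}
                for v in lset.vertebrae
            },
        }
        return json.dumps(doc, indent=1)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["case_id", "view", "vertebra", "corner", "x", "y"])
        for v in lset.vertebrae:
            for key, pt in v.corners():
                writer.writerow([lset.case_id, lset.view.value, v.label, key, repr(pt.x), repr(pt.y)])
        return buf.getvalue()
    raise ValueError(f"unsupported format {format!r} (expected 'json' or 'csv')")
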