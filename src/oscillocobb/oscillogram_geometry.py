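"""Endplate-tilt oscillograms and Cobb angle derivation.

The oscillogram of a spine view is the ordered sequence of the 34 endplate
tilt angles from the superior endplate of T1 to the inferior endplate of L5.
A scoliotic curve shows up as a peak-trough pair: its end (terminal)
vertebrae own the maximally opposed endplates, and the vertical distance
between the peak and the trough is the curve's Cobb angle.  This module
builds the oscillogram from corner landmarks, finds its alternating peaks and
troughs, derives per-region (proximal thoracic / main thoracic /
thoracolumbar-lumbar) Cobb angles with end-vertebra identification, measures
T5-T12 kyphosis on the sagittal view, and assembles the full per-case
measurement record.

Sign convention (y-down image coordinates): a positive tilt slopes downward
toward image-right.  All angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .config import RunConfig
from .landmark_model import (
    N_VERTEBRAE,
    VERTEBRA_INDEX,
    VERTEBRA_LABELS,
    CaseViews,
    LandmarkSet,
    Point2D,
    View,
)

N_ENDPLATES = 34
SUPERIOR = "superior"
INFERIOR = "inferior"


class DegenerateGeometryError(ValueError):
    """A vertical endplate (zero horizontal extent) — an annotation mistake."""


class Region(str, Enum):
    """Lenke curve regions."""

    PT = "PT"    # proximal thoracic
    MT = "MT"    # main thoracic
    TLL = "TLL"  # thoracolumbar / lumbar


#: Inclusive endplate-index spans searched per region.  Adjacent curves share
#: end vertebrae, so the spans deliberately overlap:
#: PT: T1-sup..T6-inf, MT: T5-sup..T12-inf, TL/L: T10-sup..L4-inf.
REGION_SPANS: dict[Region, tuple[int, int]] = {
    Region.PT: (0, 11),
    Region.MT: (8, 23),
    Region.TLL: (18, 31),
}

#: Vertebra-index windows used to assign a detected curve to a region by its
#: apex: T1..T5 -> PT, T6..T11 -> MT, T12..L5 -> TL/L.
_APEX_WINDOWS = (
    (Region.PT, 0, 4),
    (Region.MT, 5, 10),
    (Region.TLL, 11, 16),
)


def endplate_index(label: str, surface: str) -> int:
    """Oscillogram index of a vertebra's endplate (0 = T1 superior)."""
    v = VERTEBRA_INDEX[label]
    if surface == SUPERIOR:
        return 2 * v
    if surface == INFERIOR:
        return 2 * v + 1
    raise ValueError(f"surface must be 'superior' or 'inferior', got {surface!r}")


def endplate_label(index: int) -> tuple[str, str]:
    """Inverse of :func:`endplate_index`."""
    if not 0 <= index < N_ENDPLATES:
        raise ValueError(f"endplate index out of range: {index}")
    return VERTEBRA_LABELS[index // 2], SUPERIOR if index % 2 == 0 else INFERIOR


_T5_SUP = endplate_index("T5", SUPERIOR)    # 8
_T12_INF = endplate_index("T12", INFERIOR)  # 23


@dataclass(frozen=True)
class TiltSeries:
    """The oscillogram: 34 endplate tilts, cranial -> caudal, in degrees."""

    view: View
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (N_ENDPLATES,):
            raise ValueError(f"oscillogram must have {N_ENDPLATES} entries, got {vals.shape}")
        if not np.all(np.isfinite(vals)) or np.any(np.abs(vals) >= 90.0):
            raise ValueError("tilt values must be finite and within (-90, 90) degrees")

    def smoothed(self, window: int) -> "TiltSeries":
        """Centered moving average with edge truncation (window odd, >= 1)."""
        if window <= 1:
            return self
        half = window // 2
        out = np.empty_like(self.values)
        for i in range(N_ENDPLATES):
            lo, hi = max(0, i - half), min(N_ENDPLATES, i + half + 1)
            out[i] = self.values[lo:hi].mean()
        return TiltSeries(self.view, out)


@dataclass(frozen=True)
class Extremum:
    index: int
    value: float
    polarity: str          # "peak" | "trough"
    prominence: float


@dataclass(frozen=True)
class Curve:
    """One detected scoliotic curve with its end endplates and Cobb angle."""

    region: Region
    upper_end: tuple[str, str]   # (vertebra label, surface)
    lower_end: tuple[str, str]
    apex: str
    cobb: float
    convexity: str               # "image_left" | "image_right" | "none"
    from_extrema: bool = True    # False: region-span max-min fallback

    @property
    def upper_index(self) -> int:
        return endplate_index(*self.upper_end)

    @property
    def lower_index(self) -> int:
        return endplate_index(*self.lower_end)

    def to_dict(self) -> dict:
        return {
            "region": self.region.value,
            "upper_end": list(self.upper_end),
            "lower_end": list(self.lower_end),
            "apex": self.apex,
            "cobb": self.cobb,
            "convexity": self.convexity,
            "from_extrema": self.from_extrema,
        }

    @staticmethod
    def from_dict(d: dict) -> "Curve":
        return Curve(
            Region(d["region"]),
            tuple(d["upper_end"]),
            tuple(d["lower_end"]),
            d["apex"],
            float(d["cobb"]),
            d["convexity"],
            bool(d.get("from_extrema", True)),
        )


def endplate_tilt(left: Point2D, right: Point2D) -> float:
    """Tilt of the endplate through two corner points, in degrees.

    Positive = the endplate slopes downward toward image-right (y-down
    convention).  A vertical endplate is rejected as degenerate.
    """
    if left.x == right.x:
        raise DegenerateGeometryError("vertical endplate (left.x == right.x)")
    return math.degrees(math.atan2(right.y - left.y, right.x - left.x))


def build_oscillogram(lset: LandmarkSet) -> TiltSeries:
    """All 34 endplate tilts of a validated landmark set, T1-sup first."""
    values = np.empty(N_ENDPLATES)
    for v, vert in enumerate(lset.vertebrae):
        try:
            values[2 * v] = endplate_tilt(vert.ul, vert.ur)
            values[2 * v + 1] = endplate_tilt(vert.ll, vert.lr)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"{vert.label}: {exc}") from exc
    return TiltSeries(lset.view, values)


# ---------------------------------------------------------------------------
# Peak / trough detection
# ---------------------------------------------------------------------------

def _turning_points(v: np.ndarray) -> list[tuple[int, str]]:
    """Alternating raw extrema with plateau runs represented by their most
    cranial index; series endpoints included when they extend a monotone run."""
    # compress plateaus into runs
    starts = [0]
    for i in range(1, len(v)):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    if len(starts) == 1:
        return []
    vals = v[starts]
    out: list[tuple[int, str]] = []
    for j in range(len(starts)):
        if j == 0:
            pol = "peak" if vals[0] > vals[1] else "trough"
            out.append((starts[0], pol))
        elif j == len(starts) - 1:
            pol = "peak" if vals[j] > vals[j - 1] else "trough"
            out.append((starts[j], pol))
        elif vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            out.append((starts[j], "peak"))
        elif vals[j] < vals[j - 1] and vals[j] < vals[j + 1]:
            out.append((starts[j], "trough"))
    return out


def find_extrema(series: TiltSeries | Sequence[float], min_prominence: float = 5.0) -> list[Extremum]:
    """Alternating peaks and troughs of the oscillogram.

    Prominence of an interior extremum is its smallest tilt difference to the
    adjacent surviving extrema; a terminal (first/last) extremum additionally
    has to stand out from the neutral tilt of 0 deg, so its prominence is
    ``min(gap-to-neighbour, |value|)`` — a boundary endplate only counts as a
    curve terminus if it is meaningfully tilted.  Sub-prominence wiggles are
    removed smallest-first as adjacent pairs, which preserves alternation and
    never discards a value outside the band of its surviving neighbours.
    """
    v = np.asarray(series.values if isinstance(series, TiltSeries) else series, dtype=float)
    ext = _turning_points(v)

    def prominences(ex: list[tuple[int, str]]) -> list[float]:
        proms = []
        for j, (idx, _pol) in enumerate(ex):
            gaps = []
            if j > 0:
                gaps.append(abs(v[idx] - v[ex[j - 1][0]]))
            if j < len(ex) - 1:
                gaps.append(abs(v[idx] - v[ex[j + 1][0]]))
            p = min(gaps) if gaps else abs(v[idx])
            if j == 0 or j == len(ex) - 1:
                p = min(p, abs(v[idx]))
            proms.append(p)
        return proms

    while ext:
        proms = prominences(ext)
        worst = min(range(len(ext)), key=lambda j: (proms[j], ext[j][0]))
        if proms[worst] >= min_prominence:
            break
        if worst == 0 or worst == len(ext) - 1:
            ext.pop(worst)  # dropping a terminal extremum keeps alternation
        else:
            # remove the min-gap adjacent pair (the extremum and whichever
            # neighbour it is closest to); cranial pair on ties
            left_gap = abs(v[ext[worst][0]] - v[ext[worst - 1][0]])
            right_gap = abs(v[ext[worst][0]] - v[ext[worst + 1][0]])
            if left_gap <= right_gap:
                del ext[worst - 1:worst + 1]
            else:
                del ext[worst:worst + 2]

    proms = prominences(ext)
    return [Extremum(idx, float(v[idx]), pol, float(p)) for (idx, pol), p in zip(ext, proms)]


def region_cobb(series: TiltSeries, region: Region) -> tuple[float, int, int]:
    """Brute-force Cobb of a region: max minus min tilt over its span.

    Returns ``(cobb, argmax_endplate, argmin_endplate)``; ties break toward
    the cranial index.  This is the oracle that :func:`detect_curves` must
    agree with whenever a single peak-trough pair lies in the span.
    """
    lo, hi = REGION_SPANS[region]
    seg = series.values[lo:hi + 1]
    imax = lo + int(np.argmax(seg))
    imin = lo + int(np.argmin(seg))
    return float(series.values[imax] - series.values[imin]), imax, imin


def apex_of(upper_end: str, lower_end: str, lset: LandmarkSet) -> str:
    """Apex vertebra between two end vertebrae: the one whose centroid is
    farthest (perpendicular) from the line joining the end centroids; the
    cranial candidate wins ties.  A straight segment yields upper_end + 1."""
    iu, il = VERTEBRA_INDEX[upper_end], VERTEBRA_INDEX[lower_end]
    if iu >= il:
        raise ValueError(f"upper end {upper_end} must be cranial to lower end {lower_end}")
    cu = lset.vertebrae[iu].centroid
    cl = lset.vertebrae[il].centroid
    dx, dy = cl.x - cu.x, cl.y - cu.y
    norm = math.hypot(dx, dy)
    if il - iu == 1:
        return lower_end if norm == 0 else upper_end  # no interior vertebra
    best_v, best_d = iu + 1, -1.0
    for v in range(iu + 1, il):
        c = lset.vertebrae[v].centroid
        if norm == 0:
            d = math.hypot(c.x - cu.x, c.y - cu.y)
        else:
            d = abs(dx * (c.y - cu.y) - dy * (c.x - cu.x)) / norm
        if d > best_d + 1e-12:
            best_v, best_d = v, d
    return VERTEBRA_LABELS[best_v]


def _region_for_apex(apex: str) -> Region:
    v = VERTEBRA_INDEX[apex]
    for region, lo, hi in _APEX_WINDOWS:
        if lo <= v <= hi:
            return region
    raise AssertionError("apex windows cover all vertebrae")


def _convexity(lset: LandmarkSet, upper_v: str, lower_v: str, apex: str) -> str:
    cu = lset.vertebra(upper_v).centroid
    cl = lset.vertebra(lower_v).centroid
    ca = lset.vertebra(apex).centroid
    cross = (cl.x - cu.x) * (ca.y - cu.y) - (cl.y - cu.y) * (ca.x - cu.x)
    if abs(cross) < 1e-9:
        return "none"
    return "image_right" if cross < 0 else "image_left"


def detect_curves(series: TiltSeries, lset: LandmarkSet, config: RunConfig | None = None) -> list[Curve]:
    """Detect the PT, MT and TL/L curves of one view.

    Adjacent peak-trough pairs with a tilt difference of at least
    ``config.min_cobb`` become candidate curves, assigned to a region by
    their apex vertebra; the largest candidate per region is kept.  A region
    with no candidate falls back to its span max-min (:func:`region_cobb`),
    so every region always reports a (possibly zero) Cobb value.
    """
    cfg = config or RunConfig()
    series = series.smoothed(cfg.smoothing_window)
    extrema = find_extrema(series, cfg.min_prominence)

    candidates: dict[Region, list[Curve]] = {r: [] for r in Region}
    for e1, e2 in zip(extrema, extrema[1:]):
        delta = abs(e1.value - e2.value)
        if delta < cfg.min_cobb:
            continue
        upper_v, upper_s = endplate_label(e1.index)
        lower_v, lower_s = endplate_label(e2.index)
        if VERTEBRA_INDEX[upper_v] >= VERTEBRA_INDEX[lower_v]:
            continue  # both endplates on one vertebra: not a curve
        apex = apex_of(upper_v, lower_v, lset)
        region = _region_for_apex(apex)
        candidates[region].append(
            Curve(
                region,
                (upper_v, upper_s),
                (lower_v, lower_s),
                apex,
                float(delta),
                _convexity(lset, upper_v, lower_v, apex),
            )
        )

    curves: list[Curve] = []
    for region in Region:
        if candidates[region]:
            best = max(candidates[region], key=lambda c: (c.cobb, -c.upper_index))
            curves.append(best)
            continue
        cobb, imax, imin = region_cobb(series, region)
        iu, il = sorted((imax, imin))
        upper_v, upper_s = endplate_label(iu)
        lower_v, lower_s = endplate_label(il)
        if VERTEBRA_INDEX[upper_v] < VERTEBRA_INDEX[lower_v]:
            apex = apex_of(upper_v, lower_v, lset)
            conv = "none" if cobb == 0 else _convexity(lset, upper_v, lower_v, apex)
        else:
            apex = upper_v
            conv = "none"
        curves.append(
            Curve(region, (upper_v, upper_s), (lower_v, lower_s), apex, float(cobb), conv,
                  from_extrema=False)
        )
    return curves


def sagittal_kyphosis_T5_T12(series: TiltSeries) -> float:
    """T5-T12 thoracic kyphosis: |tilt(T12 inferior) - tilt(T5 superior)|."""
    if series.view is not View.SAGITTAL:
        raise ValueError(f"kyphosis requires the sagittal view, got {series.view.value}")
    return float(abs(series.values[_T12_INF] - series.values[_T5_SUP]))


def _segment_kyphosis(series: TiltSeries, top: tuple[str, str], bottom: tuple[str, str]) -> float:
    return float(abs(series.values[endplate_index(*bottom)] - series.values[endplate_index(*top)]))


# ---------------------------------------------------------------------------
# Case-level measurement
# ---------------------------------------------------------------------------

@dataclass
class CaseMeasurement:
    """The full indicator set for one case.

    Coronal PT/MT/TL-L curves are always present; bending Cobb values,
    residuals and T5-T12 kyphosis are ``None`` when the corresponding views
    are missing.  ``lenke`` is filled by the classifier; the lumbar modifier
    inside it is always ``None`` (not computed — the coronal data model
    carries no pelvic landmarks to construct the centre sacral vertical
    line).
    """

    case_id: str
    curves: dict[Region, Curve]
    kyphosis_t5_t12: float | None = None
    sagittal_segments: dict[str, float] | None = None  # T2-T5 / T10-L2, for canonical criteria
    bending_cobb: dict[str, dict[Region, float]] = field(default_factory=dict)
    bending_residual: dict[Region, tuple[float, str]] | None = None
    lenke: "object | None" = None  # LenkeResult; typed loosely to avoid a cycle
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "curves": {r.value: c.to_dict() for r, c in self.curves.items()},
            "kyphosis_t5_t12": self.kyphosis_t5_t12,
            "sagittal_segments": self.sagittal_segments,
            "bending_cobb": {
                view: {r.value: cobb for r, cobb in cobbs.items()}
                for view, cobbs in self.bending_cobb.items()
            },
            "bending_residual": None if self.bending_residual is None else {
                r.value: [val, view] for r, (val, view) in self.bending_residual.items()
            },
            "lenke": None if self.lenke is None else self.lenke.to_dict(),
            "notes": list(self.notes),
        }

    @staticmethod
    def from_dict(d: dict) -> "CaseMeasurement":
        from .lenke_classifier import LenkeResult

        return CaseMeasurement(
            case_id=d["case_id"],
            curves={Region(k): Curve.from_dict(v) for k, v in d["curves"].items()},
            kyphosis_t5_t12=d.get("kyphosis_t5_t12"),
            sagittal_segments=d.get("sagittal_segments"),
            bending_cobb={
                view: {Region(k): float(v) for k, v in cobbs.items()}
                for view, cobbs in d.get("bending_cobb", {}).items()
            },
            bending_residual=None if d.get("bending_residual") is None else {
                Region(k): (float(v[0]), v[1]) for k, v in d["bending_residual"].items()
            },
            lenke=None if d.get("lenke") is None else LenkeResult.from_dict(d["lenke"]),
            notes=list(d.get("notes", [])),
        )


def _bending_region_cobbs(
    bseries: TiltSeries, bset: LandmarkSet, coronal_curves: dict[Region, Curve], cfg: RunConfig
) -> dict[Region, float]:
    if cfg.lock_end_vertebrae_on_bending:
        out = {}
        for region, curve in coronal_curves.items():
            out[region] = float(
                abs(bseries.values[curve.upper_index] - bseries.values[curve.lower_index])
            )
        return out
    return {c.region: c.cobb for c in detect_curves(bseries, bset, cfg)}


def measure_case(case: CaseViews, config: RunConfig | None = None) -> CaseMeasurement:
    """Measure all available indicators of a case and classify it.

    Requires the coronal view; missing optional views degrade gracefully
    (``None`` fields plus an explanatory note).  Classification (Lenke type
    and sagittal modifier) is delegated to :mod:`oscillocobb.lenke_classifier`.
    """
    cfg = config or RunConfig()
    if case.coronal is None:
        raise ValueError("coronal view is required")
    coronal = build_oscillogram(case.coronal).smoothed(cfg.smoothing_window)
    curves = {c.region: c for c in detect_curves(coronal, case.coronal, cfg)}

    m = CaseMeasurement(case_id=case.case_id, curves=curves)

    bend_sets = {
        "left_bending": case.left_bending,
        "right_bending": case.right_bending,
    }
    for name, bset in bend_sets.items():
        if bset is None:
            continue
        bseries = build_oscillogram(bset).smoothed(cfg.smoothing_window)
        m.bending_cobb[name] = _bending_region_cobbs(bseries, bset, curves, cfg)
    if m.bending_cobb:
        m.bending_residual = {}
        for region in Region:
            best_view = min(m.bending_cobb, key=lambda vw: (m.bending_cobb[vw][region], vw))
            m.bending_residual[region] = (m.bending_cobb[best_view][region], best_view)
    else:
        m.notes.append("no bending views: structural assessment unavailable")

    if case.sagittal is not None:
        sag = build_oscillogram(case.sagittal).smoothed(cfg.smoothing_window)
        m.kyphosis_t5_t12 = sagittal_kyphosis_T5_T12(sag)
        m.sagittal_segments = {
            "T2_T5": _segment_kyphosis(sag, ("T2", SUPERIOR), ("T5", INFERIOR)),
            "T10_L2": _segment_kyphosis(sag, ("T10", SUPERIOR), ("L2", INFERIOR)),
        }
    else:
        m.notes.append("no sagittal view: T5-T12 kyphosis and sagittal modifier unavailable")

    from .lenke_classifier import classify  # deferred: classifier consumes CaseMeasurement

    m.lenke = classify(m, cfg)
    return m
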