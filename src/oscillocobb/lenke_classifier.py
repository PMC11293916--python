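"""Lenke typing of adolescent idiopathic scoliosis from oscillogram measurements.

The Lenke system assigns curve types 1-6 from which of the three regional
curves (proximal thoracic, main thoracic, thoracolumbar/lumbar) are
*structural* and which is the *major* (largest) curve, plus a sagittal
thoracic modifier from T5-T12 kyphosis.  Here a minor curve is structural
when its residual Cobb on side-bending stays strictly above 25 deg; the
major curve is structural by definition.  The sagittal modifier is "-"
below 10 deg, "+" above 40 deg, "N" between (strict inequalities at both
boundaries).

The lumbar modifier (A/B/C) is never computed: it needs the centre sacral
vertical line, i.e. pelvic landmarks outside this data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import RunConfig
from .oscillogram_geometry import CaseMeasurement, Region

#: Order of preference when coronal Cobb values tie for the major curve:
#: thoracic precedence, then thoracolumbar/lumbar.
_MAJOR_PRECEDENCE = (Region.MT, Region.TLL, Region.PT)

#: (PT structural, MT structural, TL/L structural, major region) -> type.
_TYPE_TABLE: dict[tuple[bool, bool, bool, Region], int] = {
    (False, True, False, Region.MT): 1,
    (True, True, False, Region.MT): 2,
    (False, True, True, Region.MT): 3,
    (True, True, True, Region.MT): 4,
    (True, True, True, Region.TLL): 4,
    (False, False, True, Region.TLL): 5,
    (False, True, True, Region.TLL): 6,
}


@dataclass(frozen=True)
class StructuralAssessment:
    region: Region
    coronal_cobb: float
    residual_cobb: float | None          # min over available bending views
    bending_view_used: str | None
    structural: bool | None              # None when no bending views exist
    is_major: bool


@dataclass
class LenkeResult:
    curve_type: int | None
    sagittal_modifier: str | None        # "-", "N", "+"
    lumbar_modifier: None = None         # unsupported by design
    notes: list[str] = field(default_factory=list)
    assessments: list[StructuralAssessment] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "curve_type": self.curve_type,
            "sagittal_modifier": self.sagittal_modifier,
            "lumbar_modifier": None,
            "notes": list(self.notes),
            "assessments": [
                {
                    "region": a.region.value,
                    "coronal_cobb": a.coronal_cobb,
                    "residual_cobb": a.residual_cobb,
                    "bending_view_used": a.bending_view_used,
                    "structural": a.structural,
                    "is_major": a.is_major,
                }
                for a in self.assessments
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "LenkeResult":
        return LenkeResult(
            curve_type=d.get("curve_type"),
            sagittal_modifier=d.get("sagittal_modifier"),
            notes=list(d.get("notes", [])),
            assessments=[
                StructuralAssessment(
                    Region(a["region"]),
                    float(a["coronal_cobb"]),
                    None if a.get("residual_cobb") is None else float(a["residual_cobb"]),
                    a.get("bending_view_used"),
                    a.get("structural"),
                    bool(a["is_major"]),
                )
                for a in d.get("assessments", [])
            ],
        )


def major_region(measurement: CaseMeasurement) -> Region:
    """Region of the largest coronal Cobb (MT > TL/L > PT on exact ties)."""
    return max(
        _MAJOR_PRECEDENCE,
        key=lambda r: (measurement.curves[r].cobb, -_MAJOR_PRECEDENCE.index(r)),
    )


def assess_structural(
    measurement: CaseMeasurement, threshold: float = 25.0
) -> list[StructuralAssessment]:
    """Structural flags per region from side-bending residual Cobb angles.

    A minor curve is structural iff its residual (minimum over the available
    bending views) is strictly greater than ``threshold``; the major curve is
    structural by definition regardless of residual.  Without bending views
    every flag is ``None``.
    """
    major = major_region(measurement)
    out: list[StructuralAssessment] = []
    for region in Region:
        coronal = measurement.curves[region].cobb
        if measurement.bending_residual is None:
            out.append(StructuralAssessment(region, coronal, None, None, None, region is major))
            continue
        residual, view = measurement.bending_residual[region]
        structural = True if region is major else residual > threshold
        out.append(StructuralAssessment(region, coronal, residual, view, structural, region is major))
    return out


def lenke_type(assessments: list[StructuralAssessment]) -> tuple[int | None, list[str]]:
    """Map structural flags + major region to a Lenke type 1-6.

    Unsupported patterns (e.g. a structural-PT-only spine or a PT major
    curve) return ``None`` with an explanatory note instead of raising.
    """
    flags = {a.region: a.structural for a in assessments}
    if any(v is None for v in flags.values()):
        return None, ["bending views required for Lenke typing"]
    major = next(a.region for a in assessments if a.is_major)
    key = (flags[Region.PT], flags[Region.MT], flags[Region.TLL], major)
    if key in _TYPE_TABLE:
        return _TYPE_TABLE[key], []
    pattern = "".join("S" if flags[r] else "-" for r in (Region.PT, Region.MT, Region.TLL))
    return None, [
        f"structural pattern PT/MT/TLL = {pattern} with major {major.value} "
        "has no defined Lenke type"
    ]


def sagittal_modifier(kyphosis_t5_t12: float, low: float = 10.0, high: float = 40.0) -> str:
    """Sagittal thoracic modifier: "-" below ``low``, "+" above ``high``, else "N".

    Boundary values map to "N" (both comparisons are strict).
    """
    if kyphosis_t5_t12 < 0:
        raise ValueError("kyphosis must be non-negative")
    if kyphosis_t5_t12 < low:
        return "-"
    if kyphosis_t5_t12 > high:
        return "+"
    return "N"


def classify(measurement: CaseMeasurement, config: RunConfig | None = None) -> LenkeResult:
    """Full Lenke result for a measured case.

    Composes the structural assessment, the type table and the sagittal
    modifier; every ``None`` output carries a human-readable note.  With
    ``config.canonical_lenke_sagittal_criteria`` the classical sagittal
    structural criteria (T2-T5 and T10-L2 kyphosis >= 20 deg) additionally
    mark minor curves structural; by default only the bending rule applies.
    """
    cfg = config or RunConfig()
    notes: list[str] = []

    assessments = assess_structural(measurement, cfg.structural_threshold)

    if cfg.canonical_lenke_sagittal_criteria and measurement.sagittal_segments:
        seg = measurement.sagittal_segments
        upgraded = []
        for a in assessments:
            structural = a.structural
            if structural is not None and not structural:
                if a.region is Region.PT and seg.get("T2_T5", 0.0) >= 20.0:
                    structural = True
                    notes.append("PT marked structural by T2-T5 kyphosis >= 20")
                if a.region is Region.TLL and seg.get("T10_L2", 0.0) >= 20.0:
                    structural = True
                    notes.append("TL/L marked structural by T10-L2 kyphosis >= 20")
            upgraded.append(
                StructuralAssessment(
                    a.region, a.coronal_cobb, a.residual_cobb, a.bending_view_used,
                    structural, a.is_major,
                )
            )
        assessments = upgraded

    largest = max(c.cobb for c in measurement.curves.values())
    if largest < cfg.min_cobb:
        curve_type = None
        notes.append(f"no curve >= min_cobb ({cfg.min_cobb} deg)")
    else:
        curve_type, type_notes = lenke_type(assessments)
        notes.extend(type_notes)
        majors = [a.region for a in assessments if a.is_major]
        ties = [
            r for r in Region
            if r not in majors and measurement.curves[r].cobb == measurement.curves[majors[0]].cobb
        ]
        if ties:
            notes.append(
                f"major-curve tie between {majors[0].value} and "
                f"{', '.join(r.value for r in ties)}: {majors[0].value} preferred"
            )

    if measurement.kyphosis_t5_t12 is None:
        modifier = None
        notes.append("sagittal view required for the thoracic sagittal modifier")
    else:
        modifier = sagittal_modifier(
            measurement.kyphosis_t5_t12, cfg.modifier_low, cfg.modifier_high
        )

    return LenkeResult(curve_type, modifier, notes=notes, assessments=assessments)
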