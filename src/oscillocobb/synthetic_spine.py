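"""Synthetic spines with analytically known ground truth.

The generator builds landmark sets for all four views of a simulated
scoliosis case.  The coronal endplate-tilt profile is a sum of signed
derivative-of-Gaussian bumps, one per scoliotic curve: each bump contributes
exactly one peak and one trough to the oscillogram, which is the signature a
real curve leaves (the end vertebrae own the maximally opposed endplates).
Vertebral rectangles are then placed cranial to caudal with the prescribed
endplate tilts, splitting each vertebra's local tilt between rigid rotation
and endplate wedging; bending views reuse the profile with each curve's
amplitude scaled down on its corrective side according to its flexibility;
the sagittal view follows a smooth kyphosis arc rescaled to hit the target
T5-T12 angle exactly.  Corner noise is added last.

Ground truth (per-region Cobb for every view, end endplates, apex,
structural flags, Lenke type, kyphosis, sagittal modifier) is computed from
the noise-free tilt sequences with the same region max-min oracle the
measurement side uses as its fallback, so truth and noise-free measurement
agree to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .landmark_model import (
    VERTEBRA_INDEX,
    VERTEBRA_LABELS,
    CaseViews,
    LandmarkSet,
    Point2D,
    Units,
    VertebraCorners,
    View,
)
from .oscillogram_geometry import (
    N_ENDPLATES,
    REGION_SPANS,
    Region,
    endplate_label,
)

#: Structural threshold (deg) the generator's truth uses, mirroring the
#: clinical bending rule (strictly greater than 25 deg = structural).
STRUCTURAL_THRESHOLD = 25.0
MODIFIER_LOW, MODIFIER_HIGH = 10.0, 40.0

_MAJOR_PRECEDENCE = (Region.MT, Region.TLL, Region.PT)
_TYPE_TABLE = {
    (False, True, False, "MT"): 1,
    (True, True, False, "MT"): 2,
    (False, True, True, "MT"): 3,
    (True, True, True, "MT"): 4,
    (True, True, True, "TLL"): 4,
    (False, False, True, "TLL"): 5,
    (False, True, True, "TLL"): 6,
}


@dataclass(frozen=True)
class CurveSpec:
    """One scoliotic curve of the simulated spine.

    ``apex_position`` is a vertebra label ("T9") or a fraction of the T1-L5
    span; ``amplitude`` is the peak endplate tilt the curve contributes
    (deg), so an isolated curve has a Cobb angle of about twice the
    amplitude; ``width`` is the Gaussian sigma as a fraction of the span
    (the curve's extrema sit one sigma to either side of the apex);
    ``flexibility`` is the fraction of the amplitude removed on the
    corrective side-bending view (high flexibility = nonstructural).
    """

    apex_position: str | float
    amplitude: float
    width: float = 0.15
    convexity: str = "image_right"
    flexibility: float = 0.3

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not 0.0 <= self.flexibility <= 1.0:
            raise ValueError("flexibility must be in [0, 1]")
        if self.convexity not in ("image_left", "image_right"):
            raise ValueError("convexity must be image_left or image_right")

    @property
    def mu(self) -> float:
        """Apex location in endplate-index coordinates (0..33)."""
        if isinstance(self.apex_position, str):
            return 2.0 * VERTEBRA_INDEX[self.apex_position] + 0.5
        return float(self.apex_position) * (N_ENDPLATES - 1)

    @property
    def sigma(self) -> float:
        return self.width * (N_ENDPLATES - 1)

    @property
    def apex_label(self) -> str:
        if isinstance(self.apex_position, str):
            return self.apex_position
        return VERTEBRA_LABELS[int(round((self.mu - 0.5) / 2.0))]


@dataclass(frozen=True)
class SpineSimParams:
    """Full parameter set of one simulated case.

    Geometry defaults are pixels at roughly a 1460 px T1-L5 span, the scale
    of a full-spine radiograph; ``landmark_noise_sd`` is the isotropic
    Gaussian jitter added to every corner coordinate.  ``wedging_fraction``
    is the share of each vertebra's local tilt expressed as endplate
    non-parallelism (vertebral wedging) rather than rigid rotation.
    """

    curves: tuple[CurveSpec, ...] = ()
    kyphosis_t5_t12: float = 30.0
    vertebra_height: float = 65.0
    vertebra_width: float = 90.0
    disc_height: float = 22.0
    wedging_fraction: float = 0.3
    landmark_noise_sd: float = 1.5
    units: Units = Units.PX
    seed: int = 0
    case_id: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.curves, list):
            object.__setattr__(self, "curves", tuple(self.curves))
        for name in ("vertebra_height", "vertebra_width", "disc_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.wedging_fraction <= 1.0:
            raise ValueError("wedging_fraction must be in [0, 1]")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        if self.kyphosis_t5_t12 < 0:
            raise ValueError("kyphosis_t5_t12 must be >= 0")


@dataclass
class GroundTruth:
    """Simulator-side record of what the measurement pipeline should find."""

    case_id: str
    coronal_cobb: dict[Region, float]
    bending_cobb: dict[str, dict[Region, float]]
    bending_residual: dict[Region, float]
    end_endplates: dict[Region, tuple[int, int]]   # (argmax, argmin) endplate indices
    apexes: tuple[str, ...]                        # per curve spec
    structural: dict[Region, bool]
    major: Region
    lenke_type: int | None
    kyphosis_t5_t12: float
    sagittal_modifier: str
    tilt_series: dict[str, np.ndarray] = field(default_factory=dict)  # noise-free

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "coronal_cobb": {r.value: v for r, v in self.coronal_cobb.items()},
            "bending_cobb": {
                vw: {r.value: v for r, v in d.items()} for vw, d in self.bending_cobb.items()
            },
            "bending_residual": {r.value: v for r, v in self.bending_residual.items()},
            "end_endplates": {r.value: list(v) for r, v in self.end_endplates.items()},
            "apexes": list(self.apexes),
            "structural": {r.value: v for r, v in self.structural.items()},
            "major": self.major.value,
            "lenke_type": self.lenke_type,
            "kyphosis_t5_t12": self.kyphosis_t5_t12,
            "sagittal_modifier": self.sagittal_modifier,
            "tilt_series": {k: list(map(float, v)) for k, v in self.tilt_series.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "GroundTruth":
        return GroundTruth(
            case_id=d["case_id"],
            coronal_cobb={Region(k): float(v) for k, v in d["coronal_cobb"].items()},
            bending_cobb={
                vw: {Region(k): float(v) for k, v in dd.items()}
                for vw, dd in d["bending_cobb"].items()
            },
            bending_residual={Region(k): float(v) for k, v in d["bending_residual"].items()},
            end_endplates={Region(k): tuple(v) for k, v in d["end_endplates"].items()},
            apexes=tuple(d["apexes"]),
            structural={Region(k): bool(v) for k, v in d["structural"].items()},
            major=Region(d["major"]),
            lenke_type=d["lenke_type"],
            kyphosis_t5_t12=float(d["kyphosis_t5_t12"]),
            sagittal_modifier=d["sagittal_modifier"],
            tilt_series={k: np.asarray(v, float) for k, v in d.get("tilt_series", {}).items()},
        )

    def as_measurement(self):
        """Repackage the truth as a CaseMeasurement-shaped record, usable as
        the reference side of an agreement comparison."""
        from .lenke_classifier import LenkeResult
        from .oscillogram_geometry import CaseMeasurement, Curve

        curves = {}
        for region in Region:
            imax, imin = self.end_endplates[region]
            iu, il = sorted((imax, imin))
            curves[region] = Curve(
                region,
                endplate_label(iu),
                endplate_label(il),
                self.apexes[0] if self.apexes else endplate_label(iu)[0],
                self.coronal_cobb[region],
                "none",
                from_extrema=False,
            )
        residual = {
            r: (self.bending_residual[r], min(
                self.bending_cobb, key=lambda vw: (self.bending_cobb[vw][r], vw)
            ))
            for r in Region
        } if self.bending_cobb else None
        return CaseMeasurement(
            case_id=self.case_id,
            curves=curves,
            kyphosis_t5_t12=self.kyphosis_t5_t12,
            bending_cobb={vw: dict(d) for vw, d in self.bending_cobb.items()},
            bending_residual=residual,
            lenke=LenkeResult(self.lenke_type, self.sagittal_modifier),
        )


# ---------------------------------------------------------------------------
# Tilt profiles
# ---------------------------------------------------------------------------

def _bump(u: np.ndarray) -> np.ndarray:
    """Derivative-of-Gaussian normalized to +-1 at u = +-1."""
    return u * np.exp((1.0 - u * u) / 2.0)


def _profile(curves: Sequence[CurveSpec], t: np.ndarray, scale: dict[int, float] | None = None) -> np.ndarray:
    """Continuous coronal tilt profile over endplate coordinate t (0..33).

    ``scale`` optionally multiplies individual curve amplitudes (bending
    correction).  image_right convexity puts the trough cranial to the peak:
    a vertebra drifting toward image-right as the spine descends carries a
    negative (down-to-the-left) endplate tilt.
    """
    out = np.zeros_like(t, dtype=float)
    for k, c in enumerate(curves):
        amp = c.amplitude * (1.0 if scale is None else scale.get(k, 1.0))
        sign = 1.0 if c.convexity == "image_right" else -1.0
        out += sign * amp * _bump((t - c.mu) / c.sigma)
    return out


def _endplate_tilts(profile_at) -> np.ndarray:
    """Discrete per-endplate tilts with rigid-rotation/wedging split applied
    by the caller via the ``profile_at`` callable (already mixed)."""
    t = np.arange(N_ENDPLATES, dtype=float)
    return profile_at(t)


def _mix_wedging(raw: np.ndarray, wedging_fraction: float) -> np.ndarray:
    """Split each vertebra's tilt between rigid rotation and wedging.

    ``raw`` holds the continuous profile sampled at the 34 endplates; the
    rigid component is the vertebra's mean endplate tilt, and
    ``wedging_fraction`` restores that share of the superior/inferior
    difference (endplate non-parallelism)."""
    out = np.empty_like(raw)
    for v in range(N_ENDPLATES // 2):
        sup, inf = raw[2 * v], raw[2 * v + 1]
        center = 0.5 * (sup + inf)
        out[2 * v] = (1.0 - wedging_fraction) * center + wedging_fraction * sup
        out[2 * v + 1] = (1.0 - wedging_fraction) * center + wedging_fraction * inf
    return out


def _coronal_tilts(params: SpineSimParams, scale: dict[int, float] | None = None) -> np.ndarray:
    t = np.arange(N_ENDPLATES, dtype=float)
    return _mix_wedging(_profile(params.curves, t, scale), params.wedging_fraction)


def _sagittal_tilts(params: SpineSimParams) -> np.ndarray:
    """Smooth kyphosis arc rescaled so |tilt[T12-inf] - tilt[T5-sup]| is the
    target exactly, whatever the wedging fraction."""
    t = np.arange(N_ENDPLATES, dtype=float)
    i5, i12 = 8, 23

    def base(tt: np.ndarray) -> np.ndarray:
        u = np.clip((tt - i5) / (i12 - i5), 0.0, 1.0)
        shape = -np.cos(np.pi * u)           # -1 at T5-sup, +1 at T12-inf
        # gentle lumbar return toward lordosis below T12
        tail = np.clip((tt - i12) / (N_ENDPLATES - 1 - i12), 0.0, 1.0)
        return shape - 1.2 * tail

    raw = _mix_wedging(base(t), params.wedging_fraction)
    span = raw[i12] - raw[i5]
    if span == 0:
        return np.zeros(N_ENDPLATES)
    return raw * (params.kyphosis_t5_t12 / span)


# ---------------------------------------------------------------------------
# Landmark construction
# ---------------------------------------------------------------------------

def _corners_from_tilts(
    tilts: np.ndarray,
    params: SpineSimParams,
    view: View,
    rng: np.random.Generator | None,
) -> LandmarkSet:
    """Place 17 vertebral rectangles whose endplates realize ``tilts`` exactly
    (before noise).  Centroids drift laterally with the local tilt so the
    apex is displaced toward the convexity, as on a radiograph."""
    h, w, d = params.vertebra_height, params.vertebra_width, params.disc_height
    x, y = 760.0, 120.0 + h / 2.0
    verts = []
    for v in range(N_ENDPLATES // 2):
        th_sup = math.radians(tilts[2 * v])
        th_inf = math.radians(tilts[2 * v + 1])
        half = w / 2.0
        m_sup = (x, y - h / 2.0)
        m_inf = (x, y + h / 2.0)
        pts = {
            "ul": (m_sup[0] - half * math.cos(th_sup), m_sup[1] - half * math.sin(th_sup)),
            "ur": (m_sup[0] + half * math.cos(th_sup), m_sup[1] + half * math.sin(th_sup)),
            "ll": (m_inf[0] - half * math.cos(th_inf), m_inf[1] - half * math.sin(th_inf)),
            "lr": (m_inf[0] + half * math.cos(th_inf), m_inf[1] + half * math.sin(th_inf)),
        }
        if rng is not None and params.landmark_noise_sd > 0:
            noise = rng.normal(0.0, params.landmark_noise_sd, size=(4, 2))
            pts = {
                key: (px + noise[i, 0], py + noise[i, 1])
                for i, (key, (px, py)) in enumerate(pts.items())
            }
        verts.append(
            VertebraCorners(
                VERTEBRA_LABELS[v],
                Point2D(*pts["ul"]),
                Point2D(*pts["ur"]),
                Point2D(*pts["ll"]),
                Point2D(*pts["lr"]),
            )
        )
        if v < N_ENDPLATES // 2 - 1:
            # advance along the locally tilted spine axis
            th_gap = math.radians(0.5 * (tilts[2 * v + 1] + tilts[2 * v + 2]))
            y += h + d
            x -= (h + d) * math.tan(th_gap)
    return LandmarkSet(view=view, units=params.units, vertebrae=tuple(verts), case_id=params.case_id)


def _span_cobb(vals: np.ndarray, region: Region) -> tuple[float, int, int]:
    lo, hi = REGION_SPANS[region]
    seg = vals[lo:hi + 1]
    imax = lo + int(np.argmax(seg))
    imin = lo + int(np.argmin(seg))
    return float(vals[imax] - vals[imin]), imax, imin


def _bending_scale(params: SpineSimParams, side: str) -> dict[int, float]:
    """Amplitude multipliers for one bending view: a curve is corrected
    (amplitude times 1 - flexibility) when the patient bends toward its
    convex side, and unchanged otherwise."""
    convex_side = "image_left" if side == "left_bending" else "image_right"
    return {
        k: (1.0 - c.flexibility) if c.convexity == convex_side else 1.0
        for k, c in enumerate(params.curves)
    }


def simulate_case(params: SpineSimParams) -> tuple[CaseViews, GroundTruth]:
    """Build all four views of one case plus its ground truth.

    With ``landmark_noise_sd`` zero the output is byte-identical regardless
    of seed; otherwise corner noise is drawn from ``default_rng(seed)`` in a
    fixed view order (coronal, sagittal, left, right).
    """
    rng = np.random.default_rng(params.seed)
    tilts = {
        "coronal": _coronal_tilts(params),
        "sagittal": _sagittal_tilts(params),
        "left_bending": _coronal_tilts(params, _bending_scale(params, "left_bending")),
        "right_bending": _coronal_tilts(params, _bending_scale(params, "right_bending")),
    }

    views = CaseViews(
        case_id=params.case_id,
        coronal=_corners_from_tilts(tilts["coronal"], params, View.CORONAL, rng),
        sagittal=_corners_from_tilts(tilts["sagittal"], params, View.SAGITTAL, rng),
        left_bending=_corners_from_tilts(tilts["left_bending"], params, View.LEFT_BENDING, rng),
        right_bending=_corners_from_tilts(tilts["right_bending"], params, View.RIGHT_BENDING, rng),
    )

    coronal_cobb: dict[Region, float] = {}
    ends: dict[Region, tuple[int, int]] = {}
    for region in Region:
        cobb, imax, imin = _span_cobb(tilts["coronal"], region)
        coronal_cobb[region] = cobb
        ends[region] = (imax, imin)

    bending_cobb = {
        vw: {r: _span_cobb(tilts[vw], r)[0] for r in Region}
        for vw in ("left_bending", "right_bending")
    }
    residual = {
        r: min(bending_cobb["left_bending"][r], bending_cobb["right_bending"][r])
        for r in Region
    }

    major = max(_MAJOR_PRECEDENCE, key=lambda r: (coronal_cobb[r], -_MAJOR_PRECEDENCE.index(r)))
    structural = {
        r: True if r is major else residual[r] > STRUCTURAL_THRESHOLD for r in Region
    }
    key = (structural[Region.PT], structural[Region.MT], structural[Region.TLL], major.value)
    ltype = _TYPE_TABLE.get(key)

    kyph = float(abs(tilts["sagittal"][23] - tilts["sagittal"][8]))
    if kyph < MODIFIER_LOW:
        modifier = "-"
    elif kyph > MODIFIER_HIGH:
        modifier = "+"
    else:
        modifier = "N"

    truth = GroundTruth(
        case_id=params.case_id,
        coronal_cobb=coronal_cobb,
        bending_cobb=bending_cobb,
        bending_residual=residual,
        end_endplates=ends,
        apexes=tuple(c.apex_label for c in params.curves),
        structural=structural,
        major=major,
        lenke_type=ltype,
        kyphosis_t5_t12=kyph,
        sagittal_modifier=modifier,
        tilt_series=tilts,
    )
    return views, truth


# ---------------------------------------------------------------------------
# Presets and batching
# ---------------------------------------------------------------------------

#: Canonical curve anchors: PT apex T3 (extrema near T1/T5), MT apex T9
#: (extrema near T6/T12), TL/L apex L1 (extrema near T11/L3).  Convexities
#: alternate (PT left, MT right, TL/L left), the typical AIS pattern, so
#: adjacent curves share their end vertebra as one merged oscillogram
#: extremum.  Amplitudes/flexibilities are chosen so each preset's realized
#: structural pattern matches its type with a comfortable margin from the
#: 25 deg bending rule.
_PT = lambda a, f: CurveSpec("T3", a, width=0.12, convexity="image_left", flexibility=f)
_MT = lambda a, f: CurveSpec("T9", a, width=0.165, convexity="image_right", flexibility=f)
_TL = lambda a, f: CurveSpec("L1", a, width=0.12, convexity="image_left", flexibility=f)

_PRESETS: dict[int, tuple[CurveSpec, ...]] = {
    1: (_MT(26.0, 0.35),),
    2: (_PT(20.0, 0.10), _MT(28.0, 0.30)),
    3: (_MT(26.0, 0.30), _TL(18.0, 0.15)),
    4: (_PT(18.0, 0.10), _MT(26.0, 0.25), _TL(18.0, 0.15)),
    5: (_TL(23.0, 0.70),),
    6: (_MT(16.0, 0.20), _TL(30.0, 0.15)),
}

#: Typical T5-T12 kyphosis per preset (all in the "N" band by default).
_PRESET_KYPHOSIS = {1: 28.0, 2: 25.0, 3: 30.0, 4: 32.0, 5: 24.0, 6: 30.0}


def preset_for_type(lenke_type: int, **overrides) -> SpineSimParams:
    """Simulation parameters whose realized curve pattern matches a Lenke type."""
    if lenke_type not in _PRESETS:
        raise ValueError(f"Lenke type must be 1..6, got {lenke_type!r}")
    params = SpineSimParams(
        curves=_PRESETS[lenke_type],
        kyphosis_t5_t12=_PRESET_KYPHOSIS[lenke_type],
        case_id=f"preset-lenke{lenke_type}",
    )
    return replace(params, **overrides) if overrides else params


def batch_simulate(
    n: int,
    params: SpineSimParams | int | Sequence[SpineSimParams | int],
    seed: int = 0,
) -> list[tuple[CaseViews, GroundTruth]]:
    """n independent cases with per-case seeds derived from ``seed``.

    ``params`` may be a single parameter set, a preset type number, or a
    sequence of either (cycled over the batch).  Reproducible: the same
    master seed yields the same batch.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(params, (SpineSimParams, int)):
        pool: list[SpineSimParams | int] = [params]
    else:
        pool = list(params)
        if not pool:
            raise ValueError("params sequence must not be empty")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)
    ]
    out = []
    for i in range(n):
        p = pool[i % len(pool)]
        if isinstance(p, int):
            p = preset_for_type(p)
        p = replace(p, seed=child_seeds[i], case_id=p.case_id or "case")
        p = replace(p, case_id=f"{p.case_id}-{i:04d}")
        out.append(simulate_case(p))
    return out
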