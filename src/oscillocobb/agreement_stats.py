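"""Inter-rater agreement statistics: MAE and intraclass correlation.

Method-comparison studies of angle measurements report the mean absolute
error (mean +- sample SD of absolute paired differences) and the intraclass
correlation coefficient with a 95% confidence interval.  The ICC here is
computed from the two-way ANOVA mean squares (between-subjects MSR,
between-raters MSC, residual MSE); the default form is ICC(2,1) — two-way
random effects, absolute agreement, single measure — the standard choice
when raters are a random sample and systematic offsets should count against
agreement.  Confidence limits follow the F-distribution formulation of
McGraw & Wong (1996).

Applying an ICC to integer-coded categorical labels (Lenke types) is
statistically questionable but mirrors common practice in this literature;
when done here a warning is logged and unweighted Cohen's kappa is reported
alongside as the sounder alternative.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .oscillogram_geometry import CaseMeasurement, Region

logger = logging.getLogger(__name__)

ICC_FORMS = ("1,1", "2,1", "3,1", "1,k", "2,k", "3,k")

#: The seven angle indicators compared case-by-case, plus the categorical ones.
ANGLE_INDICATORS = (
    "PT", "MT", "TLL", "kyphosis_T5_T12",
    "bending_PT", "bending_MT", "bending_TLL",
)
CATEGORICAL_INDICATORS = ("lenke_type", "sagittal_modifier")
_MODIFIER_CODE = {"-": 0, "N": 1, "+": 2}


def mae(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the absolute paired differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"x and y must be equal-length 1-D sequences, got {x.shape} vs {y.shape}")
    d = np.abs(x - y)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


@dataclass(frozen=True)
class RatingsMatrix:
    """Subjects x raters matrix of numeric ratings (no missing cells)."""

    values: np.ndarray
    raters: tuple[str, ...] = ()
    indicator: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("ratings matrix contains non-finite cells")
        if not self.raters:
            object.__setattr__(
                self, "raters", tuple(f"rater{j + 1}" for j in range(vals.shape[1]))
            )


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    form: str = "2,1"


def _mean_squares(m: np.ndarray) -> tuple[float, float, float, float]:
    """(MSR, MSC, MSE, MSW): rows=subjects, columns=raters."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    ssw = sst - ssr
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = ssw / (n * (k - 1))
    return msr, msc, mse, msw


def icc(m: RatingsMatrix | np.ndarray, form: str = "2,1", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation with a (1 - alpha) confidence interval.

    Forms: "1,1"/"1,k" one-way random; "2,1"/"2,k" two-way random, absolute
    agreement; "3,1"/"3,k" two-way mixed, consistency.  A matrix with zero
    total variance has an undefined ICC; it is reported as 1.0 (perfect
    agreement on a constant) with a warning.
    """
    vals = m.values if isinstance(m, RatingsMatrix) else np.asarray(m, dtype=float)
    if isinstance(m, np.ndarray) or not isinstance(m, RatingsMatrix):
        RatingsMatrix(vals)  # reuse the shape/finite validation
    if form not in ICC_FORMS:
        raise ValueError(f"form must be one of {ICC_FORMS}, got {form!r}")
    n, k = vals.shape
    if np.ptp(vals) == 0.0:
        warnings.warn("zero total variance: ICC undefined, reporting 1.0", stacklevel=2)
        return ICCResult(1.0, 1.0, 1.0, form)

    msr, msc, mse, msw = _mean_squares(vals)
    df1 = n - 1
    dfe = (n - 1) * (k - 1)
    dfw = n * (k - 1)

    if form in ("1,1", "1,k"):
        est1 = (msr - msw) / (msr + (k - 1) * msw) if msr + (k - 1) * msw else 1.0
        fstat = msr / msw if msw > 0 else math.inf
        fl = fstat / f_dist.ppf(1 - alpha / 2, df1, dfw)
        fu = fstat * f_dist.ppf(1 - alpha / 2, dfw, df1)
        lo1 = (fl - 1) / (fl + (k - 1))
        hi1 = (fu - 1) / (fu + (k - 1))
    elif form in ("3,1", "3,k"):
        est1 = (msr - mse) / (msr + (k - 1) * mse) if msr + (k - 1) * mse else 1.0
        fstat = msr / mse if mse > 0 else math.inf
        fl = fstat / f_dist.ppf(1 - alpha / 2, df1, dfe)
        fu = fstat * f_dist.ppf(1 - alpha / 2, dfe, df1)
        lo1 = (fl - 1) / (fl + (k - 1))
        hi1 = (fu - 1) / (fu + (k - 1))
    else:  # 2,1 / 2,k
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est1 = (msr - mse) / denom if denom else 1.0
        if mse > 0:
            fj = msc / mse
            a = k * est1 / (n * (1 - est1)) if est1 != 1.0 else math.inf
            if math.isinf(a):
                lo1 = hi1 = est1
            else:
                vn = dfe * (k * est1 * fj + n * (1 + (k - 1) * est1) - k * est1) ** 2
                vd = df1 * k**2 * est1**2 * fj**2 + (n * (1 + (k - 1) * est1) - k * est1) ** 2
                v = vn / vd
                f2u = f_dist.ppf(1 - alpha / 2, df1, v)
                f2l = f_dist.ppf(1 - alpha / 2, v, df1)
                lo1 = n * (msr - f2u * mse) / (
                    f2u * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi1 = n * (f2l * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2l * msr
                )
        else:
            lo1 = hi1 = est1

    if form.endswith(",1"):
        return ICCResult(float(est1), float(lo1), float(hi1), form)
    # average-measure forms via the Spearman-Brown step-up
    def step_up(r: float) -> float:
        return k * r / (1 + (k - 1) * r)

    return ICCResult(float(step_up(est1)), float(step_up(lo1)), float(step_up(hi1)), form)


def icc_2_1(m: RatingsMatrix | np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    return icc(m, form="2,1", alpha=alpha)


def cohen_kappa(x: Sequence, y: Sequence) -> float:
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(list(x), list(y)))


# ---------------------------------------------------------------------------
# Case-level comparison
# ---------------------------------------------------------------------------

@dataclass
class IndicatorAgreement:
    indicator: str
    n: int
    mae_mean: float | None
    mae_sd: float | None
    icc: float
    ci_low: float
    ci_high: float
    kappa: float | None = None
    dropped: int = 0


@dataclass
class AgreementReport:
    rows: list[IndicatorAgreement]
    rater_a: str = "pred"
    rater_b: str = "ref"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows]).set_index("indicator")

    def to_dict(self) -> dict:
        return {
            "rater_a": self.rater_a,
            "rater_b": self.rater_b,
            "rows": [vars(r) for r in self.rows],
        }

    def format_table(self) -> str:
        lines = [
            f"{'indicator':<18}{'n':>5}  {'MAE (mean +- sd)':<20}{'ICC (95% CI)':<26}{'kappa':>7}",
            "-" * 78,
        ]
        for r in self.rows:
            mae_s = "-" if r.mae_mean is None else f"{r.mae_mean:.2f} +- {r.mae_sd:.2f}"
            icc_s = f"{r.icc:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})"
            kap_s = "-" if r.kappa is None else f"{r.kappa:.3f}"
            lines.append(f"{r.indicator:<18}{r.n:>5}  {mae_s:<20}{icc_s:<26}{kap_s:>7}")
        return "\n".join(lines)


def _indicator_value(m: CaseMeasurement, indicator: str):
    if indicator in ("PT", "MT", "TLL"):
        return m.curves[Region(indicator)].cobb
    if indicator == "kyphosis_T5_T12":
        return m.kyphosis_t5_t12
    if indicator.startswith("bending_"):
        if m.bending_residual is None:
            return None
        return m.bending_residual[Region(indicator.removeprefix("bending_"))][0]
    if indicator == "lenke_type":
        return None if m.lenke is None else m.lenke.curve_type
    if indicator == "sagittal_modifier":
        if m.lenke is None or m.lenke.sagittal_modifier is None:
            return None
        return _MODIFIER_CODE[m.lenke.sagittal_modifier]
    raise ValueError(f"unknown indicator {indicator!r}")


def compare_measurements(
    pred: Sequence[CaseMeasurement], ref: Sequence[CaseMeasurement], alpha: float = 0.05
) -> AgreementReport:
    """Per-indicator agreement between two measurement sets matched by case_id.

    Angle indicators get MAE and ICC(2,1); the Lenke type (integer-coded) and
    sagittal modifier additionally get Cohen's kappa.  Cases missing an
    indicator on either side are dropped listwise per indicator, with the
    count logged and recorded in the report.
    """
    ref_by_id = {m.case_id: m for m in ref}
    common = [(m, ref_by_id[m.case_id]) for m in pred if m.case_id in ref_by_id]
    if not common:
        raise ValueError("no overlapping case_ids between pred and ref")

    rows: list[IndicatorAgreement] = []
    for indicator in ANGLE_INDICATORS + CATEGORICAL_INDICATORS:
        pairs = []
        dropped = 0
        for mp, mr in common:
            vp, vr = _indicator_value(mp, indicator), _indicator_value(mr, indicator)
            if vp is None or vr is None:
                dropped += 1
            else:
                pairs.append((float(vp), float(vr)))
        if dropped:
            logger.info("indicator %s: dropped %d case(s) with missing values", indicator, dropped)
        if len(pairs) < 2:
            continue
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        categorical = indicator in CATEGORICAL_INDICATORS
        if categorical:
            logger.warning(
                "indicator %s: ICC on integer-coded categories is questionable; "
                "Cohen's kappa reported alongside", indicator,
            )
        matrix = RatingsMatrix(np.column_stack([x, y]), ("pred", "ref"), indicator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = icc_2_1(matrix, alpha=alpha)
        mae_mean: float | None
        if categorical:
            mae_mean = mae_sd = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kappa = cohen_kappa(x.astype(int), y.astype(int))
            if math.isnan(kappa):  # degenerate: a single shared label
                kappa = None
        else:
            mae_mean, mae_sd = mae(x, y)
            kappa = None
        rows.append(
            IndicatorAgreement(
                indicator, len(pairs), mae_mean, mae_sd,
                res.estimate, res.ci_low, res.ci_high, kappa, dropped,
            )
        )
    if not rows:
        raise ValueError("no indicator had >= 2 complete paired cases")
    return AgreementReport(rows)
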