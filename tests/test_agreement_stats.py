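"""MAE and ICC against independent oracles (explicit ANOVA, pingouin)."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oscillocobb import RatingsMatrix, compare_measurements, icc, icc_2_1, mae


# ---------------------------------------------------------------------------
# MAE
# ---------------------------------------------------------------------------

def test_mae_identical_sequences():
    assert mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0)


def test_mae_hand_arithmetic():
    mean, sd = mae([3.0, -5.0], [0.0, 0.0])
    assert mean == pytest.approx(4.0)
    assert sd == pytest.approx(math.sqrt(2.0), abs=1e-12)  # sample sd of {3, 5}


def test_mae_length_mismatch_raises():
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])


@settings(derandomize=True, deadline=None)
@given(st.integers(0, 500))
def test_mae_matches_elementwise_oracle_and_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 30))
    x, y = rng.normal(0, 10, n), rng.normal(0, 10, n)
    mean, sd = mae(x, y)
    d = [abs(a - b) for a, b in zip(x, y)]
    mu = sum(d) / n
    assert mean == pytest.approx(mu, abs=1e-12)
    if n > 1:
        assert sd == pytest.approx(math.sqrt(sum((v - mu) ** 2 for v in d) / (n - 1)), abs=1e-10)
    assert mae(y, x) == (mean, sd)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _anova_icc21_oracle(m: np.ndarray) -> float:
    """From-scratch two-way ANOVA decomposition, written with explicit sums."""
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_identical_raters_give_icc_1():
    subjects = np.arange(10.0)
    m = np.column_stack([subjects, subjects])
    assert icc_2_1(m).estimate == pytest.approx(1.0, abs=1e-12)


def test_constant_offset_lowers_absolute_agreement():
    rng = np.random.default_rng(0)
    subjects = rng.normal(30, 10, 40)
    aligned = np.column_stack([subjects, subjects + rng.normal(0, 1, 40)])
    shifted = aligned.copy()
    shifted[:, 1] += 8.0
    assert icc_2_1(shifted).estimate < icc_2_1(aligned).estimate


def test_zero_variance_matrix_warns_and_reports_1():
    with pytest.warns(UserWarning, match="zero total variance"):
        res = icc_2_1(np.full((5, 2), 3.0))
    assert (res.estimate, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)


@settings(derandomize=True, deadline=None)
@given(st.integers(0, 300))
def test_icc_2_1_matches_anova_oracle(seed):
    rng = np.random.default_rng(seed)
    n, k = int(rng.integers(4, 12)), int(rng.integers(2, 5))
    m = rng.normal(0, 5, (n, k)) + rng.normal(0, 4, (n, 1))
    assert icc_2_1(m).estimate == pytest.approx(_anova_icc21_oracle(m), abs=1e-10)


def test_icc_invariant_to_rater_relabeling():
    rng = np.random.default_rng(2)
    m = rng.normal(10, 4, (12, 3)) + rng.normal(0, 3, (12, 1))
    perm = m[:, [2, 0, 1]]
    assert icc_2_1(perm).estimate == pytest.approx(icc_2_1(m).estimate, abs=1e-12)


@pytest.mark.parametrize("form,label", [("1,1", "ICC(1,1)"), ("2,1", "ICC(A,1)"),
                                        ("3,1", "ICC(C,1)"), ("2,k", "ICC(A,k)")])
def test_icc_forms_match_pingouin(form, label):
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(17)
    n, k = 12, 3
    m = rng.normal(20, 6, (n, k)) + rng.normal(0, 5, (n, 1)) + rng.normal(0, 2, (1, k))
    df = pd.DataFrame(
        {
            "subj": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score").set_index("Type").loc[label]
    mine = icc(m, form=form)
    assert mine.estimate == pytest.approx(ref["ICC"], abs=1e-10)
    # pingouin rounds its CI to 2 decimals
    assert mine.ci_low == pytest.approx(ref["CI95"][0], abs=6e-3)
    assert mine.ci_high == pytest.approx(ref["CI95"][1], abs=6e-3)


def test_ci_brackets_estimate_and_narrows_with_n():
    rng = np.random.default_rng(3)

    def width(n):
        m = rng.normal(0, 10, (n, 2)) + rng.normal(0, 8, (n, 1))
        res = icc_2_1(m)
        assert res.ci_low <= res.estimate <= res.ci_high
        return res.ci_high - res.ci_low

    assert width(100) < width(10)


def test_ratings_matrix_rejects_degenerate_shapes():
    with pytest.raises(ValueError):
        RatingsMatrix(np.zeros((1, 2)))
    with pytest.raises(ValueError):
        RatingsMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# compare_measurements
# ---------------------------------------------------------------------------

def _measurements(n, noise_sd, seed):
    import dataclasses

    from oscillocobb import measure_case
    from oscillocobb.synthetic_spine import batch_simulate, preset_for_type

    presets = [dataclasses.replace(preset_for_type(k), landmark_noise_sd=noise_sd) for k in (1, 3, 5)]
    cases = batch_simulate(n, presets, seed=seed)
    pred = [measure_case(v) for v, _ in cases]
    ref = [t.as_measurement() for _, t in cases]
    return pred, ref


def test_identical_measurement_sets_agree_perfectly():
    pred, _ = _measurements(8, 0.5, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = compare_measurements(pred, pred)
    rows = {r.indicator: r for r in report.rows}
    for name in ("PT", "MT", "TLL", "kyphosis_T5_T12"):
        assert rows[name].mae_mean == 0.0
        assert rows[name].icc == pytest.approx(1.0)
    assert rows["lenke_type"].kappa == pytest.approx(1.0)


def test_noise_free_pipeline_agrees_with_truth():
    pred, ref = _measurements(9, 0.0, seed=5)
    report = compare_measurements(pred, ref)
    rows = {r.indicator: r for r in report.rows}
    for name in ("PT", "MT", "TLL", "kyphosis_T5_T12", "bending_MT"):
        assert rows[name].mae_mean == pytest.approx(0.0, abs=1e-9)
        assert rows[name].icc == pytest.approx(1.0, abs=1e-9)


def test_disjoint_case_ids_raise():
    pred, ref = _measurements(4, 0.0, seed=6)
    for m in pred:
        m.case_id = "other-" + m.case_id
    with pytest.raises(ValueError, match="overlap"):
        compare_measurements(pred, ref)


def test_gaussian_noise_mae_matches_closed_form():
    """|N(0, sigma)| has mean sigma*sqrt(2/pi); check at n = 1000."""
    rng = np.random.default_rng(42)
    sigma = 3.0
    truth = rng.uniform(10, 60, 1000)
    noisy = truth + rng.normal(0, sigma, 1000)
    mean, _ = mae(noisy, truth)
    expected = sigma * math.sqrt(2.0 / math.pi)
    # SE of the mean of |N(0, s)| is s*sqrt(1 - 2/pi)/sqrt(n) ~ 0.057; allow 4 SE
    assert mean == pytest.approx(expected, abs=0.23)


def test_report_serialization_and_table():
    pred, ref = _measurements(6, 0.0, seed=9)
    report = compare_measurements(pred, ref)
    d = report.to_dict()
    assert {row["indicator"] for row in d["rows"]} >= {"PT", "MT", "TLL"}
    table = report.format_table()
    assert "MT" in table and "ICC" in table
    df = report.to_dataframe()
    assert "icc" in df.columns
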