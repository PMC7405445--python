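"""ICC(2,1) screening: ANOVA oracle, agreement vs consistency, the robust
set rule, the C-index, and the filter cascade."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from robustrad.core import FeatureID, FeatureTable, FormatError
from robustrad.robustness import (
    FilterConfig,
    RobustnessConfig,
    concordance_index,
    filter_cascade,
    icc21,
    icc31,
    robust_feature_set,
    robustness_report,
)


def icc21_by_direct_summation(x: np.ndarray):
    """Definitional oracle: two-way ANOVA mean squares by explicit sums,
    then the ICC(2,1) and F-based CI formulas applied independently."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = x.sum(axis=1) / k
    col_means = x.sum(axis=0) / n
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(0.975, n - 1, v)
    f_u = stats.f.ppf(0.975, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return icc, lower, upper


def test_icc_matches_summation_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(6, 13))
        k = int(rng.integers(3, 6))
        x = (
            rng.normal(0, 1, size=(n, k))
            + rng.normal(0, 2, size=(n, 1))
            + rng.normal(0, 1, size=(1, k))
        )
        r = icc21(x)
        icc, lo, hi = icc21_by_direct_summation(x)
        assert abs(r.icc - icc) < 1e-10
        assert abs(r.ci_low - lo) < 1e-10
        assert abs(r.ci_high - hi) < 1e-10


def test_icc_perfect_agreement_is_one_with_ci_one():
    x = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
    r = icc21(x)
    assert r.icc == 1.0 and r.ci_low == 1.0 and r.ci_high == 1.0


def test_icc_integer_matrix_against_oracle():
    x = np.array(
        [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
        dtype=float,
    )
    r = icc21(x)
    icc, lo, hi = icc21_by_direct_summation(x)
    assert r.icc == pytest.approx(icc, abs=1e-12)
    assert r.ci_low == pytest.approx(lo, abs=1e-12)
    assert (r.ci_low <= r.icc <= r.ci_high)


def test_agreement_penalizes_rater_offset_more_than_consistency():
    x = np.tile(np.array([[1.0], [2.0], [5.0], [9.0], [12.0]]), (1, 3))
    x[:, 2] += 10.0
    assert icc21(x).icc < icc31(x)
    assert icc31(x) == pytest.approx(1.0)


def test_icc_degenerate_and_error_cases():
    constant = np.full((5, 3), 2.0)
    r = icc21(constant)
    assert not r.defined and np.isnan(r.icc)
    with pytest.raises(ValueError):
        icc21(np.ones((5, 1)))
    with pytest.raises(FormatError):
        icc21(np.array([[1.0, np.nan], [2.0, 3.0]]))


# --------------------------------------------------------------------------
# report + robust set
# --------------------------------------------------------------------------

def _table(values, names):
    cols = pd.MultiIndex.from_tuples(
        [("T1c", "wt", "firstorder", n) for n in names],
        names=FeatureTable.LEVELS,
    )
    df = pd.DataFrame(values, columns=cols, index=[f"c{i}" for i in range(len(values))])
    return FeatureTable(df)


def test_report_bit_identical_feature_has_ci_low_one():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, size=(19, 1))
    orig = _table(base, ["stable"])
    perturbed = {"noise": [_table(base.copy(), ["stable"]) for _ in range(3)]}
    report = robustness_report(orig, perturbed)
    assert (report.table["ci_low"] == 1.0).all()


def test_report_fresh_noise_feature_fails_threshold():
    rng = np.random.default_rng(1)
    failures = 0
    reps = 100
    for _ in range(reps):
        orig = _table(rng.normal(0, 1, size=(19, 1)), ["junk"])
        perturbed = {
            "noise": [_table(rng.normal(0, 1, size=(19, 1)), ["junk"]) for _ in range(3)]
        }
        report = robustness_report(orig, perturbed)
        if (report.table["ci_low"] < 0.85).all():
            failures += 1
    assert failures >= 95  # non-robust with high probability


def test_robust_set_binning_exemption_and_threshold_zero():
    table = pd.DataFrame(
        [
            ("T1c", "wt", "firstorder", "a", "kspace", 0.99, 0.95, True),
            ("T1c", "wt", "firstorder", "a", "binning", 0.2, 0.1, True),
            ("T1c", "wt", "firstorder", "b", "kspace", 0.5, 0.3, True),
            ("T1c", "wt", "firstorder", "b", "binning", 0.99, 0.95, True),
        ],
        columns=["sequence", "region", "family", "name", "perturbation", "icc", "ci_low", "defined"],
    )
    from robustrad.robustness import RobustnessReport

    report = RobustnessReport(table, n_cases=19)
    robust = robust_feature_set(report, RobustnessConfig(icc_threshold=0.85))
    names = {f.name for f in robust}
    assert names == {"a"}  # failing only binning is retained; kspace failure drops
    all_kept = robust_feature_set(report, RobustnessConfig(icc_threshold=1e-9))
    assert {f.name for f in all_kept} == {"a", "b"}


def test_robust_set_size_monotone_in_threshold():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(50):
        ci = rng.uniform(0, 1)
        rows.append(("T1c", "wt", "GLCM", f"f{i}", "kspace", ci, ci, True))
        rows.append(("T1c", "wt", "GLCM", f"f{i}", "noise", ci * rng.uniform(0.8, 1.0), ci, True))
    table = pd.DataFrame(
        rows,
        columns=["sequence", "region", "family", "name", "perturbation", "icc", "ci_low", "defined"],
    )
    from robustrad.robustness import RobustnessReport

    report = RobustnessReport(table, n_cases=19)
    sizes = [
        len(robust_feature_set(report, RobustnessConfig(icc_threshold=t)))
        for t in np.linspace(0.5, 0.95, 10)
    ]
    assert all(b <= a for a, b in zip(sizes, sizes[1:]))


# --------------------------------------------------------------------------
# concordance index
# --------------------------------------------------------------------------

def test_cindex_identity_and_direction_fold():
    os = np.array([100.0, 300.0, 200.0, 800.0, 50.0])
    assert concordance_index(os, os) == 1.0
    assert concordance_index(-os, os) == 1.0


def test_cindex_five_case_toy_matches_pair_enumeration():
    values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    os = np.array([10.0, 30.0, 20.0, 50.0, 40.0])
    conc = ties = usable = 0
    for i in range(5):
        for j in range(i + 1, 5):
            if os[i] == os[j]:
                continue
            usable += 1
            if values[i] == values[j]:
                ties += 1
            elif np.sign(values[i] - values[j]) == np.sign(os[i] - os[j]):
                conc += 1
    expected = (conc + 0.5 * ties) / usable
    expected = max(expected, 1 - expected)
    assert concordance_index(values, os) == pytest.approx(expected)
    assert expected == pytest.approx(0.8)


def test_cindex_all_equal_survival_undefined():
    with pytest.raises(ValueError):
        concordance_index(np.array([1.0, 2.0]), np.array([5.0, 5.0]))


# --------------------------------------------------------------------------
# filter cascade
# --------------------------------------------------------------------------

def _cascade_table():
    rng = np.random.default_rng(9)
    n = 20
    os = rng.uniform(100, 900, size=n)
    cols = {
        "constant": np.full(n, 3.0),
        "one_nonzero": np.zeros(n),
        "predictive": os + rng.normal(0, 20, n),
        "noise": rng.normal(0, 1, n),
    }
    cols["one_nonzero"][4] = 7.0
    values = np.column_stack(list(cols.values()))
    mi = pd.MultiIndex.from_tuples(
        [("T1c", "wt", "firstorder", n_) for n_ in cols],
        names=FeatureTable.LEVELS,
    )
    df = pd.DataFrame(values, columns=mi, index=[f"c{i}" for i in range(n)])
    return FeatureTable(df), os


def test_cascade_stages_and_counts():
    table, os = _cascade_table()
    ids, counts = filter_cascade(table, os, robust_ids=None)
    names = [f.name for f in ids]
    assert "constant" not in names  # zero MAD
    assert "one_nonzero" not in names  # non-zero in one case only
    assert "predictive" in names
    vals = list(counts.values())
    assert vals == sorted(vals, reverse=True)  # non-increasing chain
    assert counts["input"] == 4


def test_cascade_idempotent():
    table, os = _cascade_table()
    ids, _ = filter_cascade(table, os, robust_ids=None)
    sub = table.subset(ids)
    ids2, counts2 = filter_cascade(sub, os, robust_ids=None)
    assert ids2 == ids
    assert counts2["input"] == counts2["predictive"]


def test_cascade_respects_robust_restriction():
    table, os = _cascade_table()
    keep = {f for f in table.feature_ids if f.name == "predictive"}
    ids, counts = filter_cascade(table, os, robust_ids=keep)
    assert [f.name for f in ids] == ["predictive"]
    assert counts["robust"] == 1
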