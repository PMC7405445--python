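"""ICC(2,1) agreement screening across perturbed variants, and the
downstream feature-filter cascade.

The intraclass correlation is the two-way random-effects, absolute-agreement,
single-rater form

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with n targets (cases), k raters (the unperturbed measurement plus the
perturbed variants), and MSR/MSC/MSE the rows/columns/error mean squares of
the two-way ANOVA.  Absolute agreement (not consistency) penalizes a
systematic offset a perturbation introduces, which is what matters when a
trained model is transferred.  The 95% confidence interval is the standard
F-based interval; the robustness cut-off acts on its lower bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureID, FeatureTable, FormatError, check_aligned


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_err: float
    n_targets: int
    n_raters: int
    defined: bool = True


@dataclass
class RobustnessConfig:
    """Robustness decision rule: CI lower bound >= 0.85 in every tested
    perturbation family, with gray-level binning reported but exempt."""

    icc_threshold: float = 0.85
    exempt_families: tuple[str, ...] = ("binning",)
    require_all_families: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.icc_threshold < 1.0):
            raise ValueError("icc_threshold must lie in (0, 1)")


@dataclass
class FilterConfig:
    """Post-robustness cascade: zero-MAD, sparsity, C-index screens."""

    mad_rule: bool = True
    sparsity_rule: bool = True
    cindex_min: float = 0.55  # strictly greater required

    def __post_init__(self) -> None:
        if not (0.5 <= self.cindex_min < 1.0):
            raise ValueError("cindex_min must lie in [0.5, 1)")


def _anova_mean_squares(x: np.ndarray):
    """(MSR, MSC, MSE) for targets x raters arrays; x may be (..., n, k)."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    row_mean = x.mean(axis=-1, keepdims=True)
    col_mean = x.mean(axis=-2, keepdims=True)
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_tot = ((x - grand) ** 2).sum(axis=(-2, -1))
    ss_err = np.clip(ss_tot - ss_rows - ss_cols, 0.0, None)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc21(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based confidence interval.

    ``ratings`` is a complete targets x raters matrix.  A fully degenerate
    decomposition (all mean squares zero) is flagged undefined.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D targets x raters matrix")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 targets")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if np.isnan(x).any():
        raise FormatError("missing cells in the ratings matrix")

    msr, msc, mse = (float(v) for v in _anova_mean_squares(x))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr == 0 and msc == 0 and mse == 0:
        return ICCResult(np.nan, np.nan, np.nan, msr, msc, mse, n, k, defined=False)
    icc = (msr - mse) / denom if denom != 0 else np.nan
    if not np.isfinite(icc):
        return ICCResult(np.nan, np.nan, np.nan, msr, msc, mse, n, k, defined=False)

    if mse == 0 and msc == 0:  # perfect agreement
        return ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, k)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a) or not np.isfinite(b):
            return ICCResult(icc, icc, icc, msr, msc, mse, n, k)
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return ICCResult(float(icc), lower, upper, msr, msc, mse, n, k)


def icc31(ratings: np.ndarray) -> float:
    """Consistency-type ICC(3,1) point estimate (test foil, not used in the
    robustness decision)."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    msr, _msc, mse = (float(v) for v in _anova_mean_squares(x))
    denom = msr + (k - 1) * mse
    return (msr - mse) / denom if denom != 0 else np.nan


@dataclass
class RobustnessReport:
    """Long-format per-(feature, perturbation-family) ICC results."""

    table: pd.DataFrame  # columns: feature levels + perturbation, icc, ci_low, defined
    n_cases: int

    def feature_ids(self) -> list[FeatureID]:
        cols = self.table[["sequence", "region", "family", "name"]]
        return [FeatureID(*t) for t in cols.drop_duplicates().itertuples(index=False)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def robustness_report(
    original: FeatureTable, perturbed: dict[str, list[FeatureTable]]
) -> RobustnessReport:
    """Pool each family's variants into one rater set per feature.

    The unperturbed table is always included as a rater (agreement is with
    the reference measurement); family lists that already contain the
    original object (as apply_plan emits) are not double-counted.
    """
    rows = []
    for fam, tables in perturbed.items():
        raters = [original] + [t for t in tables if t is not original]
        check_aligned(raters)
        x = np.stack([t.values for t in raters], axis=-1)  # cases x feats x raters
        for j, fid in enumerate(original.feature_ids):
            mat = x[:, j, :]
            if np.isnan(mat).any():
                rows.append((*fid, fam, np.nan, np.nan, False))
                continue
            r = icc21(mat)
            rows.append((*fid, fam, r.icc, r.ci_low, r.defined))
    table = pd.DataFrame(
        rows,
        columns=["sequence", "region", "family", "name", "perturbation", "icc", "ci_low", "defined"],
    )
    return RobustnessReport(table, n_cases=len(original))


def robust_feature_set(
    report: RobustnessReport, config: RobustnessConfig | None = None
) -> set[FeatureID]:
    """Features whose CI lower bound clears the threshold in every
    non-exempt family; binning is reported but never disqualifies."""
    config = config or RobustnessConfig()
    t = report.table
    tested = t[~t["perturbation"].isin(config.exempt_families)]
    if tested.empty:
        return set(report.feature_ids())
    keys = ["sequence", "region", "family", "name"]
    ok = tested.assign(
        passes=tested["defined"] & (tested["ci_low"] >= config.icc_threshold)
    )
    grouped = ok.groupby(keys, sort=False)["passes"]
    decision = grouped.all()
    if config.require_all_families:
        n_fam = tested["perturbation"].nunique()
        decision &= ok.groupby(keys, sort=False)["perturbation"].nunique() == n_fam
    return {FeatureID(*k) for k, keep in decision.items() if keep}


def concordance_index(feature_values: np.ndarray, os_days: np.ndarray) -> float:
    """Direction-folded concordance of a feature with survival time.

    Over all pairs with distinct OS: concordant orderings count 1, feature
    ties 1/2; the result is folded as max(c, 1-c) so a feature predictive in
    either direction screens as predictive.
    """
    f = np.asarray(feature_values, dtype=float)
    t = np.asarray(os_days, dtype=float)
    if f.size != t.size or f.size < 2:
        raise ValueError("need two aligned arrays with at least 2 cases")
    dt = t[:, None] - t[None, :]
    df_ = f[:, None] - f[None, :]
    usable = np.triu(dt != 0, k=1)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("all survival times equal: C-index undefined")
    conc = (np.sign(df_) == np.sign(dt)) & usable
    ties = (df_ == 0) & usable
    c = (conc.sum() + 0.5 * ties.sum()) / n_pairs
    return float(max(c, 1.0 - c))


def filter_cascade(
    table: FeatureTable,
    os_days: np.ndarray,
    robust_ids: set[FeatureID] | None,
    config: FilterConfig | None = None,
) -> tuple[list[FeatureID], dict[str, int]]:
    """Ordered screens: robustness, zero-MAD, sparsity, C-index.

    Returns the surviving feature IDs (table column order) and the per-stage
    survivor counts.  ``robust_ids=None`` skips the robustness restriction.
    """
    config = config or FilterConfig()
    os_days = np.asarray(os_days, dtype=float)
    ids = table.feature_ids
    counts = {"input": len(ids)}

    if robust_ids is not None:
        ids = [f for f in ids if f in robust_ids]
    counts["robust"] = len(ids)

    x = table.subset(ids).values if ids else np.empty((len(table), 0))

    if config.mad_rule and ids:
        med = np.nanmedian(x, axis=0)
        mad = np.nanmedian(np.abs(x - med), axis=0)
        keep = np.nan_to_num(mad, nan=0.0) > 0
        ids = [f for f, k in zip(ids, keep) if k]
        x = x[:, keep]
    counts["nonzero_mad"] = len(ids)

    if config.sparsity_rule and ids:
        n_nonzero = (np.nan_to_num(x, nan=0.0) != 0).sum(axis=0)
        keep = n_nonzero > 1
        ids = [f for f, k in zip(ids, keep) if k]
        x = x[:, keep]
    counts["nonsparse"] = len(ids)

    if ids:
        keep = []
        for j in range(x.shape[1]):
            col = x[:, j]
            ok = np.isfinite(col)
            try:
                c = concordance_index(col[ok], os_days[ok])
            except ValueError:
                keep.append(False)
                continue
            keep.append(c > config.cindex_min)
        ids = [f for f, k in zip(ids, keep) if k]
    counts["predictive"] = len(ids)

    if not ids:
        warnings.warn("filter cascade left no surviving features", stacklevel=2)
    return ids, counts
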