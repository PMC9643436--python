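"""Batch-effect detection metrics.

The harmonization-performance metric is the fraction of features whose
distribution differs across the levels of a batch variable by the
k-sample Anderson-Darling test at p < alpha ("significant fraction").
Also provides covariate residualization, batch-covariate association
tests (chi-squared / point-biserial), and the DROP feature filter that
removes every feature significant for at least one batch variable.

No multiple-testing correction is applied anywhere: the significant
fraction is itself the summary statistic, and its null expectation
(~alpha) is part of how it is read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AD_P_FLOOR",
    "AD_P_CAP",
    "ADTestReport",
    "AssociationReport",
    "ad_test",
    "count_significant",
    "residualize",
    "association_tests",
    "drop_significant_features",
]

# the interpolated critical-value approximation for the k-sample AD test
# is only valid on this p range; values outside are clipped
AD_P_FLOOR = 0.001
AD_P_CAP = 0.25


@dataclass
class ADTestReport:
    """Per-feature AD p-values for one batch variable, plus the summary."""

    batch_var: str
    per_feature_p: pd.Series
    alpha: float
    n_features_original: int

    @property
    def significant_count(self) -> int:
        return int((self.per_feature_p < self.alpha).sum())

    @property
    def fraction(self) -> float:
        # denominator is the ORIGINAL feature count so fractions stay
        # comparable after feature dropping
        return self.significant_count / self.n_features_original

    def to_dict(self) -> dict:
        return {
            "batch_var": self.batch_var,
            "alpha": self.alpha,
            "significant_count": self.significant_count,
            "fraction": self.fraction,
            "n_features_original": self.n_features_original,
            "p_floor": AD_P_FLOOR,
            "p_cap": AD_P_CAP,
        }


@dataclass
class AssociationReport:
    """Pairwise association tests between batch variables and covariates."""

    pairs: pd.DataFrame  # columns: variable_a, variable_b, test_name, p_value

    def to_dict(self) -> dict:
        return {"pairs": self.pairs.to_dict(orient="records")}


def ad_test(values: np.ndarray, group_labels: np.ndarray) -> float:
    """k-sample Anderson-Darling p-value with midrank tie handling.

    The p-value comes from the standard interpolated critical-value
    approximation and is clipped to [0.001, 0.25]; identical
    distributions therefore report the cap, never exactly 1.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2:
        raise ValidationError("AD test needs at least 2 groups")
    for g, arr in zip(pd.unique(group_labels), groups):
        if len(arr) < 2:
            raise ValidationError(
                f"AD test group {g!r} has fewer than 2 observations"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns when p hits the clip
        res = stats.anderson_ksamp(groups, midrank=True)
    return float(np.clip(res.pvalue, AD_P_FLOOR, AD_P_CAP))


def count_significant(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_vars: list[str] | None = None,
    alpha: float = 0.05,
    n_features_original: int | None = None,
) -> tuple[dict[str, ADTestReport], int]:
    """AD-significant feature counts per batch variable and their total.

    The total over batch variables is the objective the order-optimized
    sequential harmonization minimizes.
    """
    batch_vars = list(batch_vars or metadata.batch_vars)
    n_orig = n_features_original or features.n_features
    Y = features.values
    reports: dict[str, ADTestReport] = {}
    total = 0
    for var in batch_vars:
        labels = metadata.batch_labels(var).to_numpy()
        pvals = pd.Series(
            [ad_test(Y[f].to_numpy(), labels) for f in Y.columns],
            index=Y.columns,
            name=var,
        )
        rep = ADTestReport(var, pvals, alpha, n_orig)
        reports[var] = rep
        total += rep.significant_count
    return reports, total


def _covariate_design(
    metadata: SampleMetadata, covariate_names: list[str]
) -> np.ndarray:
    """Intercept + reference-coded categoricals + centered continuous."""
    n = metadata.n_samples
    cols = [np.ones(n)]
    for name in covariate_names:
        col = metadata.covariate(name)
        if name in metadata.continuous_covariates:
            x = pd.to_numeric(col).to_numpy(dtype=float)
            cols.append(x - x.mean())
        else:
            cats = sorted(col.astype(str).unique())
            for cat in cats[1:]:
                cols.append((col.astype(str) == cat).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"covariate design {covariate_names} is rank-deficient"
        )
    return X


def residualize(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    covariate_names: list[str],
) -> FeatureMatrix:
    """Replace each feature by its OLS residual on the covariate design.

    Used to ask how much apparent batch effect survives once clinical
    structure is regressed out before testing.
    """
    X = _covariate_design(metadata, covariate_names)
    Y = features.values.to_numpy()
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return features.with_values(Y - X @ B)


def association_tests(
    metadata: SampleMetadata,
    grouping: pd.Series | None = None,
) -> AssociationReport:
    """Test every batch variable (and optional inferred grouping) against
    every clinical covariate and every other batch variable.

    Categorical-categorical pairs use the chi-squared test of independence;
    binary-continuous pairs use the point-biserial correlation t-test.
    Categorical variables with more than two levels against a continuous
    covariate fall back to one-way ANOVA (flagged ``anova_extension``).
    Constant variables are skipped with a warning.
    """
    batch_like: dict[str, pd.Series] = {
        v: metadata.batch_labels(v) for v in metadata.batch_vars
    }
    if grouping is not None:
        batch_like[str(grouping.name or "grouping")] = grouping.astype(str)

    rows = []

    def _chi2(name_a, a, name_b, b):
        tab = pd.crosstab(a, b)
        if tab.values.sum() == 0:
            raise ValidationError(f"empty contingency table {name_a} x {name_b}")
        res = stats.chi2_contingency(tab)
        rows.append((name_a, name_b, "chi_squared", float(res.pvalue)))

    def _cat_cont(name_a, a, name_b, x):
        levels = pd.unique(a)
        if len(levels) == 2:
            ind = (a == levels[1]).astype(float)
            r, p = stats.pointbiserialr(ind, x)
            rows.append((name_a, name_b, "point_biserial", float(p)))
        else:
            groups = [x[a == lv] for lv in levels]
            _, p = stats.f_oneway(*groups)
            rows.append((name_a, name_b, "anova_extension", float(p)))

    clin_cat = list(metadata.categorical_covariates)
    if metadata.event_col is not None:
        clin_cat.append(metadata.event_col)
    clin_cont = list(metadata.continuous_covariates)
    if metadata.time_col is not None:
        clin_cont.append(metadata.time_col)

    for name_a, a in batch_like.items():
        if a.nunique() < 2:
            logger.warning("skipping constant variable %r", name_a)
            continue
        for name_b in clin_cat:
            b = metadata.covariate(name_b).astype(str)
            if b.nunique() < 2:
                logger.warning("skipping constant covariate %r", name_b)
                continue
            _chi2(name_a, a, name_b, b)
        for name_b in clin_cont:
            x = pd.to_numeric(metadata.covariate(name_b)).to_numpy(dtype=float)
            if np.ptp(x) == 0:
                logger.warning("skipping constant covariate %r", name_b)
                continue
            _cat_cont(name_a, a.to_numpy(), name_b, x)
    # batch x batch pairs
    names = list(batch_like)
    for i, name_a in enumerate(names):
        for name_b in names[i + 1:]:
            a, b = batch_like[name_a], batch_like[name_b]
            if a.nunique() < 2 or b.nunique() < 2:
                continue
            _chi2(name_a, a, name_b, b)
    return AssociationReport(
        pd.DataFrame(rows, columns=["variable_a", "variable_b", "test_name", "p_value"])
    )


def drop_significant_features(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_vars: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[FeatureMatrix, list[str]]:
    """DROP filter: remove features AD-significant for >= 1 batch variable."""
    reports, _ = count_significant(features, metadata, batch_vars, alpha)
    sig = pd.Series(False, index=features.feature_names)
    for rep in reports.values():
        sig |= rep.per_feature_p < alpha
    dropped = list(features.feature_names[sig])
    if len(dropped) == features.n_features:
        raise ValidationError(
            "all features significant for some batch variable; "
            "review the significance threshold before dropping"
        )
    kept = [f for f in features.feature_names if f not in set(dropped)]
    return features.subset_features(kept), dropped
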