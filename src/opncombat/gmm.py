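"""Latent binary grouping from feature bimodality.

Multimodal feature distributions usually mean an unobserved variable —
a scanner setting nobody recorded, or an unmeasured clinical subtype —
splits the samples. Each feature is z-scored and fitted with a
two-component univariate Gaussian mixture; the feature whose mixture
best improves on a single Gaussian (by BIC, tie-broken by standardized
component separation) donates its maximum-posterior labels as the
inferred grouping.

The grouping can then be fed to the order-optimized harmonizer in two
ways: as an extra batch variable whose effect is removed
(``opnested_plus_gmm``) or as a protected covariate whose effect is
preserved (``opnested_minus_gmm``). Which is right depends on whether
the hidden variable is technical or biological — the data alone cannot
say.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .data import FeatureMatrix, SampleMetadata, ValidationError
from .detect import count_significant
from .nested import HarmonizationReport, opnested

logger = logging.getLogger(__name__)

__all__ = [
    "GMMGrouping",
    "NoGroupingFoundError",
    "fit_feature_gmm",
    "select_grouping",
    "opnested_plus_gmm",
    "opnested_minus_gmm",
    "GROUPING_VAR",
]

GROUPING_VAR = "gmm_grouping"
N_RESTARTS = 10
EM_TOL = 1e-6
MIN_SAMPLES = 10


class NoGroupingFoundError(ValidationError):
    """No feature shows usable bimodality; use plain order-optimized
    harmonization instead."""


@dataclass
class GMMGrouping:
    labels: pd.Series               # 'g0'/'g1' per sample
    source_feature: str
    means: np.ndarray               # shape (2,) on the z-scored feature
    variances: np.ndarray
    weights: np.ndarray
    selection_score: float
    candidate_scores: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "source_feature": self.source_feature,
            "selection_score": float(self.selection_score),
            "means": [float(m) for m in self.means],
            "variances": [float(v) for v in self.variances],
            "weights": [float(w) for w in self.weights],
            "labels": {str(k): str(v) for k, v in self.labels.items()},
            "candidate_scores": {
                k: float(v) for k, v in self.candidate_scores.items()
            },
        }


def _separation(means: np.ndarray, variances: np.ndarray) -> float:
    return float(abs(means[0] - means[1]) / np.sqrt(variances.max()))


def fit_feature_gmm(
    values: np.ndarray, seed: int
) -> tuple[dict, np.ndarray, float]:
    """Two-component EM fit of one feature with seeded restarts.

    Returns ``(params, labels, selection_score)`` where the score is the
    BIC improvement of the 2-component fit over a single Gaussian
    (positive = bimodality pays for its extra parameters). Labels are
    maximum-posterior component assignments in {0, 1}.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < MIN_SAMPLES:
        raise ValidationError(
            f"GMM fitting needs at least {MIN_SAMPLES} samples, got {x.shape[0]}"
        )
    if not np.isfinite(x).all():
        raise ValidationError("GMM fitting requires finite values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm2 = GaussianMixture(
            n_components=2,
            n_init=N_RESTARTS,
            tol=EM_TOL,
            max_iter=300,
            random_state=seed,
            reg_covar=1e-10,
        ).fit(x)
        gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    score = float(gm1.bic(x) - gm2.bic(x))
    labels = gm2.predict(x)
    params = {
        "means": gm2.means_.ravel().copy(),
        "variances": gm2.covariances_.ravel().copy(),
        "weights": gm2.weights_.copy(),
    }
    return params, labels, score


def select_grouping(
    features: FeatureMatrix,
    seed: int = 0,
    min_group_fraction: float = 0.05,
) -> GMMGrouping:
    """Fit every feature, rank by bimodality score, return the best grouping.

    Features are z-scored before fitting so scores are comparable across
    heterogeneous feature scales. Candidates whose smaller component holds
    fewer than ``min_group_fraction`` of samples (or fewer than 2 samples)
    are discarded: a near-empty level cannot be harmonized and destabilizes
    the empirical-Bayes step.
    """
    Y = features.values
    n = features.n_samples
    min_count = max(2, int(np.ceil(min_group_fraction * n)))
    candidate_scores: dict[str, float] = {}
    eligible: list[tuple[float, float, str, dict, np.ndarray]] = []
    rng = np.random.default_rng(seed)
    for name in Y.columns:
        x = Y[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        feat_seed = int(rng.integers(0, 2**31 - 1))
        try:
            params, labels, score = fit_feature_gmm(z, feat_seed)
        except ValidationError:
            raise
        candidate_scores[name] = score
        counts = np.bincount(labels, minlength=2)
        if counts.min() < min_count:
            continue
        if score <= 0:  # one Gaussian explains it at least as well
            continue
        sep = _separation(params["means"], params["variances"])
        eligible.append((score, sep, name, params, labels))
    if not eligible:
        raise NoGroupingFoundError(
            "no feature shows a usable two-component structure; "
            "run plain order-optimized harmonization instead"
        )
    eligible.sort(key=lambda t: (-t[0], -t[1], t[2]))
    score, _, name, params, labels = eligible[0]
    label_series = pd.Series(
        np.where(labels == 0, "g0", "g1"), index=features.sample_ids,
        name=GROUPING_VAR,
    )
    return GMMGrouping(
        labels=label_series,
        source_feature=name,
        means=params["means"],
        variances=params["variances"],
        weights=params["weights"],
        selection_score=score,
        candidate_scores=candidate_scores,
    )


def opnested_plus_gmm(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_vars: list[str] | None = None,
    covariate_names: list[str] | None = None,
    alpha: float = 0.05,
    eb: bool = True,
    seed: int = 0,
    min_group_fraction: float = 0.05,
    grouping: GMMGrouping | None = None,
) -> tuple[FeatureMatrix, HarmonizationReport, GMMGrouping | None]:
    """Treat the inferred grouping as one more batch effect to remove.

    The grouping joins the batch-variable list, so the permutation search
    runs over (k+1)! orders and the grouping's own significant fraction is
    part of the selection score. Falls back to plain order-optimized
    harmonization (with a warning) when no grouping is found. Pass a
    precomputed ``grouping`` to skip the per-feature mixture fits.
    """
    batch_vars = list(batch_vars or metadata.batch_vars)
    try:
        if grouping is None:
            grouping = select_grouping(features, seed, min_group_fraction)
    except NoGroupingFoundError:
        logger.warning("no GMM grouping found; falling back to plain opnested")
        harmonized, report = opnested(
            features, metadata, batch_vars, covariate_names, alpha, eb,
            mode="opnested+gmm(fallback)",
        )
        return harmonized, report, None
    meta_plus = metadata.with_batch_var(GROUPING_VAR, grouping.labels)
    harmonized, report = opnested(
        features,
        meta_plus,
        batch_vars + [GROUPING_VAR],
        covariate_names,
        alpha,
        eb,
        mode="opnested+gmm",
    )
    report.extra["gmm"] = grouping.to_dict()
    return harmonized, report, grouping


def opnested_minus_gmm(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_vars: list[str] | None = None,
    covariate_names: list[str] | None = None,
    alpha: float = 0.05,
    eb: bool = True,
    seed: int = 0,
    min_group_fraction: float = 0.05,
    grouping: GMMGrouping | None = None,
) -> tuple[FeatureMatrix, HarmonizationReport, GMMGrouping | None]:
    """Treat the inferred grouping as a protected covariate to preserve.

    The permutation search covers only the k! orders of the known batch
    variables; the grouping enters the design as a categorical covariate so
    its associated variation survives harmonization. The report records the
    grouping's own significant fraction before and after for comparison
    with the removing variant.
    """
    batch_vars = list(batch_vars or metadata.batch_vars)
    try:
        if grouping is None:
            grouping = select_grouping(features, seed, min_group_fraction)
    except NoGroupingFoundError:
        logger.warning("no GMM grouping found; falling back to plain opnested")
        harmonized, report = opnested(
            features, metadata, batch_vars, covariate_names, alpha, eb,
            mode="opnested-gmm(fallback)",
        )
        return harmonized, report, None
    meta_minus = metadata.with_categorical_covariate(GROUPING_VAR, grouping.labels)
    harmonized, report = opnested(
        features,
        meta_minus,
        batch_vars,
        list(covariate_names or []) + [GROUPING_VAR],
        alpha,
        eb,
        mode="opnested-gmm",
    )
    report.extra["gmm"] = grouping.to_dict()
    # grouping is protected, not scored, but report its fractions for context
    meta_g = metadata.with_batch_var(GROUPING_VAR, grouping.labels)
    rep_before, _ = count_significant(features, meta_g, [GROUPING_VAR], alpha)
    rep_after, _ = count_significant(harmonized, meta_g, [GROUPING_VAR], alpha)
    report.extra["gmm_fraction_before"] = rep_before[GROUPING_VAR].fraction
    report.extra["gmm_fraction_after"] = rep_after[GROUPING_VAR].fraction
    return harmonized, report, grouping
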