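"""Single-batch ComBat harmonization with parametric empirical Bayes.

The model for feature g of sample j in batch i is

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

where alpha_g is the grand mean, X the protected-covariate design,
gamma_ig / delta_ig additive and multiplicative batch effects, and
eps ~ N(0, sigma_g^2). Features are standardized, per-batch effects are
estimated and shrunk across features with a parametric empirical-Bayes
prior (normal prior on gamma, inverse-gamma on delta^2), and the fitted
effects are removed while the covariate contribution is re-added.

Constant features cannot be standardized; they are flagged and passed
through unchanged so column alignment survives the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "CombatEstimates",
    "build_design",
    "standardize",
    "eb_shrink",
    "apply_combat",
    "harmonize_single",
]

EB_TOL = 1e-4
EB_MAX_ITER = 1000


@dataclass
class Design:
    """Bookkeeping for the batch + protected-covariate design matrix."""

    batch_var: str
    levels: list[str]
    batch_onehot: np.ndarray        # n x k indicator columns, one per level
    covariate_matrix: np.ndarray    # n x q expanded covariate columns
    covariate_columns: list[str]
    batch_labels: np.ndarray        # per-sample level index into `levels`
    n_per_level: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack([self.batch_onehot, self.covariate_matrix])

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class CombatEstimates:
    """Fitted parameters of one ComBat harmonization step."""

    batch_var: str
    levels: list[str]
    feature_names: list[str]
    alpha: np.ndarray               # per-feature grand mean
    beta: np.ndarray                # q x p covariate coefficients
    covariate_columns: list[str]
    sigma2: np.ndarray              # per-feature pooled residual variance
    gamma_hat: np.ndarray           # k x p raw location effects
    delta2_hat: np.ndarray          # k x p raw scale effects
    gamma_star: np.ndarray          # k x p EB-shrunk location effects
    delta2_star: np.ndarray         # k x p EB-shrunk scale effects
    prior_params: list[dict]        # per level: gamma_bar, tau2, lamda, theta
    eb_enabled: bool
    constant_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable summary (per-level hyperparameters only)."""
        return {
            "batch_var": self.batch_var,
            "levels": list(self.levels),
            "eb_enabled": self.eb_enabled,
            "n_features": len(self.feature_names),
            "constant_features": list(self.constant_features),
            "prior_params": [
                {k: float(v) for k, v in pp.items()} for pp in self.prior_params
            ],
            "gamma_star_mean_abs": [
                float(np.mean(np.abs(row))) for row in self.gamma_star
            ],
            "delta2_star_mean": [float(np.mean(row)) for row in self.delta2_star],
        }


def build_design(
    metadata: SampleMetadata,
    batch_var: str,
    covariate_names: list[str] | None = None,
) -> Design:
    """Build the batch-indicator + protected-covariate design.

    Categorical covariates are reference-coded (first level dropped);
    continuous covariates are centered. Raises on constant covariates and
    on perfect collinearity between covariate columns and batch indicators.
    """
    covariate_names = list(covariate_names or [])
    labels = metadata.batch_labels(batch_var)
    levels = sorted(labels.unique())
    level_idx = labels.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    n = len(labels)
    onehot = np.zeros((n, len(levels)))
    onehot[np.arange(n), level_idx] = 1.0
    n_per_level = onehot.sum(axis=0)

    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    for name in covariate_names:
        col = metadata.covariate(name)
        if name in metadata.continuous_covariates:
            x = pd.to_numeric(col).to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValidationError(f"covariate {name!r} is constant")
            cov_cols.append(x - x.mean())
            cov_names.append(name)
        else:
            cats = sorted(col.astype(str).unique())
            if len(cats) < 2:
                raise ValidationError(f"covariate {name!r} is constant")
            for cat in cats[1:]:  # reference coding
                cov_cols.append((col.astype(str) == cat).to_numpy(dtype=float))
                cov_names.append(f"{name}[{cat}]")
    cov_matrix = np.column_stack(cov_cols) if cov_cols else np.empty((n, 0))

    full = np.hstack([onehot, cov_matrix])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # identify offending covariate columns by incremental rank checks
        bad = []
        base = onehot
        for j, name in enumerate(cov_names):
            cand = np.hstack([base, cov_matrix[:, : j + 1]])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                bad.append(name)
        raise ValidationError(
            f"design for batch {batch_var!r} is rank-deficient; "
            f"collinear covariate column(s): {bad or cov_names}"
        )
    return Design(
        batch_var=batch_var,
        levels=levels,
        batch_onehot=onehot,
        covariate_matrix=cov_matrix,
        covariate_columns=cov_names,
        batch_labels=level_idx,
        n_per_level=n_per_level,
    )


def standardize(
    features: FeatureMatrix, design: Design
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardize features to batch-free zero mean, unit pooled variance.

    Returns ``(Z, alpha, beta, sigma2, constant_mask)`` where
    ``Z = (Y - alpha - X beta) / sigma`` with alpha the batch-size-weighted
    grand mean and sigma2 the pooled residual variance. Constant features
    (zero pooled variance) are flagged in ``constant_mask`` and carried as
    Z = 0 so downstream steps leave them untouched.
    """
    Y = features.values.to_numpy()
    n, p = Y.shape
    if np.any(design.n_per_level < 2):
        lvl = design.levels[int(np.argmin(design.n_per_level))]
        raise ValidationError(
            f"batch level {lvl!r} has fewer than 2 samples"
        )
    X = design.matrix
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    k = design.n_levels
    props = design.n_per_level / n
    alpha = props @ B[:k]                       # grand mean
    beta = B[k:]
    cov_part = design.covariate_matrix @ beta if beta.size else np.zeros((n, p))
    stand_mean = alpha[None, :] + cov_part
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / n

    constant_mask = sigma2 <= np.finfo(float).eps * np.maximum(
        1.0, np.abs(alpha) ** 2
    )
    if constant_mask.any():
        names = list(features.feature_names[constant_mask])
        logger.warning(
            "%d constant feature(s) passed through unadjusted: %s",
            len(names), names[:5],
        )
    safe_sigma = np.where(constant_mask, 1.0, np.sqrt(sigma2))
    Z = (Y - stand_mean) / safe_sigma
    Z[:, constant_mask] = 0.0
    return Z, alpha, beta, sigma2, constant_mask


def _moments_estimates(Z: np.ndarray, design: Design) -> tuple[np.ndarray, np.ndarray]:
    """Per-level batch means and (ddof=1) variances of standardized data."""
    k, p = design.n_levels, Z.shape[1]
    gamma_hat = np.empty((k, p))
    delta2_hat = np.empty((k, p))
    for i in range(k):
        sel = design.batch_labels == i
        gamma_hat[i] = Z[sel].mean(axis=0)
        delta2_hat[i] = Z[sel].var(axis=0, ddof=1)
    return gamma_hat, delta2_hat


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, lamda, theta):
    return (0.5 * sum2 + theta) / (n / 2.0 + lamda - 1.0)


def eb_shrink(
    Z: np.ndarray,
    design: Design,
    tol: float = EB_TOL,
    max_iter: int = EB_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[dict]]:
    """Parametric empirical-Bayes shrinkage of per-batch effects.

    Hyperparameters are estimated by method of moments across features:
    the normal prior on gamma uses (gamma_bar, tau2) = (mean, variance) of
    gamma_hat; the inverse-gamma prior on delta^2 uses shape/scale (lamda,
    theta) matched to the mean and variance of delta2_hat. The conditional
    posterior means are then iterated to their joint fixed point.

    Returns ``(gamma_hat, delta2_hat, gamma_star, delta2_star, priors)``.
    """
    gamma_hat, delta2_hat = _moments_estimates(Z, design)
    k, p = gamma_hat.shape
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    priors: list[dict] = []
    for i in range(k):
        sel = design.batch_labels == i
        n_i = int(sel.sum())
        g_hat, d_hat = gamma_hat[i], delta2_hat[i]
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1) if p > 1 else 0.0
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1) if p > 1 else 0.0
        if s2 > 0:
            lamda = (2 * s2 + m**2) / s2
            theta = (m * s2 + m**3) / s2
        else:  # degenerate spread: prior collapses on the common value
            lamda, theta = 2.0 + m, m * (1.0 + m)
        priors.append(
            {"gamma_bar": g_bar, "tau2": t2, "lamda": lamda, "theta": theta}
        )

        g_old, d_old = g_hat.copy(), d_hat.copy()
        Zi = Z[sel]
        for _ in range(max_iter):
            g_new = _postmean(g_hat, g_bar, n_i, d_old, t2)
            sum2 = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = _postvar(sum2, n_i, lamda, theta)
            change = max(
                np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        else:
            raise RuntimeError(
                f"EB fixed point did not converge for batch level "
                f"{design.levels[i]!r} (last change {change:.3g})"
            )
        gamma_star[i] = g_old
        delta2_star[i] = d_old
    return gamma_hat, delta2_hat, gamma_star, delta2_star, priors


def apply_combat(
    features: FeatureMatrix, design: Design, estimates: CombatEstimates
) -> FeatureMatrix:
    """Remove fitted batch effects and re-add grand mean + covariate part."""
    if list(features.feature_names) != list(estimates.feature_names):
        raise ValidationError("estimates were fitted on different features")
    Y = features.values.to_numpy()
    n, p = Y.shape
    const = np.isin(np.asarray(features.feature_names), estimates.constant_features)
    sigma = np.where(const, 1.0, np.sqrt(estimates.sigma2))
    cov_part = (
        design.covariate_matrix @ estimates.beta
        if estimates.beta.size
        else np.zeros((n, p))
    )
    stand_mean = estimates.alpha[None, :] + cov_part
    Z = (Y - stand_mean) / sigma
    idx = design.batch_labels
    adj = (Z - estimates.gamma_star[idx]) / np.sqrt(estimates.delta2_star[idx])
    out = adj * sigma + stand_mean
    out[:, const] = Y[:, const]
    return features.with_values(out)


def harmonize_single(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_var: str,
    covariate_names: list[str] | None = None,
    eb: bool = True,
) -> tuple[FeatureMatrix, CombatEstimates]:
    """One ComBat step: standardize, (optionally) shrink, adjust.

    With ``eb=False`` the raw per-batch moments are removed exactly, which
    equalizes per-batch means and variances of every feature; with
    ``eb=True`` the effects are stabilized by shrinkage across features
    before removal.
    """
    if list(features.sample_ids) != list(metadata.sample_ids):
        raise ValidationError("features and metadata sample IDs differ")
    design = build_design(metadata, batch_var, covariate_names)
    Z, alpha, beta, sigma2, constant_mask = standardize(features, design)
    if eb:
        gamma_hat, delta2_hat, gamma_star, delta2_star, priors = eb_shrink(Z, design)
    else:
        gamma_hat, delta2_hat = _moments_estimates(Z, design)
        gamma_star, delta2_star = gamma_hat.copy(), delta2_hat.copy()
        priors = [{} for _ in design.levels]
    # constant features carry Z = 0; force neutral effects there
    gamma_star = gamma_star.copy()
    delta2_star = delta2_star.copy()
    gamma_star[:, constant_mask] = 0.0
    delta2_star[:, constant_mask] = 1.0
    gamma_hat[:, constant_mask] = 0.0
    delta2_hat[:, constant_mask] = 1.0
    estimates = CombatEstimates(
        batch_var=batch_var,
        levels=design.levels,
        feature_names=list(features.feature_names),
        alpha=alpha,
        beta=beta,
        covariate_columns=design.covariate_columns,
        sigma2=sigma2,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        prior_params=priors,
        eb_enabled=eb,
        constant_features=list(features.feature_names[constant_mask]),
    )
    return apply_combat(features, design, estimates), estimates
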