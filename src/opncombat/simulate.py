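"""Seeded synthetic datasets with planted batch, latent and survival structure.

The generator emulates the structure of multi-scanner radiomic feature
tables: a couple of hundred samples, on the order of a hundred
heterogeneously scaled continuous features, two or three imbalanced
categorical batch variables with additive (location) and multiplicative
(scale) effects, an optional latent binary grouping that makes affected
features bimodal and can be confounded with a batch variable or with
survival, protected clinical covariates, and right-censored survival
times from an exponential proportional-hazards model.

Effects are planted in standardized (SD) units on an N(0,1) base matrix,
then each feature is mapped to its own arbitrary scale and offset — the
rank-based detection tests and the PCA standardization must not care.
Every planted assignment and coefficient is returned in a truth record
so tests never have to re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import FeatureMatrix, SampleMetadata, ValidationError

__all__ = [
    "BatchSpec",
    "LatentSpec",
    "CovariateSpec",
    "SurvivalSpec",
    "SimConfig",
    "generate",
    "make_fixture",
    "FIXTURES",
]


@dataclass
class BatchSpec:
    """One categorical batch variable and its planted effects.

    ``level_probs`` are sampling probabilities unless ``exact_counts`` is
    given, in which case the level sizes are fixed and shuffled. Level 0
    is the reference; level i receives additive shift ``i*location_shift``
    SD and multiplicative scale ``scale_factor**i`` on the affected
    feature subset.
    """

    name: str
    level_probs: tuple[float, ...] = (0.5, 0.5)
    location_shift: float = 0.0
    scale_factor: float = 1.0
    fraction_affected: float = 1.0
    exact_counts: tuple[int, ...] | None = None


@dataclass
class LatentSpec:
    """Hidden binary grouping producing bimodal feature distributions."""

    separation: float = 3.0          # SD units added to group 1
    group_prob: float = 0.5
    fraction_affected: float = 1.0
    confounding_with: str | None = None   # batch-variable name or "outcome"
    confounding_strength: float = 0.0     # phi correlation / log-hazard coef


@dataclass
class CovariateSpec:
    """A protected clinical covariate with a linear effect on features."""

    name: str
    kind: str = "categorical"        # or "continuous"
    level_probs: tuple[float, ...] = (0.5, 0.5)
    effect_size: float = 0.0         # SD units per level step / per SD of x
    fraction_affected: float = 1.0


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.1
    coef_latent: float = 0.0
    coef_covariates: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3


@dataclass
class SimConfig:
    n_samples: int = 200
    n_features: int = 100
    batch_specs: list[BatchSpec] = field(default_factory=list)
    latent_spec: LatentSpec | None = None
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    survival_spec: SurvivalSpec | None = None
    heterogeneous_scales: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4 or self.n_features < 1:
            raise ValidationError("need n_samples >= 4 and n_features >= 1")
        for spec in self.batch_specs:
            probs = np.asarray(spec.level_probs, dtype=float)
            if spec.exact_counts is None and not np.isclose(probs.sum(), 1.0):
                raise ValidationError(
                    f"level_probs for {spec.name!r} must sum to 1"
                )
            if spec.scale_factor <= 0:
                raise ValidationError("scale_factor must be positive")
        if self.latent_spec is not None:
            if not 0 < self.latent_spec.group_prob < 1:
                raise ValidationError("group_prob must be in (0,1)")
        if self.survival_spec is not None:
            if not 0 <= self.survival_spec.censoring_rate < 1:
                raise ValidationError("censoring_rate must be in [0,1)")


def _draw_labels(rng, n: int, spec: BatchSpec) -> np.ndarray:
    if spec.exact_counts is not None:
        if sum(spec.exact_counts) != n:
            raise ValidationError(
                f"exact_counts for {spec.name!r} sum to "
                f"{sum(spec.exact_counts)}, expected {n}"
            )
        labels = np.repeat(np.arange(len(spec.exact_counts)), spec.exact_counts)
        rng.shuffle(labels)
        return labels
    return rng.choice(len(spec.level_probs), size=n, p=spec.level_probs)


def _confounded_binary(rng, g: np.ndarray, p: float, q: float, rho: float) -> np.ndarray:
    """Binary labels with marginal P(=1)=q and phi correlation rho with g."""
    cov = rho * np.sqrt(p * (1 - p) * q * (1 - q))
    p11 = p * q + cov
    if not (0 <= p11 <= min(p, q)) or not (0 <= q - p11 <= 1 - p):
        raise ValidationError(
            f"confounding strength {rho} infeasible for marginals "
            f"p={p}, q={q}"
        )
    prob1 = np.where(g == 1, p11 / p, (q - p11) / (1 - p))
    return (rng.uniform(size=len(g)) < prob1).astype(int)


def generate(config: SimConfig) -> tuple[FeatureMatrix, SampleMetadata, dict]:
    """Draw one dataset from the configured generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    truth: dict = {"seed": config.seed}

    X = rng.normal(size=(n, p))

    # latent grouping first: it may drive a batch variable's labels
    latent = None
    if config.latent_spec is not None:
        ls = config.latent_spec
        latent = (rng.uniform(size=n) < ls.group_prob).astype(int)
        n_aff = max(1, int(round(ls.fraction_affected * p)))
        aff = rng.choice(p, size=n_aff, replace=False)
        X[:, aff] += ls.separation * latent[:, None]
        truth["latent_labels"] = latent.tolist()
        truth["latent_affected"] = sorted(int(j) for j in aff)
        truth["latent_separation"] = ls.separation

    meta = pd.DataFrame(index=[f"S{i:04d}" for i in range(n)])
    batch_effects = {}
    for spec in config.batch_specs:
        ls = config.latent_spec
        if (
            ls is not None
            and ls.confounding_with == spec.name
            and ls.confounding_strength != 0
        ):
            if len(spec.level_probs) != 2:
                raise ValidationError(
                    "confounding with a batch variable requires 2 levels"
                )
            labels = _confounded_binary(
                rng, latent, ls.group_prob, spec.level_probs[1],
                ls.confounding_strength,
            )
        else:
            labels = _draw_labels(rng, n, spec)
        n_aff = max(1, int(round(spec.fraction_affected * p)))
        aff = rng.choice(p, size=n_aff, replace=False)
        shift = spec.location_shift * labels
        scale = spec.scale_factor ** labels
        X[:, aff] = X[:, aff] * scale[:, None] + shift[:, None]
        meta[spec.name] = [f"{spec.name}_L{l}" for l in labels]
        batch_effects[spec.name] = {
            "labels": labels.tolist(),
            "affected": sorted(int(j) for j in aff),
            "location_shift": spec.location_shift,
            "scale_factor": spec.scale_factor,
        }
    truth["batch_effects"] = batch_effects

    cov_values: dict[str, np.ndarray] = {}
    cat_names, cont_names = [], []
    for spec in config.covariate_specs:
        if spec.kind == "continuous":
            x = rng.normal(size=n)
            meta[spec.name] = x
            cont_names.append(spec.name)
        else:
            x = rng.choice(len(spec.level_probs), size=n,
                           p=np.asarray(spec.level_probs))
            meta[spec.name] = [f"{spec.name}_L{l}" for l in x]
            cat_names.append(spec.name)
        cov_values[spec.name] = x.astype(float)
        if spec.effect_size != 0:
            n_aff = max(1, int(round(spec.fraction_affected * p)))
            aff = rng.choice(p, size=n_aff, replace=False)
            X[:, aff] += spec.effect_size * x[:, None]
            truth.setdefault("covariate_effects", {})[spec.name] = {
                "affected": sorted(int(j) for j in aff),
                "effect_size": spec.effect_size,
            }

    time_col = event_col = None
    if config.survival_spec is not None:
        ss = config.survival_spec
        lp = np.zeros(n)
        coef_latent = ss.coef_latent
        ls = config.latent_spec
        if ls is not None and ls.confounding_with == "outcome":
            coef_latent += ls.confounding_strength
        if latent is not None:
            lp += coef_latent * latent
        for name, coef in ss.coef_covariates.items():
            lp += coef * cov_values[name]
        rate = ss.baseline_hazard * np.exp(lp)
        T = rng.exponential(1.0 / rate)
        if ss.censoring_rate > 0:
            # exponential censoring with rate solved so the expected
            # censored fraction matches the request
            def expected_cens(log_mu):
                mu = np.exp(log_mu)
                return np.mean(mu / (rate + mu)) - ss.censoring_rate
            log_mu = brentq(expected_cens, -30, 30)
            C = rng.exponential(1.0 / np.exp(log_mu), size=n)
            event = (T <= C).astype(int)
            obs = np.minimum(T, C)
        else:
            event = np.ones(n, dtype=int)
            obs = T
        meta["time"] = obs
        meta["event"] = event
        time_col, event_col = "time", "event"
        truth["survival"] = {
            "coef_latent": coef_latent,
            "coef_covariates": dict(ss.coef_covariates),
            "censoring_rate": ss.censoring_rate,
            "observed_censored_fraction": float(1 - event.mean()),
        }

    feat_names = [f"f{j:03d}" for j in range(p)]
    if config.heterogeneous_scales:
        scales = 10.0 ** rng.uniform(-1, 2, size=p)
        offsets = rng.normal(0, 5, size=p) * scales
        X = X * scales[None, :] + offsets[None, :]
        truth["feature_scales"] = scales.tolist()
        truth["feature_offsets"] = offsets.tolist()

    features = FeatureMatrix(pd.DataFrame(X, index=meta.index, columns=feat_names))
    metadata = SampleMetadata(
        meta,
        batch_vars=[s.name for s in config.batch_specs],
        categorical_covariates=cat_names,
        continuous_covariates=cont_names,
        time_col=time_col,
        event_col=event_col,
    )
    return features, metadata, truth


# ---------------------------------------------------------------------------
# Named fixtures used across the test suite. Sizes mirror the multi-scanner
# CT feature tables the methods target: ~100-200 samples, ~100 features,
# imbalanced 2-3 level batch variables.
# ---------------------------------------------------------------------------

def _null_config(seed, n_features=100):
    return SimConfig(
        n_samples=200,
        n_features=n_features,
        batch_specs=[
            BatchSpec("scanner", (0.5, 0.5)),
            BatchSpec("contrast", (0.4, 0.6)),
        ],
        seed=seed,
    )


def _two_batch_shift_config(seed):
    return SimConfig(
        n_samples=200,
        n_features=100,
        batch_specs=[
            BatchSpec("scanner", (0.5, 0.5), location_shift=0.8, scale_factor=1.5)
        ],
        seed=seed,
    )


def _two_batch_vars_config(seed):
    return SimConfig(
        n_samples=200,
        n_features=100,
        batch_specs=[
            BatchSpec("scanner", (0.5, 0.5), location_shift=1.0, scale_factor=1.4),
            BatchSpec("contrast", (0.45, 0.55), location_shift=0.8, scale_factor=1.3),
        ],
        seed=seed,
    )


def _confounded_latent_config(seed):
    # the hidden grouping drives bimodality, is correlated with a batch
    # variable, and carries the survival signal
    return SimConfig(
        n_samples=160,
        n_features=80,
        batch_specs=[
            BatchSpec("scanner", (0.5, 0.5), location_shift=0.8, scale_factor=1.3),
            BatchSpec("contrast", (0.45, 0.55), location_shift=0.6, scale_factor=1.2),
        ],
        latent_spec=LatentSpec(
            separation=3.0,
            group_prob=0.5,
            fraction_affected=0.8,
            confounding_with="scanner",
            confounding_strength=0.4,
        ),
        survival_spec=SurvivalSpec(
            baseline_hazard=0.1, coef_latent=1.5, censoring_rate=0.3
        ),
        seed=seed,
    )


def _lung3_like_config(seed):
    # level imbalance patterned on an 84-case two-scanner lung CT cohort:
    # contrast 34/50, spatial resolution 49/35, manufacturer 37/47
    return SimConfig(
        n_samples=84,
        n_features=100,
        batch_specs=[
            BatchSpec("contrast", exact_counts=(34, 50),
                      location_shift=0.5, scale_factor=1.2,
                      fraction_affected=0.5),
            BatchSpec("resolution", exact_counts=(49, 35),
                      location_shift=0.5, scale_factor=1.2,
                      fraction_affected=0.5),
            BatchSpec("manufacturer", exact_counts=(37, 47),
                      location_shift=0.8, scale_factor=1.3,
                      fraction_affected=0.7),
        ],
        latent_spec=LatentSpec(separation=2.5, group_prob=0.4,
                               fraction_affected=0.6),
        covariate_specs=[
            CovariateSpec("histology", "categorical", (0.5, 0.3, 0.2),
                          effect_size=0.3, fraction_affected=0.4),
            CovariateSpec("age", "continuous", effect_size=0.2,
                          fraction_affected=0.4),
        ],
        survival_spec=SurvivalSpec(
            baseline_hazard=0.1, coef_latent=1.0,
            coef_covariates={"age": 0.3}, censoring_rate=0.45,
        ),
        seed=seed,
    )


FIXTURES = {
    "null": _null_config,
    "two_batch_shift": _two_batch_shift_config,
    "two_batch_vars": _two_batch_vars_config,
    "confounded_latent": _confounded_latent_config,
    "lung3_like": _lung3_like_config,
}


def make_fixture(
    name: str, seed: int = 0, **overrides
) -> tuple[FeatureMatrix, SampleMetadata, dict]:
    """Generate one of the named study-condition fixtures.

    ``overrides`` are forwarded to the fixture's config builder (e.g.
    ``n_features=1000`` for the null-calibration runs).
    """
    if name not in FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    config = FIXTURES[name](seed, **overrides)
    return generate(config)
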