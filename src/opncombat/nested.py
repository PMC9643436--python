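"""Order-optimized sequential (nested) ComBat harmonization.

Sequential ComBat removes one batch effect at a time, but the result
depends on the order when batch variables are correlated. The optimizer
enumerates every permutation of the batch-variable list, harmonizes under
each order, scores each candidate by the total number of AD-significant
features summed over all batch variables, and returns the candidate with
the lowest total. Candidates are evaluated one at a time so only the
incumbent best matrix is ever retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

from .combat import CombatEstimates, harmonize_single
from .data import FeatureMatrix, SampleMetadata, ValidationError
from .detect import count_significant

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationReport",
    "enumerate_orders",
    "sequential_harmonize",
    "opnested",
]

MAX_BATCH_VARS = 6  # 7! = 5040 sequential pipelines is past any sane budget


@dataclass
class HarmonizationReport:
    mode: str
    batch_vars: list[str]
    selected_order: tuple[str, ...]
    candidate_scores: dict[tuple[str, ...], int]
    fractions_before: dict[str, float]
    fractions_after: dict[str, float]
    per_step_estimates: list[CombatEstimates]
    alpha: float
    covariate_names: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        best = min(self.candidate_scores.values())
        if self.candidate_scores[self.selected_order] != best:
            raise ValidationError("selected order does not attain the minimum score")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "batch_vars": list(self.batch_vars),
            "alpha": self.alpha,
            "covariates": list(self.covariate_names),
            "selected_order": list(self.selected_order),
            "candidate_scores": {
                ", ".join(order): int(score)
                for order, score in self.candidate_scores.items()
            },
            "fractions_before": {k: float(v) for k, v in self.fractions_before.items()},
            "fractions_after": {k: float(v) for k, v in self.fractions_after.items()},
            "per_step_estimates": [e.to_dict() for e in self.per_step_estimates],
            **self.extra,
        }


def enumerate_orders(batch_vars: list[str]) -> list[tuple[str, ...]]:
    """All k! orderings of the batch variables, lexicographic in input order."""
    if not batch_vars:
        raise ValidationError("need at least one batch variable")
    if len(set(batch_vars)) != len(batch_vars):
        raise ValidationError(f"duplicate batch variable names: {batch_vars}")
    return list(permutations(batch_vars))


def sequential_harmonize(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    order: tuple[str, ...] | list[str],
    covariate_names: list[str] | None = None,
    eb: bool = True,
) -> tuple[FeatureMatrix, list[CombatEstimates]]:
    """Harmonize by each batch variable in turn, feeding each step's output
    into the next."""
    current = features
    estimates: list[CombatEstimates] = []
    for var in order:
        current, est = harmonize_single(current, metadata, var, covariate_names, eb)
        estimates.append(est)
    return current, estimates


def opnested(
    features: FeatureMatrix,
    metadata: SampleMetadata,
    batch_vars: list[str] | None = None,
    covariate_names: list[str] | None = None,
    alpha: float = 0.05,
    eb: bool = True,
    mode: str = "opnested",
) -> tuple[FeatureMatrix, HarmonizationReport]:
    """Exhaustive permutation search over sequential harmonization orders.

    Every order is scored on its FINAL harmonized matrix by the total
    AD-significant feature count across all batch variables; the minimum
    wins, with ties broken by enumeration (lexicographic) order.
    """
    batch_vars = list(batch_vars or metadata.batch_vars)
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    if len(batch_vars) > MAX_BATCH_VARS:
        raise ValidationError(
            f"{len(batch_vars)} batch variables means "
            f"{math.factorial(len(batch_vars))} sequential pipelines; "
            "pass an explicit order to sequential_harmonize instead"
        )
    orders = enumerate_orders(batch_vars)
    before_reports, _ = count_significant(features, metadata, batch_vars, alpha)
    fractions_before = {v: r.fraction for v, r in before_reports.items()}

    candidate_scores: dict[tuple[str, ...], int] = {}
    best: tuple[FeatureMatrix, list[CombatEstimates], dict] | None = None
    best_score = None
    for order in orders:
        candidate, estimates = sequential_harmonize(
            features, metadata, order, covariate_names, eb
        )
        reports, total = count_significant(candidate, metadata, batch_vars, alpha)
        candidate_scores[order] = total
        logger.info("order %s -> %d significant", order, total)
        if best_score is None or total < best_score:
            best_score = total
            best = (candidate, estimates, {v: r.fraction for v, r in reports.items()})
            selected = order
    assert best is not None
    harmonized, estimates, fractions_after = best
    report = HarmonizationReport(
        mode=mode,
        batch_vars=batch_vars,
        selected_order=selected,
        candidate_scores=candidate_scores,
        fractions_before=fractions_before,
        fractions_after=fractions_after,
        per_step_estimates=estimates,
        alpha=alpha,
        covariate_names=list(covariate_names or []),
    )
    return harmonized, report
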