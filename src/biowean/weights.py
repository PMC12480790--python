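"""Relative importance of criteria and user weight adjustment.

The model's built-in relative importance of a criterion is its share of
the total coefficient mass, w_k = beta_k / sum_j beta_j.  Users can
override the weights on a 0-100 rating scale ("not important" to "very
important"); ratings are renormalized to sum to 1 and mapped back into
coefficients by rescaling the betas while conserving the total mass
sum(beta), so default ratings reproduce the unadjusted model exactly and
the utility scale stays comparable.  The intercept and the time-baseline
parameters are never touched by an adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import AdjustmentError, ConfigurationError, ValidationError
from .model import (
    CRITERIA,
    CoefficientSet,
    CriterionProfile,
    WithdrawalPrediction,
    canonical_criterion,
    predict_withdrawal,
)


@dataclass(frozen=True)
class WeightSet:
    """Per-criterion ratings (0-100) and their normalized fractions."""

    ratings: Mapping[str, float]
    normalized: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.normalized.values())
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise AdjustmentError(f"normalized weights sum to {total!r}, not 1")


def normalize_ratings(ratings: Mapping[str, float]) -> WeightSet:
    """Validate 0-100 ratings for all nine criteria and normalize to 1.

    Zero ratings stay exactly zero after normalization.  All-zero ratings
    are rejected (no importance can be allocated).
    """
    resolved: dict[str, float] = {}
    errors: list[str] = []
    for name, value in dict(ratings).items():
        try:
            canon = canonical_criterion(name)
        except ConfigurationError as exc:
            errors.append(str(exc))
            continue
        if canon in resolved:
            errors.append(f"duplicate rating for {canon!r}")
            continue
        value = float(value)
        if not (0.0 <= value <= 100.0):
            errors.append(f"rating {name}={value:g} outside the [0, 100] scale")
            continue
        resolved[canon] = value
    missing = [name for name in CRITERIA if name not in resolved]
    if missing:
        errors.append("missing rating(s): " + ", ".join(missing))
    if errors:
        raise ValidationError(errors)
    total = sum(resolved.values())
    if total == 0:
        raise AdjustmentError("all ratings are zero; at least one must be > 0")
    ordered = {name: resolved[name] for name in CRITERIA}
    normalized = {
        name: (0.0 if rating == 0 else rating / total)
        for name, rating in ordered.items()
    }
    return WeightSet(ratings=ordered, normalized=normalized)


def derive_relative_importance(coeffs: CoefficientSet) -> WeightSet:
    """Coefficient-implied weights: w_k = beta_k / sum(beta).

    The ratings are presented with the most important criterion anchored
    at 100 on the 0-100 scale; any positive rescaling yields identical
    normalized weights, so the anchor is purely presentational.
    """
    negative = [name for name, b in coeffs.betas.items() if b < 0]
    if negative:
        raise ConfigurationError(
            "relative importance undefined for negative coefficient(s): "
            + ", ".join(negative)
        )
    beta_max = max(coeffs.betas.values())
    ratings = {name: 100.0 * b / beta_max for name, b in coeffs.betas.items()}
    return normalize_ratings(ratings)


def to_percent(weights: WeightSet) -> tuple[dict[str, int], dict[str, float]]:
    """Display percentages: round-half-up of 100 x normalized weight.

    Returns ``(rounded, exact)``.  Because each entry is rounded
    independently, the rounded integers need not sum to exactly 100 (the
    default coefficient set sums to 101).
    """
    exact = {name: 100.0 * w for name, w in weights.normalized.items()}
    rounded = {name: int(math.floor(value + 0.5)) for name, value in exact.items()}
    return rounded, exact


def apply_weights(coeffs: CoefficientSet, weights: WeightSet) -> CoefficientSet:
    """Rebuild the coefficient set from adjusted weights.

    beta'_k = w_k * sum_j beta_j, conserving total coefficient mass;
    intercept and baseline parameters are unchanged.
    """
    total = coeffs.beta_total()
    betas = {name: weights.normalized[name] * total for name in CRITERIA}
    return CoefficientSet(
        intercept=coeffs.intercept,
        betas=betas,
        baseline_intercept=coeffs.baseline_intercept,
        baseline_slope=coeffs.baseline_slope,
    )


def predict_with_adjustment(
    profile: CriterionProfile,
    coeffs: CoefficientSet,
    ratings: Mapping[str, float],
) -> WithdrawalPrediction:
    """Score a profile under user-adjusted criterion weights."""
    weights = normalize_ratings(ratings)
    adjusted = apply_weights(coeffs, weights)
    return predict_withdrawal(profile, adjusted)
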