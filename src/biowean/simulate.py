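"""Synthetic vignette-study data and parameter recovery.

The published coefficients come from a stated-preference study in which
pediatric rheumatologists chose continue-vs-withdraw for hypothetical
patient vignettes, fitted with a binary logit.  This module closes the
loop: it generates vignette designs, simulates Bernoulli continue/withdraw
choices under the logit model (choice probability = logistic(U_continue)),
refits the model by maximum likelihood, and separately recovers the
log-time baseline by least squares on withdraw fractions over CID time.
The two stages mirror the model's own structure: the choice logit carries
the nine criteria, the time baseline is fit on its own.

All randomness flows through one seeded numpy Generator per operation, so
identical seeds give identical datasets, fits, and reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, SeparationError, ValidationError
from .model import CID_MAX, CID_MIN, CRITERIA, CoefficientSet, CriterionProfile


def generate_profiles(
    n: int,
    prevalence: Mapping[str, float],
    cid_range: tuple[float, float] = (CID_MIN, CID_MAX),
    seed: int = 0,
) -> list[CriterionProfile]:
    """Draw ``n`` random patient profiles.

    Flags are independent Bernoulli draws at the given per-criterion
    prevalence (criteria absent from the mapping default to 0); CID time
    is uniform on ``cid_range``, which must lie inside [6, 24] months.
    """
    lo, hi = float(cid_range[0]), float(cid_range[1])
    errors = []
    if not (CID_MIN <= lo <= hi <= CID_MAX):
        errors.append(f"cid_range {cid_range!r} must lie within [6, 24] months")
    rates = {}
    for name in CRITERIA:
        rate = float(prevalence.get(name, 0.0))
        if not (0.0 <= rate <= 1.0):
            errors.append(f"prevalence for {name} must be in [0, 1], got {rate:g}")
        rates[name] = rate
    unknown = set(prevalence) - set(CRITERIA)
    if unknown:
        errors.append("unknown criterion in prevalence: " + ", ".join(sorted(unknown)))
    if errors:
        raise ValidationError(errors)
    rng = np.random.default_rng(seed)
    cid = rng.uniform(lo, hi, size=n)
    flags = {
        name: (rng.random(n) < rates[name]).astype(int) for name in CRITERIA
    }
    return [
        CriterionProfile(
            cid_months=float(cid[i]),
            **{name: int(flags[name][i]) for name in CRITERIA},
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class VignetteDesign:
    """A set of vignettes shown to simulated raters.

    ``replicates`` is the number of raters answering every vignette;
    ``seed`` drives the choice simulation.
    """

    profiles: Sequence[CriterionProfile]
    replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) == 0:
            raise ValidationError(["design contains no vignettes"])
        if self.replicates < 1:
            raise ValidationError(["replicates must be >= 1"])

    @classmethod
    def full_factorial(
        cls, cid_months: float = 12.0, replicates: int = 50, seed: int = 0
    ) -> "VignetteDesign":
        """All 2^9 = 512 flag combinations at a fixed CID time."""
        profiles = [
            CriterionProfile(
                cid_months=cid_months,
                **dict(zip(CRITERIA, combo)),
            )
            for combo in itertools.product((0, 1), repeat=len(CRITERIA))
        ]
        return cls(profiles=profiles, replicates=replicates, seed=seed)

    @classmethod
    def random_subset(
        cls,
        n_vignettes: int,
        cid_months: float = 12.0,
        replicates: int = 50,
        seed: int = 0,
    ) -> "VignetteDesign":
        """A random subset of the full factorial (without replacement)."""
        rng = np.random.default_rng(seed)
        combos = list(itertools.product((0, 1), repeat=len(CRITERIA)))
        picks = rng.choice(len(combos), size=n_vignettes, replace=False)
        profiles = [
            CriterionProfile(cid_months=cid_months, **dict(zip(CRITERIA, combos[i])))
            for i in picks
        ]
        return cls(profiles=profiles, replicates=replicates, seed=seed)

    def design_matrix(self) -> np.ndarray:
        return np.array([[p.flags[name] for name in CRITERIA] for p in self.profiles])


@dataclass(frozen=True)
class ChoiceDataset:
    """Simulated rater choices, one row per (vignette, rater).

    ``table`` columns: vignette, rater, cid_months, the nine criterion
    flags, and chose_continue (1 = continue, 0 = withdraw).
    """

    table: pd.DataFrame
    seed: Optional[int] = None

    def to_csv(self) -> str:
        return self.table.to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str) -> "ChoiceDataset":
        import io as _io

        return cls(table=pd.read_csv(_io.StringIO(text)))


def simulate_choices(
    design: VignetteDesign, coeffs: CoefficientSet
) -> ChoiceDataset:
    """Simulate continue/withdraw choices under the stated-preference logit.

    Each rater's choice for a vignette is Bernoulli with
    P(continue) = logistic(U_continue(profile)); draws use the design's
    seed and are fully reproducible.
    """
    rng = np.random.default_rng(design.seed)
    x = design.design_matrix()
    utility = coeffs.intercept + x @ np.array([coeffs.betas[c] for c in CRITERIA])
    p_continue = 1.0 / (1.0 + np.exp(-utility))
    rows = []
    for v, profile in enumerate(design.profiles):
        draws = rng.random(design.replicates) < p_continue[v]
        for r, choice in enumerate(draws):
            rows.append(
                {
                    "vignette": v,
                    "rater": r,
                    "cid_months": profile.cid_months,
                    **profile.flags,
                    "chose_continue": int(choice),
                }
            )
    return ChoiceDataset(table=pd.DataFrame(rows), seed=design.seed)


@dataclass(frozen=True)
class ChoiceModelFit:
    """Refit result: recovered coefficients plus convergence diagnostics."""

    coeffs: CoefficientSet
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_observations: int
    std_errors: Mapping[str, float] = field(default_factory=dict)


def fit_choice_model(
    data: ChoiceDataset, baseline_from: Optional[CoefficientSet] = None
) -> ChoiceModelFit:
    """Maximum-likelihood logit refit of the choice model.

    Recovers the intercept and the nine criterion coefficients from
    simulated (or imported) choice data.  The time-baseline parameters are
    not identified by single-time choice data; they are copied from
    ``baseline_from`` (default: the packaged coefficients) — fit them
    separately with :func:`fit_time_baseline`.

    Raises :class:`SeparationError` when one action is never observed
    (the MLE does not exist) and :class:`EstimationError` on rank
    deficiency or non-convergence.
    """
    table = data.table
    y = table["chose_continue"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError(
            "all simulated choices are identical; logit estimates do not exist"
        )
    x = table[list(CRITERIA)].to_numpy(dtype=float)
    exog = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise EstimationError(
            "design matrix is rank deficient over the nine criteria; "
            "use a richer vignette design"
        )
    model = sm.Logit(y, exog)
    try:
        result = model.fit(disp=False, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise EstimationError(f"logit estimation failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise EstimationError("logit estimation did not converge")
    params = np.asarray(result.params)
    base = baseline_from or CoefficientSet.default()
    coeffs = CoefficientSet(
        intercept=float(params[0]),
        betas={name: float(params[1 + i]) for i, name in enumerate(CRITERIA)},
        baseline_intercept=base.baseline_intercept,
        baseline_slope=base.baseline_slope,
    )
    se = np.asarray(result.bse)
    return ChoiceModelFit(
        coeffs=coeffs,
        log_likelihood=float(result.llf),
        n_iterations=int(result.mle_retvals.get("iterations", -1)),
        converged=True,
        n_observations=int(len(y)),
        std_errors={
            name: float(se[1 + i]) for i, name in enumerate(CRITERIA)
        },
    )


def fit_time_baseline(
    withdraw_fractions: Mapping[float, float]
) -> tuple[float, float]:
    """Least-squares fit of withdraw fraction = a + b * ln(months).

    Returns ``(a, b)``.  Requires at least two distinct time points.
    Inputs outside [0, 1] are accepted with a warning: the linear-in-log
    baseline itself is unbounded, so unclamped model output (e.g. the
    default curve above ~20.6 months) is a legitimate fitting target.
    """
    items = sorted(dict(withdraw_fractions).items())
    months = np.array([m for m, _ in items], dtype=float)
    fractions = np.array([f for _, f in items], dtype=float)
    if len(np.unique(months)) < 2:
        raise EstimationError(
            "time-baseline fit needs >= 2 distinct CID time points"
        )
    if np.any(months <= 0):
        raise ValidationError(["CID months must be positive"])
    if np.any((fractions < 0) | (fractions > 1)):
        import warnings

        warnings.warn("withdraw fraction(s) outside [0, 1]; fitting raw values")
    slope, intercept = np.polyfit(np.log(months), fractions, deg=1)
    return float(intercept), float(slope)
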