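"""Core decision model for biologic-therapy withdrawal in nonsystemic JIA.

The model scores a child who has reached clinically inactive disease (CID)
on nine dichotomous patient/disease/treatment criteria.  A linear utility
for *continuing* biologic therapy,

    U_continue = intercept + sum_k beta_k * x_k,

is converted to a continuation probability with the logistic function, and
the predicted likelihood that pediatric rheumatologists would withdraw the
biologic is the product of a log-time baseline withdrawal probability and
the complement of the continuation probability:

    P_withdraw = clamp01(a + b * ln(CID months)) * (1 - logistic(U_continue)).

The baseline is linear in log-time, so with the default parameters it
exceeds 1 beyond roughly 20.6 months of CID; it is clamped to [0, 1] and a
flag records when clamping occurred, while the raw value stays inspectable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, InitVar
from importlib import resources
from typing import Mapping, Optional

from .errors import ConfigurationError, DomainError, ValidationError

#: Canonical criterion names, in the order the utility equation lists them.
CRITERIA: tuple[str, ...] = (
    "slow_response",
    "rf_positive",
    "flare_history",
    "joint_damage",
    "uveitis_history",
    "spine_involvement",
    "tmj_involvement",
    "treatment_failure",
    "prefer_continue",
)

#: Short symbols accepted as aliases in files and configs.
ALIASES: dict[str, str] = {
    "RS": "slow_response",
    "RF": "rf_positive",
    "F": "flare_history",
    "JD": "joint_damage",
    "U": "uveitis_history",
    "S": "spine_involvement",
    "TMJ": "tmj_involvement",
    "TF": "treatment_failure",
    "PPcontinue": "prefer_continue",
}

#: Supported CID-time domain in months (the intake slider range).
CID_MIN, CID_MAX = 6.0, 24.0


def canonical_criterion(name: str) -> str:
    """Map a criterion name or short symbol to its canonical name.

    Raises :class:`ConfigurationError` for names outside the model.
    """
    if name in CRITERIA:
        return name
    if name in ALIASES:
        return ALIASES[name]
    lowered = str(name).strip().lower()
    if lowered in CRITERIA:
        return lowered
    raise ConfigurationError(f"unknown criterion name: {name!r}")


@dataclass(frozen=True)
class CriterionProfile:
    """One child's decision inputs.

    ``cid_months`` is time in clinically inactive disease, restricted to
    the supported [6, 24] month range.  The nine flags are strictly 0/1:

    - ``slow_response``: CID reached 6-12 months after biologic start
      (0 = under 6 months; response times over 12 months are outside the
      model's support and are not representable)
    - ``rf_positive``: rheumatoid-factor-positive JIA
    - ``flare_history``: history of flares
    - ``joint_damage``: history of joint damage
    - ``uveitis_history``: history of uveitis
    - ``spine_involvement``: history of spine involvement
    - ``tmj_involvement``: temporomandibular-joint involvement
    - ``treatment_failure``: history of treatment failure with biologics
    - ``prefer_continue``: child/parents prefer to continue therapy
      (0 = prefer withdrawal)

    ``notes`` carries opaque pass-through metadata and is never used in
    computation.  A missing criterion is an input error; there is no
    imputation.
    """

    cid_months: float
    slow_response: int = 0
    rf_positive: int = 0
    flare_history: int = 0
    joint_damage: int = 0
    uveitis_history: int = 0
    spine_involvement: int = 0
    tmj_involvement: int = 0
    treatment_failure: int = 0
    prefer_continue: int = 0
    patient_id: Optional[str] = None
    notes: Optional[dict] = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if validate:
            errors = self.violations()
            if errors:
                raise ValidationError(errors)

    def violations(self) -> list[str]:
        """Collect every invariant violation (empty list = valid)."""
        errors: list[str] = []
        try:
            cid = float(self.cid_months)
            if not math.isfinite(cid):
                errors.append("cid_months must be finite")
            elif not (CID_MIN <= cid <= CID_MAX):
                errors.append(
                    f"cid_months={cid:g} outside the supported [6, 24] month range"
                )
        except (TypeError, ValueError):
            errors.append(f"cid_months={self.cid_months!r} is not a number")
        for name in CRITERIA:
            value = getattr(self, name)
            if value not in (0, 1) or isinstance(value, float):
                errors.append(f"{name}={value!r} must be exactly 0 or 1")
        return errors

    @property
    def flags(self) -> dict[str, int]:
        """The nine criterion indicators as an ordered mapping."""
        return {name: int(getattr(self, name)) for name in CRITERIA}


@dataclass(frozen=True)
class CoefficientSet:
    """Model parameters: utility intercept, nine criterion coefficients,
    and the two log-time baseline parameters.

    The packaged default reproduces the published regression exactly:
    intercept -1.61; betas 0.55 (RS), 0.57 (RF), 1.36 (F), 0.87 (JD),
    1.28 (U), 0.75 (S), 0.35 (TMJ), 1.09 (TF), 1.85 (PPcontinue);
    baseline -1.2861 + 0.7557 ln(months).
    """

    intercept: float
    betas: Mapping[str, float]
    baseline_intercept: float
    baseline_slope: float

    def __post_init__(self) -> None:
        resolved: dict[str, float] = {}
        for name, value in dict(self.betas).items():
            canon = canonical_criterion(name)
            if canon in resolved:
                raise ConfigurationError(f"duplicate coefficient for {canon!r}")
            resolved[canon] = float(value)
        missing = [name for name in CRITERIA if name not in resolved]
        if missing:
            raise ConfigurationError(
                "missing coefficient(s): " + ", ".join(missing)
            )
        ordered = {name: resolved[name] for name in CRITERIA}
        object.__setattr__(self, "betas", ordered)
        if not sum(ordered.values()) > 0:
            raise ConfigurationError("sum of criterion coefficients must be > 0")

    @classmethod
    def default(cls) -> "CoefficientSet":
        """The packaged published coefficient set."""
        text = (
            resources.files("biowean.data")
            .joinpath("default_coefficients.json")
            .read_text(encoding="utf-8")
        )
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "CoefficientSet":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"coefficient config is not valid JSON: {exc}")
        for key in ("intercept", "betas", "baseline_intercept", "baseline_slope"):
            if key not in raw:
                raise ConfigurationError(f"coefficient config missing key {key!r}")
        return cls(
            intercept=float(raw["intercept"]),
            betas=raw["betas"],
            baseline_intercept=float(raw["baseline_intercept"]),
            baseline_slope=float(raw["baseline_slope"]),
        )

    def to_json(self, pretty: bool = False) -> str:
        payload = {
            "intercept": self.intercept,
            "betas": dict(self.betas),
            "baseline_intercept": self.baseline_intercept,
            "baseline_slope": self.baseline_slope,
        }
        return json.dumps(payload, indent=2 if pretty else None)

    def beta_total(self) -> float:
        return float(sum(self.betas.values()))


@dataclass(frozen=True)
class WithdrawalPrediction:
    """Full decomposition of one withdrawal-likelihood prediction."""

    utility_continue: float
    p_continue_given_profile: float
    baseline_raw: float
    baseline_clamped: float
    p_withdraw: float
    clamped: bool

    def as_dict(self) -> dict:
        return {
            "utility_continue": self.utility_continue,
            "p_continue_given_profile": self.p_continue_given_profile,
            "baseline_raw": self.baseline_raw,
            "baseline_clamped": self.baseline_clamped,
            "p_withdraw": self.p_withdraw,
            "clamped": self.clamped,
        }


def continuation_utility(profile: CriterionProfile, coeffs: CoefficientSet) -> float:
    """Linear continuation utility: intercept + sum of beta_k * flag_k.

    Deterministic; the CID time does not enter the utility.
    """
    utility = coeffs.intercept
    for name in CRITERIA:
        utility += coeffs.betas[name] * getattr(profile, name)
    return utility


def continuation_probability(utility: float) -> float:
    """Logistic transform e^u / (1 + e^u), strictly inside (0, 1)."""
    if not math.isfinite(utility):
        raise DomainError(f"utility must be finite, got {utility!r}")
    # numerically stable two-branch form
    if utility >= 0:
        return 1.0 / (1.0 + math.exp(-utility))
    expu = math.exp(utility)
    return expu / (1.0 + expu)


def baseline_withdrawal(
    cid_months: float, coeffs: CoefficientSet, check_domain: bool = True
) -> tuple[float, float]:
    """Log-time baseline withdrawal probability.

    Returns ``(raw, clamped)`` where raw = a + b*ln(months) and clamped is
    raw truncated to [0, 1].  ``check_domain=False`` bypasses the [6, 24]
    month restriction (useful for inspecting the raw curve, e.g. its root
    near 5.48 months with the default parameters).
    """
    cid = float(cid_months)
    if check_domain and not (CID_MIN <= cid <= CID_MAX):
        raise DomainError(
            f"cid_months={cid:g} outside the supported [6, 24] month "
            "slider range"
        )
    if cid <= 0:
        raise DomainError(f"cid_months must be positive, got {cid:g}")
    raw = coeffs.baseline_intercept + coeffs.baseline_slope * math.log(cid)
    clamped = min(1.0, max(0.0, raw))
    return raw, clamped


def predict_withdrawal(
    profile: CriterionProfile, coeffs: CoefficientSet, check_domain: bool = True
) -> WithdrawalPrediction:
    """Predicted likelihood that pediatric rheumatologists would withdraw
    the biologic: baseline(CID time) x (1 - logistic(U_continue))."""
    utility = continuation_utility(profile, coeffs)
    p_continue = continuation_probability(utility)
    raw, clamped = baseline_withdrawal(
        profile.cid_months, coeffs, check_domain=check_domain
    )
    p_withdraw = clamped * (1.0 - p_continue)
    return WithdrawalPrediction(
        utility_continue=utility,
        p_continue_given_profile=p_continue,
        baseline_raw=raw,
        baseline_clamped=clamped,
        p_withdraw=p_withdraw,
        clamped=(raw != clamped),
    )
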