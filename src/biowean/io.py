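"""Reading patient profiles (JSON / CSV) and writing prediction reports.

File conventions: criterion columns/keys use the lower_snake_case
canonical names; the short regression symbols (RS, RF, F, JD, U, S, TMJ,
TF, PPcontinue) are accepted as aliases.  Unknown keys or extra CSV
columns are not errors — they are routed verbatim into the profile's
``notes`` so intake metadata passes through untouched.  Validation is
all-at-once: every violation in a record (or every bad row in a batch) is
reported in a single error.
"""

from __future__ import annotations

import io as _io
import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from ._version import __version__
from .errors import ConfigurationError, ValidationError
from .model import (
    CRITERIA,
    CoefficientSet,
    CriterionProfile,
    WithdrawalPrediction,
    canonical_criterion,
    predict_withdrawal,
)
from .weights import WeightSet, apply_weights, normalize_ratings, to_percent

_PROFILE_KEYS = ("cid_months",) + CRITERIA
_OPTIONAL_KEYS = ("patient_id", "notes")


def _coerce_flag(value):
    """Accept 0/1 as int, bool, or canonical strings; anything else is
    returned unchanged so profile validation reports it."""
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value in (0.0, 1.0) and value == int(value):
        return int(value)
    if isinstance(value, str):
        text = value.strip()
        if text in ("0", "1"):
            return int(text)
    return value


def profile_from_mapping(record: Mapping) -> CriterionProfile:
    """Build a validated profile from a parsed JSON object or CSV row."""
    known: dict = {}
    notes: dict = {}
    errors: list[str] = []
    for key, value in dict(record).items():
        if key in ("cid_months",) + _OPTIONAL_KEYS:
            known[key] = value
            continue
        try:
            canon = canonical_criterion(key)
        except ConfigurationError:
            notes[key] = value
            continue
        if canon in known:
            errors.append(f"duplicate value for criterion {canon!r}")
        known[canon] = _coerce_flag(value)
    missing = [k for k in _PROFILE_KEYS if k not in known]
    if missing:
        errors.append("missing required field(s): " + ", ".join(missing))
    if errors:
        raise ValidationError(errors)
    if notes:
        extra = known.get("notes")
        known["notes"] = {**notes, **({"notes": extra} if extra is not None else {})}
    if known.get("patient_id") is not None:
        known["patient_id"] = str(known["patient_id"])
    try:
        cid = float(known["cid_months"])
    except (TypeError, ValueError):
        raise ValidationError(
            [f"cid_months={known['cid_months']!r} is not a number"]
        )
    known["cid_months"] = cid
    return CriterionProfile(**known)


def read_profile(source: str) -> CriterionProfile:
    """Parse and validate a single-patient JSON record.

    Unknown keys become pass-through ``notes``; every violation (missing
    field, non-binary flag, CID time outside [6, 24] months) is listed in
    one :class:`ValidationError`.
    """
    try:
        record = json.loads(source)
    except json.JSONDecodeError as exc:
        raise ValidationError([f"profile is not valid JSON: {exc}"])
    if not isinstance(record, dict):
        raise ValidationError(["profile JSON must be an object"])
    return profile_from_mapping(record)


def read_batch(source: str) -> list[CriterionProfile]:
    """Parse a CSV batch (header row required) into validated profiles.

    Errors are collected per row and reported together with 1-based data
    row numbers; an empty file yields an empty list with a warning.
    Extra annotation columns are routed into each profile's notes.
    """
    frame = pd.read_csv(_io.StringIO(source), dtype=object, skip_blank_lines=True)
    if frame.empty:
        warnings.warn("batch CSV contains a header but no data rows")
        return []
    profiles: list[CriterionProfile] = []
    errors: list[str] = []
    for position, (_, row) in enumerate(frame.iterrows(), start=1):
        record = {
            key: value
            for key, value in row.items()
            if not (value is None or (isinstance(value, float) and pd.isna(value)))
        }
        blank = [
            key
            for key in row.index
            if key not in record
            and _is_required_column(key)
        ]
        try:
            if blank:
                raise ValidationError(
                    ["blank required cell(s): " + ", ".join(sorted(blank))]
                )
            profiles.append(profile_from_mapping(record))
        except ValidationError as exc:
            errors.extend(f"row {position}: {message}" for message in exc.messages)
    if errors:
        raise ValidationError(errors)
    return profiles


def _is_required_column(name: str) -> bool:
    if name == "cid_months":
        return True
    try:
        canonical_criterion(name)
        return True
    except ConfigurationError:
        return False


@dataclass(frozen=True)
class PredictionReport:
    """Machine-readable scoring result for one patient.

    ``pie`` holds the two chart fractions (withdraw vs continue) that the
    prototype displays; they always sum to 1.
    """

    patient_id: Optional[str]
    inputs: dict
    prediction: WithdrawalPrediction
    adjusted: Optional[WithdrawalPrediction] = None
    weights: Optional[WeightSet] = None
    model_version: str = __version__
    seed: Optional[int] = None

    @property
    def pie(self) -> dict[str, float]:
        shown = self.adjusted if self.adjusted is not None else self.prediction
        return {"withdraw": shown.p_withdraw, "continue": 1.0 - shown.p_withdraw}


def build_report(
    profile: CriterionProfile,
    coeffs: CoefficientSet,
    ratings: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> PredictionReport:
    """Score a profile, optionally under adjusted weights, into a report."""
    prediction = predict_withdrawal(profile, coeffs)
    adjusted = None
    weights = None
    if ratings is not None:
        weights = normalize_ratings(ratings)
        adjusted = predict_withdrawal(profile, apply_weights(coeffs, weights))
    inputs = {"cid_months": profile.cid_months, **profile.flags}
    if profile.notes:
        inputs["notes"] = dict(profile.notes)
    return PredictionReport(
        patient_id=profile.patient_id,
        inputs=inputs,
        prediction=prediction,
        adjusted=adjusted,
        weights=weights,
        seed=seed,
    )


def write_report(report: PredictionReport, pretty: bool = False) -> str:
    """Serialize a report to schema-stable JSON.

    Numeric fields are written at full precision; display-rounded percent
    fields are added alongside.  The adjusted block is present only when
    an adjustment was applied (absent, not null-filled).
    """
    payload: dict = {
        "model_version": report.model_version,
        "patient_id": report.patient_id,
        "inputs": dict(report.inputs),
        "prediction": report.prediction.as_dict(),
        "pie": dict(report.pie),
        "display": {
            "p_withdraw_percent": int(math.floor(100.0 * report.pie["withdraw"] + 0.5)),
            "p_continue_percent": int(math.floor(100.0 * report.pie["continue"] + 0.5)),
        },
    }
    if report.seed is not None:
        payload["seed"] = report.seed
    if report.adjusted is not None:
        rounded, exact = to_percent(report.weights)
        payload["adjusted"] = report.adjusted.as_dict()
        payload["weights"] = {
            "ratings": dict(report.weights.ratings),
            "normalized": dict(report.weights.normalized),
            "percent": rounded,
            "percent_exact": exact,
        }
    return json.dumps(payload, indent=2 if pretty else None)


def score_batch(
    profiles: Sequence[CriterionProfile],
    coeffs: CoefficientSet,
    ratings: Optional[Mapping[str, float]] = None,
) -> list[PredictionReport]:
    """Score every profile; exactly one report per input, never a drop."""
    return [build_report(p, coeffs, ratings=ratings) for p in profiles]
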