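"""Validators for the seventeen input-control types.

Each entry-form field declares one control type; the trigger step runs the
matching validator against the raw user input before any other execution
step.  On success the validator returns a typed RDF literal (integer,
decimal, boolean, date, dateTime or string) ready to be stored; on failure
it returns the control's error message and nothing is written.

Numeric range controls (pH, percentages, latitude, longitude, decimal
degree) are closed intervals including both endpoints.  Dates and
date-times are ISO 8601 only; the decimal separator is '.', never ','.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass
from typing import Callable, Optional

from rdflib import Literal
from rdflib.namespace import XSD

from .vocabulary import InputControlType


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    message: Optional[str] = None
    normalized: Optional[Literal] = None


_MESSAGES: dict[InputControlType, str] = {
    InputControlType.BOOLEAN: "Please use a Boolean value (true or false).",
    InputControlType.CLICK: "This control accepts click events only.",
    InputControlType.PHONE_NUMBER: "Please use a valid phone number (digits, spaces, hyphens, parentheses, optional leading +).",
    InputControlType.EMAIL_ADDRESS: "Please use a valid email address.",
    InputControlType.COMPOSITE_LITERAL: "Please provide a non-empty composite literal.",
    InputControlType.GEOJSON_STRING: 'Please provide a well-formed GeoJSON object with a "type" member.',
    InputControlType.LITERAL: "Please provide a literal value.",
    InputControlType.DATE: "Please use an ISO 8601 date (YYYY-MM-DD).",
    InputControlType.DATE_TIME: "Please use an ISO 8601 date time (YYYY-MM-DDThh:mm:ss).",
    InputControlType.DECIMAL_DEGREE: "Please use a decimal degree between -180 and 180.",
    InputControlType.FLOAT: "Please use a floating point number.",
    InputControlType.FLOAT_PH: "Please use a pH value between 0 and 14.",
    InputControlType.FLOAT_PERCENTAGE: "Please use a percentage between 0 and 100.",
    InputControlType.GEO_LATITUDE: "Please use a decimal latitude between -90 and 90.",
    InputControlType.GEO_LONGITUDE: "Please use a decimal longitude between -180 and 180.",
    InputControlType.INTEGER_PERCENTAGE: "Please use an integer percentage between 0 and 100.",
    InputControlType.POSITIVE_INTEGER: "Please use only natural numbers (1, 2, 3, ...).",
}

_FLOAT_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_EMAIL_RE = re.compile(r"^[^@\s]+@[^@\s]+\.[^@\s.]+$")


def _fail(control: InputControlType) -> ValidationResult:
    return ValidationResult(False, _MESSAGES[control])


def _ok(normalized: Optional[Literal]) -> ValidationResult:
    return ValidationResult(True, None, normalized)


def _parse_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not _FLOAT_RE.match(raw):
        return None
    return float(raw)


def _float_in_range(raw: str, lo: float, hi: float) -> Optional[Literal]:
    val = _parse_float(raw)
    if val is None or not (lo <= val <= hi):
        return None
    return Literal(raw.strip(), datatype=XSD.decimal)


def _validate_boolean(raw: str) -> Optional[Literal]:
    if raw.strip().lower() in ("true", "false"):
        return Literal(raw.strip().lower() == "true")
    return None


def _validate_phone(raw: str) -> Optional[Literal]:
    raw = raw.strip()
    if not re.match(r"^\+?[0-9 ()\-]+$", raw):
        return None
    if sum(c.isdigit() for c in raw) < 5:
        return None
    return Literal(raw)


def _validate_date(raw: str) -> Optional[Literal]:
    try:
        datetime.date.fromisoformat(raw.strip())
    except ValueError:
        return None
    return Literal(raw.strip(), datatype=XSD.date)


def _validate_date_time(raw: str) -> Optional[Literal]:
    raw = raw.strip()
    try:
        datetime.datetime.fromisoformat(raw)
    except ValueError:
        return None
    if "T" not in raw:
        return None
    return Literal(raw, datatype=XSD.dateTime)


def _validate_geojson(raw: str) -> Optional[Literal]:
    try:
        obj = json.loads(raw)
    except (ValueError, TypeError):
        return None
    if not isinstance(obj, dict) or "type" not in obj:
        return None
    return Literal(raw)


def _validate_positive_integer(raw: str) -> Optional[Literal]:
    raw = raw.strip()
    if not raw.isdigit():  # rejects signs, decimals, blanks
        return None
    if int(raw) < 1:
        return None
    return Literal(int(raw))


def _validate_integer_percentage(raw: str) -> Optional[Literal]:
    raw = raw.strip()
    if not _INT_RE.match(raw):
        return None
    if not 0 <= int(raw) <= 100:
        return None
    return Literal(int(raw))


_VALIDATORS: dict[InputControlType, Callable[[str], Optional[Literal]]] = {
    InputControlType.BOOLEAN: _validate_boolean,
    InputControlType.PHONE_NUMBER: _validate_phone,
    InputControlType.EMAIL_ADDRESS: lambda raw: Literal(raw.strip()) if _EMAIL_RE.match(raw.strip()) else None,
    InputControlType.COMPOSITE_LITERAL: lambda raw: Literal(raw) if raw.strip() else None,
    InputControlType.GEOJSON_STRING: _validate_geojson,
    InputControlType.LITERAL: lambda raw: Literal(raw),
    InputControlType.DATE: _validate_date,
    InputControlType.DATE_TIME: _validate_date_time,
    InputControlType.DECIMAL_DEGREE: lambda raw: _float_in_range(raw, -180.0, 180.0),
    InputControlType.FLOAT: lambda raw: (
        Literal(raw.strip(), datatype=XSD.decimal) if _parse_float(raw) is not None else None
    ),
    InputControlType.FLOAT_PH: lambda raw: _float_in_range(raw, 0.0, 14.0),
    InputControlType.FLOAT_PERCENTAGE: lambda raw: _float_in_range(raw, 0.0, 100.0),
    InputControlType.GEO_LATITUDE: lambda raw: _float_in_range(raw, -90.0, 90.0),
    InputControlType.GEO_LONGITUDE: lambda raw: _float_in_range(raw, -180.0, 180.0),
    InputControlType.INTEGER_PERCENTAGE: _validate_integer_percentage,
    InputControlType.POSITIVE_INTEGER: _validate_positive_integer,
}


def validate(control: InputControlType, raw: str) -> ValidationResult:
    """Validate raw form input against one of the seventeen control types.

    Failures are returned as :class:`ValidationResult` values, never raised.
    """
    if control is InputControlType.CLICK:
        # a click carries no value; any event passes
        return ValidationResult(True, None, None)
    normalized = _VALIDATORS[control](raw)
    if normalized is None:
        return _fail(control)
    return _ok(normalized)


def error_message(control: InputControlType) -> str:
    """The stable error message shown when input fails this control."""
    return _MESSAGES[control]
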