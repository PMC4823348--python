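"""Unit-string validation.

NSDF datasets that represent physical quantities carry a ``unit`` attribute
written as a plain ASCII string in SI convention.  This module implements a
closed, UDUNITS-style subset of that convention:

* base symbols: ``m s A V S F ohm mol M Hz C K cd kg g L`` ("ohm" is written
  in full because the Greek letter is not ASCII),
* the standard SI prefixes (``Y`` down to ``y``, with ``u`` for micro),
* products, quotients and integer powers: ``mS/cm^2``, ``V*s``, ``s^-1``.

Exponents may be written with or without the caret (``cm^2`` and ``cm2`` are
both accepted); the normalized form always uses the caret.  The module does
no unit conversion or dimensional analysis — it only decides whether a string
belongs to the grammar and returns its canonical spelling.
"""

from __future__ import annotations

import re

from .exceptions import UnitError

__all__ = ["validate_unit", "is_valid_unit", "BASE_UNITS", "SI_PREFIXES"]

#: Accepted base unit symbols.  ``M`` is molar concentration, ``L`` litre.
BASE_UNITS = frozenset(
    {"m", "s", "A", "V", "S", "F", "ohm", "mol", "M", "Hz", "C", "K",
     "cd", "kg", "g", "L"}
)

#: SI prefixes, ASCII only ("u" stands in for the micro sign).
SI_PREFIXES = frozenset(
    {"Y", "Z", "E", "P", "T", "G", "M", "k", "h", "da",
     "d", "c", "m", "u", "n", "p", "f", "a", "z", "y"}
)

_TERM_RE = re.compile(r"^([A-Za-z]+)(?:\^?(-?\d+))?$")


def _symbol_ok(symbol: str) -> bool:
    # A bare base symbol wins over a prefixed reading ("M" is molar, not
    # mega-nothing; "mol" is the mole, not milli-"ol").
    if symbol in BASE_UNITS:
        return True
    for plen in (2, 1):
        prefix, rest = symbol[:plen], symbol[plen:]
        if prefix in SI_PREFIXES and rest in BASE_UNITS:
            return True
    return False


def validate_unit(unit: str, allow_empty: bool = False) -> str:
    """Validate *unit* and return its normalized spelling.

    Parameters
    ----------
    unit:
        Candidate unit string, e.g. ``"mV"`` or ``"mS/cm^2"``.
    allow_empty:
        Accept the empty string, used for table columns that carry no
        physical quantity (indices, identifiers).

    Raises
    ------
    UnitError
        If the string is not ASCII, contains an unknown symbol, or does not
        parse as ``term (('*'|'/') term)*``.
    """
    if not isinstance(unit, str):
        raise UnitError(f"unit must be a string, got {type(unit).__name__}")
    if unit == "":
        if allow_empty:
            return ""
        raise UnitError("empty unit string not allowed here")
    if not unit.isascii():
        raise UnitError(f"unit contains non-ASCII characters: {unit!r} "
                        "(write 'ohm' in full, 'u' for micro)")

    compact = unit.replace(" ", "")
    parts = re.split(r"([*/])", compact)
    if parts[0] == "" or parts[-1] == "":
        raise UnitError(f"dangling operator in unit: {unit!r}")

    out: list[str] = []
    for i, part in enumerate(parts):
        if i % 2 == 1:  # operator slot
            out.append(part)
            continue
        if part == "":
            raise UnitError(f"empty term in unit: {unit!r}")
        if part == "1":
            # dimensionless numerator as in "1/s"
            out.append("1")
            continue
        m = _TERM_RE.match(part)
        if m is None:
            raise UnitError(f"cannot parse unit term {part!r} in {unit!r}")
        symbol, exponent = m.group(1), m.group(2)
        if not _symbol_ok(symbol):
            raise UnitError(f"unknown unit symbol {symbol!r} in {unit!r}")
        out.append(symbol if exponent is None else f"{symbol}^{exponent}")
    return "".join(out)


def is_valid_unit(unit: str, allow_empty: bool = False) -> bool:
    """True if :func:`validate_unit` would accept *unit*."""
    try:
        validate_unit(unit, allow_empty=allow_empty)
    except UnitError:
        return False
    return True
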