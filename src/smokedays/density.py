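"""Smoke density categories and label normalization.

NOAA HMS analysts tag each smoke plume with a density class — light, medium
or heavy — assigned upstream from GOES aerosol optical depth.  The classes
approximately correspond to PM2.5 bands of 0–10, 10–21 and 22+ µg/m³.  The
archival attribute is inconsistently encoded: older years carry the literal
strings (including ``"Dense"`` as a synonym for heavy), other years carry the
GASP-style numeric codes 5 / 16 / 27.  This module owns the single canonical
mapping from any of those encodings to the three categories.
"""

from __future__ import annotations

import enum


class Density(enum.IntEnum):
    """Smoke density category, ordered by severity (light < medium < heavy).

    The integer values (1, 2, 3) are the numeric smoke levels used by the
    population-weighted density index, where "no smoke" is 0.
    """

    LIGHT = 1
    MEDIUM = 2
    HEAVY = 3

    @property
    def numeric_level(self) -> int:
        return int(self)

    @property
    def pm25_range(self) -> str:
        """Approximate PM2.5 concentration band (µg/m³) — descriptive only."""
        return _PM25_RANGE[self]


_PM25_RANGE = {
    Density.LIGHT: "0-10 ug/m^3",
    Density.MEDIUM: "10-21 ug/m^3",
    Density.HEAVY: "22+ ug/m^3",
}


class UnknownDensityError(ValueError):
    """A density attribute value outside the documented label set.

    Carries the offending raw value and, when known, the source file so a
    run log can point at the feature that failed.
    """

    def __init__(self, raw_label: object, source: str | None = None):
        self.raw_label = raw_label
        self.source = source
        where = f" in {source}" if source else ""
        super().__init__(f"unrecognized smoke density label {raw_label!r}{where}")


# String labels seen in the archive; "dense" is the archival synonym for heavy.
_STRING_LABELS = {
    "light": Density.LIGHT,
    "medium": Density.MEDIUM,
    "heavy": Density.HEAVY,
    "dense": Density.HEAVY,
}

# GASP-style numeric density codes.
_NUMERIC_LABELS = {5: Density.LIGHT, 16: Density.MEDIUM, 27: Density.HEAVY}


def normalize_density(raw_label: object, source: str | None = None) -> Density:
    """Map a raw density attribute value to a :class:`Density`.

    Accepts the case-insensitive strings ``light`` / ``medium`` / ``heavy`` /
    ``dense`` and the numeric codes 5 / 16 / 27 in any numeric or decimal
    string rendering (``27``, ``27.0``, ``"27.000"``).

    Raises
    ------
    UnknownDensityError
        If the value is empty or outside the documented label set.
    """
    if raw_label is None:
        raise UnknownDensityError(raw_label, source)

    if isinstance(raw_label, (int, float)):
        return _numeric_density(float(raw_label), raw_label, source)

    text = str(raw_label).strip()
    if not text:
        raise UnknownDensityError(raw_label, source)
    cat = _STRING_LABELS.get(text.lower())
    if cat is not None:
        return cat
    try:
        value = float(text)
    except ValueError:
        raise UnknownDensityError(raw_label, source) from None
    return _numeric_density(value, raw_label, source)


def _numeric_density(value: float, raw: object, source: str | None) -> Density:
    if value == int(value) and int(value) in _NUMERIC_LABELS:
        return _NUMERIC_LABELS[int(value)]
    raise UnknownDensityError(raw, source)
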