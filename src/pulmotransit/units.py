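"""Lightweight semantic-unit layer for hemodynamic quantities.

The canonical internal units of the package are seconds (time), ml (volume),
ml/s (flow) and m^2 (area).  Plain floats passed to hemodynamic functions are
interpreted in canonical units; a :class:`Quantity` carrying any other unit is
rejected rather than silently converted, so a cardiac output expressed in
l/min can never be mistaken for ml/s.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnitError(ValueError):
    """Raised when a quantity arrives in a non-canonical unit without explicit conversion."""


#: multiplicative conversion factors between compatible units
_CONVERSIONS: dict[tuple[str, str], float] = {
    ("l/min", "ml/s"): 1000.0 / 60.0,
    ("ml/s", "l/min"): 60.0 / 1000.0,
    ("ml", "l"): 1e-3,
    ("l", "ml"): 1e3,
    ("s", "min"): 1.0 / 60.0,
    ("min", "s"): 60.0,
    ("m", "cm"): 100.0,
    ("cm", "m"): 0.01,
}


@dataclass(frozen=True)
class Quantity:
    """A scalar with an explicit unit label."""

    value: float
    unit: str

    def to(self, unit: str) -> "Quantity":
        """Convert to a compatible unit, raising :class:`UnitError` otherwise."""
        if unit == self.unit:
            return self
        try:
            factor = _CONVERSIONS[(self.unit, unit)]
        except KeyError:
            raise UnitError(f"no conversion from {self.unit!r} to {unit!r}") from None
        return Quantity(self.value * factor, unit)

    def __float__(self) -> float:
        return float(self.value)


def expect(value: "float | Quantity", unit: str, name: str = "value") -> float:
    """Return ``value`` in ``unit``.

    Floats are taken at face value (canonical-unit contract).  A
    :class:`Quantity` must already carry ``unit``; anything else is rejected
    with a hint to convert explicitly via :meth:`Quantity.to`.
    """
    if isinstance(value, Quantity):
        if value.unit != unit:
            raise UnitError(
                f"{name} given in {value.unit!r} but {unit!r} required; "
                f"convert explicitly with .to({unit!r})"
            )
        return float(value.value)
    return float(value)
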