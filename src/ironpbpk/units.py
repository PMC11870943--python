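"""Unit handling.

Canonical internal units are micromoles (amounts), micromoles/litre
(concentrations), litres, and hours.  Iron mass units convert through the
atomic mass of iron, 55.845 g/mol (1 mg Fe = 1000/55.845 umol).
"""

from __future__ import annotations

FE_MOLAR_MASS_G_PER_MOL = 55.845

#: accepted dose-amount units; per-kg units require a body weight
DOSE_UNITS = ("umol", "mg", "umol/kg", "mg/kg")
#: accepted observation units (concentration or amount)
VALUE_UNITS = ("umol/L", "mg/L", "umol", "mg")


def mg_to_umol(mg: float) -> float:
    """Convert a mass of elemental iron in mg to micromoles."""
    return mg * 1e3 / FE_MOLAR_MASS_G_PER_MOL


def umol_to_mg(umol: float) -> float:
    return umol * FE_MOLAR_MASS_G_PER_MOL / 1e3


def dose_to_umol(amount: float, units: str, body_weight_kg: float | None = None) -> float:
    """Normalize a dose to micromoles of iron.

    Per-kilogram units scale by *body_weight_kg*, which must then be given.
    """
    if units not in DOSE_UNITS:
        raise ValueError(f"unknown dose units {units!r}; expected one of {DOSE_UNITS}")
    if units.endswith("/kg"):
        if body_weight_kg is None:
            raise ValueError(f"dose units {units!r} require a body weight")
        amount = amount * body_weight_kg
        units = units[: -len("/kg")]
    return mg_to_umol(amount) if units == "mg" else amount


def value_to_canonical(value: float, units: str) -> tuple[float, str]:
    """Normalize an observed value to (umol/L) or (umol); returns (value, units)."""
    if units not in VALUE_UNITS:
        raise ValueError(f"unknown value units {units!r}; expected one of {VALUE_UNITS}")
    if units == "mg/L":
        return mg_to_umol(value), "umol/L"
    if units == "mg":
        return mg_to_umol(value), "umol"
    return value, units


def parse_dose_string(text: str, body_weight_kg: float | None = None) -> float:
    """Parse strings like ``"1000 mg"``, ``"0.2 umol/kg"`` or ``"30mg/kg"`` to umol."""
    s = text.strip()
    for u in sorted(DOSE_UNITS, key=len, reverse=True):
        if s.endswith(u):
            try:
                num = float(s[: -len(u)].strip())
            except ValueError as exc:
                raise ValueError(f"cannot parse dose {text!r}") from exc
            return dose_to_umol(num, u, body_weight_kg)
    raise ValueError(f"dose {text!r} must carry one of the units {DOSE_UNITS}")
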