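"""Unit normalization to the internal SI system.

All model computation is carried out in SI base combinations
(m, s, Pa, mol·m⁻³, T).  Literature parameter tables for tumor transport
mix molar concentrations, centimetres and millimetres of mercury; a single
conversion point avoids unit mistakes in composite rate constants such as
``K_ON·C_rec``.
"""

from __future__ import annotations

__all__ = ["normalize_units", "UnknownUnitError", "SI_FACTORS"]


class UnknownUnitError(ValueError):
    """Raised for a unit token outside the documented set."""


#: Multiplicative factor taking ``value [unit]`` to the SI combination.
SI_FACTORS: dict[str, float] = {
    # concentration
    "mol/m^3": 1.0,
    "mol/m3": 1.0,
    "M": 1.0e3,            # 1 mol/L = 1e3 mol/m^3
    "mM": 1.0,
    "uM": 1.0e-3,
    # inverse-concentration rate (binding constants)
    "1/M/s": 1.0e-3,       # M^-1 s^-1 -> m^3 mol^-1 s^-1
    "m^3/mol/s": 1.0,
    # diffusivity
    "m^2/s": 1.0,
    "cm^2/s": 1.0e-4,
    "cm2/s": 1.0e-4,
    # velocity / permeability
    "m/s": 1.0,
    "cm/s": 1.0e-2,
    "um/s": 1.0e-6,
    # pressure
    "Pa": 1.0,
    "kPa": 1.0e3,
    "mmHg": 133.322387415,
    # length
    "m": 1.0,
    "cm": 1.0e-2,
    "mm": 1.0e-3,
    "um": 1.0e-6,
    "nm": 1.0e-9,
    # magnetic flux density
    "T": 1.0,
    "mT": 1.0e-3,
    # time
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    # dimensionless
    "-": 1.0,
    "1": 1.0,
}


def normalize_units(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the SI base combination.

    The conversion is a single multiplication and therefore exact to double
    precision.  Unknown tokens raise :class:`UnknownUnitError` naming the
    offending token.

    >>> normalize_units(1.5e2, "1/M/s")
    0.15
    >>> normalize_units(3.40e-6, "cm^2/s")
    3.4e-10
    """
    try:
        factor = SI_FACTORS[unit]
    except KeyError:
        raise UnknownUnitError(f"unknown unit token: {unit!r}") from None
    return value * factor
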