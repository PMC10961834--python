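"""Shared physical-quantity containers and uncertainty arithmetic.

All enthalpies are carried in kJ/mol with an (expanded, as-reported)
uncertainty and an explicit reference temperature.  Uncertainties are
combined in quadrature throughout the package; rounding happens only at
report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

#: CODATA value of the molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Thermodynamic reference temperature, K.
T_REF = 298.15

VALID_KINDS = frozenset(
    {
        "fusion",
        "vaporization",
        "sublimation",
        "formation_cr",
        "formation_g",
        "combustion",
    }
)


class ThermoError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class EnthalpyValue:
    """An enthalpy with uncertainty, reference temperature and provenance.

    Parameters
    ----------
    value : float
        Enthalpy in kJ/mol.
    u : float
        Uncertainty in kJ/mol (expanded, i.e. on the level it is reported).
    T : float
        Temperature the value refers to, K.
    kind : str
        One of ``fusion``, ``vaporization``, ``sublimation``,
        ``formation_cr``, ``formation_g``, ``combustion``.
    route : str
        Free-text provenance (e.g. ``"fusion+vaporization"``).
    """

    value: float
    u: float = 0.0
    T: float = T_REF
    kind: str = "formation_cr"
    route: str = ""

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ThermoError(f"uncertainty must be >= 0, got {self.u}")
        if self.kind not in VALID_KINDS:
            raise ThermoError(f"unknown enthalpy kind {self.kind!r}")

    def with_route(self, route: str) -> "EnthalpyValue":
        return replace(self, route=route)

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "u": self.u,
            "T": self.T,
            "kind": self.kind,
            "route": self.route,
        }


def combine_quadrature(us: list[float] | tuple[float, ...]) -> float:
    """Root-sum-square combination of independent uncertainty components."""
    us = list(us)
    if any(u < 0 for u in us):
        raise ThermoError("uncertainty components must be >= 0")
    return math.sqrt(math.fsum(u * u for u in us))
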