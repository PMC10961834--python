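"""Chickos temperature adjustment of phase-change enthalpies.

Fusion, vaporization and sublimation enthalpies measured at T_obs are
moved to 298.15 K with the empirical heat-capacity corrections of
Chickos and co-workers, all of the affine form

    dH(T_target) = dH(T_obs) + c * (T_obs - T_target) / 1000

with c (J/mol/K) a linear function of the crystalline and/or liquid
molar heat capacity:

    sublimation    c = 0.75  + 0.15 * Cp(cr)
    vaporization   c = 10.58 + 0.26 * Cp(l)
    fusion         c = 0.15 * Cp(cr) - 0.26 * Cp(l) - 9.83

(the fusion coefficient is the sublimation one minus the vaporization
one, which keeps the three adjustments thermodynamically consistent).
The coefficients ship as versioned config data
(``data/chickos_coefficients.json``) rather than being hard-coded, so a
different parameterization can be swapped in without touching code.

The module also fits the molar heat-capacity polynomial Cp(T) used to
supply Cp(cr) from DSC data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .quantities import EnthalpyValue, T_REF, ThermoError, combine_quadrature

#: Fraction of the adjustment term taken as its standard uncertainty.
#: Configurable per call; see docs/methods.md for the rationale.
DEFAULT_TERM_U_FRACTION = 0.1


@dataclass(frozen=True)
class AdjustmentInputs:
    """Inputs for one temperature adjustment.

    ``dH_at_T``/``u`` in kJ/mol at ``T_obs`` (K); heat capacities are
    molar, J/mol/K; ``Cp_l`` may be NaN for the sublimation adjustment
    and ``Cp_cr`` for the vaporization one.
    """

    dH_at_T: float
    u: float
    T_obs: float
    Cp_cr: float = float("nan")
    Cp_l: float = float("nan")
    T_target: float = T_REF

    def __post_init__(self) -> None:
        if self.T_obs <= 0 or self.T_target <= 0:
            raise ThermoError("temperatures must be > 0")
        if self.u < 0:
            raise ThermoError("uncertainty must be >= 0")


@dataclass(frozen=True)
class CpPolynomial:
    """Least-squares polynomial Cp(T), molar J/mol/K, valid on T_range."""

    coefficients: tuple[float, ...]  # constant first
    T_range: tuple[float, float]

    def __call__(self, T: float) -> float:
        lo, hi = self.T_range
        if not (lo <= T <= hi):
            raise ThermoError(f"T={T} outside fitted range [{lo}, {hi}]")
        return float(np.polynomial.polynomial.polyval(T, self.coefficients))


@dataclass(frozen=True)
class ChickosCoefficients:
    """One affine coefficient set c = a + b_cp_cr*Cp(cr) + b_cp_l*Cp(l)."""

    a: float
    b_cp_cr: float = 0.0
    b_cp_l: float = 0.0

    def coefficient(self, Cp_cr: float = float("nan"), Cp_l: float = float("nan")) -> float:
        c = self.a
        if self.b_cp_cr != 0.0:
            if not np.isfinite(Cp_cr):
                raise ThermoError("Cp(cr) required but not supplied")
            c += self.b_cp_cr * Cp_cr
        if self.b_cp_l != 0.0:
            if not np.isfinite(Cp_l):
                raise ThermoError("Cp(l) required but not supplied")
            c += self.b_cp_l * Cp_l
        return c


def load_coefficients(path=None) -> dict[str, ChickosCoefficients]:
    """Load the per-process coefficient sets (packaged default if no path)."""
    if path is None:
        text = resources.files("aromatherm.data").joinpath(
            "chickos_coefficients.json"
        ).read_text()
        raw = json.loads(text)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out = {}
    for process in ("fusion", "vaporization", "sublimation"):
        spec = raw[process]
        out[process] = ChickosCoefficients(
            a=spec["a"],
            b_cp_cr=spec.get("b_cp_cr", 0.0),
            b_cp_l=spec.get("b_cp_l", 0.0),
        )
    return out


def fit_cp_polynomial(
    data: list[tuple[float, float]], degree: int
) -> CpPolynomial:
    """Least-squares polynomial through (T, Cp) points, storing the range."""
    if len(data) < degree + 1:
        raise ThermoError(
            f"need >= {degree + 1} points for degree {degree}, got {len(data)}"
        )
    T = np.array([d[0] for d in data], dtype=float)
    Cp = np.array([d[1] for d in data], dtype=float)
    if len(np.unique(T)) < degree + 1:
        raise ThermoError("temperatures not distinct enough; underdetermined fit")
    series = np.polynomial.Polynomial.fit(T, Cp, deg=degree)
    coefs = series.convert().coef
    return CpPolynomial(
        coefficients=tuple(float(c) for c in coefs),
        T_range=(float(T.min()), float(T.max())),
    )


def _adjust(
    inputs: AdjustmentInputs,
    coeffs: ChickosCoefficients,
    kind: str,
    term_u_fraction: float,
) -> EnthalpyValue:
    c = coeffs.coefficient(inputs.Cp_cr, inputs.Cp_l)
    term = c * (inputs.T_obs - inputs.T_target) / 1000.0
    u = combine_quadrature([inputs.u, term_u_fraction * abs(term)])
    return EnthalpyValue(
        value=inputs.dH_at_T + term,
        u=u,
        T=inputs.T_target,
        kind=kind,
        route=f"chickos-{kind}",
    )


def adjust_fusion(
    inputs: AdjustmentInputs,
    coeffs: dict[str, ChickosCoefficients] | None = None,
    term_u_fraction: float = DEFAULT_TERM_U_FRACTION,
) -> EnthalpyValue:
    """Fusion enthalpy at T_fus adjusted to the target temperature.

    Requires both Cp(cr) and Cp(l) (measured or group-estimated).
    """
    coeffs = coeffs or load_coefficients()
    return _adjust(inputs, coeffs["fusion"], "fusion", term_u_fraction)


def adjust_vaporization(
    inputs: AdjustmentInputs,
    coeffs: dict[str, ChickosCoefficients] | None = None,
    term_u_fraction: float = DEFAULT_TERM_U_FRACTION,
) -> EnthalpyValue:
    """Vaporization enthalpy at the mean experimental temperature -> target."""
    coeffs = coeffs or load_coefficients()
    return _adjust(inputs, coeffs["vaporization"], "vaporization", term_u_fraction)


def adjust_sublimation(
    inputs: AdjustmentInputs,
    coeffs: dict[str, ChickosCoefficients] | None = None,
    term_u_fraction: float = DEFAULT_TERM_U_FRACTION,
) -> EnthalpyValue:
    """Sublimation enthalpy at the average experimental temperature -> target."""
    coeffs = coeffs or load_coefficients()
    return _adjust(inputs, coeffs["sublimation"], "sublimation", term_u_fraction)
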