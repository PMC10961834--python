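"""Thermochemical-cycle assembly with quadrature uncertainty propagation.

Two independent routes to the sublimation enthalpy at 298.15 K —
fusion + vaporization, and direct sublimation — are combined with the
crystalline formation enthalpy to give the gas-phase formation
enthalpy.  Both routes are always reported side by side; the package
expresses no preference between them.
"""

from __future__ import annotations

from .quantities import EnthalpyValue, ThermoError, combine_quadrature

__all__ = [
    "EnthalpyValue",
    "combine_quadrature",
    "sublimation_from_fusion_plus_vaporization",
    "formation_gas",
    "cycle_report",
]

_T_MATCH_TOL = 0.01  # K


def _check_same_T(a: EnthalpyValue, b: EnthalpyValue) -> None:
    if abs(a.T - b.T) > _T_MATCH_TOL:
        raise ThermoError(f"temperature mismatch: {a.T} K vs {b.T} K")


def sublimation_from_fusion_plus_vaporization(
    fus: EnthalpyValue, vap: EnthalpyValue
) -> EnthalpyValue:
    """Sublimation enthalpy as the fusion + vaporization sum (same T)."""
    if fus.kind != "fusion" or vap.kind != "vaporization":
        raise ThermoError(
            f"expected fusion + vaporization, got {fus.kind} + {vap.kind}"
        )
    _check_same_T(fus, vap)
    return EnthalpyValue(
        value=fus.value + vap.value,
        u=combine_quadrature([fus.u, vap.u]),
        T=fus.T,
        kind="sublimation",
        route="fusion+vaporization",
    )


def formation_gas(f_cr: EnthalpyValue, sub: EnthalpyValue) -> EnthalpyValue:
    """Gas-phase formation enthalpy dfH(g) = dfH(cr) + dsubH."""
    if f_cr.kind != "formation_cr":
        raise ThermoError(f"expected formation_cr, got {f_cr.kind}")
    if sub.kind != "sublimation":
        raise ThermoError(f"expected sublimation, got {sub.kind}")
    _check_same_T(f_cr, sub)
    return EnthalpyValue(
        value=f_cr.value + sub.value,
        u=combine_quadrature([f_cr.u, sub.u]),
        T=f_cr.T,
        kind="formation_g",
        route=sub.route,
    )


def cycle_report(
    f_cr: EnthalpyValue,
    fus: EnthalpyValue,
    vap: EnthalpyValue,
    sub_direct: EnthalpyValue | None = None,
) -> dict:
    """Assemble the full cycle, both routes, as a report dict.

    Route A: sublimation = fusion + vaporization.
    Route B: direct sublimation, when supplied.
    """
    sub_a = sublimation_from_fusion_plus_vaporization(fus, vap)
    report = {
        "formation_cr": f_cr.as_dict(),
        "fusion": fus.as_dict(),
        "vaporization": vap.as_dict(),
        "sublimation_routeA": sub_a.as_dict(),
        "formation_g_routeA": formation_gas(f_cr, sub_a).as_dict(),
    }
    if sub_direct is not None:
        if sub_direct.kind != "sublimation":
            raise ThermoError("direct route must have kind 'sublimation'")
        report["sublimation_routeB"] = sub_direct.as_dict()
        report["formation_g_routeB"] = formation_gas(f_cr, sub_direct).as_dict()
    return report
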