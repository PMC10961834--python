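"""Isoperibolic bomb-calorimetry data reduction.

Reduces combustion-experiment records (masses, temperatures,
energy-equivalent terms and correction energies) to the standard massic
energy of combustion of the sample, then to the molar combustion
energy/enthalpy and the crystalline-phase standard enthalpy of formation
via a Hess cycle over CO2(g) and H2O(l).

Sign conventions
----------------
Energies of combustion are stored negative (energy released).  The
nitric-acid correction ``dU_HNO3`` is stored as printed (negative for
acid formation).  ``dU_corr`` is the standard-state (Washburn)
correction, supplied as an input; its computation, like that of the
adiabatic temperature correction ``dT_corr``, is outside the scope of
this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantities import EnthalpyValue, R_GAS, T_REF, ThermoError, combine_quadrature

#: Air density at the ambient pressure of the source experiments
#: (ideal gas, 78.8 kPa, 298.15 K), g/cm^3.
DEFAULT_RHO_AIR = 0.00092

#: Conventional density of stainless-steel calibration weights, g/cm^3.
DEFAULT_RHO_WEIGHTS = 8.0

EXPERIMENT_COLUMNS = [
    "m_sample_g",
    "m_oil_g",
    "m_cotton_g",
    "m_crucible_g",
    "T_i_K",
    "T_f_K",
    "dT_corr_K",
    "eps_cont_i_kJK",
    "eps_cont_f_kJK",
    "dU_ign_kJ",
    "dU_HNO3_kJ",
    "dU_corr_kJ",
]


@dataclass(frozen=True)
class CombustionExperiment:
    """One bomb-calorimetry run.

    Masses in g (already buoyancy-corrected), temperatures in K, energy
    equivalents in kJ/K, energies in kJ.
    """

    m_sample: float
    m_aux_oil: float
    m_aux_cotton: float
    m_crucible: float
    T_i: float
    T_f: float
    dT_corr: float
    eps_cont_i: float
    eps_cont_f: float
    dU_ign: float
    dU_HNO3: float
    dU_corr: float

    def __post_init__(self) -> None:
        if self.T_f <= self.T_i:
            raise ThermoError(f"T_f={self.T_f} must exceed T_i={self.T_i}")
        for name in ("m_sample", "m_aux_oil", "m_aux_cotton", "m_crucible"):
            if getattr(self, name) < 0:
                raise ThermoError(f"{name} must be >= 0")
        if self.dT_corr < 0:
            raise ThermoError("dT_corr must be >= 0")


@dataclass(frozen=True)
class CalorimeterCalibration:
    """Calorimeter energy equivalent and auxiliary-material energies.

    Defaults are the benzoic-acid calibration of the source apparatus:
    eps(calor) = 10.1351 +- 0.0025 kJ/K, paraffin oil
    -46.2385 +- 0.0066 kJ/g, cotton fuse -16.9452 +- 0.0042 kJ/g,
    aqueous nitric-acid formation -59.7 kJ/mol.
    """

    eps_calor: float = 10.1351
    u_eps_calor: float = 0.0025
    du_oil: float = -46.2385
    u_du_oil: float = 0.0066
    du_cotton: float = -16.9452
    u_du_cotton: float = 0.0042
    dH_HNO3_molar: float = -59.7
    T_ref: float = T_REF

    def __post_init__(self) -> None:
        if self.eps_calor <= 0:
            raise ThermoError("eps_calor must be > 0")
        if self.du_oil >= 0 or self.du_cotton >= 0:
            raise ThermoError("auxiliary combustion energies must be < 0")


@dataclass(frozen=True)
class CompoundPhysical:
    """Physical data of the combusted compound.

    ``du_dp`` (J/g/MPa) is retained for documentation; it would enter
    only a Washburn-correction computation, which this package treats as
    an input.
    """

    formula: dict[str, int]
    M: float
    density: float = float("nan")
    cp_massic: float = float("nan")
    du_dp: float = float("nan")
    name: str = ""

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ThermoError("molar mass must be > 0")
        unsupported = set(self.formula) - {"C", "H", "O"}
        if unsupported:
            raise ThermoError(f"unsupported elements: {sorted(unsupported)}")
        if any(v < 0 for v in self.formula.values()):
            raise ThermoError("element counts must be >= 0")


@dataclass(frozen=True)
class ReferenceEnthalpies:
    """CODATA formation enthalpies of the combustion products, kJ/mol."""

    dfH_CO2_g: float = -393.51
    u_dfH_CO2_g: float = 0.13
    dfH_H2O_l: float = -285.83
    u_dfH_H2O_l: float = 0.04
    R_gas: float = R_GAS

    def __post_init__(self) -> None:
        if self.dfH_CO2_g >= 0 or self.dfH_H2O_l >= 0:
            raise ThermoError("reference formation enthalpies must be < 0")


# ---------------------------------------------------------------------------
# elementary reductions
# ---------------------------------------------------------------------------

def buoyancy_correct(
    m_apparent: float,
    rho_sample: float,
    rho_air: float = DEFAULT_RHO_AIR,
    rho_weights: float = DEFAULT_RHO_WEIGHTS,
) -> float:
    """True mass from an apparent balance reading.

    m_true = m_app * (1 - rho_air/rho_weights) / (1 - rho_air/rho_sample).
    ``rho_air = 0`` is the vacuum limit and returns the reading unchanged.
    """
    if rho_sample <= 0 or rho_weights <= 0:
        raise ThermoError("densities must be > 0")
    if rho_air < 0 or rho_air >= rho_sample:
        raise ThermoError("require 0 <= rho_air < rho_sample")
    return m_apparent * (1.0 - rho_air / rho_weights) / (1.0 - rho_air / rho_sample)


def corrected_temperature_rise(T_i: float, T_f: float, dT_corr: float) -> float:
    """Adiabatic-corrected temperature increment dT_c = T_f - T_i - dT_corr."""
    if T_f <= T_i:
        raise ThermoError("T_f must exceed T_i")
    dT_c = T_f - T_i - dT_corr
    if dT_c <= 0:
        raise ThermoError("corrected temperature rise is non-positive; inconsistent record")
    return dT_c


def content_energy_term(exp: CombustionExperiment, T_ref: float = T_REF) -> float:
    """Bomb-contents energy eps(cont)*dT_c, kJ.

    Two-piece sum: the initial contents equivalent acts from T_i to the
    reference temperature, the final one from the reference temperature
    to the corrected final temperature.
    """
    return exp.eps_cont_i * (T_ref - exp.T_i) + exp.eps_cont_f * (
        exp.T_f - T_ref - exp.dT_corr
    )


def isothermal_bomb_energy(
    exp: CombustionExperiment, cal: CalorimeterCalibration
) -> float:
    """Energy of the isothermal bomb process, dU_IBP (negative), kJ.

    |dU_IBP| = eps(calor)*dT_c + eps(cont)*dT_c - dU_ign.
    """
    dT_c = corrected_temperature_rise(exp.T_i, exp.T_f, exp.dT_corr)
    magnitude = cal.eps_calor * dT_c + content_energy_term(exp, cal.T_ref) - exp.dU_ign
    return -magnitude


def specific_combustion_energy(
    exp: CombustionExperiment, cal: CalorimeterCalibration
) -> float:
    """Standard massic energy of combustion of the sample, kJ/g (negative).

    The sample's energy release is the bomb-process energy less the
    auxiliary materials (oil, cotton), the nitric-acid formation energy
    and the standard-state correction:

    (-m*dcu)(sample) = |dU_IBP| + dU_HNO3 - dU_corr
                       - m_oil*|du_oil| - m_cotton*|du_cotton|
    """
    if exp.m_sample <= 0:
        raise ThermoError("sample mass must be > 0")
    sample_energy = (
        -isothermal_bomb_energy(exp, cal)
        + exp.dU_HNO3
        - exp.dU_corr
        - exp.m_aux_oil * abs(cal.du_oil)
        - exp.m_aux_cotton * abs(cal.du_cotton)
    )
    du = -sample_energy / exp.m_sample
    if du >= 0:
        raise ThermoError(
            "reduced massic combustion energy is non-negative; check sign conventions"
        )
    return du


def aggregate_runs(values: list[float]) -> tuple[float, float]:
    """Mean massic energy over replicate runs and twice the s.d. of the mean."""
    if len(values) < 2:
        raise ThermoError("need at least 2 replicate runs")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    u = float(2.0 * arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, u


# ---------------------------------------------------------------------------
# molar chain
# ---------------------------------------------------------------------------

def molar_combustion_energy(du: float, M: float) -> float:
    """Molar combustion energy dcU_m = du * M, kJ/mol."""
    if M <= 0:
        raise ThermoError("molar mass must be > 0")
    return du * M


def delta_n_gas(formula: dict[str, int]) -> float:
    """Change in moles of gas for CxHyOz + (x + y/4 - z/2) O2 -> x CO2 + y/2 H2O(l).

    Equals z/2 - y/4 (water is condensed at the reference temperature).
    """
    unsupported = set(formula) - {"C", "H", "O"}
    if unsupported:
        raise ThermoError(f"unsupported elements: {sorted(unsupported)}")
    x = formula.get("C", 0)
    y = formula.get("H", 0)
    z = formula.get("O", 0)
    if x < 1:
        raise ThermoError("need at least one carbon")
    return z / 2.0 - y / 4.0


def enthalpy_from_energy(
    dU_m: float, dn: float, T: float = T_REF, R: float = R_GAS
) -> float:
    """Ideal-gas conversion dH = dU + dn*R*T, with R*T in J/mol converted to kJ."""
    if T <= 0:
        raise ThermoError("temperature must be > 0")
    return dU_m + dn * R * T / 1000.0


def formation_enthalpy_cr(
    dcH_m: float,
    formula: dict[str, int],
    refs: ReferenceEnthalpies = ReferenceEnthalpies(),
    u_dcH_m: float = 0.0,
) -> EnthalpyValue:
    """Hess cycle: dfH(cr) = x*dfH(CO2,g) + (y/2)*dfH(H2O,l) - dcH(cr).

    The uncertainty combines the combustion-enthalpy uncertainty with
    the stoichiometry-scaled reference uncertainties in quadrature.
    """
    unsupported = set(formula) - {"C", "H", "O"}
    if unsupported:
        raise ThermoError(f"unsupported elements: {sorted(unsupported)}")
    x = formula.get("C", 0)
    y = formula.get("H", 0)
    value = x * refs.dfH_CO2_g + (y / 2.0) * refs.dfH_H2O_l - dcH_m
    u = combine_quadrature(
        [u_dcH_m, x * refs.u_dfH_CO2_g, (y / 2.0) * refs.u_dfH_H2O_l]
    )
    return EnthalpyValue(value=value, u=u, T=T_REF, kind="formation_cr", route="combustion")


# ---------------------------------------------------------------------------
# uncertainty budget and orchestration
# ---------------------------------------------------------------------------

def massic_uncertainty_budget(
    experiments: list[CombustionExperiment],
    cal: CalorimeterCalibration,
    du_mean: float,
    u_repeat: float,
) -> float:
    """Expanded uncertainty of the mean massic combustion energy, kJ/g.

    Quadrature of the replicate scatter (2 s/sqrt(n), supplied) with the
    calibration and auxiliary-material energy uncertainties, each scaled
    by its mean sensitivity and doubled to the expanded level.  The
    exact recipe behind the source's reported molar uncertainty is not
    published; this budget is the package's own and is reported
    alongside (see docs/methods.md).
    """
    n = len(experiments)
    mean_dTc = np.mean(
        [corrected_temperature_rise(e.T_i, e.T_f, e.dT_corr) for e in experiments]
    )
    mean_m = np.mean([e.m_sample for e in experiments])
    mean_oil = np.mean([e.m_aux_oil for e in experiments])
    mean_cotton = np.mean([e.m_aux_cotton for e in experiments])
    # sensitivities of du to each calibrated quantity, per run
    s_eps = mean_dTc / mean_m  # d(du)/d(eps_calor)
    s_oil = mean_oil / mean_m  # d(du)/d(du_oil)
    s_cotton = mean_cotton / mean_m
    return combine_quadrature(
        [
            u_repeat,
            2.0 * s_eps * cal.u_eps_calor,
            2.0 * s_oil * cal.u_du_oil,
            2.0 * s_cotton * cal.u_du_cotton,
        ]
    )


def reduce_experiments(
    experiments: list[CombustionExperiment],
    compound: CompoundPhysical,
    cal: CalorimeterCalibration = CalorimeterCalibration(),
    refs: ReferenceEnthalpies = ReferenceEnthalpies(),
) -> dict:
    """Full reduction: per-run massic energies through to dfH(cr).

    Returns a report dict with per-run values, the replicate mean and
    its uncertainty, the molar combustion energy/enthalpy and the
    crystalline formation enthalpy.
    """
    per_run = [specific_combustion_energy(e, cal) for e in experiments]
    du_mean, u_repeat = aggregate_runs(per_run)
    u_massic = massic_uncertainty_budget(experiments, cal, du_mean, u_repeat)
    dcU_m = molar_combustion_energy(du_mean, compound.M)
    u_molar = u_massic * compound.M
    dn = delta_n_gas(compound.formula)
    dcH_m = enthalpy_from_energy(dcU_m, dn, cal.T_ref, refs.R_gas)
    f_cr = formation_enthalpy_cr(dcH_m, compound.formula, refs, u_dcH_m=u_molar)
    return {
        "per_run_du_kJ_per_g": per_run,
        "du_mean_kJ_per_g": du_mean,
        "u_repeat_kJ_per_g": u_repeat,
        "u_massic_kJ_per_g": u_massic,
        "dcU_m_kJ_per_mol": dcU_m,
        "dcH_m_kJ_per_mol": dcH_m,
        "u_molar_kJ_per_mol": u_molar,
        "delta_n_gas": dn,
        "dfH_cr": f_cr.as_dict(),
    }


def read_experiments_csv(path) -> list[CombustionExperiment]:
    """Load combustion experiments from the canonical CSV layout."""
    df = pd.read_csv(path)
    missing = set(EXPERIMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ThermoError(f"combustion CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CombustionExperiment(
                m_sample=row.m_sample_g,
                m_aux_oil=row.m_oil_g,
                m_aux_cotton=row.m_cotton_g,
                m_crucible=row.m_crucible_g,
                T_i=row.T_i_K,
                T_f=row.T_f_K,
                dT_corr=row.dT_corr_K,
                eps_cont_i=row.eps_cont_i_kJK,
                eps_cont_f=row.eps_cont_f_kJK,
                dU_ign=row.dU_ign_kJ,
                dU_HNO3=row.dU_HNO3_kJ,
                dU_corr=row.dU_corr_kJ,
            )
        )
    return out
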