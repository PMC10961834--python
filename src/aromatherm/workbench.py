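"""End-to-end orchestration: the packaged trimellitic-acid reproduction.

``reproduce_tmac`` runs the deterministic chain from the packaged
combustion-experiment table and group catalog through every stage —
calorimetric reduction, Chickos fusion adjustment, both sublimation
routes, the gas-phase formation enthalpies, and the group-additivity
estimates — and emits a machine-readable report with pass/fail flags
against the packaged expected values at their stated tolerances.
Comparisons are made on values rounded to the report precision
(4 decimals for kJ/g, 1 decimal for kJ/mol), never by string equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources

from . import benson, calorimetry, chickos, cycle
from .quantities import EnthalpyValue, ThermoError

log = logging.getLogger("aromatherm")

#: report rounding, decimals
ROUND_MASSIC = 4  # kJ/g
ROUND_MOLAR = 1  # kJ/mol


class StageError(ThermoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Paths to the pipeline inputs; ``None`` means the packaged fixture."""

    experiments_csv: str | None = None
    compound_json: str | None = None
    catalog_csv: str | None = None
    chickos_json: str | None = None


def _data_path(name: str):
    return resources.files("aromatherm.data").joinpath(name)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_tmac_config(path=None) -> dict:
    if path is None:
        text = _data_path("tmac.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = json.loads(text)
    cfg["_digest"] = _digest(text)
    return cfg


def _check(value: float, expected: float, tol: float, decimals: int) -> dict:
    rounded = round(value, decimals)
    return {
        "value": value,
        "rounded": rounded,
        "expected": expected,
        "tol": tol,
        "ok": abs(rounded - expected) <= tol + 1e-9,
    }


def reproduce_tmac(config: RunConfig = RunConfig()) -> dict:
    """Run the full deterministic chain on the packaged (or given) inputs."""
    cfg = load_tmac_config(config.compound_json)
    compound = calorimetry.CompoundPhysical(
        formula=cfg["compound"]["formula"],
        M=cfg["compound"]["M_g_per_mol"],
        density=cfg["compound"]["density_g_per_cm3"],
        cp_massic=cfg["compound"]["cp_massic_J_per_gK"],
        du_dp=cfg["compound"]["du_dp_J_per_gMPa"],
        name=cfg["compound"]["name"],
    )
    cal_cfg = cfg["calibration"]
    cal = calorimetry.CalorimeterCalibration(
        eps_calor=cal_cfg["eps_calor_kJK"],
        u_eps_calor=cal_cfg["u_eps_calor_kJK"],
        du_oil=cal_cfg["du_oil_kJ_per_g"],
        u_du_oil=cal_cfg["u_du_oil_kJ_per_g"],
        du_cotton=cal_cfg["du_cotton_kJ_per_g"],
        u_du_cotton=cal_cfg["u_du_cotton_kJ_per_g"],
        dH_HNO3_molar=cal_cfg["dH_HNO3_kJ_per_mol"],
        T_ref=cal_cfg["T_ref_K"],
    )
    refs_cfg = cfg["references"]
    refs = calorimetry.ReferenceEnthalpies(
        dfH_CO2_g=refs_cfg["dfH_CO2_g_kJ_per_mol"],
        u_dfH_CO2_g=refs_cfg["u_dfH_CO2_g_kJ_per_mol"],
        dfH_H2O_l=refs_cfg["dfH_H2O_l_kJ_per_mol"],
        u_dfH_H2O_l=refs_cfg["u_dfH_H2O_l_kJ_per_mol"],
        R_gas=refs_cfg["R_J_per_molK"],
    )
    exp = cfg["expected"]

    # --- stage 1: calorimetric reduction ---------------------------------
    try:
        if config.experiments_csv is None:
            with _data_path("tmac_combustion.csv").open() as fh:
                experiments = calorimetry.read_experiments_csv(fh)
        else:
            experiments = calorimetry.read_experiments_csv(config.experiments_csv)
        log.info("reduce-combustion: %d runs", len(experiments))
        red = calorimetry.reduce_experiments(experiments, compound, cal, refs)
    except Exception as e:  # structured stage failure
        raise StageError("calorimetry", e) from e

    # --- stage 2: Chickos fusion adjustment ------------------------------
    try:
        ci = cfg["chickos_inputs"]
        coeffs = chickos.load_coefficients(config.chickos_json)
        fus = chickos.adjust_fusion(
            chickos.AdjustmentInputs(
                dH_at_T=ci["fusion"]["dH_kJ_per_mol"],
                u=ci["fusion"]["u_kJ_per_mol"],
                T_obs=ci["fusion"]["T_obs_K"],
                Cp_cr=ci["Cp_cr_J_per_molK"],
                Cp_l=ci["Cp_l_J_per_molK"],
            ),
            coeffs,
        )
    except Exception as e:
        raise StageError("chickos", e) from e

    # --- stage 3: thermochemical cycle -----------------------------------
    try:
        ri = cfg["route_inputs"]
        vap = EnthalpyValue(kind="vaporization", route="tga", **ri["vaporization"])
        sub_b = EnthalpyValue(
            kind="sublimation", route="direct-sublimation", **ri["sublimation_direct"]
        )
        f_cr = EnthalpyValue(**red["dfH_cr"])
        cyc = cycle.cycle_report(f_cr, fus, vap, sub_b)
    except Exception as e:
        raise StageError("cycle", e) from e

    # --- stage 4: group additivity ---------------------------------------
    try:
        if config.catalog_csv is None:
            catalog = benson.load_default_catalog("benson_original")
        else:
            catalog = benson.read_catalog_csv(config.catalog_csv, "benson_original")
        benzoic = benson.BenzeneSubstitution({1: "COOH"}, name="benzoic acid")
        tere = benson.BenzeneSubstitution(
            {1: "COOH", 4: "COOH"}, name="terephthalic acid"
        )
        est = {
            "benzoic_gas": -benson.estimate(benson.decompose(benzoic), catalog, "gas"),
            "benzoic_cr": -benson.estimate(benson.decompose(benzoic), catalog, "cr"),
            "terephthalic_gas": -benson.estimate(benson.decompose(tere), catalog, "gas"),
        }
    except Exception as e:
        raise StageError("benson", e) from e

    report = {
        "inputs_digest": cfg["_digest"],
        "calorimetry": red,
        "fusion_adjusted": fus.as_dict(),
        "cycle": cyc,
        "benson": est,
        "checks": {
            "du_mean": _check(
                red["du_mean_kJ_per_g"], exp["du_mean_kJ_per_g"],
                exp["du_mean_tol"], ROUND_MASSIC,
            ),
            "dcU_m": _check(
                red["dcU_m_kJ_per_mol"], exp["dcU_m_kJ_per_mol"],
                exp["table4_tol"], ROUND_MOLAR,
            ),
            "dcH_m": _check(
                red["dcH_m_kJ_per_mol"], exp["dcH_m_kJ_per_mol"],
                exp["table4_tol"], ROUND_MOLAR,
            ),
            "dfH_cr": _check(
                red["dfH_cr"]["value"], exp["dfH_cr_kJ_per_mol"],
                exp["table4_tol"], ROUND_MOLAR,
            ),
            "fusion_298": _check(
                fus.value, exp["fusion_298_kJ_per_mol"], exp["fusion_tol"], ROUND_MOLAR
            ),
            "sublimation_routeA": _check(
                cyc["sublimation_routeA"]["value"],
                exp["sublimation_routeA_kJ_per_mol"], exp["cycle_tol"], ROUND_MOLAR,
            ),
            "dfH_g_routeA": _check(
                cyc["formation_g_routeA"]["value"],
                exp["dfH_g_routeA_kJ_per_mol"], exp["cycle_tol"], ROUND_MOLAR,
            ),
            "dfH_g_routeB": _check(
                cyc["formation_g_routeB"]["value"],
                exp["dfH_g_routeB_kJ_per_mol"], exp["cycle_tol"], ROUND_MOLAR,
            ),
        },
    }
    return report


def report_json(report: dict) -> str:
    """Byte-stable serialization of a report."""
    return json.dumps(report, indent=2, sort_keys=True)
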