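"""Synthetic-data generators for every pipeline stage.

Each generator is the exact inverse of its reduction at zero noise, so
round-trip tests close to machine precision; with noise, the
perturbation enters where measurement error physically enters
(the final calorimeter temperature for combustion runs,
multiplicatively on the mass-loss rate for TGA traces, additively on
the target enthalpies for group-contribution datasets).  Fixed seeds
give identical output across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calorimetry import CalorimeterCalibration, CombustionExperiment
from .mlr import GCDataset
from .quantities import R_GAS, T_REF, ThermoError
from .tga import DEFAULT_ORIFICE_AREA, MassLossTrace


@dataclass(frozen=True)
class SimulationSpec:
    """Seed, size and noise level for one synthetic draw."""

    seed: int = 0
    n: int = 7
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ThermoError("noise_sd must be >= 0")
        if self.n < 1:
            raise ThermoError("n must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CombustionTruth:
    """True conditions for synthetic bomb-calorimetry runs.

    Defaults emulate the study conditions: ~1 g sample aliquots with a
    massic combustion energy near -15.35 kJ/g, ~0.17 g paraffin-oil
    auxiliary, milligram cotton fuses and an isoperibolic jacket a few
    kelvin below the 298.15 K reference temperature.
    """

    du_true: float = -15.3489
    m_sample: float = 0.985
    m_oil: float = 0.17
    m_cotton: float = 0.0017
    m_crucible: float = 11.52
    T_i: float = 295.30
    dT_corr: float = 0.043
    eps_cont_i: float = 0.0174
    eps_cont_f: float = 0.0185
    dU_ign: float = 0.0042
    dU_HNO3: float = -0.0013
    dU_corr: float = 0.021

    def __post_init__(self) -> None:
        if self.du_true >= 0:
            raise ThermoError("du_true must be < 0 (energy released)")


def gen_combustion(
    truth: CombustionTruth,
    spec: SimulationSpec,
    cal: CalorimeterCalibration = CalorimeterCalibration(),
) -> list[CombustionExperiment]:
    """Combustion records whose exact reduction returns ``du_true``.

    The bomb-process energy implied by the truth is inverted for the
    final temperature T_f (the content term is linear in T_f); Gaussian
    noise of sd ``spec.noise_sd`` kelvin is then added to T_f.
    """
    rng = spec.rng()
    out = []
    for _ in range(spec.n):
        sample_energy = -truth.du_true * truth.m_sample
        ibp = (
            sample_energy
            + truth.m_oil * abs(cal.du_oil)
            + truth.m_cotton * abs(cal.du_cotton)
            - truth.dU_HNO3
            + truth.dU_corr
        )
        # ibp = eps*(Tf - Ti - dTcorr) + ei*(Tref - Ti) + ef*(Tf - Tref - dTcorr) - dU_ign
        numer = (
            ibp
            + truth.dU_ign
            - truth.eps_cont_i * (cal.T_ref - truth.T_i)
            + truth.eps_cont_f * (cal.T_ref + truth.dT_corr)
            + cal.eps_calor * (truth.T_i + truth.dT_corr)
        )
        T_f = numer / (cal.eps_calor + truth.eps_cont_f)
        if spec.noise_sd > 0:
            T_f += rng.normal(0.0, spec.noise_sd)
        out.append(
            CombustionExperiment(
                m_sample=truth.m_sample,
                m_aux_oil=truth.m_oil,
                m_aux_cotton=truth.m_cotton,
                m_crucible=truth.m_crucible,
                T_i=truth.T_i,
                T_f=T_f,
                dT_corr=truth.dT_corr,
                eps_cont_i=truth.eps_cont_i,
                eps_cont_f=truth.eps_cont_f,
                dU_ign=truth.dU_ign,
                dU_HNO3=truth.dU_HNO3,
                dU_corr=truth.dU_corr,
            )
        )
    return out


@dataclass(frozen=True)
class TgaTruth:
    """True line for a synthetic mass-loss trace.

    Defaults emulate a vaporization experiment in the 310-360 K window
    with a transition enthalpy of ~91 kJ/mol (the magnitude of the
    pyrene validation standard) and an intercept placing the rates in
    the instrument's sensitivity range.
    """

    dH_true: float = 91.4
    intercept_B: float = 12.0
    T_min: float = 310.0
    T_max: float = 360.0
    M: float = 202.25
    process: str = "vaporization"

    def __post_init__(self) -> None:
        if self.dH_true <= 0:
            raise ThermoError("dH_true must be > 0")
        if self.T_max <= self.T_min:
            raise ThermoError("T grid must be increasing")


def gen_tga_trace(truth: TgaTruth, spec: SimulationSpec) -> MassLossTrace:
    """A trace with dm/dt = exp(B - dH/(R T)) / sqrt(T), lognormal noise.

    ``spec.noise_sd`` is the sd of the multiplicative lognormal factor
    (e.g. 0.01 for 1% rate noise).
    """
    rng = spec.rng()
    T = np.linspace(truth.T_min, truth.T_max, spec.n)
    rates = np.exp(truth.intercept_B - truth.dH_true * 1000.0 / (R_GAS * T)) / np.sqrt(T)
    if spec.noise_sd > 0:
        rates = rates * np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n))
    return MassLossTrace(
        points=tuple(zip(T.tolist(), rates.tolist())),
        M=truth.M,
        A=DEFAULT_ORIFICE_AREA,
        process=truth.process,
    )


def gen_gc_dataset(
    w_true: dict[str, float],
    spec: SimulationSpec,
    inject_alias: bool = False,
    phase: str = "gas",
) -> tuple[GCDataset, dict[str, float]]:
    """A synthetic group-count design with linear targets.

    Counts are benzene-plausible small integers (Poisson(1.2) clipped to
    0-6), redrawn until the design has full column rank (error after 100
    redraws); y = X w_true + Gaussian(0, noise_sd).  ``inject_alias``
    appends an exact duplicate of the first column (named
    ``<feature>_alias``) for degeneracy tests; the returned truth map is
    unchanged by the alias.
    """
    features = tuple(w_true)
    if len(features) < 2:
        raise ThermoError("need at least 2 features")
    if spec.n <= len(features):
        raise ThermoError("need more molecules than features")
    rng = spec.rng()
    for _ in range(100):
        X = np.minimum(rng.poisson(1.2, size=(spec.n, len(features))), 6).astype(float)
        # no all-zero rows: give an empty row one count of a random feature
        zero_rows = ~X.any(axis=1)
        if zero_rows.any():
            X[zero_rows, rng.integers(0, len(features), size=zero_rows.sum())] = 1.0
        if np.linalg.matrix_rank(X) == len(features):
            break
    else:
        raise ThermoError("could not draw a full-rank design in 100 attempts")
    w = np.array([w_true[f] for f in features])
    y = X @ w
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    if inject_alias:
        X = np.column_stack([X, X[:, 0]])
        features = features + (f"{features[0]}_alias",)
    ds = GCDataset(
        molecules=tuple(f"mol{i:03d}" for i in range(spec.n)),
        features=features,
        X=X,
        y=y,
        phase=phase,
    )
    return ds, dict(w_true)
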