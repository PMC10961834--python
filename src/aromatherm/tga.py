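"""Vaporization/sublimation enthalpies from thermogravimetric mass loss.

Under free evaporation through a known orifice, the Langmuir relation
converts a mass-loss rate dm/dt at temperature T into a vapor pressure

    p = (dm/dt) / (A * gamma) * sqrt(2 pi R T / M).

Combining this with the Clausius-Clapeyron equation (with a constant
absorbing the gas-phase diffusion effect) linearizes to

    ln[(dm/dt) * sqrt(T)] = B - dH / (R T),

so an ordinary least-squares fit of ln(dm_dt * sqrt(T)) on 1/T yields
the transition enthalpy at the mean experimental temperature from the
slope alone; neither the orifice area nor the vaporization constant
needs calibrating.  The same fit applied to the pre-melting temperature
window gives the sublimation enthalpy; window selection is done by
filtering the input, not automated here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantities import EnthalpyValue, R_GAS, ThermoError

#: Default orifice area, m^2: the cross-section of the 5.25 mm internal
#: diameter alumina cup.
DEFAULT_ORIFICE_AREA = math.pi * (5.25e-3 / 2.0) ** 2

VALID_PROCESSES = ("vaporization", "sublimation")


@dataclass(frozen=True)
class MassLossTrace:
    """A (T, dm/dt) series from one TGA run.

    ``points`` is a list of (temperature K, mass-loss rate g/s) with
    strictly increasing positive temperatures; ``A`` the orifice area in
    m^2; ``M`` the molar mass in g/mol.
    """

    points: tuple[tuple[float, float], ...]
    M: float
    A: float = DEFAULT_ORIFICE_AREA
    process: str = "vaporization"

    def __post_init__(self) -> None:
        if self.process not in VALID_PROCESSES:
            raise ThermoError(f"unknown process {self.process!r}")
        if len(self.points) < 3:
            raise ThermoError("need at least 3 trace points")
        T = np.array([p[0] for p in self.points])
        r = np.array([p[1] for p in self.points])
        if np.any(T <= 0) or np.any(np.diff(T) <= 0):
            raise ThermoError("temperatures must be positive and strictly increasing")
        if np.any(r <= 0):
            raise ThermoError("mass-loss rates must be > 0")
        if self.M <= 0 or self.A <= 0:
            raise ThermoError("M and A must be > 0")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class ClausiusFit:
    """Result of the Clausius-Clapeyron linearization.

    ``slope`` is in K and equals -dH/R; ``intercept`` houses the
    diffusion constant and the absorbed Langmuir prefactor; ``u`` is the
    standard uncertainty of the enthalpy, R * slope_sd.
    """

    slope: float
    intercept: float
    slope_sd: float
    T_mean: float
    dH_at_Tmean: float
    u: float
    process: str = "vaporization"
    n: int = 0


def langmuir_pressure(
    dm_dt: float, T: float, A: float, M: float, gamma: float = 1.0
) -> float:
    """Vapor pressure in Pa from a mass-loss rate via the Langmuir relation.

    ``M`` is given in g/mol and converted to kg/mol internally.
    """
    if min(dm_dt, T, A, M, gamma) <= 0:
        raise ThermoError("all Langmuir arguments must be > 0")
    M_kg = M / 1000.0
    # dm/dt in g/s -> kg/s
    return (dm_dt / 1000.0) / (A * gamma) * math.sqrt(2.0 * math.pi * R_GAS * T / M_kg)


def fit_clausius(
    trace: MassLossTrace, t_mean_mode: str = "arithmetic"
) -> ClausiusFit:
    """OLS fit of ln(dm_dt * sqrt(T)) on 1/T.

    dH at the mean temperature is -slope * R; its standard uncertainty
    is the standard deviation of the slope propagated through R.
    ``t_mean_mode`` selects the arithmetic mean of the trace
    temperatures (default) or the midpoint of their range.
    """
    T = trace.temperatures
    r = trace.rates
    if len(np.unique(T)) < 3:
        raise ThermoError("need at least 3 distinct temperatures")
    x = 1.0 / T
    y = np.log(r * np.sqrt(T))
    if np.ptp(x) == 0:
        raise ThermoError("zero temperature spread; degenerate fit")
    X = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    dof = len(x) - 2
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_sd = math.sqrt(sigma2 / sxx)
    else:
        slope_sd = 0.0
    if t_mean_mode == "arithmetic":
        T_mean = float(T.mean())
    elif t_mean_mode == "midpoint":
        T_mean = float((T.min() + T.max()) / 2.0)
    else:
        raise ThermoError(f"unknown t_mean_mode {t_mean_mode!r}")
    dH = -slope * R_GAS / 1000.0
    u = R_GAS * slope_sd / 1000.0
    return ClausiusFit(
        slope=slope,
        intercept=intercept,
        slope_sd=slope_sd,
        T_mean=T_mean,
        dH_at_Tmean=dH,
        u=u,
        process=trace.process,
        n=len(trace.points),
    )


def weighted_mean_enthalpy(fits: list[ClausiusFit]) -> EnthalpyValue:
    """Inverse-variance weighted mean over replicate Clausius fits.

    Uncertainty of the mean is (sum of weights)^(-1/2), w_i = 1/u_i^2.
    """
    if not fits:
        raise ThermoError("need at least one fit")
    processes = {f.process for f in fits}
    if len(processes) > 1:
        raise ThermoError(f"mixed processes {sorted(processes)}")
    if any(f.u <= 0 for f in fits):
        raise ThermoError("all fits must have u > 0 for inverse-variance weighting")
    w = np.array([1.0 / f.u**2 for f in fits])
    values = np.array([f.dH_at_Tmean for f in fits])
    mean = float(np.sum(w * values) / np.sum(w))
    u = float(1.0 / math.sqrt(np.sum(w)))
    T_mean = float(np.mean([f.T_mean for f in fits]))
    return EnthalpyValue(
        value=mean, u=u, T=T_mean, kind=processes.pop(), route="tga-weighted-mean"
    )


def read_trace_csv(path, meta_path=None, **overrides) -> MassLossTrace:
    """Load a trace from ``T_K,dmdt_g_per_s`` CSV plus optional sidecar JSON."""
    df = pd.read_csv(path)
    for col in ("T_K", "dmdt_g_per_s"):
        if col not in df.columns:
            raise ThermoError(f"trace CSV missing column {col}")
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    meta.update(overrides)
    return MassLossTrace(
        points=tuple(zip(df["T_K"].astype(float), df["dmdt_g_per_s"].astype(float))),
        M=float(meta["M_g_per_mol"]),
        A=float(meta.get("A_m2", DEFAULT_ORIFICE_AREA)),
        process=meta.get("process", "vaporization"),
    )
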