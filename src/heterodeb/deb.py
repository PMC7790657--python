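"""Temperature-corrected standard-DEB metabolic kernel.

All fluxes are daily energy flows (MJ d-1).  Assimilated energy enters the
reserve ``E``; mobilized reserve ``pC`` is split by the kappa rule into a
somatic branch (somatic maintenance ``pS``, then growth ``pG``) and a
maturity/reproduction branch (maturity maintenance ``pJ``, then reproduction
``pR``).  Rates ``pM``, ``kJ`` and ``v`` are Arrhenius-corrected to body
temperature; assimilation is corrected with its own factor ``TC_feed`` so
that feeding can be made independent of heterothermy.

Functions accept scalars or numpy arrays (a cohort) in the state fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Union

import numpy as np

from .params import DEBParams

__all__ = [
    "DEBState",
    "FluxSet",
    "StepAudit",
    "KELVIN_OFFSET",
    "celsius_to_kelvin",
    "temperature_correction",
    "compute_fluxes",
    "step_state",
    "field_metabolic_rate",
    "scaled_reserve_density",
    "body_mass_kg",
]

Arrayish = Union[float, np.ndarray]

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(tb_celsius: Arrayish) -> Arrayish:
    return np.asarray(tb_celsius, dtype=float) + KELVIN_OFFSET


@dataclass
class DEBState:
    """Energetic state of one individual (or a cohort, as arrays).

    ``V``: structural volume [cm^3]; ``E``: reserve [MJ]; ``EH``: maturity
    [MJ], frozen at puberty for simulated adults; ``ER``: reproduction
    buffer [MJ].
    """

    V: Arrayish
    E: Arrayish
    EH: Arrayish
    ER: Arrayish

    def copy(self) -> "DEBState":
        return DEBState(*(np.array(getattr(self, f), dtype=float, copy=True)
                          for f in ("V", "E", "EH", "ER")))


@dataclass
class FluxSet:
    """Daily energy fluxes [MJ d-1]."""

    pA: Arrayish   # assimilation
    pC: Arrayish   # mobilization
    pS: Arrayish   # somatic maintenance
    pJ: Arrayish   # maturity maintenance
    pG: Arrayish   # growth
    pR: Arrayish   # reproduction
    pDf: Arrayish  # dissipating fluxes of the developing embryo (0 if none)


@dataclass
class StepAudit:
    """Daily energy bookkeeping for conservation checks [MJ].

    ``dissipated`` counts maintenance actually paid, reproduction overhead
    and unusable mobilization remainders; ``unpaid_maintenance`` records
    maintenance that could not be covered once reserve and reproduction
    buffer were exhausted (flagged, never raised).
    """

    assimilated: Arrayish
    dissipated: Arrayish
    to_embryo: Arrayish
    unpaid_maintenance: Arrayish


def temperature_correction(tb_kelvin: Arrayish, params: DEBParams) -> Arrayish:
    """Arrhenius temperature correction factor TC(TB).

    TC = exp(TAr/TREF - TAr/TB); equal to 1 at the reference temperature and
    strictly increasing in body temperature.
    """
    tb = np.asarray(tb_kelvin, dtype=float)
    if np.any(tb <= 0.0):
        raise ValueError("body temperature must be positive (kelvin)")
    tc = np.exp(params.TAr / params.TREF - params.TAr / tb)
    return tc if tc.ndim else float(tc)


def compute_fluxes(
    state: DEBState,
    f: Arrayish,
    TC: Arrayish,
    TC_feed: Arrayish,
    params: DEBParams,
    pregnant_embryo_flux: Arrayish = 0.0,
    dt: float = 1.0,
) -> FluxSet:
    """Daily DEB fluxes for scaled functional response ``f``.

    ``TC`` corrects the metabolic rates (pM, kJ, v); ``TC_feed`` corrects
    assimilation only, so that ingestion can follow either the individual's
    own body temperature or a normothermic reference trajectory.
    ``pregnant_embryo_flux`` is the embryo's dissipating flux (pDf), computed
    by the gestation sub-model and passed through for FMR reporting.

    Mobilization is capped so one explicit-Euler day cannot drive the
    reserve negative.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("functional response f must lie in [0, 1]")
    TC = np.asarray(TC, dtype=float)
    TC_feed = np.asarray(TC_feed, dtype=float)
    if np.any(TC <= 0.0) or np.any(TC_feed <= 0.0):
        raise ValueError("temperature correction factors must be positive")
    V = np.asarray(state.V, dtype=float)
    E = np.asarray(state.E, dtype=float)
    if np.any(E < 0.0):
        raise ValueError("reserve E must be nonnegative")

    surface = V ** (2.0 / 3.0)
    pA = f * TC_feed * params.pAm_ref * surface
    pS = TC * params.pM_ref * V
    pJ = TC * params.kJ_ref * np.asarray(state.EH, dtype=float)

    # Standard reserve mobilization with temperature-corrected conductance.
    E_density = E / V
    pC = E_density * (params.EG * TC * params.v_ref * surface + pS) \
        / (params.EG + params.kappa * E_density)
    # Euler guard: cannot mobilize more than reserve plus today's intake.
    pC = np.minimum(pC, E / dt + pA)

    pG = np.maximum(0.0, params.kappa * pC - pS)
    pR = np.maximum(0.0, (1.0 - params.kappa) * pC - pJ)
    pDf = np.maximum(0.0, np.asarray(pregnant_embryo_flux, dtype=float))
    return FluxSet(pA=pA, pC=pC, pS=pS, pJ=pJ, pG=pG, pR=pR, pDf=pDf)


def step_state(
    state: DEBState,
    fluxes: FluxSet,
    params: DEBParams,
    dt: float = 1.0,
    embryo_demand: Arrayish = 0.0,
) -> tuple[DEBState, StepAudit]:
    """One explicit-Euler day of the state equations with starvation rules.

    Updates: E' = E + (pA - pC) dt, V' = V + (pG/EG) dt,
    ER' = ER + (kappaR pR - embryo_demand) dt.  When mobilization cannot
    cover maintenance (kappa pC < pS, or the maturity branch falls short of
    pJ), the shortfall is paid first from the reproduction buffer and then
    from the reserve directly; structure never shrinks.  Any remaining
    deficit is clamped and reported via the audit (depressed e_tot feeds the
    mortality model).  Maturation is inactive: adults stay at EHp.
    """
    V = np.asarray(state.V, dtype=float)
    E = np.asarray(state.E, dtype=float)
    ER = np.asarray(state.ER, dtype=float)
    pA, pC, pS, pJ = (np.asarray(x, dtype=float)
                      for x in (fluxes.pA, fluxes.pC, fluxes.pS, fluxes.pJ))
    pG, pR = np.asarray(fluxes.pG, dtype=float), np.asarray(fluxes.pR, dtype=float)
    demand = np.asarray(embryo_demand, dtype=float)

    E_new = E + (pA - pC) * dt
    V_new = V + (pG / params.EG) * dt
    ER_new = ER + (params.kappaR * pR - demand) * dt

    # Maintenance shortfalls under starvation, paid from ER then E.
    shortfall = (np.maximum(0.0, pS - params.kappa * pC)
                 + np.maximum(0.0, pJ - (1.0 - params.kappa) * pC)) * dt
    from_ER = np.minimum(np.maximum(ER_new, 0.0), shortfall)
    ER_new = ER_new - from_ER
    remaining = shortfall - from_ER
    from_E = np.minimum(np.maximum(E_new, 0.0), remaining)
    E_new = E_new - from_E
    unpaid = remaining - from_E

    # Clamp float dust; genuine deficits are already captured in `unpaid`.
    E_new = np.maximum(E_new, 0.0)
    ER_new = np.maximum(ER_new, 0.0)

    paid_maintenance = (pS + pJ) * dt - unpaid
    # Mobilized energy not captured by any sink dissipates as overhead
    # (reproduction efficiency loss and the part of each branch that fell
    # between maintenance and the clamped allocations).
    overhead = (pC - pS - pJ - pG) * dt + shortfall - pR * dt \
        + (1.0 - params.kappaR) * pR * dt
    dissipated = paid_maintenance + overhead

    new_state = DEBState(V=V_new, E=E_new,
                         EH=np.asarray(state.EH, dtype=float), ER=ER_new)
    audit = StepAudit(assimilated=pA * dt, dissipated=dissipated,
                      to_embryo=demand * dt, unpaid_maintenance=unpaid)
    return new_state, audit


def field_metabolic_rate(fluxes: FluxSet, params: DEBParams) -> Arrayish:
    """Field metabolic rate, the reported daily energy expenditure.

    FMR = pS + pJ + pA (1 - kappaX) + pR (1 - kappaR) + pDf: dissipated
    maintenance fluxes plus assimilation and reproduction overheads plus the
    dissipating fluxes of a developing embryo.
    """
    return (fluxes.pS + fluxes.pJ
            + fluxes.pA * (1.0 - params.kappaX)
            + fluxes.pR * (1.0 - params.kappaR)
            + fluxes.pDf)


def scaled_reserve_density(state: DEBState, params: DEBParams) -> Arrayish:
    """Body-condition index e_tot = (E + ER) / ([Em] V)."""
    V = np.asarray(state.V, dtype=float)
    if np.any(V <= 0.0):
        raise ValueError("structural volume must be positive")
    return (np.asarray(state.E, dtype=float)
            + np.asarray(state.ER, dtype=float)) / (params.Em * V)


def body_mass_kg(state: DEBState, params: DEBParams) -> Arrayish:
    """Total body mass: structural tissue plus reserve tissue [kg]."""
    grams = (np.asarray(state.V, dtype=float) * params.struct_density
             + (np.asarray(state.E, dtype=float)
                + np.asarray(state.ER, dtype=float)) / params.mu_E)
    return grams / 1000.0
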