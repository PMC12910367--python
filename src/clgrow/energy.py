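"""Light interception, harvest traits, LUE, and the LED/HVAC energy model.

The quantitative core of the vertical-farm comparison: how much supplied
light the canopy intercepts, how efficiently intercepted light becomes
biomass (LUE, g mol-1), how much electricity the lighting and cooling
systems draw under different LED-efficacy/temperature scenarios, and how
efficiently that electricity becomes biomass (EUE, g kWh-1).

LED electricity follows directly from photon bookkeeping,

    E_led [kWh m-2] = TPFD [mol m-2 d-1] * 1e6 / efficacy [umol J-1]
                      * days / 3.6e6,

which at a fixed daily photon sum is independent of the photoperiod: the
central "same TPFD, different PPFD" design of the comparison.  HVAC
electricity uses a static heat balance for an airtight, well-insulated,
perfectly-mixed chamber: all LED electrical input degrades to heat (a
pluggable ``heat_fraction``), optionally corrected by an envelope-loss
term under a day/night setpoint regime, and is removed at a fixed
coefficient of performance (COP), ``E_hvac = heat / COP``.  Every
assumption is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import defaults
from .photon import percent_change

logger = logging.getLogger(__name__)

__all__ = [
    "HarvestRecord",
    "DerivedTraits",
    "EnergyScenario",
    "EnergyResult",
    "EfficiencyResult",
    "TemperatureRegime",
    "add_derived_traits",
    "daily_interception",
    "derive_traits",
    "lue",
    "led_energy",
    "hvac_energy",
    "run_scenario",
    "eue",
    "scenario",
]


def daily_interception(dli: float, coverage_pct: float) -> float:
    """Daily intercepted light: supplied DLI times floor coverage.

    ``coverage_pct`` in [0, 100]; result in mol m-2 d-1.
    """
    if not 0 <= coverage_pct <= 100:
        raise ValueError(f"coverage_pct must be in [0, 100], got {coverage_pct}")
    if dli < 0:
        raise ValueError("dli must be >= 0")
    return dli * coverage_pct / 100.0


@dataclass(frozen=True)
class HarvestRecord:
    """Destructive harvest measurements of one plant at 19 DAT."""

    block: int
    treatment: str
    cultivar: str
    plant_id: int
    fresh_mass: float  # g plant-1
    dry_mass: float    # g plant-1
    leaf_area: float   # cm2 plant-1
    leaf_count: int = 1

    def __post_init__(self) -> None:
        if self.fresh_mass <= 0 or self.dry_mass <= 0:
            raise ValueError("masses must be positive")
        if self.dry_mass > self.fresh_mass:
            raise ValueError("dry mass cannot exceed fresh mass")
        if self.leaf_count < 1:
            raise ValueError("leaf_count must be >= 1")


@dataclass(frozen=True)
class DerivedTraits:
    """Per-plant derived traits.

    dmc : dry matter content, % of fresh mass
    lai : leaf area index, cm2 leaf per cm2 ground
    sla : specific leaf area, cm2 g_DM-1
    fresh_per_area, dry_per_area : g m-2 ground
    """

    dmc: float
    lai: float
    sla: float
    fresh_per_area: float
    dry_per_area: float


def derive_traits(record: HarvestRecord, density: float = defaults.PLANT_DENSITY) -> DerivedTraits:
    """Derive DMC, LAI, SLA and ground-area-based masses for one plant.

    ``density`` is plants m-2.  LAI converts cm2 plant-1 times plants m-2
    to the dimensionless cm2 cm-2 (divide by 1e4 cm2/m2).  Treatment-level
    summaries of these ratio traits are means of per-plant ratios, not
    ratios of treatment means.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    return DerivedTraits(
        dmc=100.0 * record.dry_mass / record.fresh_mass,
        lai=record.leaf_area * density / 1e4,
        sla=record.leaf_area / record.dry_mass,
        fresh_per_area=record.fresh_mass * density,
        dry_per_area=record.dry_mass * density,
    )


def add_derived_traits(table, density: float = defaults.PLANT_DENSITY):
    """Append dmc, lai and sla columns to a per-plant harvest table.

    ``table`` needs fresh_mass, dry_mass and leaf_area columns; returns a
    copy with the ratio traits computed per plant.
    """
    out = table.copy()
    out["dmc"] = 100.0 * out.dry_mass / out.fresh_mass
    out["lai"] = out.leaf_area * density / 1e4
    out["sla"] = out.leaf_area / out.dry_mass
    return out


def lue(mass_per_area: float, cumulative_interception: float) -> float:
    """Light use efficiency: biomass per intercepted light (g mol-1).

    ``mass_per_area`` in g m-2 (fresh or dry), ``cumulative_interception``
    in mol m-2 over the growing period.
    """
    if cumulative_interception <= 0:
        raise ValueError("cumulative interception must be > 0")
    return mass_per_area / cumulative_interception


# --------------------------------------------------------------------------
# energy model

@dataclass(frozen=True)
class TemperatureRegime:
    """Air-temperature setpoints over the light/dark cycle (degC)."""

    t_light: float = 23.0
    t_dark: float = 23.0
    photoperiod_h: float = 18.0


@dataclass(frozen=True)
class EnergyScenario:
    """One LED-efficacy / temperature scenario of the energy model.

    ``efficacy`` maps treatment label to LED photon efficacy (umol J-1);
    ``photoperiod_h`` maps treatment to its photoperiod.  ``tpfd_per_day``
    is the common daily photon sum both treatments deliver, and ``days``
    the number of light-days cumulated (20, covering 0-19 DAT inclusive).
    """

    label: str
    efficacy: dict[str, float]
    cop: float = defaults.COP
    t_light: float = 23.0
    t_dark: float = 23.0
    tpfd_per_day: float = defaults.NOMINAL_TPFD
    days: int = defaults.ENERGY_DAYS
    photoperiod_h: dict[str, float] | None = None
    heat_fraction: float = 1.0
    envelope_ua: float = 0.0       # W m-2 K-1 envelope conductance
    t_ambient: float | None = None  # surroundings temperature for envelope loss

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.efficacy.values()):
            raise ValueError("efficacies must be > 0")
        if self.cop <= 0:
            raise ValueError("COP must be > 0")
        if self.days < 1:
            raise ValueError("days must be >= 1")


def scenario(label: str) -> EnergyScenario:
    """Build one of the three canonical scenarios A/B/C.

    A: equal photon efficacy (3.6 umol J-1), constant 23 degC.
    B: custom efficacies (3.4 for the 18-h photoperiod, 3.6 for CL),
       constant 23 degC.
    C: efficacies as B, day/night setpoints 24/20 degC (mean 23 degC).
    """
    if label not in defaults.SCENARIO_EFFICACIES:
        raise ValueError(f"unknown scenario {label!r}; expected one of A, B, C")
    t_light, t_dark = defaults.SCENARIO_TEMPERATURES[label]
    return EnergyScenario(
        label=label,
        efficacy=dict(defaults.SCENARIO_EFFICACIES[label]),
        t_light=t_light,
        t_dark=t_dark,
        photoperiod_h=dict(defaults.PHOTOPERIOD_H),
    )


@dataclass(frozen=True)
class EnergyResult:
    """LED, HVAC and total electricity per treatment (kWh m-2)."""

    led: float
    hvac: float

    @property
    def total(self) -> float:
        return self.led + self.hvac


def led_energy(tpfd_per_day: float, days: int, efficacy: float) -> float:
    """LED electricity to deliver a daily photon sum for a number of days.

    ``tpfd_per_day`` mol m-2 d-1, ``efficacy`` umol J-1; result kWh m-2.
    Independent of how the day's photons are spread over the photoperiod.
    """
    if tpfd_per_day <= 0 or days <= 0 or efficacy <= 0:
        raise ValueError("tpfd_per_day, days and efficacy must all be > 0")
    joules = tpfd_per_day * 1e6 / efficacy * days
    return joules / 3.6e6


def hvac_energy(
    led_electrical: float,
    cop: float = defaults.COP,
    regime: TemperatureRegime | None = None,
    heat_fraction: float = 1.0,
    envelope_ua: float = 0.0,
    t_ambient: float | None = None,
    days: int = defaults.ENERGY_DAYS,
) -> float:
    """Cooling electricity for the chamber heat load (kWh m-2).

    Static heat balance: the load is ``led_electrical * heat_fraction``
    (all LED electrical input degrades to sensible heat in an airtight,
    well-insulated chamber; ``heat_fraction`` < 1 lets callers park part of
    the input in biomass or losses).  With a non-zero envelope conductance
    ``envelope_ua`` (W m-2 K-1) and a surroundings temperature, conduction
    through the envelope offsets the load period-by-period under the
    day/night setpoints of ``regime``.  The remaining load is removed at
    ``hvac = load / cop``.  All assumptions are logged.
    """
    if cop <= 0:
        raise ValueError("COP must be > 0")
    if led_electrical < 0:
        raise ValueError("led_electrical must be >= 0")
    load = led_electrical * heat_fraction
    if envelope_ua > 0 and t_ambient is not None and regime is not None:
        h_light = regime.photoperiod_h
        h_dark = 24.0 - h_light
        # W m-2 K-1 * K * h * days -> Wh m-2 -> kWh m-2
        loss = envelope_ua * (
            (regime.t_light - t_ambient) * h_light
            + (regime.t_dark - t_ambient) * h_dark
        ) * days / 1000.0
        load = max(load - loss, 0.0)
        logger.info("hvac_energy: envelope loss %.3f kWh m-2 at UA=%.2f", loss, envelope_ua)
    logger.info(
        "hvac_energy: load=%.3f kWh m-2 (heat_fraction=%.2f), COP=%.1f",
        load, heat_fraction, cop,
    )
    return load / cop


def run_scenario(sc: EnergyScenario,
                 treatments: tuple[str, ...] = defaults.TREATMENTS,
                 ) -> dict[str, object]:
    """Energy use per treatment under one scenario, with CL/18-h contrasts.

    Returns ``{"per_treatment": {treatment: EnergyResult}, "percent_change":
    {"led": ..., "hvac": ..., "total": ...}}`` where percent changes are of
    the second treatment relative to the first (CL vs 18-h by default).
    """
    photoperiods = sc.photoperiod_h or dict(defaults.PHOTOPERIOD_H)
    per: dict[str, EnergyResult] = {}
    for tr in treatments:
        led = led_energy(sc.tpfd_per_day, sc.days, sc.efficacy[tr])
        regime = TemperatureRegime(sc.t_light, sc.t_dark,
                                   photoperiods.get(tr, 24.0))
        hvac = hvac_energy(led, sc.cop, regime, sc.heat_fraction,
                           sc.envelope_ua, sc.t_ambient, sc.days)
        per[tr] = EnergyResult(led=led, hvac=hvac)
    ref, alt = treatments[0], treatments[-1]
    pct = {
        "led": percent_change(per[ref].led, per[alt].led),
        "hvac": percent_change(per[ref].hvac, per[alt].hvac),
        "total": percent_change(per[ref].total, per[alt].total),
    }
    return {"scenario": sc.label, "per_treatment": per, "percent_change": pct}


@dataclass(frozen=True)
class EfficiencyResult:
    """Energy-use efficiencies (g kWh-1) for one mass basis.

    The total EUE composes harmonically: 1/eue_total = 1/eue_led +
    1/eue_hvac, so the total is always below both components.
    """

    eue_led: float
    eue_hvac: float
    eue_total: float


def eue(mass_per_area: float, energy: EnergyResult) -> EfficiencyResult:
    """Energy use efficiency: biomass per electricity, per subsystem.

    ``mass_per_area`` in g m-2 (fresh- or dry-mass based), ``energy`` the
    cumulated LED/HVAC electricity of the treatment.
    """
    if energy.led <= 0 or energy.hvac <= 0:
        raise ValueError("energies must be > 0")
    return EfficiencyResult(
        eue_led=mass_per_area / energy.led,
        eue_hvac=mass_per_area / energy.hvac,
        eue_total=mass_per_area / energy.total,
    )
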