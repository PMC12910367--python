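"""Default study conditions for the continuous-light lettuce experiment.

The package models a climate-chamber experiment comparing an 18-hour
photoperiod against continuous light (CL) at the same daily light integral,
for the leaf-lettuce cultivars 'Danstar' and 'Jagger' grown at 56 plants/m2
for 0-19 days after transplant (DAT).  This module collects the published
summary conditions that drive the synthetic-data generator and the energy
scenarios: light recipes, harvest-trait and carbohydrate cell means with
their standard errors, and the scenario energy-use reference table.

All values are printed summary statistics of the emulated study; per-plant
raw data are not available and are re-created stochastically by
:mod:`clgrow.synth`.
"""

from __future__ import annotations

TREATMENTS = ("18h", "CL")
CULTIVARS = ("Danstar", "Jagger")

#: plants per square metre (chessboard layout, 15.6 cm in-row x 11.5 cm rows)
PLANT_DENSITY = 56.0
WITHIN_ROW_SPACING_CM = 15.6
ROW_SPACING_CM = 11.5

#: photoperiod hours per treatment
PHOTOPERIOD_H = {"18h": 18.0, "CL": 24.0}

#: measured photon fluxes, umol m-2 s-1 (mean over replicate experiments)
LIGHT_RECIPES = {
    "18h": {"ppfd": 258.0, "fr": 50.0, "photoperiod_h": 18.0},
    "CL": {"ppfd": 196.0, "fr": 38.0, "photoperiod_h": 24.0},
}

#: representative line spectrum of the deep-red/white + far-red lamps:
#: relative photon fractions by band (blue 400-499, green 500-599,
#: red 600-699, far-red 700-800 nm), placed at band-representative lines.
LAMP_SPECTRUM = {449.0: 0.065, 550.0: 0.148, 661.0: 0.613, 730.0: 0.174}

#: nominal cross-treatment total photon flux per day, mol m-2 d-1
NOMINAL_TPFD = 20.1
#: nominal supplied DLI used for interception accounting, mol m-2 d-1
NOMINAL_DLI = 16.9

#: harvest-trait cell means at 19 DAT, by (treatment, cultivar)
#: fresh/dry mass g plant-1, LAI cm2 cm-2, SLA cm2 g-1
HARVEST_CELL_MEANS = {
    ("18h", "Danstar"): {"fresh_mass": 40.6, "dry_mass": 2.00, "lai": 3.1, "sla": 279.0},
    ("CL", "Danstar"): {"fresh_mass": 42.9, "dry_mass": 2.27, "lai": 3.3, "sla": 257.0},
    ("18h", "Jagger"): {"fresh_mass": 49.5, "dry_mass": 2.04, "lai": 5.3, "sla": 460.0},
    ("CL", "Jagger"): {"fresh_mass": 60.9, "dry_mass": 2.50, "lai": 6.5, "sla": 465.0},
}

#: main-level (photoperiod, averaged over cultivars) harvest trait means
HARVEST_MAIN_MEANS = {
    "18h": {"fresh_mass": 45.0, "dry_mass": 2.02, "dmc": 4.78, "lai": 4.2, "sla": 369.0},
    "CL": {"fresh_mass": 51.9, "dry_mass": 2.38, "dmc": 4.94, "lai": 4.9, "sla": 361.0},
}

#: printed standard errors of treatment means (common-variance pooled)
HARVEST_SEM_MAIN = {"fresh_mass": 0.75, "dry_mass": 0.04, "dmc": 0.02, "lai": 0.05, "sla": 2.0}
HARVEST_SEM_INTERACTION = {"fresh_mass": 1.88, "dry_mass": 0.07, "dmc": 0.09, "lai": 0.15, "sla": 5.0}

#: carbohydrate cell means at 19 DAT, mg g_DW-1
CARB_CELL_MEANS = {
    ("18h", "Danstar"): {"glucose": 28.7, "fructose": 41.4, "sucrose": 42.2, "starch": 65.4},
    ("CL", "Danstar"): {"glucose": 24.6, "fructose": 31.8, "sucrose": 31.4, "starch": 73.5},
    ("18h", "Jagger"): {"glucose": 14.8, "fructose": 25.0, "sucrose": 39.7, "starch": 58.2},
    ("CL", "Jagger"): {"glucose": 19.0, "fructose": 25.3, "sucrose": 37.9, "starch": 86.6},
}
CARB_MAIN_MEANS = {
    "18h": {"glucose": 21.8, "fructose": 33.2, "sucrose": 40.9, "starch": 61.8},
    "CL": {"glucose": 21.8, "fructose": 28.6, "sucrose": 34.6, "starch": 80.0},
}
CARB_SEM_MAIN = {"glucose": 1.5, "fructose": 1.6, "sucrose": 1.1, "starch": 1.6}
CARB_SEM_INTERACTION = {"glucose": 2.5, "fructose": 3.0, "sucrose": 2.2, "starch": 3.4}

#: scenario energy-use reference table (kWh m-2, cumulated over 0-19 DAT) as
#: published by the emulated study's dynamic climate model.  The package's own
#: static heat balance reproduces the LED cells exactly; the HVAC cells derive
#: from unpublished model internals and are kept as reference inputs only.
ENERGY_REFERENCE = {
    "A": {"18h": {"led": 31.0, "hvac": 9.6, "total": 40.6},
          "CL": {"led": 31.0, "hvac": 9.2, "total": 40.2}},
    "B": {"18h": {"led": 32.8, "hvac": 10.2, "total": 43.0},
          "CL": {"led": 31.0, "hvac": 9.2, "total": 40.2}},
    "C": {"18h": {"led": 32.8, "hvac": 10.5, "total": 43.4},
          "CL": {"led": 31.0, "hvac": 9.3, "total": 40.3}},
}

#: LED photon efficacies per scenario, umol J-1
SCENARIO_EFFICACIES = {
    "A": {"18h": 3.6, "CL": 3.6},
    "B": {"18h": 3.4, "CL": 3.6},
    "C": {"18h": 3.4, "CL": 3.6},
}
#: air-temperature setpoints per scenario (light period / dark period, degC)
SCENARIO_TEMPERATURES = {
    "A": (23.0, 23.0),
    "B": (23.0, 23.0),
    "C": (24.0, 20.0),
}
#: HVAC coefficient of performance
COP = 3.0
#: light-days cumulated in the energy model (0-19 DAT inclusive)
ENERGY_DAYS = 20
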