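"""Energy scenarios and efficiency: LED/HVAC electricity, LUE and EUE.

Runs the three LED-efficacy/temperature scenarios (A: equal efficacy 3.6
umol J-1 at constant 23 degC; B: custom efficacies 3.4/3.6; C: B plus
24/20 degC day/night setpoints), writes the scenario energy table, and
combines simulated harvest masses with the cumulative interception series
to compute light-use efficiency (g mol-1) and scenario-A energy-use
efficiency (g kWh-1) per treatment, with CL vs 18-h contrasts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from clgrow import defaults
from clgrow.energy import eue, lue, run_scenario, scenario
from clgrow.photon import percent_change, round_half_away
from clgrow.synth import SimConfig, simulate_harvest


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results", type=Path)
    ap.add_argument("--growth", default="results/growth_fits.json", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for label in ("A", "B", "C"):
        res = run_scenario(scenario(label))
        for tr, e in res["per_treatment"].items():
            rows.append((label, tr, e.led, e.hvac, e.total))
        pc = res["percent_change"]
        rows.append((label, "pct_change", pc["led"], pc["hvac"], pc["total"]))
    energy = pd.DataFrame(rows, columns=["scenario", "treatment", "led", "hvac", "total"])
    energy.to_csv(args.out / "energy_scenarios.csv", index=False)
    print("energy use, kWh m-2 (0-19 DAT):")
    print(energy.round(2).to_string(index=False))
    print("note: HVAC is the static heat balance load/COP "
          "(all LED input degrades to heat, COP 3)")

    cfg = SimConfig(seed=args.seed)
    harvest = simulate_harvest(cfg)
    main_means = harvest.groupby("treatment")[["fresh_mass", "dry_mass"]].mean()

    if args.growth.exists():
        cum = json.loads(args.growth.read_text())["cumulative_interception"]
        cum_main = {tr: sum(v for k, v in cum.items() if k.startswith(tr)) / 2
                    for tr in defaults.TREATMENTS}
        lue_rows = []
        for tr in defaults.TREATMENTS:
            lue_rows.append((
                tr,
                lue(main_means.loc[tr, "fresh_mass"] * cfg.density, cum_main[tr]),
                lue(main_means.loc[tr, "dry_mass"] * cfg.density, cum_main[tr]),
            ))
        lue_tab = pd.DataFrame(lue_rows, columns=["treatment", "lue_fm", "lue_dm"])
        lue_tab.to_csv(args.out / "lue.csv", index=False)
        print("\nlight use efficiency (g mol-1):")
        print(lue_tab.round(3).to_string(index=False))
        print(f"LUE_DM change CL vs 18h: "
              f"{percent_change(lue_tab.lue_dm[0], lue_tab.lue_dm[1]):+.1f}%")
    else:
        print(f"\n(no {args.growth}; run 04_fit_growth.py for the LUE table)")

    per_a = run_scenario(scenario("A"))["per_treatment"]
    eue_rows = []
    for tr in defaults.TREATMENTS:
        fm = eue(main_means.loc[tr, "fresh_mass"] * cfg.density, per_a[tr])
        dm = eue(main_means.loc[tr, "dry_mass"] * cfg.density, per_a[tr])
        eue_rows.append((tr, fm.eue_led, fm.eue_hvac, fm.eue_total,
                         dm.eue_led, dm.eue_hvac, dm.eue_total))
    eue_tab = pd.DataFrame(eue_rows, columns=[
        "treatment", "fm_led", "fm_hvac", "fm_total", "dm_led", "dm_hvac", "dm_total"])
    eue_tab.to_csv(args.out / "eue_scenario_a.csv", index=False)
    pct = percent_change(eue_tab.fm_total[0], eue_tab.fm_total[1])
    print("\nscenario-A EUE (g kWh-1):")
    print(eue_tab.round(1).to_string(index=False))
    print(f"fresh-mass total-EUE change CL vs 18h: {round_half_away(pct):+.0f}%")
    print(f"wrote energy/LUE/EUE tables to {args.out}")


if __name__ == "__main__":
    main()
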