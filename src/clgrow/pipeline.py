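"""End-to-end orchestration: simulate -> segment -> fit -> efficiency -> stats.

:func:`run_pipeline` composes the whole analysis chain from one
configuration and returns a machine-readable report:

1. photon accounting of both light recipes (treatment-summary shape);
2. synthetic cohort generation (PLA trajectories, harvest and
   carbohydrate tables, rendered top-view images);
3. image segmentation, floor coverage and daily light interception;
4. exponential PLA fits and the Bayesian Richards interception fit with
   cumulative interception 1-19 DAT;
5. light-use efficiency per treatment x cultivar;
6. LED/HVAC energy scenarios and energy-use efficiency;
7. Tukey-fence outlier exclusion, split-plot ANOVA and protected-LSD
   letters for every harvest and carbohydrate trait.

Stage artefacts can be persisted as plain CSV/JSON under an output
directory so any stage is independently re-runnable; the seed recorded in
the report fully determines every stochastic stage.  A stage failure
raises with the stage name attached, leaving the partial report on the
exception.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .energy import add_derived_traits, daily_interception, eue, lue, run_scenario, scenario
from .growth import cumulative_interception, fit_exponential_pla, fit_richards_mcmc
from .imaging import chessboard_layout, floor_coverage_series, segment_canopy
from .photon import LightRecipe, percent_change
from .stats import split_plot_anova, tukey_outliers
from .synth import (
    SimConfig,
    render_topview,
    simulate_carbohydrates,
    simulate_harvest,
    simulate_pla,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

HARVEST_TRAITS = ("fresh_mass", "dry_mass", "dmc", "lai", "sla")
CARB_TRAITS = ("glucose", "fructose", "sucrose", "starch")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial report."""

    def __init__(self, stage: str, report: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_report = report


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    sim: SimConfig | None = None
    outdir: str | Path | None = None
    density: float = defaults.PLANT_DENSITY
    scenarios: tuple[str, ...] = ("A", "B", "C")
    alpha: float = 0.05
    cm_per_px: float = 0.1
    image_rows: int = 4
    image_cols: int = 5
    mcmc_chains: int = 4
    mcmc_iterations: int = 4000
    mcmc_warmup: int = 1000
    run_mcmc: bool = True

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        return SimConfig(seed=self.seed)


def _coverage_for_group(cfg: PipelineConfig, params, tr: str, cv: str,
                        seed: int) -> list[tuple[float, float]]:
    """Render daily top views for one treatment x cultivar and segment them."""
    layout = chessboard_layout(cfg.image_rows, cfg.image_cols, density=cfg.density)
    # frame the tray so pixel area per plant matches the planting density
    extent = (cfg.image_cols * layout.within_row_spacing,
              cfg.image_rows * layout.row_spacing)
    a, r = params[(tr, cv)]
    masks = []
    for dat in range(1, 20):
        pla = float(a * np.exp(r * dat))
        img, _truth = render_topview([pla] * len(layout.centres), layout,
                                     cm_per_px=cfg.cm_per_px,
                                     seed=seed + dat, dat=float(dat),
                                     extent_cm=extent)
        # fixed calibrated ExG threshold: the daily series spans 0-100%
        # coverage, where Otsu is unreliable once either class nearly
        # vanishes (see docs/methods.md)
        masks.append(segment_canopy(img, "fixed", fixed_threshold=60.0))
    return floor_coverage_series(masks)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain; return the report dictionary."""
    report: dict = {"seed": config.seed, "stages": []}
    sim = config.resolved_sim()
    stage = "photon"
    try:
        photon_rows = {}
        for tr, rec in defaults.LIGHT_RECIPES.items():
            recipe = LightRecipe(spectrum=dict(defaults.LAMP_SPECTRUM), **rec)
            s = recipe.summary()
            photon_rows[tr] = {
                "ppfd": recipe.ppfd, "fr": recipe.fr, "pfd": s.pfd,
                "photoperiod_h": recipe.photoperiod_h,
                "dli": s.dli, "tpfd": s.tpfd, "r_fr": s.r_fr, "pss": s.pss,
            }
        photon_rows["percent_change"] = {
            k: percent_change(photon_rows["18h"][k], photon_rows["CL"][k])
            for k in ("ppfd", "fr", "pfd", "dli", "tpfd")
        }
        report["photon"] = photon_rows
        report["stages"].append(stage)

        stage = "simulate"
        pla_table, pla_truth = simulate_pla(sim)
        harvest = simulate_harvest(sim)
        carbs = simulate_carbohydrates(sim)
        report["stages"].append(stage)

        stage = "coverage"
        params = pla_truth["params"]
        interception: dict[str, dict] = {}
        for tr in defaults.TREATMENTS:
            for cv in defaults.CULTIVARS:
                cov = _coverage_for_group(config, params, tr, cv, seed=sim.seed)
                daily = [(d, daily_interception(sim.dli, c)) for d, c in cov]
                interception[f"{tr}:{cv}"] = {
                    "coverage": cov,
                    "daily": daily,
                    "cumulative": cumulative_interception(
                        [d for d, _ in daily], [y for _, y in daily]
                    ),
                }
        report["interception"] = {
            k: {"cumulative": v["cumulative"]} for k, v in interception.items()
        }
        report["stages"].append(stage)

        stage = "growth_fits"
        fits = {}
        for cv in defaults.CULTIVARS:
            sub = pla_table[pla_table.cultivar == cv]
            series = {
                tr: (sub[sub.treatment == tr].dat.to_numpy(),
                     sub[sub.treatment == tr].pla_cm2.to_numpy())
                for tr in defaults.TREATMENTS
            }
            fit = fit_exponential_pla(series)
            fits[cv] = {
                "pla_initial": fit.pla_initial,
                "rgr": fit.rgr,
                "rgr_se": fit.rgr_se,
                "converged": fit.converged,
            }
        report["exponential_fits"] = fits
        if config.run_mcmc:
            rich = {}
            for key, ic in interception.items():
                dat = np.array([d for d, _ in ic["daily"]])
                y = np.array([v for _, v in ic["daily"]])
                post = fit_richards_mcmc(
                    dat, y, chains=config.mcmc_chains,
                    iterations=config.mcmc_iterations,
                    warmup=config.mcmc_warmup, seed=sim.seed,
                )
                rich[key] = {
                    "posterior_mean": post.posterior_mean(),
                    "rhat": post.rhat, "ess": post.ess,
                    "converged": post.converged,
                }
            report["richards"] = rich
        report["stages"].append(stage)

        stage = "traits"
        traits = add_derived_traits(harvest, density=config.density)
        report["stages"].append(stage)

        stage = "stats"
        stats_report: dict = {}
        excluded: dict[str, int] = {}
        for name, tab, cols in (("harvest", traits, HARVEST_TRAITS),
                                ("carbohydrates", carbs, CARB_TRAITS)):
            stats_report[name] = {}
            for trait in cols:
                work = tab.rename(columns={trait: "value"})[
                    ["block", "treatment", "cultivar", "value"]
                ]
                flags = tukey_outliers(work)
                excluded[f"{name}:{trait}"] = int(flags.sum())
                res = split_plot_anova(work[~flags], alpha=config.alpha)
                stats_report[name][trait] = {
                    "p_main": res.f_prob_main,
                    "p_cultivar": res.f_prob_cultivar,
                    "p_interaction": res.f_prob_interaction,
                    "sem_main": res.sem_main,
                    "sem_interaction": res.sem_interaction,
                    "means_main": {str(k): float(v) for k, v in res.means_main.items()},
                    "means_cell": {f"{k[0]}:{k[1]}": float(v)
                                   for k, v in res.means_cell.items()},
                    "letters_main": res.letters_main,
                    "letters_interaction": {f"{k[0]}:{k[1]}": v for k, v in
                                            res.letters_interaction.items()},
                    "n_outliers_excluded": int(flags.sum()),
                }
        report["stats"] = stats_report
        report["stages"].append(stage)

        stage = "lue"
        lue_report = {}
        cell_means = traits.groupby(["treatment", "cultivar"], observed=True)[
            ["fresh_mass", "dry_mass"]
        ].mean()
        for (tr, cv), row in cell_means.iterrows():
            cum = interception[f"{tr}:{cv}"]["cumulative"]
            lue_report[f"{tr}:{cv}"] = {
                "lue_fm": lue(row.fresh_mass * config.density, cum),
                "lue_dm": lue(row.dry_mass * config.density, cum),
            }
        report["lue"] = lue_report
        report["stages"].append(stage)

        stage = "energy"
        energy_report = {}
        for label in config.scenarios:
            res = run_scenario(scenario(label))
            per = res["per_treatment"]
            energy_report[label] = {
                tr: {"led": e.led, "hvac": e.hvac, "total": e.total}
                for tr, e in per.items()
            }
            energy_report[label]["percent_change"] = res["percent_change"]
        report["energy"] = energy_report

        main_means = traits.groupby("treatment", observed=True)[
            ["fresh_mass", "dry_mass"]
        ].mean()
        eue_report = {}
        per_a = run_scenario(scenario("A"))["per_treatment"]
        for tr in defaults.TREATMENTS:
            e = per_a[tr]
            fm = eue(main_means.loc[tr, "fresh_mass"] * config.density, e)
            dm = eue(main_means.loc[tr, "dry_mass"] * config.density, e)
            eue_report[tr] = {
                "fm": asdict(fm), "dm": asdict(dm),
            }
        eue_report["percent_change_total_fm"] = percent_change(
            eue_report["18h"]["fm"]["eue_total"], eue_report["CL"]["fm"]["eue_total"]
        )
        eue_report["percent_change_total_dm"] = percent_change(
            eue_report["18h"]["dm"]["eue_total"], eue_report["CL"]["dm"]["eue_total"]
        )
        report["eue"] = eue_report
        report["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - halt with stage name + partial report
        raise PipelineError(stage, report, exc) from exc

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pla_table.to_csv(out / "pla_series.csv", index=False)
        harvest.to_csv(out / "harvest.csv", index=False)
        carbs.to_csv(out / "carbohydrates.csv", index=False)
        traits.to_csv(out / "harvest_derived.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
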