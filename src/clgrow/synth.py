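"""Synthetic-data generator for the continuous-light lettuce pipeline.

The study's raw data (daily top-view images, per-plant harvest and
carbohydrate tables) are not deposited; this module re-creates inputs with
the statistical structure the analysis assumes, so every pipeline stage is
testable without a download.  Every generator is a pure function of its
configuration and seed.

What is emulated
----------------
* Projected leaf area grows exponentially,
  ``PLA(t) = PLA_initial * exp(RGR * t) * eps`` with lognormal noise eps,
  three phase-stamped observations per day.  Per-cultivar growth rates are
  chosen so the 19-DAT leaf area reproduces the study's cell-mean LAI, and
  the continuous-light RGR offsets are derived from the published CL/18-h
  LAI ratios (1.06 'Danstar', 1.23 'Jagger').
* Top-view images render each plant as a green disc of area PLA on its
  chessboard layout centre, with pixel noise, alongside the ground-truth
  mask.
* Harvest traits are drawn around the published treatment x cultivar cell
  means with a block (replicate experiment) effect, a whole-plot
  (block x photoperiod) effect, and plant-level noise.  Dry mass is
  generated as fresh mass times a dry-matter-content draw so that
  ``dry <= fresh`` holds by construction.
* Carbohydrates (glucose, fructose, sucrose, starch) are drawn around the
  published cell means with SEM-scaled noise.

Noise calibration: the plant-level SD of each trait is set so the
simulated main-level standard error matches the printed main-level SEM
(``sd = SEM_main * sqrt(N_main)``), with a 1%-CV whole-plot SD and a 2%-CV
block SD; the printed main- and interaction-level SEMs are pooled
common-variance quantities that no non-negative variance pair reproduces
jointly (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .imaging import CanopyImage, CanopyMask, PlantLayout

__all__ = [
    "SimConfig",
    "simulate_pla",
    "render_topview",
    "simulate_harvest",
    "simulate_carbohydrates",
    "pla_trajectory_params",
]

#: number of observations per main-level (photoperiod) mean at full design
_N_MAIN = 4 * 2 * 10.5


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the emulated study's conditions: 4 blocks, 10-11
    plants per treatment x cultivar cell, 56 plants m-2 chessboard layout,
    16.9 mol m-2 d-1 supplied DLI, days 0-19, lognormal PLA noise, and
    harvest/carbohydrate cell means from the published tables with
    SEM-calibrated noise.
    """

    seed: int = 0
    n_blocks: int = 4
    plants_per_cell: tuple[int, ...] = (11, 10)  # per cultivar (Danstar, Jagger)
    days: tuple[int, int] = (0, 19)
    dli: float = defaults.NOMINAL_DLI
    pla_initial: float = 5.0
    pla_noise_sd: float = 0.05        # lognormal sd of PLA observations
    cl_lai_ratio: dict[str, float] = field(
        default_factory=lambda: {"Danstar": 1.06, "Jagger": 1.23}
    )
    trait_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.HARVEST_CELL_MEANS.items()}
    )
    carb_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.CARB_CELL_MEANS.items()}
    )
    trait_sems: dict = field(default_factory=lambda: dict(defaults.HARVEST_SEM_MAIN))
    carb_sems: dict = field(default_factory=lambda: dict(defaults.CARB_SEM_MAIN))
    noise_scale: float = 1.0          # 0 switches all stochastic terms off
    block_cv: float = 0.02
    wholeplot_cv: float = 0.01
    density: float = defaults.PLANT_DENSITY

    def with_zero_noise(self) -> "SimConfig":
        return replace(self, noise_scale=0.0, pla_noise_sd=0.0)


def pla_trajectory_params(config: SimConfig) -> dict[tuple[str, str], tuple[float, float]]:
    """True (PLA_initial, RGR) per (treatment, cultivar).

    The 18-h RGR of each cultivar is set so PLA at 19 DAT matches the
    cell-mean leaf area implied by the published LAI
    (``leaf_area = LAI * 1e4 / density``); the CL rate adds
    ``ln(cl_lai_ratio) / 19`` so the end-state LAI ratio reproduces the
    published CL/18-h contrast.
    """
    t_end = config.days[1]
    out = {}
    for cv in defaults.CULTIVARS:
        leaf_area_18 = config.trait_means[("18h", cv)]["lai"] * 1e4 / config.density
        rgr_18 = math.log(leaf_area_18 / config.pla_initial) / t_end
        rgr_cl = rgr_18 + math.log(config.cl_lai_ratio[cv]) / t_end
        out[("18h", cv)] = (config.pla_initial, rgr_18)
        out[("CL", cv)] = (config.pla_initial, rgr_cl)
    return out


#: within-day imaging phases as fractional-day offsets (start, midpoint and
#: end of the 18-h photoperiod, or equivalent clock times under CL)
_PHASES = (("start-photoperiod", 0.0), ("midpoint", 0.375), ("end-photoperiod", 0.75))


def simulate_pla(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate per-plant PLA trajectories with multiplicative noise.

    Returns a long table (block, treatment, cultivar, plant_id, dat,
    phase, pla_cm2) plus a ground-truth dict holding the generating
    parameters and the noiseless trajectories.
    """
    rng = np.random.default_rng(config.seed)
    params = pla_trajectory_params(config)
    d0, d1 = config.days
    rows = []
    truth_series: dict = {}
    for tr in defaults.TREATMENTS:
        for cv_i, cv in enumerate(defaults.CULTIVARS):
            a, r = params[(tr, cv)]
            for blk in range(1, config.n_blocks + 1):
                n_pl = config.plants_per_cell[cv_i % len(config.plants_per_cell)]
                for pid in range(n_pl):
                    # small per-plant spread of initial size and rate
                    a_i = a * math.exp(config.noise_scale * 0.05 * rng.standard_normal())
                    r_i = r * (1 + config.noise_scale * 0.02 * rng.standard_normal())
                    for dat in range(d0, d1 + 1):
                        for phase, off in _PHASES:
                            t = dat + off
                            mu = a_i * math.exp(r_i * t)
                            eps = math.exp(config.pla_noise_sd * rng.standard_normal()) \
                                if config.pla_noise_sd > 0 else 1.0
                            rows.append((blk, tr, cv, pid, t, phase, mu * eps))
                    truth_series[(tr, cv, blk, pid)] = (a_i, r_i)
    table = pd.DataFrame(
        rows,
        columns=["block", "treatment", "cultivar", "plant_id", "dat", "phase", "pla_cm2"],
    )
    truth = {"params": params, "per_plant": truth_series,
             "pla_initial": config.pla_initial}
    return table, truth


def render_topview(
    plas: list[float],
    layout: PlantLayout,
    cm_per_px: float = 0.05,
    seed: int = 0,
    noise_sd: float = 4.0,
    dat: float = 0.0,
    phase: str = "midpoint",
    extent_cm: tuple[float, float] | None = None,
) -> tuple[CanopyImage, CanopyMask]:
    """Render plants as green discs on a dark tray; return image + truth mask.

    ``plas[i]`` (cm2) becomes a disc of radius ``sqrt(pla/pi)`` centred on
    ``layout.centres[i]``.  Discs may merge once radii exceed half the
    plant spacing (canopy closure); clipping at full coverage is allowed.
    Additive Gaussian pixel noise with SD ``noise_sd`` (8-bit counts) is
    applied to the RGB render; the returned mask is the exact ground
    truth, unaffected by noise.
    """
    if len(plas) != len(layout.centres):
        raise ValueError("need one PLA per layout centre")
    if any(p < 0 for p in plas):
        raise ValueError("PLA values must be >= 0")
    centres = np.asarray(layout.centres, dtype=float)
    if extent_cm is None:
        w_cm = centres[:, 0].max() + layout.within_row_spacing / 2.0
        h_cm = centres[:, 1].max() + layout.row_spacing / 2.0
    else:
        w_cm, h_cm = extent_cm
    w_px = int(round(w_cm / cm_per_px))
    h_px = int(round(h_cm / cm_per_px))
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    mask = np.zeros((h_px, w_px), dtype=bool)
    for (cx, cy), pla in zip(centres, plas):
        if pla <= 0:
            continue
        r_px = math.sqrt(pla / math.pi) / cm_per_px
        mask |= (xx - cx / cm_per_px) ** 2 + (yy - cy / cm_per_px) ** 2 <= r_px ** 2

    rng = np.random.default_rng(seed)
    img = np.empty((h_px, w_px, 3), dtype=float)
    img[..., 0] = np.where(mask, 45.0, 30.0)
    img[..., 1] = np.where(mask, 150.0, 32.0)
    img[..., 2] = np.where(mask, 45.0, 30.0)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return (
        CanopyImage(pixels=img, cm_per_px=cm_per_px, dat=dat, phase=phase),
        CanopyMask(mask=mask, cm_per_px=cm_per_px, dat=dat, phase=phase),
    )


def _cell_effects(rng: np.random.Generator, config: SimConfig,
                  grand_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw block and block x treatment (whole-plot) multiplicative effects."""
    s = config.noise_scale
    blk = 1.0 + s * config.block_cv * rng.standard_normal(config.n_blocks)
    wp = 1.0 + s * config.wholeplot_cv * rng.standard_normal((config.n_blocks, 2))
    return blk, wp


def simulate_harvest(config: SimConfig) -> pd.DataFrame:
    """Simulate the per-plant harvest-trait table at 19 DAT.

    Columns: block, treatment, cultivar, plant_id, fresh_mass, dry_mass,
    leaf_area, leaf_count.  At ``noise_scale = 0`` every cell reproduces
    its configured means exactly.  Dry mass is fresh mass times a DMC
    draw, so ``dry <= fresh`` whenever DMC < 100%.
    """
    rng = np.random.default_rng(config.seed + 1)
    s = config.noise_scale
    sd_fresh = config.trait_sems["fresh_mass"] * math.sqrt(_N_MAIN)
    sd_lai = config.trait_sems["lai"] * math.sqrt(_N_MAIN)
    sd_dmc = config.trait_sems["dmc"] * math.sqrt(_N_MAIN)
    blk_eff, wp_eff = _cell_effects(rng, config, 0.0)
    rows = []
    for t_i, tr in enumerate(defaults.TREATMENTS):
        for cv_i, cv in enumerate(defaults.CULTIVARS):
            m = config.trait_means[(tr, cv)]
            dmc_mean = 100.0 * m["dry_mass"] / m["fresh_mass"]
            leaf_area_mean = m["lai"] * 1e4 / config.density
            for blk in range(1, config.n_blocks + 1):
                scale = blk_eff[blk - 1] * wp_eff[blk - 1, t_i]
                n_pl = config.plants_per_cell[cv_i % len(config.plants_per_cell)]
                for pid in range(n_pl):
                    fresh = m["fresh_mass"] * scale + s * sd_fresh * rng.standard_normal()
                    fresh = max(fresh, 0.05 * m["fresh_mass"])
                    dmc = dmc_mean + s * sd_dmc * rng.standard_normal()
                    dmc = float(np.clip(dmc, 0.5, 99.0))
                    leaf_area = leaf_area_mean * scale + s * sd_lai * 1e4 / config.density \
                        * rng.standard_normal()
                    leaf_area = max(leaf_area, 1.0)
                    leaf_count = max(int(round(25 + s * 3 * rng.standard_normal())), 1)
                    rows.append((blk, tr, cv, pid, fresh, fresh * dmc / 100.0,
                                 leaf_area, leaf_count))
    return pd.DataFrame(
        rows,
        columns=["block", "treatment", "cultivar", "plant_id",
                 "fresh_mass", "dry_mass", "leaf_area", "leaf_count"],
    )


def simulate_carbohydrates(config: SimConfig) -> pd.DataFrame:
    """Simulate the leaf carbohydrate table (mg g_DW-1) at 19 DAT.

    Samples are nominally taken at noon (midpoint of the 18-h photoperiod,
    or the equivalent clock time under CL); no diel dynamics are
    simulated.  At ``noise_scale = 0`` every cell reproduces its
    configured means exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    s = config.noise_scale
    sds = {k: v * math.sqrt(_N_MAIN) for k, v in config.carb_sems.items()}
    blk_eff, wp_eff = _cell_effects(rng, config, 0.0)
    rows = []
    for t_i, tr in enumerate(defaults.TREATMENTS):
        for cv_i, cv in enumerate(defaults.CULTIVARS):
            m = config.carb_means[(tr, cv)]
            for blk in range(1, config.n_blocks + 1):
                scale = blk_eff[blk - 1] * wp_eff[blk - 1, t_i]
                n_pl = config.plants_per_cell[cv_i % len(config.plants_per_cell)]
                for pid in range(n_pl):
                    vals = {
                        k: max(m[k] * scale + s * sds[k] * rng.standard_normal(),
                               0.05 * m[k])
                        for k in ("glucose", "fructose", "sucrose", "starch")
                    }
                    rows.append((blk, tr, cv, pid, vals["glucose"], vals["fructose"],
                                 vals["sucrose"], vals["starch"]))
    return pd.DataFrame(
        rows,
        columns=["block", "treatment", "cultivar", "plant_id",
                 "glucose", "fructose", "sucrose", "starch"],
    )
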