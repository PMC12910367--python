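"""Growth-model fits: exponential PLA and the Bayesian Richards curve.

Fits (a) the shared-initial exponential to per-plant PLA in the 2-13 DAT
no-overlap window, per cultivar with one rate per photoperiod, and (b) the
Richards light-interception curve per treatment x cultivar by MCMC (4
chains x 4000 iterations, 1000 warm-up, normal priors on the natural
scale), then integrates daily interception 1-19 DAT.  Reads the coverage
series written by 03_segment_and_coverage.py (regenerates the cohort
itself from the seed) and writes fit summaries plus posterior draws.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from clgrow.growth import cumulative_interception, fit_exponential_pla, fit_richards_mcmc
from clgrow.synth import SimConfig, pla_trajectory_params, simulate_pla


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results", type=Path)
    ap.add_argument("--coverage", default="results/coverage_interception.csv", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    pla_table, _ = simulate_pla(cfg)
    truth = pla_trajectory_params(cfg)

    summary: dict = {"seed": args.seed, "exponential": {}, "richards": {},
                     "cumulative_interception": {}}
    print("exponential PLA fits (2-13 DAT window, shared initial PLA):")
    for cv in ("Danstar", "Jagger"):
        sub = pla_table[pla_table.cultivar == cv]
        series = {tr: (sub[sub.treatment == tr].dat.to_numpy(),
                       sub[sub.treatment == tr].pla_cm2.to_numpy())
                  for tr in ("18h", "CL")}
        fit = fit_exponential_pla(series)
        summary["exponential"][cv] = {
            "pla_initial": fit.pla_initial, "rgr": fit.rgr, "rgr_se": fit.rgr_se,
            "iterations": fit.iterations, "converged": fit.converged,
        }
        for tr in ("18h", "CL"):
            print(f"  {cv:<8} {tr:>3}: RGR {fit.rgr[tr]:.4f} "
                  f"(+- {fit.rgr_se[tr]:.4f}) d-1   [truth {truth[(tr, cv)][1]:.4f}]")

    if not args.coverage.exists():
        raise SystemExit(f"coverage series {args.coverage} missing; "
                         "run 03_segment_and_coverage.py first")
    cov = pd.read_csv(args.coverage)
    draws_frames = []
    print("\nRichards interception fits (4 chains x 4000, 1000 warm-up):")
    for (tr, cv), grp in cov.groupby(["treatment", "cultivar"]):
        post = fit_richards_mcmc(grp.dat.to_numpy(), grp.dli_int.to_numpy(),
                                 seed=args.seed)
        m = post.posterior_mean()
        summary["richards"][f"{tr}:{cv}"] = {
            "posterior_mean": m, "rhat": post.rhat, "ess": post.ess,
            "converged": post.converged, "warnings": post.warnings,
        }
        cum = cumulative_interception(grp.dat.to_numpy(), grp.dli_int.to_numpy())
        summary["cumulative_interception"][f"{tr}:{cv}"] = cum
        print(f"  {tr:>3} x {cv:<8} DLI_int_max {m['dli_int_max']:5.2f}  "
              f"t_m {m['t_m']:5.2f}  v {m['v']:4.2f}  "
              f"rhat<= {max(post.rhat.values()):.3f}  ESS>= {min(post.ess.values()):.0f}  "
              f"cumulative {cum:6.1f} mol m-2")
        flat = pd.DataFrame(post.flat(), columns=list(post.names))
        flat.insert(0, "cultivar", cv)
        flat.insert(0, "treatment", tr)
        draws_frames.append(flat.iloc[::48])  # thinned draws for the archive

    (args.out / "growth_fits.json").write_text(
        json.dumps(summary, indent=2, default=float))
    pd.concat(draws_frames).to_csv(args.out / "richards_draws_thinned.csv",
                                   index=False)
    print(f"\nwrote {args.out / 'growth_fits.json'} and thinned posterior draws")


if __name__ == "__main__":
    main()
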