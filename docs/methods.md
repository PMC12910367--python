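# Methods

`clgrow` re-implements, as tested reusable code, the analysis chain of a
controlled-environment experiment in which lettuce ('Danstar' and
'Jagger', 56 plants·m⁻², 0–19 days after transplant, DAT) was grown under
continuous light (CL) or an 18-hour photoperiod delivering the same daily
light integral. The chain runs from photon accounting and top-view canopy
images to light interception, light-use efficiency (LUE), a scenario-based
LED/HVAC energy model with energy-use efficiency (EUE), and the split-plot
statistics applied to every trait. Because the study's raw data are not
deposited, a synthetic-data generator re-creates per-plant inputs from the
published summary statistics; every stage is therefore testable end to end.

## Photon accounting

A light recipe is (PPFD, far-red flux, photoperiod, optional relative
spectrum). Derived quantities:

- PFD = PPFD + FR (µmol·m⁻²·s⁻¹, 400–800 nm);
- DLI = PPFD × photoperiod × 3600 / 10⁶ (mol·m⁻²·d⁻¹), TPFD likewise from
  PFD;
- R:FR = Σ photon flux 600–700 nm / Σ 700–800 nm;
- PSS = Σ σ_R N / Σ (σ_R + σ_FR) N, the phytochrome photostationary state.

The bundled cross-section table
(`data/phytochrome_cross_sections_synthetic.csv`, 300–800 nm at 2-nm
steps) is a **synthetic** Gaussian-mixture model of the Pr/Pfr photon
cross-sections, not measured data: σ_R is a 666-nm Gaussian plus a blue
band, σ_FR a 725-nm Gaussian with a 672-nm shoulder and a blue band, with
amplitudes calibrated once against standard photoequilibrium anchors —
PSS(660 nm) ≈ 0.89, PSS(730 nm) ≈ 0.10, and PSS ≈ 0.82 for a
deep-red/white + far-red recipe with R:FR 3.5 (6.5% blue, 14.8% green,
61.3% red, 17.4% far-red). Within composite horticultural spectra the
table behaves like published tables; for narrow-band green/amber light its
values are unreliable because both cross-sections are vanishingly small
there.

Printed-value comparisons round half away from zero at the displayed
precision; raw values are kept at full precision internally. The
continuous-light row of the emulated study's light table prints DLI 17.0
while its fluxes integrate to 16.93; such printed values are treated as
rounded reports and never force-fitted.

## Canopy imaging

Segmentation thresholds the excess-green index ExG = 2G − R − B, by
default with Otsu's method on the pooled ExG histogram; a degenerate
single-intensity image falls back to a fixed threshold of 0 with a logged
warning. Otsu has a known failure mode when either class occupies less
than roughly 1% of pixels: the criterion then prefers splitting the
majority mode, which in a daily series appears as a spurious coverage
collapse at canopy closure. The pipeline's coverage stage therefore uses
the operator's fixed mode with a calibrated threshold (ExG > 60, halfway
between the renderer's background ≈ 4 and plant ≈ 190 counts); fixtures at
moderate coverage exercise both modes.

Per-plant projected leaf area (PLA) assigns each connected component to
the nearest layout centre by centroid distance (ties to the lower plant
id), summing fragments; PLA = pixel count × (cm/px)². A component
containing two layout centres signals canopy closure, where per-plant PLA
is undefined (the no-overlap window of the emulated study is 2–13 DAT);
this raises `OverlapError` rather than returning a wrong split.
Border-touching components are included in floor coverage but flagged for
PLA.

## Growth models

**Exponential PLA (no-overlap window).** PLA = PLA_initial ·
exp(RGR_PLA1 · DAT), fitted by Levenberg–Marquardt least squares on the
natural scale with one PLA_initial shared across treatments (plants were
homogenised at transplant) and one rate per treatment, via a joint stacked
design. Start values: PLA_initial = mean first observation, RGR = 0.1 d⁻¹;
hard cap of 100 iterations; hitting the cap raises a structured
non-convergence error carrying the last iterate. Standard errors come from
the Gauss–Newton covariance.

**Windowed RGR.** RGR = (ln PLA₂ − ln PLA₁)/(DAT₂ − DAT₁).

**Richards interception curve.** Daily light interception DLI_int =
supplied DLI × floor coverage follows

DLI_int(t) = DLI_int_max / (1 + exp(−RGR·(t − t_m)))^(1/v),

with Gaussian observation noise σ and normal priors on the natural scale:
DLI_int_max ~ N(16.9, 0.25), RGR ~ N(0.5, 0.3), t_m ~ N(13, 6),
v ~ N(2, 1), plus a weakly-informative half-normal(1) prior on σ. Sampling
uses an adaptive random-walk Metropolis scheme: v and σ are sampled on the
log scale with the Jacobian correction so the stated priors apply on the
natural scale; the proposal covariance is a Laplace approximation (inverse
Hessian of the negative log posterior at its mode, scaled by 2.38²/d), and
the 1000-draw warm-up tunes only a scalar step size by Robbins–Monro
towards 0.28 acceptance, after which the proposal is frozen so kept draws
form a valid Markov chain. Four chains of 4000 iterations each (12 000
kept draws) are run; rank-normalised R-hat and bulk ESS (arviz) are
attached to every fit, with a convergence warning — never a silent pass —
when any R-hat exceeds 1.05. The inference target, not the sampler, is the
contract: on the seeded recovery fixture the sampler achieves R-hat ≤ 1.02
and ESS ≥ 400 per parameter. On sharp near-step interception series
(canopy closing within a day or two) the asymmetry parameter v mixes more
slowly and ESS can drop below that mark; the diagnostics report it
honestly.

**Cumulative interception** integrates the daily series over 1–19 DAT by
the trapezoid rule on the observed DAT grid (the integration convention is
stated because the emulated study says only "integrating"); range bounds
are linearly interpolated when not observed.

## Energy and efficiency

LED electricity: E = TPFD × 10⁶/efficacy × days / 3.6·10⁶ kWh·m⁻², with
the nominal cross-treatment TPFD 20.1 mol·m⁻²·d⁻¹ and 20 light-days (0–19
DAT inclusive — the only day-count convention consistent with the printed
31.0/32.8 kWh·m⁻² cells). At fixed TPFD this is photoperiod-invariant,
which is the experiment's central design point. Scenarios: A — equal
efficacy 3.6 µmol·J⁻¹, constant 23 °C; B — 3.4 (18-h) vs 3.6 (CL) µmol·J⁻¹
(dimming raises efficacy), constant 23 °C; C — efficacies as B with 24/20
°C day/night setpoints (mean 23 °C).

HVAC electricity uses a deliberately transparent static heat balance for
an airtight, well-insulated, perfectly mixed chamber: heat load =
LED electricity × heat_fraction (default 1.0 — all electrical input
degrades to heat), optionally reduced by an envelope-conduction term
UA·ΔT·hours under the day/night setpoints, and removed at a fixed COP of 3.
Every assumption is logged per call. The emulated study used a dynamic
climate model whose internal equations are not published; its absolute
HVAC values (9.6/9.2 kWh·m⁻²) sit below total-electrical-load/COP (≈10.3)
and cannot be reproduced from first principles here, so HVAC agreement is
a non-goal; the printed scenario table is bundled as reference input for
EUE reconstruction only.

LUE = mass per ground area (g·m⁻²) / cumulative interception (mol·m⁻²);
EUE = mass per ground area / electricity (g·kWh⁻¹), per subsystem, with
the harmonic identity 1/EUE_total = 1/EUE_LED + 1/EUE_HVAC. Treatment
summaries of ratio traits (DMC, SLA, LUE, EUE) are means of per-plant
ratios, not ratios of means, matching the summary-table convention of the
emulated study.

## Statistics

Outlier screen: Tukey fences Q1 − 1.5·IQR to Q3 + 1.5·IQR computed within
block × photoperiod × cultivar groups, quartiles by linear interpolation
(the choice matters at n = 10–11 and is therefore fixed and documented);
groups under 4 values are skipped with a warning.

Split-plot ANOVA with blocks: photoperiod (main plot) is tested against
the block × photoperiod mean square with (1, (b−1)) degrees of freedom;
cultivar and the interaction against the pooled within-plot residual.
Sums of squares are Type-III RSS differences under sum-to-zero coding,
which equals the classical projection partition in the balanced case and
handles the 10-vs-11 unbalance after outlier removal. Equal variance is
assumed by design (four blocks cannot support variance modelling).
Conventions for degenerate inputs: a zero treatment SS reports p = 1; a
zero error MS with positive treatment SS reports F = ∞, p = 0. SEMs are
computed from the standard stratum expectations — main level
√(MS_wholeplot/n_per_main), interaction level √(MS_residual/ñ_cell) with
the harmonic-mean cell size; the exact pooled-SEM formula of the study's
software is not recoverable (see the generator calibration below).

Mean separation uses Fisher's protected LSD at α = 0.05: no comparisons
unless the gating F-probability is below α; LSD = t(1−α/2, df_err) ×
SE_diff; letters are assigned by descending mean with maximal-interval
chaining, which with a constant LSD is exactly consistent with all
pairwise decisions. Residual normality is checked by Shapiro–Wilk
(scipy's implementation of the standard approximation, 3 ≤ n ≤ 5000).

## Synthetic-data generator

The generator inverts the study's descriptive models; it contains no
physiology (no photosynthesis, carbon allocation, or tip-burn).

- **PLA trajectories**: PLA(t) = PLA_initial · exp(RGR·t) · ε with
  lognormal ε (sd 0.05), three phase-stamped observations per day
  (start/midpoint/end of the 18-h photoperiod or equivalent clock times),
  small per-plant spreads of initial size (5% CV) and rate (2% CV).
  PLA_initial = 5 cm² (a homogenised transplant); each cultivar's 18-h
  rate is set so PLA at 19 DAT matches the published cell-mean LAI
  (0.248 d⁻¹ 'Danstar', 0.276 d⁻¹ 'Jagger'), and the CL rate adds
  ln(LAI ratio)/19 using the published CL/18-h LAI ratios (1.06, 1.23).
- **Top views**: each plant is a green disc of area PLA on its chessboard
  centre (15.6 cm in-row, 11.5 cm rows), additive Gaussian pixel noise
  (sd 4 counts), ground-truth mask emitted alongside. Discs may merge at
  closure; the renderer's tray extent is chosen so pixel area per plant
  matches the 56 plants·m⁻² density.
- **Harvest traits**: per-plant draws around the published
  treatment × cultivar cell means with multiplicative block (2% CV) and
  whole-plot (1% CV) effects plus plant-level Gaussian noise. Dry mass is
  generated as fresh mass × a dry-matter-content draw, so dry ≤ fresh by
  construction. **Calibration**: the printed main- and interaction-level
  SEMs are pooled common-variance quantities that no non-negative
  (whole-plot, plant) variance pair can reproduce jointly under the
  stated design; the plant SD is therefore calibrated to the main-level
  SEM (σ = SEM_main·√84, e.g. 17% CV for dry mass), because the main-plot
  photoperiod test is the analysis target. Simulated interaction-level
  SEMs consequently fall somewhat below the printed ones.
- **Carbohydrates**: glucose/fructose/sucrose/starch drawn around the
  published cell means with the same block/whole-plot structure and
  SEM-scaled plant noise; the nominal noon sampling time is metadata only
  (no diel dynamics).

Every generator is a pure function of (config, seed); `noise_scale = 0`
reproduces all configured means exactly, making each analysis stage an
exact round trip on noiseless input.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: disc-shaped plants produce more floor
coverage per unit leaf area than lobed rosettes and close the canopy by
~14–15 DAT, so the CL interception advantage in 'Jagger' comes out near
+4% instead of the published +10% (the LUE ratios built on it still fall
in the published 5–17% band); Gaussian plant noise has heavier tails than
the real cohort apparently had (the real screen flagged 4 of 168 plants,
while Tukey fences on Gaussian groups of 10–11 flag ~1–2% of inliers as a
matter of course — detection correctness is therefore tested on a
bounded-grid fixture with planted extremes); and no image distortion,
colour miscalibration or per-treatment camera-height perspective is
modelled.

## Problem sizes and determinism

Default analysis sizes: 168-plant cohorts (4 blocks × 2 × (11 + 10)); 19
daily renders per treatment × cultivar of a 20-plant tray at 0.1 cm/px;
MCMC 4 × 4000/1000; the design-power summary uses 100 seeded cohorts.
These sizes keep the full suite and the acceptance script in the
tens-of-seconds range while leaving every statistical conclusion
unchanged at larger sizes. All randomness flows from explicit
`numpy.random.default_rng` seeds; identical seeds give bit-identical
tables, images, and posterior draws.

## Known limitations

- PSS values for narrow-band mid-spectrum light are not trustworthy
  (synthetic cross-section table).
- The HVAC model is a static bound, not a thermodynamic simulation; COP
  is fixed, latent loads and duct design are out of scope.
- Per-plant PLA is undefined after canopy closure by design; the
  `OverlapError` is the intended signal, not a defect.
- The split-plot SEM/LSD conventions at the interaction level follow the
  standard stratum expectations and may differ in the second decimal from
  the study's proprietary software.
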