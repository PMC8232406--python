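# Methods

## Indirect calorimetry

Metabolic cages measure O₂ consumption and CO₂ production normalized to
body mass (ml/kg/hr) in 4-minute intervals. Per interval the pipeline
computes RER = VCO₂/VO₂, the Lusk calorific value CV = 3.815 + 1.232·RER
(kcal per liter O₂), energy expenditure EE = CV·VO₂ (VO₂ in L/kg/hr, so EE
is kcal/kg/hr), and the two substrate-oxidation linear forms

    carbohydrate = 4.585·VCO₂ − 3.226·VO₂
    lipid        = 1.695·VO₂ − 1.701·VCO₂.

These two forms make a nonsingular 2×2 system, so gas volumes can be
recovered exactly from a (carbohydrate, lipid) pair; the package uses this
inversion as a consistency check tying published 24-h oxidation rates back
to the published 24-h RER (the recovered RER is 0.9075 against the
published ~0.90).

**Scale caveat.** Published whole-animal EE values (~19 kcal/hr) and
oxidation rates (~5.9 g/min) are not mutually consistent under any single
VO₂ unit: at EE ≈ 19 the gas volumes are ~3.9/3.5 L/kg/hr while the printed
oxidation rates imply ~6.3/5.7 on the oxidation scale. The package
therefore evaluates each equation on its own scale — EE from L/kg/hr, and
oxidation from L/kg/hr values with the output labelled with the nominal
"g/min" unit string — rather than inventing a correction. Negative
oxidation values are reported as computed (the lipid form crosses zero at
RER = 1.695/1.701 ≈ 0.9965, the carbohydrate form at 3.226/4.585 ≈ 0.7036)
with counters on the derived series.

## Diurnal analysis

The day is a 12:12 light-dark cycle, lights on 06:00. Phase assignment is
half-open: clock times in [06:00, 18:00) are inactive (light), the rest
active (dark); a subject-day runs 06:00 → 06:00 so one full inactive phase
precedes one full active phase. Channels are binned at 1, 6, 12 and 24 h
(6-h bins anchored at 06:00/12:00/18:00/00:00), each interval assigned by
its start time; bin SD is the sample standard deviation. The hourly moving
average is a *trailing* window of 15 four-minute intervals (output length
n − 14, stamped with the last interval's start); AUC is the trapezoidal
rule with time in hours (4-min spacing = 1/15 h), with 6-h sub-AUCs
computed on the points falling inside each bin (no edge interpolation, so
sub-AUCs do not sum exactly to the 24-h AUC). Metabolic-rate flux and
metabolic flexibility are the active-minus-inactive 12-h deltas of EE and
RER; the AUCs provide the cumulative version.

Hour-based AUC is an internal convention: published AUC magnitudes for
these curves (≈5,900 for EE, ≈64 for RER) are not reproducible from the
published phase means under any x-axis convention we tested, so AUCs are
compared only within this package, never against those two numbers.

## Physical activity

Every beam interruption is a total count; an interruption from a different
beam than the immediately preceding one on the same axis is additionally an
ambulatory count (in-place movement — grooming, feeding — accrues totals
only). The per-bin classifier resets its previous-beam memory at each 10-s
export bin boundary. Ambulation distance = (X + Y ambulatory counts) ×
1.27 cm, the beam spacing; Z-axis (rearing) counts are excluded from
distance. Whether the instrument requires exactly two consecutive distinct
beams or a longer run is undocumented; the one-step rule is a declared
convention, and the X+Y sum (rather than an Euclidean combination) is the
simplest rule consistent with per-axis beam spacing.

## Synthetic generator

The generator emulates the study conditions, not any particular animal:

* **Gas traces.** Latent EE(t) and RER(t) are phase-level square waves with
  logistic ramps (default width 60 min, logistic scale = width/8) centered
  on the 06:00/18:00 transitions, plus stationary AR(1) Gaussian noise
  (default lag-1 coefficient 0.6; marginal SDs 2.0 kcal/kg/hr for EE and
  0.04 for RER, matching the dispersion of published hourly values). The
  two plateau levels are solved from the switching curve's phase means (a
  2×2 linear system) so the noiseless 12-h phase means equal the preset
  parameters to machine precision, ramps included. Gas volumes are
  back-computed (VO₂ = EE/CV, VCO₂ = RER·VO₂), guaranteeing that the metric
  pipeline reproduces the latents exactly. RER values driven outside
  (0, 1.2] — which never occurs at the default noise level — are clamped
  into the physiologic [0.7, 1.0] band and counted; ordinary noise is left
  untouched so phase means stay calibrated and unbiased.
* **Activity traces.** Per-10-s ambulatory counts are Poisson with
  phase-specific rates split evenly between X and Y; totals add Poisson
  non-ambulatory counts at `nonamb_fraction` (default 0.5) of the
  ambulatory rate, and the Z axis records rearing-scale totals at the same
  rate. Baseline rates are calibrated so expected distances are 1.0 km
  (active) and 0.3 km (inactive).
* **Presets.** `baseline`: EE 21.25/16.75 (24-h mean 19, delta 4.5), RER
  0.93/0.87, 1.3 km/day — the published pre-allocation phenotype.
  `vml_6wk`: 24-h EE scaled by 0.90 with the delta preserved (19.35/14.85)
  and 24-h RER scaled by 0.96 with a 0.04 phase delta (0.884/0.844), the
  published 6-week contrasts. `vml_2wk`: EE unchanged, RER 0.93/0.85 (24-h
  mean 0.89, delta 0.08) — a mild blunting consistent with the published
  2-week delta; ambulation 1.4 km at both post-injury timepoints. These
  values are the study conditions and are not tuning knobs.
* **Cohorts.** Per-trace seeds derive from
  `SeedSequence([design_seed, subject_index, timepoint_index])`, a stable
  documented scheme: identical design seeds reproduce cohorts byte-for-byte
  and subjects persist across timepoints (repeated-measures structure).
* **Terminal tables.** Function outcomes are Gaussian around published
  group means/SDs; fiber tables assign types by region-specific published
  percentages (multinomial; largest-remainder when SDs are scaled to 0),
  draw CSA log-normally around a per-subject mean (fiber-level CV 0.35 — a
  typical within-muscle dispersion, since published SDs are between-subject
  SDs of means), Poisson capillary counts and Bernoulli stain/nucleus flags.

**What the generator does not model** — and hence what passing tests do not
show about real data: thermoneutrality and feeding events, body-composition
differences, surgical-recovery dynamics between timepoints, ultradian bouts
in gas exchange, instrument drift, and any vendor export quirks (a
normalized CSV dialect is assumed). Parameter-recovery results demonstrate
that the pipeline measures what the generator encodes, not that the
biological effect sizes are correct.

## Statistics

One-way ANOVA (between/within F, df (k−1, N−k)); one-way repeated-measures
ANOVA with subject effects removed, df (t−1, (t−1)(n−1)), sphericity
assumed (no Greenhouse-Geisser correction, matching the study's plan),
complete matrices required (no imputation); two-way ANOVA with Type-II sums
of squares — the standard default for main-effect inference with unbalanced
groups (16/5/7) absent a stated alternative; Tukey HSD at alpha 0.05;
Pearson chi-squared on 2×k histograms at the corrected alpha 0.0167
(0.05/3 pairwise group comparisons). Before chi-squared, adjacent bins are
merged until all expected counts are ≥ 1 and at least 80% are ≥ 5
(Cochran's rule); pooling cannot change a statistic of 0. Degenerate
inputs: zero between-group and residual variance reports F = 0, p = 1.
Computation is delegated to scipy/statsmodels; tests verify the surfaces
against hand-computed sums of squares, a permutation oracle, the paired-t
F = t² identity, and null-simulation type-I error calibration.

## Problem sizes and numerical choices

Parameter recovery runs 200 replicate cohorts (28 subject-days baseline;
12 × 3 timepoints longitudinal), reported as grand mean ± SE (replicate
SD/√200) and checked at 2 SE — with 200 replicates the 2-SE band is about
half as wide as at the 50-replicate minimum, making the check strictly more
stringent while keeping the full run around two minutes on one CPU.
Oxidation inversion round-trips are required to 1e-9; bin-mean conservation
and noiseless round-trip identities to machine precision. CSV export uses
fixed 6-decimal formatting, which bounds write→read error at 5e-7 and makes
round trips byte-stable.

## Known limitations

The gastrocnemius weight ratio is treated as an opaque printed quantity
(its normalization basis is not reconstructible); the torque-by-frequency
profile in the synthetic tables uses a smooth saturating curve anchored at
the twitch and peak values rather than published per-frequency data; the
oxidation-rate unit discrepancy above means absolute oxidation magnitudes
should be compared only within a consistent pipeline; and one recorded day
per timepoint is assumed (no multi-day averaging or rhythm fitting).
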