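# Methods

`tcekin` estimates how much the metabolism of trichloroethylene (TCE)
varies across genetically distinct mouse strains, and what that implies
for population variability in internal dose. The pipeline couples a
physiologically based pharmacokinetic (PBPK) model of TCE and its
metabolites to a hierarchical Bayesian population model fit by MCMC,
with an ANOVA-based heritability screen, forward Monte Carlo
uncertainty propagation, and posterior variability summaries.

## The PBPK model

The parent compound follows a flow-limited compartmental structure:
gastrointestinal lumen (stomach and duodenum, holding the unabsorbed
gavage dose), gut tissue, liver, fat, kidney, rapidly and slowly
perfused tissue, and venous and arterial blood. Pulmonary exchange
equilibrates arterial blood with alveolar air through the blood:air
partition coefficient `P_ba`; with zero inhaled concentration the
arterial concentration leaving the lung is

    C_art,lung = Q_c * C_ven / (Q_c + Q_alv / P_ba)

and the exhalation rate is `Q_alv * C_art,lung / P_ba`. Oral absorption
uses two sequential first-order lumen compartments (stomach ->
duodenum), each absorbing into the liver; zeroing the transfer rate
collapses this to a single first-order compartment. The two-step form
captures the prolonged uptake of a corn-oil bolus. All of the dose is
eventually absorbed (no faecal loss), so the cumulative absorbed amount
converges to the administered dose.

Liver metabolism is saturable in both pathways (Michaelis–Menten in the
liver venous concentration): oxidation with maximum rate `VMax` (mg/hr)
and affinity `KM` (mg/L), and glutathione (GSH) conjugation with
`VMaxDCVG` and `KMDCVG`. The oxidation flux is split by molar yield
fractions into trichloroacetic acid (TCA), trichloroethanol (TCOH) and
directly formed dichloroacetic acid (DCA); the remainder is untracked
"other oxidation". TCOH is glucuronidated to TCOG (excreted) or
oxidised to TCA; TCA is cleared to urine or dehalogenated to DCA, so
DCA is produced both directly and via TCA. The conjugation flux forms
DCVG, which clears by metabolism to DCVC, which is eliminated first
order. Metabolites use lumped one-compartment distribution volumes
except DCA, which has central and peripheral compartments; serum
concentrations are amounts divided by distribution volumes. TCOH and
TCOG are carried for flux bookkeeping even though the assay panel does
not measure them.

Cumulative trackers (absorbed, exhaled, oxidised, conjugated, total TCA
and DCA produced) are integrated as extra states, so mass balance is
checkable exactly: systemic TCE plus the exhaled and metabolised sinks
must equal the absorbed amount in parent-mass units. Units are mg, L,
hr throughout; molar quantities (the TCA/DCA production ratio) appear
only at the reporting layer through the molecular-weight table.

Numerics: LSODA (stiff-capable) with `rtol = 1e-8` and an absolute
tolerance of 1e-12 of the administered dose, so conservation holds to
the same relative accuracy at any dose level; tiny negative round-off
is clamped to zero. Flux totals default to a 168-hr horizon, by which
>99.9% of the absorbed dose sits in sinks. Defaults describe a 0.0364
kg male mouse given 2,100 mg/kg TCE in 10 mL/kg corn oil; maximal
metabolic rates scale with body weight^0.75 and flows with body
weight^0.74 when defaults are built for another body weight. The
default parameter values are nominal, literature-typical choices, and
everything is overridable from a YAML config.
Enterohepatic recirculation of TCOG is not modelled, and DCVG
production is placed in the liver only.

## The hierarchical population model

Strains are tied to an index strain (B6C3F1/J) through multiplicative
scaling factors psi: a strain's value of a scaled parameter equals the
study-level value theta times its psi. The index strain is pinned at
psi = 1 and never sampled, which identifies theta. The psi are
exchangeable lognormal draws with log-scale mean `M_psi` and variance
`V_psi` per scaled parameter, truncated to [1/50, 50] (beyond 4 SD of
any plausible population). The default scaled set for fitting is
(`VMax`, `VMaxDCVG`) — the two parameters the 2/8/24-hr serum panel can
identify — while the broader metabolism/excretion set remains available
and configurable.

Residuals are lognormal per metabolite: log observations are normal
about log predictions with metabolite-specific variance sigma^2. This
was chosen because the data are positive and span decades.
Observations below the limit of detection (LOD) contribute the
left-censored mass `Phi((ln LOD - ln f)/sigma)` instead of a density;
substitution or deletion would bias low-concentration metabolites
(DCVG, DCVC), a large share of whose late records censor.

Priors: `M_psi ~ Normal(0, 0.5^2)` on the log scale (strains centred on
the index strain); the population log-scale SD `sqrt(V_psi)` gets a
half-normal prior with scale ln(2.5) (a weakly informative choice that
admits populations up to several-fold spread); sigma^2 gets an
inverse-gamma(2.5, 0.3) prior spanning residual geometric SDs of
roughly 1.1–2.5. The single-study design estimates one theta;
interstudy variability hooks exist but are out of scope.

## Sampling and diagnostics

The sampler is component-wise random-walk Metropolis on log-transformed
positive parameters (the Jacobian enters the acceptance ratio, so the
target stays the density over natural parameters). Each component has
its own step size, adapted toward an acceptance rate of 0.3 during
burn-in in batches of 50 proposals and frozen afterwards, preserving
the stationary target. Chains initialise at prior medians jittered
±20% on the log scale, with seed-derived, per-chain random streams;
runs are bit-reproducible given the seed.

Convergence uses the split-chain potential scale reduction factor
(each chain halved; R from between/within-sequence variances), which is
stricter than the classic whole-chain form because it also flags
within-chain trends. A parameter with zero variance everywhere reports
R = 1 by convention. Thinning retains every k-th post-burn-in
iteration, aligned so the final iteration survives; with 8 chains of
160,000 iterations, half burn-in and thin 500, exactly 1,280 draws
remain. The production-scale protocol is available but long-running;
the shipped experiments use 4 chains of 20,000 sweeps, which the
diagnostic shows is ample for this posterior (max split-chain R well
under 1.07).

### Tabulated forward model

A component-wise sweep over ~40 parameters with 17 strain simulations
per likelihood would need millions of stiff ODE solves per fit. Because
every strain's predictions depend on psi only through the (at most two)
scaled parameters, the forward model can be tabulated once: the ODE is
solved on a 33x33 grid of log psi spanning the truncation range,
refined to a 321-point-per-axis surface by bicubic spline, and queried
by bilinear interpolation of log concentrations. The tabulation error
(max absolute log error ~4e-4) is three orders of magnitude below the
residual SD (~0.26), and the table is validated against the direct
ODE model in the test suite. The direct (ODE-solving) posterior remains
the reference implementation and the two agree exactly in structure on
small problems. Fits over more than two scaled parameters fall back to
the direct model.

## ANOVA heritability

Concentrations are power-transformed toward normality over a grid of
exponents from 0 (the log) to 1 (untransformed); the transform is
scored by the Shapiro–Wilk W statistic averaged across metabolites,
with ties broken toward the smaller exponent, and the quarter-power
y^0.25 is the default for analysis. Strain effects are tested one-way
within each timepoint and in an overall two-way strain + time model
with time entered first, so sums of squares are sequential (Type I) and
the strain partial R^2 — SS(strain | time)/SS(total) — reads as an
approximate heritability. Unbalanced cells are handled by least
squares; saturated designs report an undefined F but still return R^2.
No multiple-testing correction is applied: each metabolite is a
separate hypothesis of independent interest. Below-LOD records are
excluded here (their magnitude is unknown), which mirrors the shrinking
late-timepoint sample sizes; the Bayesian stage, by contrast, models
them as censored.

## Forward Monte Carlo

The preliminary uncertainty analysis draws metabolism and excretion
parameters from normal distributions on the natural scale (mean =
nominal, SD = CV x mean, redrawn at zero; a parameter truncating more
than half the time is flagged), simulates each of the default 100
iterations, and reports pointwise 2.5/25/50/75/97.5 percentile bands of
the serum concentrations. The natural-scale normal is deliberate —
it matches the described procedure — although log-scale sampling would
be more conventional; the CVs default to 0.3 and are configurable.

## Variability metrics

Per-strain flux summaries push every retained posterior draw through
the PBPK model and summarise each quantity by median and (2.5%, 97.5%)
bounds; ratio quantities (oxidation/conjugation, molar TCA/DCA) are
computed per draw and then summarised — never as ratios of summaries.
Fold-range is max/min of strain medians. The 95th/50th percentile
ratio across strains is computed per posterior draw and summarised
(median and 95% CI); fewer than five strains sets a wide-CI flag.
Percentiles use linear interpolation between order statistics
throughout. Low-dose fluxes are evaluated at 0.001 mg/kg-day given as
one daily bolus, iterating days until the daily incremental fluxes
change by <0.1% (steady state), and normalising by the daily dose; a
built-in check halves the dose and warns if any normalised flux moves
by more than 1% (saturation).

## Synthetic data generator

The generator emulates the study design: 17 strains (16 inbred plus the
B6C3F1/J index), single 2,100 mg/kg oral gavage, serum TCA/DCA/DCVG/
DCVC at 2, 8 and 24 hr, 3 animals per strain-timepoint. True strain
scalings are lognormal with geometric SD 2.0 per scaled parameter
(index pinned at 1); records multiply the strain prediction by an
independent lognormal residual with geometric SD 1.3 (animal plus
assay variation — there is no separate animal random effect, matching
the two-level hierarchy); and values under the metabolite's LOD are
flagged censored. Default LODs (TCA 0.25, DCA 0.005, DCVG 0.02, DCVC
0.08 mg/L) were set so that roughly 10% of DCVG and 20% of DCVC records
censor under the default design, concentrated at 24 hr — reproducing
the sparse late conjugation-metabolite counts typical of such studies.
The generator's default scaled set is (`VMax`, `VMaxDCVG`), the same
pair the default fit estimates, so the shipped simulation study is a
coherent recovery experiment.

What passing on synthetic data does and does not show: the generator
draws from exactly the model family the fit assumes (same ODE, same
lognormal residuals, same censoring mechanism), so recovery and
coverage results certify the inference machinery, not robustness to the
model misspecification, inter-laboratory effects, assay artefacts or
non-lognormal tails present in real serum data.

## Problem sizes of the shipped experiments

The default convergence experiment fits 40 parameters (32 strain
scalings, 4 residual variances, 4 population hyperparameters) to 612
records with 4 chains of 20,000 sweeps; the recovery experiment uses an
enriched design (6 timepoints, 5 animals per strain-timepoint, 2,040
records) with 4 chains of 6,000 sweeps. Both were sized to give the
split-chain diagnostic ample draws while keeping a full run on a single
CPU in minutes.

## Known limitations

- Tissue dosimetry beyond serum concentrations and cumulative fluxes is
  out of scope, as are inhalation routes and human physiology.
- TCOH/TCOG kinetics are bookkeeping-grade: no enterohepatic
  recirculation, and their parameters are only weakly constrained by a
  serum panel that does not measure them.
- The tabulated forward model covers at most two scaled parameters;
  larger scaled sets use the direct ODE posterior and are slower.
- Low-concentration metabolites near the LOD carry most of the
  censoring; their psi posteriors are correspondingly wide, and
  confounding between production and clearance of DCA is inherent to
  the design (only serum DCA is observed).
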