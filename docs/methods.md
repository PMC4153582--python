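# Methods

## Model structure and assumptions

Two identical 8-compartment flow-limited bodies describe the *d*- and
*l*-enantiomers of methylphenidate (MPH): plasma, fat, brain, richly
perfused, slowly perfused, gonads, heart and liver.  Distribution is
flow-limited (tissue venous concentration = tissue concentration divided
by the tissue:plasma partition coefficient), which is appropriate for a
small lipophilic base whose tissue and plasma levels decay in parallel.
Blood flows carry plasma concentrations directly; no blood:plasma ratio
or protein-binding submodel is applied, consistent with the
plasma-compartment formulation of the physiological tables.  Ritalinic
acid (RA), the inactive hydrolysis metabolite, is a single well-mixed
compartment per enantiomer with volume equal to total body water and
first-order urinary clearance; urinary excretion of parent MPH (<1% of
dose) and fecal loss are omitted.

Hepatic hydrolysis by carboxylesterase 1 is saturable and mutually
competitive between enantiomers: each enantiomer's Michaelis constant
serves as the other's inhibition constant.  A parallel first-order
hepatic oxidation clearance routes drug to an oxidized sink (not to RA);
its magnitude was originally set so oxidation is ~20% of hepatic
metabolism in adult humans.  Oral doses pass a stomach lumen
(first-order gastric emptying, GE) into the small-intestine lumen where
first-order uptake into the portal circulation (K3, routed to the liver
compartment) competes with first-order gut metabolism (K5); a fraction
F = 0.8 of gut metabolism forms RA, which enters the systemic RA pool
immediately, and 1 − F is oxidized.  RA formation is equated with MPH
consumption on an amount (µg) basis, without a molar-mass correction;
adopting the correction would lower RA concentrations by ~6% and leaves
every MPH output unchanged.

Internal units are µg, µg/L (≡ ng/mL), h, L and L/h.  Capacities and
clearances (Vmaxliver, Kmet, K5, Ku_RA) scale as BW^0.75; first-order
rate constants (GE, K3) scale as BW^−0.25.  Reading the gut-metabolism
coefficient K5 as a BW^0.75-scaled quantity (its tabulated unit) rather
than a BW^−0.25 rate is validated by a closed-form consequence: at 70 kg
it yields a dose-averaged gut-metabolized fraction K5/(K3+K5) of 84%,
matching the ~85% presystemic intestinal loss the calibrated adult model
is known to imply.

## Populations and parameters

All constants live in YAML registries (`src/mph_pbpk/registry/`): one
partition-coefficient set shared by all populations; physiological
tables for adult humans and rhesus monkeys (male/female pairs where
reported); chemical parameter sets per population and route.  The
richly/slowly perfused flow and volume fractions close the circulatory
budget (QRC = 0.76 − QLC − QGC − QBC, QSC = 0.24 − QFC − QHC; VRC =
0.33 − VLC − VPC − VGC − VBC, VSC = 0.60 − VFC − VHC), enforced to
1e-12 at load time.

Children (4–15 yr) reuse the adult chemical parameters except a
~14-fold lower gut metabolism of *l*-MPH and pediatric body water for
RA.  Pediatric adipose volume follows piecewise-linear age anchors
(3.68, 6.25, 11.49 L at 6, 10, 14 yr; flat extrapolation) and hepatic
blood flow age bands (325/665/915 mL/min for 4–8/9–12/13–15 yr).  The
literature growth regressions for pediatric cardiac output, brain blood
flow, plasma volume and the remaining organ volumes are not available in
machine-readable form; the registry therefore defaults these to adult
allometric scaling (QCC = 15.87 L/h/kg^0.75) and adult fractional
values, and exposes them as editable entries so transcribed regressions
can be dropped in without code changes.  Child outputs consequently
carry more uncertainty than adult outputs, and the package's reference
checks use a wider (25%) band for them.

Monkeys share one physiology table.  Juvenile rhesus hepatic hydrolysis
and oxidation capacities are ~10× and 100× the adult-monkey (= adult
human) coefficients, reflecting their much faster clearance, and their
oral model has no gut metabolism (K5 = 0).  Canonical body weights: 70
kg adult human, 9.77 kg adult rhesus, 4.0 kg juvenile rhesus, 21.3 kg
(age 6) and 59.4 kg (age 15) boys — values consistent with the scaled
capacities and absolute-dose equivalents the model family reports.  An
IVIVE helper reproduces the initial hepatic Vmax coefficients from the
in vitro velocities (38,496 / 78,111 ng/h/mg protein × 39.19 mg
protein/g liver × 2.06 kg liver × RAF 0.22, normalized by BW^0.75 at
79.4 kg → 25,760 / 52,270 µg/h/kg^0.75); the registry values include the
additional ~1.5-fold manual adjustment made during the original
calibration.

## Numerics

The 28-state ODE system is integrated with LSODA (stiff-capable,
adaptive) at rtol 1e-8 / atol 1e-10 µg, restarting at every dose event;
iv boluses are instantaneous plasma increments and oral doses deposit in
the stomach lumen, each split 50:50 between enantiomers.  At an event
time the post-dose state is the one reported, so iv peaks register on
the grid.  The output grid is uniform at 50 points/h (200 per 4-h dosing
interval), which bounds grid-induced Cmax error well under 0.5%; halving
solver tolerances moves Cmax by <0.1%.  The plasma outflow term uses the
realized sum of tissue flows, so mass balance holds exactly even when a
sensitivity perturbation deliberately breaks the flow closure.  Mass
balance (dose = body + RA + urine + oxidized sinks) holds to ~1e-14 of
dose in practice; trajectories are verified against a matrix-exponential
solution of the linearized system and a closed-form one-compartment
reduction (all partitions 1, single small clearance, near-instant
distribution).

## Dose metrics and HED inversion

Cmax is read from the dense grid over the steady-state window (days 4–7
for daily dosing in humans, who accumulate slightly with periodicity
reached within ~3 days; any dosing day for monkeys, which do not
accumulate).  Daily AUC conventions follow the dosing calendar: weekly
AUC/7 ("adjusted") for the 5-day/week monkey schedule, (week − first 3
days)/4 for daily dosing, and final-day AUC where a single-day summary
is wanted.  The HED search inverts the child dose→metric map on
[1e-4, 10] mg/kg by bracketing and bisection to 1e-4 relative width,
after a monotonicity pre-check on a coarse geometric dose grid guards
against silent multi-root behavior; metrics are strictly increasing in
dose throughout the therapeutic range, so the round-trip error is at the
bisection tolerance (<0.1%).  Whether the cross-species 0.3 mg/kg
comparison uses a 5- or 7-day monkey week is nearly inconsequential
(monkeys show no accumulation); the 7-day reading is used.

## Sensitivity analysis

Normalized sensitivity coefficients use a forward difference at +1%
parameter perturbation, evaluated on 97 grid points (15-min resolution)
over 24 h after a single oral 0.3 mg/kg dose, with the time course
collapsed to max |NSC| and a 0.1 sensitivity threshold.  Perturbing a
primary flow or volume fraction recomputes its richly/slowly perfused
complement (QRC absorbs QLC/QGC/QBC; QSC absorbs QFC/QHC; VRC/VSC
analogously) so closure is preserved to 1e-12; complements themselves
are perturbed directly.  BW perturbations rescale the whole body
including any mg/kg dose resolved from it; Age (children only) rebuilds
the pediatric physiology at the perturbed age.  NSC is masked (NaN, with
a warning) wherever the baseline output is zero, e.g. the instant before
oral absorption begins.

## Calibration utilities and synthetic data

The objective is RMSE on linear concentrations, pooled with equal
per-record weight across datasets (a log-scale option exists, off by
default; the original workflow's weighting is unstated, so equal weights
are adopted).  Fitting is Nelder-Mead with bounds and a
restart-from-best; non-convergence returns the best-so-far flagged as
such — deliberately, since simultaneous d/l hepatic capacities on a
single dataset are weakly identified and the honest outcome is a flag,
not a forced answer.

Because the original concentration-time datasets are figure-derived,
the package ships no observed data.  The synthetic generator simulates a
scenario, samples observables at stated times and applies multiplicative
lognormal noise per subject (concentrations are positive and PK
coefficients of variation are roughly constant), returning subject
means.  It reproduces the study *conditions* (schedules, doses, sampling
spans, ~10% CV); it does not emulate inter-individual physiological
variability, assay limits of quantification, or model misspecification,
so recovery tests demonstrate estimator correctness, not real-data
performance — the published fit-quality figures (mean RMSE ≈ 4.1 in
juvenile monkeys, ≈ 2.1 in children) are not reproducible without the
original digitized data and are not asserted anywhere.

## Known limitations

Human oral exposures run somewhat above the original implementation's
printed outputs (adult daily AUC at 0.3 mg/kg BID: 128.8 vs 107.1
ng/mL·h/day; boy-6 Cmax 20.0 vs 17.2 ng/mL) while monkey outputs and all
iv-anchored diagnostics (intrinsic clearances 0.48/3.06 L/h/kg, urinary
RA fraction ~0.8, d-MPH oral bioavailability ~20%) agree closely; the
printed equations do not fully determine the original human oral
formulation, and the residual is documented rather than tuned away.
Extended-release formulations, pharmacodynamics, diffusion-limited
tissues, enterohepatic recirculation, minor metabolites,
population-variability Monte Carlo and partition-coefficient derivation
from tissue composition are all out of scope; partition coefficients are
constants.  Supported child ages are 4–15 years, males for all reference
scenarios (female physiology loads when requested).
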