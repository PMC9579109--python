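# Methods

This note documents the model, its parameters and the design choices made
where the problem was genuinely open.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## State-dependent model

A pregnant female is described by body length *L* (m, fixed for the
season), fat mass *F* (kg), fetal length *G* (m) and location (one of 11
feeding cells, or outside the study area).  The season runs 25 weeks from
May 15: daily decision steps for the dynamic program, 6-h bins (four per
day) for the forward simulation and the acoustic exposure series.

**Energetics.**  Total mass follows a power law M = a·L^b (a = 12.2,
b = 3, giving ≈ 24 t at 12.7 m).  Daily field metabolic cost is
0.586·M^0.75 MJ (about twice a Kleiber basal prediction).  Daily energy
intake while feeding is capped at 0.90·M^0.75 MJ — a handling/digestive
ceiling that, like metabolism, scales with M^0.75.  This ceiling is load-
bearing: in uniformly rich offshore prey, short females are intake-limited
(rich cells become nearly equivalent to them) while long females can still
distinguish the richest cell.  Fetal length grows 4.6 mm/day when energy
permits, costed at 2000 MJ/m; under a deficit growth continues at half
schedule (configurable).  Surplus energy becomes fat at 90% deposition
efficiency; deficits are met from fat at 39.3 MJ/kg.  Fat is clamped to
[0, 0.5·M]; a female dies if fat falls below 5% of M, and faces a
background annual mortality of 0.02 compounded per bin.  Travel costs
11 MJ/km over 20 km between cells and 5 km within a cell, divided by the
drawn path linearity in simulation.

**Terminal fitness.**  The probability of successful reproduction at
departure is the product of three curves:

- overwinter maternal survival: logistic in F/M, midpoint 0.11, steepness
  30 — a female departing at typical arrival condition (F/M ≈ 0.15)
  mostly survives; it is the calf that fails;
- calf survival by maternal fat: asymptote × logistic in F/M^0.75,
  midpoint 2.7 kg/kg^0.75, steepness 2.0.  The metabolic scaling encodes
  that fasting endurance is stored energy over metabolic rate, so the fat
  a calf requires of its mother grows like M^0.75: small mothers saturate
  this curve at stores that leave large mothers on its steep part;
- calf survival by fetal length: logistic (steepness 8/m) rescaled to be
  exactly 0 at G = 0, with variant midpoints 0.95 / 0.85 / 0.70 m.

The three variants (low / medium / high) share every other parameter; the
mass-component asymptote is 0.78 (low) or 0.92 (medium, high).  With equal
steepness and ordered midpoints/asymptotes the variants are ordered
pointwise, which the suite asserts on a grid.  Departure *time* acts only
through the fetal length it permitted; no separate time penalty exists.

**Backward iteration.**  Because daily costs are state-independent, the
energy update is a uniform shift of the grid coordinates and each backward
step reduces to a separable linear interpolation of the category-averaged
continuation surface `Vbar(day, cell, F, G)`.  The prey category is
redrawn i.i.d. per day; travel days forgo foraging; travel-within yields
half a feeding day plus a short travel cost; leaving is absorbing with
value (overwinter survival × terminal fitness) at the current state.
Policies are solved per maternal length on a coarse grid (default 7
lengths spanning 11–14 m) and selected by nearest length in simulation.
Only `Vbar` is stored (about 30 MB per length at the default 60 × 30
fat × fetal grid); action values and probabilities at any state are
recomputed from it on demand.

**Behavior probabilities.**  How the optimality computation becomes a
behavior *distribution* is not determined by the problem, so three rules
are implemented: `argmax` (uniform over actions within ε of the best; the
operation default), a flat `softmax`, and `class_softmax` — a nested
logit over the four behavior classes with a destination softmax inside
the travel class.  The flat softmax over 13 actions overweights the ten
travel variants (red-bus/blue-bus) and at any workable temperature
produced either near-random wandering or no mixing; the shipped scenarios
therefore use `class_softmax` with temperature 5 × 10⁻⁴ (fitness units).
The temperature sits below typical feed-vs-travel value gaps (~10⁻³–10⁻²)
so behavior is purposeful but destinations with near-equal value are
genuinely mixed.  Under a softmax rule the stored value is a mixture over
actions, so it is monotone in fat only to within a couple of temperatures;
the argmax table is exactly monotone.

**Forward simulation.**  One behavior is drawn per female per day and
governs its four bins (the DP's decision cadence); arrival and a
disturbance response trigger a fresh draw mid-day.  Drawing anew every
bin instead makes females execute a *mixture* of the day's actions, which
the daily backward iteration never values — in development this starved
the thin-margin (largest) females for reasons the policy could not
anticipate, so the daily hold is used.  Dive fraction (truncated normal,
mean 0.75) scales each feeding bout; travel speed, time, linearity and
dive-cycle draws are made on a fixed per-bin schedule from dedicated
substreams so that disturbed and undisturbed runs with the same master
seed are coupled (common random numbers, for variance reduction in
Cohen's d).  Arrival dates are normal (June 15 ± 5 d), initial location
is an even nearshore/offshore split, initial fat is a truncated-normal
fraction of mass (mean 0.15) and initial fetal length 0.20 ± 0.05 m.
Reproduction is a Bernoulli draw with probability overwinter survival ×
terminal fitness at departure, so per-replicate standard deviations are
meaningful.  Females dying mid-season count as "outside" in occupancy so
the three areas always partition the population.

## Disturbance

A block is disturbed within a 6-h bin if any of its windows reaches
163 dB re 1 µPa² SPL (inclusive); cell exposure probability is the
fraction of reporting blocks disturbed (a fraction-of-windows variant is
available).  A disturbed whale relocates to the first cell in its
proximity-ordered neighbor list with zero exposure that bin (cells 8 and
9 are each other's first neighbor), pays an inter-cell travel cost, takes
no intake that bin, and re-decides from the new cell.  The response
probability defaults to 1.0 (conservative; 0.1 is a documented preset).

## Synthetic truth

The generators emulate the statistical structure the analysis assumes;
they make no claim of oceanographic or acoustic realism.

**Prey.**  Lognormal MJ per 6-h foraging bout per cell × period (equal
thirds of the season).  Nearshore cells: mean 110 / 100 / 50
(early/mid/late — nearshore beds senesce by fall), σ_log 0.4 (cell 2:
0.2).  Offshore cells 8–10: ≈ 550–660, peaking mid-season; cell 11: 500 /
640 / 850 — the overall richest, with a late surge; offshore σ_log 0.05
(rich, stable amphipod beds).  Offshore means are ≥ 5× nearshore.  This
structure, with the intake ceiling, is what produces the qualitative
patterns the study design expects: occupancy shifts offshore and stays
there; use of cells 8–10 is roughly constant mid-season; use of cell 11
grows late; and a population restricted to longer females (L_min = 13.0)
uses cell 11 more in the late season than one including short females,
because short females are intake-capped and indifferent among the
offshore cells while long females can exploit the surge.

**Acoustics.**  A point source (SL 230 dB re 1 µPa² at 1 m) moves along a
survey plan; each reporting block (twelve 1-km² blocks per nearshore
cell, six 100-km² blocks per offshore cell) logs one max-SPL window per
bin: SL − 17·log10(r in m) + N(0, 2 dB).  The 17·log10 spreading puts the
163-dB radius near 9 km, so one offshore cell can be ensonified while its
20-km neighbor stays a quiet refuge — with a 15·log10 spreading the
footprint is ~29 km, both cells 8 and 9 are hit at once, displaced whales
flee to deficit nearshore cells, and disturbance effects become large, a
regime contrary to the measured-field conditions this stand-in emulates.
The default plan traverses the nearshore early (days 30–50) and then
alternates 15-day stints over cells 8 and 9 (days 55–110).

**Regressions.**  Daily nearshore proportions come from the
zero-inflated beta truth, reported as continuous proportions (the
regression's own assumption) with rounded counts alongside; scan surveys
draw a cell-level hurdle-gamma density and spread it uniformly over a
pre-split block partition so aggregation recovers it exactly; the
pregnant fraction is binomial-logit.  All truths are stated on the
fitting design scale.  The environmental covariates are centered at fixed
reference conditions (visibility 0.75, Beaufort 2.5, coverage 0.7) and
the week enters through Legendre polynomials of week scaled to [−1, 1]:
raw visibility barely varies (nearly collinear with the intercept) and a
raw cubic week polynomial has column correlations around 0.95, both of
which degrade interval calibration for reasons that have nothing to do
with the models themselves.

**Roster.**  Calving histories are simulated year by year with a 0.35
annual calving probability gated by the two-year minimum inter-birth
interval.

## Inference

The three regression families maximize nothing exotic: flat priors on the
unconstrained scales (bounds ±20 on coefficients, ±10 on log φ / log ω,
checked post hoc for truncation), logit links for the occupancy
probabilities and the beta mean, log links for the gamma mean and the
shape/precision constants.  Posteriors are sampled with emcee (40
walkers, differential-evolution moves) initialized from a Laplace
approximation at the mode found by Nelder–Mead/Powell, so short chains
(default 800 steps; 2500 for calibration runs) start in approximate
equilibrium.  Convergence is flagged by split-R̂ across walkers; a
non-converged fit warns, never passes silently.  Model stacking across
covariate subsets is out of scope; each family fits its single full
covariate set (cells with few positive records are restricted to one
explanatory variable, and cells with no positives get a hurdle-only fit
with the gamma mean reported as unavailable).

## Numerical choices and problem sizes

Grids default to 60 fat × 30 fetal nodes and 7 policy lengths with K = 10
prey categories; the heavier tests and the acceptance script run at
40 × 20 × 5 with 20 replicate populations of 50 females, sizes at which
the qualitative patterns of interest are stable and a full factorial
re-runs in minutes.  Prey discretization spans the 0.5–99.5% lognormal
quantiles with midpoint-interval masses renormalized to one.  Bilinear
interpolation clamps to the grid hull (logged once).  Degenerate inputs
are rejected loudly: zero-variance prey strata, lengths outside 11–14 m,
exposure for unknown cells, proportions of exactly one under the
zero-inflated beta support.

The "nearshore share non-increasing after week 4" structural check is
evaluated on the share of in-area females (isolating habitat choice from
arrival timing) with a slack of one whale-week (1/population), the finest
resolution a 50-animal binomial process supports.

## What passing tests do and do not show

The synthetic truth has exactly the structure the fitting stages assume
(lognormal prey, conditionally independent hurdle draws, logistic links,
no spatial autocorrelation within a survey, detection probability 1.0).
Recovery and calibration results therefore demonstrate the correctness of
the machinery, not robustness to the misspecification, unmodeled
heterogeneity and observation error of real field data.  Likewise the
bioenergetic constants are plausible-magnitude stand-ins for a companion
bioenergetics model that is not reproduced here; conclusions that depend
on their specific values (absolute reproduction rates, absolute density
levels) are illustrative, while the structural comparisons the package is
built for — disturbed vs undisturbed under coupled seeds, orderings
across fitness variants and length cutoffs, seasonal occupancy shape —
are parameterization-robust by design and are the quantities the test
suite pins.

## Known limitations

- Single breeding event: no abortion decision, no multi-year carryover,
  no lactation simulation beyond its embedding in the terminal fitness.
- The terminal-day value uses terminal fitness without the overwinter
  survival factor, while voluntary departure applies it; the resulting
  incentive to stay until season end is negligible but present.
- Under softmax rules the stored value surface can be locally
  non-monotone in fat at the behavioral-mixing scale.
- The acoustic stand-in has no bathymetry, directionality or calibration;
  only exceedance geometry is emulated.
- Occupancy of females that die mid-season is a convention (counted
  outside), as the underlying bookkeeping is not observable in the field.
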