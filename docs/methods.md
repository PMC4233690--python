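# Methods

## Model

Incarceration is modelled as a susceptible–incarcerated–susceptible (SIS)
process on a fixed influence network.  Agents are susceptible, incarcerated
("infectious"), dead, or not yet born.  An incarcerated agent *i* transmits
to each susceptible neighbour *j* independently each month with probability
*p(i→j)*; a successful transmission starts a freshly drawn sentence for *j*
the following month.  Release returns an agent to the susceptible state
with no immunity and no residual infectivity.  The infectious period of a
spell equals the sentence length in months, so the whole-sentence
transmission probability is `1 − (1 − p(i→j))^s`.

Assumptions inherited from this design: infectivity is constant over the
sentence and zero after release; transmission operates only along recorded
family/friendship ties; sentence length is the only quantity that differs
between the Black and White scenarios (network, rates and initialization
are held fixed to isolate the sentencing mechanism).

## Synthetic population

The generator produces one multi-generational population per experiment,
reused across replicates and scenarios.  Two clocks are used: population
events (births, deaths, tie formation) run on a yearly clock; the epidemic
runs on a monthly clock with month 0 at the end of the burn-in year
(year × 12 conversion).

Founders: 1500 agents with birth years uniform over the 60 years before
iteration 0 (the founder window is a package choice; initial ages are then
Uniform(0, 60)).  Each agent receives sex ~ Bernoulli(0.5), a location in
the unit square (friend and spouse choice is by Euclidean proximity, which
is what creates community structure), and a lifespan drawn from an annual
life table.  Yearly event order is fixed for reproducibility: scheduled
births → friendship formation (agents turning 10) → partnering and child
scheduling (females reaching their age at first birth) → deaths.  The
clock starts at the earliest founder birth year so that founders' own
life-course events fire; agents alive at any time from year 150 on are
retained (default 200 total iterations).

Parameter choices, with units and rationale:

- **Age at first birth** `h = 15 + r`, `r ~ Poisson(10.6)` years, giving
  mean 25.6 — the reported mean age at first childbirth; the Poisson form
  is a package choice (only the mean is published).
- **Number of children** per mother from a pmf on {0..5} with mean 2.07
  (matching the reported total fertility rate after adjustment for
  population replacement): {0: 0.15, 1: 0.17, 2: 0.33, 3: 0.21, 4: 0.09,
  5: 0.05}.
- **Inter-birth spacing**: each child after the first is born at the
  first-birth year plus an independent Poisson(4.5)-year offset.
- **Child location**: parents' midpoint plus Uniform(±0.05) noise per
  axis, clipped to [0, 1]².
- **Friend count** from a pmf on {0..5} with mean 1.46 (survey-based
  non-kin confidant counts are not published; this shape is a package
  choice).  Friends are the nearest non-sibling agents aged 9–11 at the
  chooser's 10th birthday.
- **Partnering**: in her first-birth year a female is matched to the
  nearest alive, unmarried, non-friend male 0–9 years older who shares no
  ancestor within two generations; monogamy is enforced.  If none exists
  she remains a single mother.
- **Life table**: the packaged default is a synthetic Gompertz–Makeham
  schedule `q(x) = A + B·e^{x/11.5}` calibrated to expected completed ages
  at death of 80 (female) and 75 (male) years, absorbing at 119; a real
  period life table can be supplied as CSV.  Death year is birth year +
  completed age at death + 1, so agents are alive over the half-open
  interval [birth, death).
- Births require the mother to be alive in the scheduled year.

A realisation at the default settings has several thousand retained agents
and tens of thousands of ties (the run used throughout the tests has 6946
agents and 25 559 ties, ≈ 3.7 ties per agent).

## Sentences

Sentence lengths are a negative binomial on {0, 1, …} shifted by +1 month
(no zero-month sentences, which would make the infectious period empty),
fitted to a (mean, median) target: White mean 14 / median 10, Black mean
17 / median 12, months served for drug possession.  The dispersion
parameter is scanned over (0.05, 50] in steps of 0.005 with the success
probability solved exactly from the mean; among candidates whose CDF-based
integer median equals the target, the smallest dispersion parameter is
chosen (deterministic, and the most dispersed — hence heaviest-tailed —
feasible fit).  Equal mean and median yields a point mass.

## Transmission probabilities

Whole-sentence co-incarceration probabilities from an inmate survey, by
relation and inmate sex, are converted to monthly rates by inverting the
cumulative-risk identity at a calibration sentence of s = 14 months
(between the two scenario means): `p = 1 − (1 − p_sentence)^{1/14}`.
Rows are the susceptible's role relative to the inmate (mother/father for
the inmate's parents by their sex; sister/brother for siblings *and close
friends* by the susceptible's sex; spouse; adult child), columns the
inmate's sex.  Transmission to the inmate's child activates at the child's
18th birthday (no rate is published for minors, so younger children
receive rate 0).  Display rounding is half-up to 3 decimals; all internal
computation keeps full precision.

Sentence-marginalised transmission probabilities are computed by Monte
Carlo (averaging `1 − (1 − p)^S` over sentence draws) and cross-checked
against direct summation truncated where the survivor mass falls below
1e-10.

## Epidemic engine

Monthly step, in order: (1) apply scheduled deaths — the death of an
inmate truncates its spell; (2) every incarcerated agent draws an
independent Bernoulli for each alive, susceptible neighbour of
incarcerable age (default minimum 15 years), using the start-of-month
infectious set only, so there are no within-month infection chains; a
susceptible infected by any neighbour starts one new spell (the recorded
transmitter is the first successful source in agent-id order); (3)
sentences that have run out return agents to susceptibility; (4) new
spells begin the following month.  Initialization seeds
`round(init_prevalence × alive agents)` inmates uniformly among eligible
(alive, incarcerable-age) agents, each serving a full freshly drawn
sentence from month 0, so month-0 prevalence over the alive population
equals the configured value.  Prevalence is incarcerated / alive at the
start of each month.  Ensembles run replicate *r* with seed base + *r* and
summarise month-wise (mean, 2.5/97.5 percentiles, per-month Welch tests).

## Non-contagious control

Identical bookkeeping with contact transmission replaced by an independent
Bernoulli(spontaneous rate) per eligible susceptible per month.  Flow
balance gives the closed-form equilibrium `π₀E[s] / (1 + π₀E[s])` over the
eligible population, used both to anchor the rate tuner (bisection on
ensemble-mean final prevalence, 25 replicates per evaluation by default)
and as an independent oracle in tests.  Because minors are not eligible,
equilibrium prevalence over the whole alive population is lower than the
closed form by the adult fraction; the tuner absorbs this.

## Mean-field analysis

Ignoring vital dynamics, the SIS ODE steady state is
`I* = max(0, 1 − 1/(p·s))` with critical sentence `s_c = 1/p`.  The
population-wide mean transmission rate is calibrated from simulation event
logs as contact infections divided by incarcerated person-months actually
served, pooled over replicates — one defensible estimator among several;
it is exposed so users can substitute their own.  On the default network
this estimator gives ≈ 0.061–0.062 per month, i.e. `s_c ≈ 16.3` months,
between the two scenario means.

## Recidivism statistics

A release record is a spell ending in release.  Return = a new spell
starting within a 36-month follow-up (3-year recidivism convention).
Releases with fewer than 36 observable months (horizon or death) are
censored and excluded from denominators.  Rates are tabulated by prior
spell count {1, 2, 3, 4, 5+}, age at release (5-year bins, 60+), and
sentence length (12-month bins, 97+); the cumulative return curve is
normalised over returners.  Everything is computed per replicate and
summarised with the cross-replicate mean and empirical 2.5/97.5
percentiles (linear interpolation between order statistics).

The contagious/control contrast in the return curve is measured by a
signed departure-from-linearity index (mean of curve − diagonal): strongly
positive (concave, early returns) for the contagious model, near zero for
the constant-hazard control, whose geometric return-time law is
analytically close to linear over 36 months.

## Problem sizes

Tests and the acceptance script use 50-replicate ensembles on one
full-scale population realisation (the published experiments used 250);
ensemble means are stable at this size, and the small-instance oracles
(exhaustive Markov-chain enumeration on a 3-agent line; flow-balance
equilibrium on a static all-adult population) run at 10⁴ and 30 replicates
respectively.

## Known limitations

- **Near-threshold sensitivity of the White scenario.**  With the
  calibrated rates, mean White sentences put the system just below the
  mean-field bifurcation (`p̂ × 14 ≈ 0.86 < 1`).  In this regime
  persistence vs extinction is decided by network-heterogeneity details
  (degree tails, family-size variance) that the published moments do not
  pin down.  On the packaged generator's networks, White-sentence
  ensembles go extinct (final prevalence well under 0.5%), while
  Black-sentence ensembles grow to ≈ 3% over 50 years; the Black/White
  contrast is therefore reproduced as a threshold effect, but the precise
  sub-threshold White level should not be over-interpreted.
- The generator holds demography constant across scenarios by design;
  race-specific network structure, migration, divorce/re-partnering and
  same-sex partnerships are out of scope.
- Lifespans are independent of incarceration history, so simulated agents
  live (and remain at risk) longer than real justice-involved populations;
  recidivism-by-age curves are correspondingly stretched toward older
  ages.
- The survey-derived rate table is sparse: no rates exist for minors,
  grandparents, or multiple simultaneous relationship types beyond the
  recorded tie label (a friend who is also a cousin is just a friend).
- One cell of the 3-decimal monthly-rate display (mother row, male-inmate
  column) rounds to 0.004 from the survey value 0.048 at s = 14 under any
  half-rounding rule; published summaries of the same derivation print
  0.003.  Simulation uses full precision throughout, where the distinction
  is immaterial.
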