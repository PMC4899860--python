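# Methods

`quadratdyn` reimplements a complete analysis chain for long-term mapped
("chart") quadrat data from semi-arid grasslands: extracting genet
demography from yearly polygon maps, fitting climate-dependent vital-rate
regressions, building two multispecies population models from those fits —
a spatially explicit individual-based model (IBM) and a spatially implicit
integral projection model (IPM) — and using the IPM to quantify negative
frequency dependence (NFD) and to decompose species' responses to climate
perturbations into direct and indirect components.

## Genet tracking

Plants are mapped yearly as basal-cover polygons (grasses), canopy
polygons (shrubs), or points (very small plants, assigned 0.25 cm²).
Because genets resprout and maps carry pantograph error, identity is
resolved by a buffering/overlap rule: every year-(t−1) polygon of the
focal species is dilated by a 5-cm buffer (`buffer_cm`, configurable);
each year-t conspecific polygon inherits the identity of the buffered
antecedent with which it shares the greatest overlap area, or is labelled
a new recruit if it overlaps none. Genets may fragment (several year-t
polygons inheriting one identity — they are merged back under that
identity) and coalesce. Ties on greatest overlap are broken by larger
antecedent area, then lower genet id, making output deterministic; only
the year-(t−1) polygons are buffered. Each tracked genet-year is reduced
to a circle with the summed area of its member polygons at their
area-weighted centroid; inter-genet distance is centroid distance.
Transitions spanning census gaps are excluded, and the year after a gap
is treated as a restart (its plants are not recruits).

On the shipped low-movement, sparse synthetic archive the tracker
recovers ≥ 99% of identities. Accuracy degrades in dense stands, where
new recruits frequently emerge within the buffered canopy of an
established conspecific and are absorbed into its identity — a limitation
shared by any overlap-based tracker and reported separately by the
acceptance script.

## Neighbourhood crowding

Competition enters the regressions through a Gaussian-kernel crowding
index: the crowding genet *i* of species *j* experiences from species *m*
is w_ijm = Σ_k u_k·exp(−α_jm·d²_ik), summing over same-quadrat neighbours
*k* of species *m*, with u the neighbour's area (cm²), d the centroid
distance (cm) and α_jm (cm⁻²) the spatial scale of the interaction. The
index is linear in neighbour size, monotone decreasing in distance, and
tends to the plain cover sum as α → 0. α values are inputs read from the
species registry (they are estimated in a separate single-species
analysis in this literature); a likelihood grid-search utility is
provided for synthetic work. Synthetic scenarios use a single α = 0.05
cm⁻² for all pairs and vital rates. No distance truncation is applied.

## Vital-rate regressions

Survival of genet *i* (species *j*, group *g*, year *t*) is Bernoulli
with logit S = γ_t + φ_g + β·u + **ω**·**w** + (crowding×size)·u·**w** +
**η**·**C** + **Γ**·(**C**·u), where u is log area, **w** the crowding
vector, **C** the climate covariate vector (five named covariates — prior
water-year precipitation `pptLag`, critical-season precipitation `ppt1`,
`ppt2` and temperature `T1`, `T2` of the two transition years — plus
within-year precipitation×temperature products). Growth of survivors has
the same linear-predictor structure for the mean v̄ of next log size,
with variance Var = a·exp(b·v̄) capturing the size-dependence of growth
noise; the variance function is fitted to the squared mean-model
residuals by a gamma GLM with log link.

Recruitment is modelled at the quadrat level (parentage is unobservable):
recruit counts y of species j arriving in quadrat q are negative binomial
with size θ and mean λ_j = N′_j·exp(γ_t + φ_g + **ω**·√**N′** +
**η**·**C**), a Ricker-type form in the square root of effective cover.
Effective cover N′ = p·N_q + (1−p)·(group mean cover) acknowledges seed
rain from outside the quadrat; the mixing fraction p is profiled over a
grid (0 … 1, step 0.1) by maximum likelihood. The negative binomial is
parameterized so the variance is λ + λ²/θ; sampling uses the exact
gamma–Poisson mixture.

**Estimation.** All models are fitted per focal species (coefficients are
species-specific; the fitters reject mixed-species tables). Year and
group enter as dummy (fixed) effects in maximum-likelihood fits
(binomial GLM, OLS, negative-binomial count regression); fitted per-year
deviations are centred and stored, and they double as the empirical
year-effect library that the simulators draw from. With tens of years and
a handful of groups this recovers generating parameters as well as a
random-effects fit while keeping the per-year draws first-class and the
whole procedure deterministic.

**Climate effects are estimated in a second stage.** The climate
covariates are constant within a year, hence exactly collinear with year
dummies; a one-stage fit cannot identify them. Stage one fits year
dummies (plus the within-year-varying climate×size interactions); stage
two regresses the fitted per-year intercept deviations on the (centred)
year-level covariates by OLS. The stage-two coefficients are the climate
effects **η**, the stage-two residuals replace the raw deviations as the
random-year-effect library (no double counting), and the intercept
absorbs the centring. Stepwise covariate selection is bidirectional on
the stage-two regression, minimizing the small-sample-corrected AICc
(the year-level sample is only tens of points); interactions respect
marginality, and interactions are excluded for recruitment. Selection is
deterministic given the data.

**Variance explained by climate.** For each vital rate a model triplet is
fitted — constant (no temporal terms), climate-only, and full (year
effects) — and the share of interannual variation attributed to climate
is (X_constant − X_climate)/(X_constant − X_full), with X the residual
sum of squares (growth) or residual deviance (survival, recruitment; for
the count model −2·loglik, whose differences equal deviance differences).
The ratio is clipped to [0, 1] with a warning when sampling noise inverts
an ordering, and NaN when constant and full models tie.

## Individual-based model

The IBM simulates every genet in a 1-m² quadrat with demographic
stochasticity in all three vital rates: Bernoulli survival, normal growth
with the fitted size-dependent variance, negative-binomial recruit
counts. Recruitment intensities are computed from the time-t community
(parents are the plants present before mortality acts) with effective
cover taken as the quadrat's own cover; recruits appear at uniform-random
locations at the 0.25 cm² point size. Crowding is recomputed from current
geometry every step; boundaries are absorbing (no wraparound, neighbours
outside the quadrat do not exist). Each simulation step draws one
observed climate year and, independently, one year-effect set shared
across species and vital rates (preserving their cross-correlations); a
"climate covariates only" mode zeroes the year effects. Historical
(hindcast) mode initializes from the plants observed in the first census
year, applies year-specific effects in chronological order, re-initializes
after census gaps, and averages cover over 50 replicates by default.

## Integral projection model

The IPM is the environmentally stochastic but demographically
deterministic counterpart: each species is a density n(u, t) over log
size, projected by n_j(v, t+1) = ∫ K_j(v, u, W̄(u)) n_j(u, t) du with
K = S(u)·G(v, u) + f(u)·r(v). Per-capita fecundity is linear in
arithmetic size, f(u) ∝ exp(u), normalized so total recruitment equals
the quadrat-level intensity λ_j (recruitment is proportional to total
cover); r(v) is a point mass at the 0.25 cm² recruit size.

Numerical choices. Midpoint rule on a default 100-node mesh from
log(0.2 cm²) to log(max observed area) + 1; a convergence test guards the
discretization (one-step cover changes < 0.1% when the mesh doubles).
Point masses (recruits, individual plants when converting an IBM state)
are deposited by two-node linear interpolation, preserving both count and
mean log size — nearest-node snapping would bias recruit-cohort cover by
≈ +3.6% at this resolution. Negative densities from round-off are clipped
at zero with a counter. Mass that grows past the mesh bounds is evicted;
the upper bound is set beyond observed sizes so the loss is negligible.

Mean crowding. The IPM replaces the individual crowding index by its
expectation W̄(u). For heterospecific neighbours, treated as spatially
random, the expectation is (π/α)·(cover density); for conspecifics a
"no-overlap" rule excludes neighbour centres within the sum of the two
genets' circle radii, giving (π/α)·∫ exp(u′) n(u′) exp(−α(r(u)+r(u′))²)
du′ / A — an exact closed form of the radial integral, cached on the
mesh. Both carry an exact finite-quadrat boundary factor — the
expectation of exp(−α·d²) for two independent uniform points in the
quadrat, separable in x and y with an erf closed form — so the
expectation matches an absorbing-boundary quadrat; `extent_cm=None`
recovers the infinite-plane forms.

The no-overlap discount deserves comment. Measured against the synthetic
IBM at stationarity, realized conspecific crowding is far below the
random-placement expectation even though recruits land uniformly: density
-dependent mortality preferentially removes crowded individuals, thinning
neighbourhoods, and the no-overlap rule approximates that emergent
segregation well (disabling it drives IPM covers ~25% below the IBM
ensemble). It is the default everywhere; `conspecific_exclusion=False`
is available for strictly random communities.

Cross-engine agreement. After the deposition fix, IPM trajectories track
the 200-replicate IBM ensemble mean within 0–4.5% of cover over 30 steps
on the symmetric two-species fixture. The residual disagreement is the
irreducible price of a mean-field closure: emergent spatial correlations
feed back through the crowding coefficients, and the ensemble mean of a
50–300-individual stochastic process differs from any deterministic
skeleton by Jensen-type terms at 1-m² scale. At a few time points this
exceeds two Monte-Carlo standard errors of the ensemble mean.

## Negative frequency dependence

Equilibrium cover is the time-average over a post-burn-in window of a run
seeded at very low abundance (defaults: 500-step burn-in, 2,000-step
window; a no-trend diagnostic on total log cover certifies
equilibration). Equilibrium frequency is relative cover. The invasion
growth rate (IGR) of a focal species runs the residents to stochastic
equilibrium without it, introduces it at a cover of 10⁻⁶ (initially the
recruit-size point mass), and repeats one-step invasion experiments: step
the whole community, record log(C_{t+1}/C_t) for the focal, rescale its
cover back to 10⁻⁶ *preserving its evolved size structure* (the standard
structured-invader treatment; the structure converges to the low-density
stationary form within a few steps). The IGR is the arithmetic mean of
the step log growth rates over 1,000 steps by default — the log of the
geometric mean growth rate — with a naive Monte-Carlo SE. The NFD slope,
the community-level niche-difference proxy, is the slope of the line
through (≈0, IGR) and (f_eq, 0): −IGR/f_eq; more negative means stronger
stabilization.

Two structural facts are worth knowing. First, a species' per-capita
growth is zero (on the log scale) at its equilibrium frequency; the
package exposes this as `resident_growth_rate`, the time-mean log cover
ratio of each resident at stochastic equilibrium, which is ≈ 0 within
Monte-Carlo error. Second, inviting a *clone* of a resident as a
heterospecific invader is not neutral here even with identical
coefficients: the clone experiences the random-neighbour expectation of
its twin's crowding while the resident enjoys the no-overlap discount, so
clone-invasion IGRs are slightly negative (≈ −0.05 on the neutral
fixture). Neutrality diagnostics should therefore use
`resident_growth_rate`, not clone invasion.

## Climate perturbations and the effect decomposition

Three perturbation kinds: precipitation means × 1.01 (a deliberately
small, 1%, shift to stay within the fitted covariate range); temperature
means shifted additively by 1% of the site mean (multiplicative °C
scaling would depend on the temperature origin; a multiplicative mode is
config-selectable); and variability, mapping every covariate x → mean +
√1.10·(x − mean), which multiplies each sample variance by exactly 1.10
and leaves means unchanged (variance, not SD, is inflated). Interaction
covariates are always recomputed from the perturbed base covariates.

For each community the experiment runs paired simulations sharing one
pre-drawn sequence of climate-year and year-effect indices (common random
numbers): a baseline under observed climate; a *full* run in which every
species sees the perturbed climate; and one *direct* run per focal
species in which only the focal sees the perturbed climate. The full
effect is the focal's equilibrium-cover change in the full run; the
direct effect is its change in its own mixed run; the indirect effect is
full − direct, exact under the common-random-number contract (a
zero-magnitude perturbation yields exactly zero effects, and a
single-species community has full = direct identically). Raw effects are
rescaled by baseline cover to proportional effects, and compared through
log(|proportional indirect|/|proportional direct|), positive when
indirect effects dominate; the log ratio is flagged NaN when the direct
effect is exactly zero. The community-level sample variance of raw direct
effects (n−1 denominator) is attached identically to every species row of
a site × perturbation.

Across communities, variation in |raw indirect| is synthesized with a
linear mixed model — fixed effects: NFD slope and variance of direct
effects; random intercepts: site, and perturbation nested within site —
fit by maximum likelihood, falling back (with a warning) to site-only
random intercepts and then OLS when the variance components are singular,
as they are in small designs.

## Synthetic data

The generator emulates the study's two input streams. Climate series are
independent normal draws per covariate per year (no autocorrelation,
matching the simulation protocol's independent annual draws) with
realistic semi-arid defaults (pptLag 300 ± 60 mm, ppt1/ppt2 150 ± 40 mm,
T1 10 ± 1.2 °C, T2 16 ± 1.2 °C). Chart-quadrat archives are produced by
running the IBM from known parameters and rendering each genet's circle
as a 12-segment polygon clipped to the quadrat (plants at the 0.25 cm²
floor become points), with true identities and recruit flags kept aside
for scoring. Year effects are drawn once per calendar year and shared
across quadrats, as real interannual variation is; group effects are
zero-sum normal draws (SD 0.1).

Scenario registry (all pre-validated to persist over 100 IBM steps):
`symmetric-2sp` (identical species, interspecific coefficients 0.4× the
intraspecific ones; equilibrium frequencies exactly 0.5 —
identical species share their year-effect draws, because clones must
respond identically to the same year), `neutral-2sp` (inter = intra),
`niche-partitioned` (0.15×), `neutral-ish` (0.9×), `pure-indirect` (a
climate-blind focal suppressed ~6× more strongly by its climate-sensitive
competitor than vice versa; the focal's direct effect is exactly zero and
its whole response is competitor-mediated), `variance-gradient`
(opposite-signed climate effects), `single-species`, and
`sparse-tracking` (few, slowly recruiting, immobile genets for identity
scoring). Baseline demography: survival logit intercept 1.5 at mean
climate with size slope 0.8; growth intercept 0.35, slope 0.9, variance
a = 0.15, b = 0; recruitment intercept 1.0 on the Ricker scale with
intraspecific √cover coefficient −0.12 and θ = 2. Effect sizes are chosen
so recovery succeeds at ≈ 5,000 transitions. A direct generative
transition simulator (`generate_transitions`) bypasses the IBM where the
estimand must match the generative model exactly (selection calibration).

What the generator does not emulate: mapping error and digitization
noise, within-genet polygon shapes (genets are circles), climate
autocorrelation, observation gaps' real causes, multi-site covariate
structure, and trophic interactions. Passing tests therefore demonstrate
internal consistency of the pipeline and recoverability under the model's
own assumptions, not robustness to the messiness of the historical
archives.

## Problem sizes and defaults

Simulation defaults: 100 mesh nodes; 500-step burn-in; 2,000-step
equilibrium window; 1,000 invasion steps; 50 IBM hindcast replicates;
invasion cover 10⁻⁶. The test-suite and acceptance-script runs scale
these down (typically 250–300 burn-in, 300–700 windows, 250–600 invasion
steps, 8–40 quadrats × 18–26 years of synthetic data) to keep full runs
in the minutes range on one CPU; the quantities they compute are
insensitive to these sizes beyond Monte-Carlo error at the reported
precision.

## Known limitations

* Mean-field crowding: IPM-vs-IBM cover agreement is 0–4.5%, not exact
  (see Cross-engine agreement above).
* Clone invasion is structurally non-neutral (see NFD above).
* Identity tracking degrades in dense stands (recruits under established
  canopies inherit the canopy's identity).
* The two-stage climate estimation gives year-level SEs (n = number of
  years); with few years, climate effects are estimated honestly but
  imprecisely, and stepwise selection has limited power.
* The recruitment mixing fraction p is weakly identified when quadrat
  and group covers are similar; it is profiled, not tested.
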