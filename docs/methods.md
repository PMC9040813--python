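# Methods

## Constraint-based model and solvers

A metabolic model is a stoichiometric matrix `N` (metabolites × reactions)
with per-reaction flux bounds in mmol h⁻¹ gDCW⁻¹ and one objective
reaction (biomass, whose flux is the growth rate in h⁻¹). Flux balance
analysis solves `max c·v` subject to `N·v = 0`, `lb ≤ v ≤ ub` with the
HiGHS simplex behind `scipy.optimize.linprog`. Solver outcomes are
reported as-is: infeasible or unbounded problems return a status and no
flux vector. Fluxes below 10⁻⁶ in magnitude are reported as zero; blocked
reactions are classified with a 10⁻⁹ tolerance on their per-reaction
min/max feasible flux.

FBA optima are generally degenerate. Whenever a representative flux
*vector* matters (pathway summaries, PCA, parametrized-model predictions),
the cycle-free second stage is used: with every exchange flux and the
objective flux fixed to their stage-one values, and each internal flux
confined to the closed interval between 0 and its stage-one value, the
summed absolute internal flux is minimized. Because each internal
variable's sign is fixed by the box, the absolute-value objective is
linear without auxiliary variables. The stage preserves the objective and
all exchanges exactly, never grows any internal flux magnitude, and drains
circulating flux from internal loops.

Knockouts clamp to zero every reaction whose GPR rule evaluates false with
the deleted genes off (an empty rule — an orphan reaction — is always
active). Knockout growth is recomputed either by FBA or by linearized
MOMA: minimize `Σᵢ|vᵢ − v_refᵢ|` over the knockout model's constraint set
via auxiliary variables `dᵢ ≥ |vᵢ − v_refᵢ|`, with the wild-type
cycle-free FBA solution as reference. A gene is called essential when its
knockout drops the growth ratio below 0.01; the threshold is a
configurable convention, and because knocking out the maintenance
pseudo-gene *relieves* the NGAM demand, growth ratios slightly above 1 are
possible. FBA- and MOMA-based essential sets are reported per method,
never merged implicitly.

Phenotype phase planes clamp two exchange uptakes (`lb = ub = −magnitude`)
on a grid and maximize the objective at each cell; infeasible cells are
recorded as 0 with a flag. The optimal-ratio ridge is summarized as the
through-origin least-squares slope of the objective-maximizing B-magnitude
against the A-magnitude.

## The reduced methanotroph network

The packaged fixture encodes the central carbon and energy metabolism of
an obligate aerobic, RuMP-cycle methanotroph in 58 metabolites and 65
reactions, every internal non-biomass reaction balanced in C, H, O and N
(real elemental formulas are carried even for cofactors, with NADH and
ubiquinol written as their oxidized partner plus H₂, and protons tracked
explicitly in cytosolic and periplasmic pools). The structural choices
that drive its behavior:

* **pMMO** (`CH4 + O2 + NADH → CH3OH + H2O + NAD`) is the only methane
  sink, so feasible growth requires an oxygen:methane uptake ratio of at
  least 1:1.
* **Methanol dehydrogenase is PQQ-linked** and reduces the quinone pool;
  an NAD-linked alternative is present but purposely clamped to zero flux
  (bounds (0, 0)), mirroring curated-model practice of shipping blocked
  alternatives.
* **The NADH dehydrogenase is reversible** (4 protons pumped per NADH).
  Reverse electron transport lets the network regenerate the NADH that
  pMMO consumes even when respiration is oxygen-starved, at the cost of
  proton-motive force ultimately paid by substrate-level ATP — the
  mixed respiration/fermentation mode that appears at low
  oxygen:methane ratios together with acetate excretion through the
  phosphoketolase (Bifidobacterium shunt) and acetyl-CoA routes.
* **Electron capacity caps the feasible band.** Complete combustion fixes
  2 mol O2 per mol CH4; a capacity-limited H2O2-forming NADH oxidase
  (respiratory overflow, upper bound 5 mmol h⁻¹ gDCW⁻¹ at the default
  methane scale) lets the network dissipate surplus oxygen at 2 electrons
  per O2, extending feasibility to just under 2.25:1, beyond which the
  oxygen clamp cannot be satisfied.
* **Formaldehyde** is assimilated through the RuMP cycle (EMP, EDD and
  phosphoketolase variants, closed by transketolase/transaldolase) or
  oxidized to formate through lumped H4MPT and folate branches; a partial
  serine cycle links malate to acetyl-CoA and glycerate. Methanol
  secretion is allowed but capped (1 mmol h⁻¹ gDCW⁻¹ at the default
  scale) as a pre-assimilation overflow.

### Tunable constants and calibration

`ReducedNetworkConfig` exposes: growth-associated ATP maintenance
GAM = 59.8 mmol gDCW⁻¹ and non-growth-associated maintenance
NGAM = 3.5 mmol gDCW⁻¹ h⁻¹ (standard literature values for
gammaproteobacterial methanotroph reconstructions, applied as the
biomass ATP draw and the ATP-demand lower bound respectively); the ATP
synthase proton stoichiometry (default 3 H⁺/ATP, giving effective P/O of
8/3 per NADH and 4/3 per ubiquinol); the biomass precursor coefficients;
the default gas uptake caps (10 mmol h⁻¹ gDCW⁻¹ each); and the two
overflow capacities.

The biomass draw (per gDCW: 4.2 pyruvate, 4.2 oxaloacetate,
1.4 2-oxoglutarate, 1.4 acetyl-CoA, 4.8 NH3, GAM ATP, with 25 mmol NADH
*released* by the lumped synthesis) together with the proton stoichiometry
was calibrated once, as a fixture-design step, so that the growth-optimal
oxygen:methane uptake ratio lands at ≈1.5:1 and the growth-optimal CO2
excretion stays below 2 mmol h⁻¹ gDCW⁻¹ at bounded uptakes. The resulting
lumped biomass is more oxidized (≈1.7 electrons per carbon net of the
NADH release) than real cell material (≈4.2); this is the price of
reproducing whole-organism energy ratios in a 65-reaction network and is
deliberate. The excretion-fraction structure (acetate's fraction largest
below ≈1.23:1, CO2 plus formate dominant above 2:1) is *not* separately
tuned — it follows from the degree-of-reduction bookkeeping of the
excreted compounds under the oxygen clamp.

Every non-exchange reaction carries a synthetic GPR rule (plausible gene
mnemonics, including one isozyme pair on formate dehydrogenase and
multi-subunit AND-rules on pMMO and ATP synthase) so that knockout and
essentiality machinery is exercised realistically; exchanges are orphans,
as in genome-scale reconstructions.

## Culture kinetics estimators

All estimators implement the closed-bottle exponential-phase recipe.
Growth rate: pooled least-squares slope of ln X against time over all
replicate points in the window (pooling preserves degrees of freedom for
the confidence interval; replicates are never averaged first). Specific
flux of a compound: slope of its culture concentration against X/μ, which
is exact under exponential growth since `dC/dt = q·X(t)` integrates to
`C = C0 + (q/μ)(X − X0)`; positive slopes are excretion, negative uptake.
Headspace gas amounts (mmol) are divided by the liquid volume before the
regression — concentrations are per liquid volume by default, with the
vessel geometry carried in the series metadata. Confidence intervals come
from the slope standard error and Student's t: 99% for growth and fluxes
(the level at which measured intervals are imposed on models), 95% for
the nonlinear kinetic fits. Yields are computed over the whole culture
period as change per total methane consumed.

The exponential window is detected as the longest contiguous run of ≥4
sampled times whose pooled log-linear fit reaches R² ≥ 0.98 (ties broken
by R²), followed by a greedy endpoint trim that drops a boundary time
while doing so cuts the residual variance by at least 25%. The trim is
what sheds lag and plateau points that a long window can absorb without
breaching the global threshold; on noiseless lag/exponential/plateau
series it recovers the true phase boundaries exactly, and at 5%
multiplicative noise it lands within one sampling step. Both thresholds
are engineering conventions, and a user-supplied window always overrides
detection. Estimator coverage claims are evaluated against the true
(generator-known) window, so they measure the regression machinery, not
window detection.

Monod fits use nonlinear least squares initialized at μmax₀ = max μ,
Km₀ = median S; bounded-exponential fits (`y = a(1 − e^{−bx})`) at
a₀ = max y, b₀ = 1/median x. Both are order-invariant up to solver
round-off. When every substrate level saturates the enzyme, Km is
reported with an honestly enormous CI rather than suppressed.

Headspace accounting is ideal-gas: `n = P·V·(pct/100)/(R·T)` with
configurable temperature and pressure. Printed experimental gas amounts
in source data sheets are treated as metadata, never re-derived, because
measurement conventions (temperature, over-pressure, sampling makeup gas)
vary between laboratories.

## Synthetic batch cultures

The generator emulates triplicate closed serum-bottle cultures: 20 mL
medium under a 140 mL headspace at 303 K, initial CH4 and O2 headspace
percentages convertible to mmol by the ideal-gas law. Biomass grows
exponentially from X₀ (optionally after a lag) until the first gas —
oxygen, under the default parameterization — is exhausted, then all
quantities plateau hard (no death phase: only the exponential phase feeds
the estimators). Compound amounts follow the closed-form integral of
`dM/dt = q·X·V_liq`. Noise is multiplicative log-normal per observation
at a configurable coefficient of variation (default 5%), independent
across replicates; the exact parameterization, depletion time and
limiting substrate are embedded in the output metadata.

The default condition uses μ = 0.09 h⁻¹ with specific fluxes
(CH4 −4.2, O2 −5.67, CO2 +1.64, formate +0.05 mmol h⁻¹ gDCW⁻¹), chosen so
the implied biomass yield (0.021 gDCW mmol-CH4⁻¹) and CO2 yield
(0.39 mmol mmol-CH4⁻¹) match the highest yields measured for the modeled
organism, the uptake ratio (1.35:1) sits in the experimentally observed
band, and oxygen depletes first while methane remains. A carbon audit
(consumed CH4 carbon ≥ excreted + biomass carbon at a configurable
carbon fraction, default 0.33 g C gDCW⁻¹ as implied by closing the carbon
balance over those yields) rejects inconsistent parameterizations at
construction.

What the generator does *not* emulate: gas-liquid transfer limitation
(kLa), CO2 speciation into carbonate, death/lysis phases, measurement
drift, or correlated errors between compounds. Passing recovery and
coverage tests therefore demonstrates that the estimators are correct
under their own model assumptions — unbiased slopes, honest CIs — not
that those assumptions hold for any particular real culture.

## Integrative scans

Ratio scans clamp methane uptake (default 10 mmol h⁻¹ gDCW⁻¹, `lb = ub`)
and sweep the oxygen clamp over 701 grid points on [0, 30], maximizing
each requested objective independently — growth, the ATP maintenance
demand (the proxy for "ATP generation"), and each excretion exchange.
Excretion fractions at each ratio are each compound's independent maximum
divided by the sum of the three experimentally measurable compounds'
maxima (CO2, formate, acetate); defining fractions over independent
maxima rather than a jointly optimized excretion vector is a design
choice, flagged wherever the denominator is zero. Coupling scans bound
both gas uptakes at (−10, 0) so the model chooses its own uptake ratio,
clamp one excretion at 500 levels from zero to its unconstrained maximum,
and maximize growth at each level; when the growth curve has a plateau
the first (smallest) maximizer is reported.

Parametrized models impose measured CI99 intervals directly as reaction
bounds (the estimators' sign convention makes uptake intervals negative
already); joint infeasibility is diagnosed by single-constraint
relaxation and reported with the offending reactions named. PCA of flux
states divides each flux vector by its methane uptake magnitude, centers
(no unit-variance scaling by default, since normalized fluxes share
units) and decomposes the covariance; loadings are orthonormal and the
top-loading reactions per component are available for inspection.
Reference phenotypes for ordination are computed on the fixture with
methane clamped at 10, oxygen free up to 15, optimizing growth, ATP
maintenance, or one excretion each, then passed through the cycle-free
stage — a convention chosen because covariance PCA on raw FBA vertices
would mostly pick up arbitrary loop flux.

## Known limitations

* The reduced network reproduces *ratio structure* (optimal ≈1.5:1,
  feasibility band, excretion hierarchy), not absolute yields; its growth
  per methane is below that of a full genome-scale reconstruction, so
  measured growth rates from rich cultures may be infeasible as
  simultaneous growth-plus-flux constraints. Constraining uptakes only
  and predicting growth is the supported comparison.
* Cycle-free flux vectors are representative, not unique: alternate
  loopless optima with equal Σ|v| can exist, and PCA scores inherit that
  residual arbitrariness.
* Linear MOMA uses the L1 metric; quadratic MOMA is out of scope.
* The SBML support is deliberately a subset (species, reactions, FBC
  bounds, GPRs, one maximization objective, M_/R_/G_ id namespacing);
  documents with rules, events or constraints are rejected loudly rather
  than partially read.
* The window detector assumes a single contiguous exponential phase;
  diauxic or biphasic growth requires a manual window.
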