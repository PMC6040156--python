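# Methods

This note records the models, numerical choices and known limitations
behind fluxkit, at the level of detail a user needs to judge what a result
does and does not establish.

## Constraint-based model and solvers

A model is a set of metabolites, reactions (stoichiometry, flux bounds in
mmol·gDW⁻¹·h⁻¹, boolean GPR over gene ids), genes, a biomass objective and
a designated ATP-maintenance reaction. Signs follow the steady-state
convention: negative coefficients consume, positive produce; exchange
reactions have a single metabolite and carry uptake as negative flux.

FBA and pFBA are solved with HiGHS through `scipy.optimize.linprog` at
primal/dual feasibility tolerance 1e-9; post-hoc checks (|S v|, bound
violations) use 1e-6. pFBA fixes the objective at `(1 − 1e-6)·optimum` as a
lower bound — strict equality is brittle in floating point — and minimizes
Σ|v| via auxiliary variables `t_i ≥ |v_i|`. Consequence: pFBA fluxes carry
a relative slack of up to 1e-6 against the FBA optimum, and comparisons
should be made at that resolution. Plain FBA returns whichever optimal
vertex the solver selects; because alternate optima make individual fluxes
ill-defined, every per-reaction series (trajectories, expression
correlation) is computed from pFBA vectors.

Default bounds are ±1000 for reversible and [0, 1000] for irreversible
reactions, the conventional big-M for GSMMs.

GPR semantics: `and` = complex (all genes required), `or` = isoenzymes,
case-insensitive keywords, `and` binds tighter than `or`, no negation (it
does not occur in GSMMs). The empty rule is always active. Knockouts close
both bounds of every reaction whose rule evaluates false.

## Medium and measured-rate constraints

`set_medium` closes uptake (lower bound 0) for every exchange not in the
medium and opens uptake to the stated maximum for those in it; secretion
stays open everywhere, so by-products can always leave. `fix_measured_rates`
pins an exchange to `rate·(1 ± band)`; band 0 is an equality. On a fully
determined network, equality constraints from noisy measurements are
mutually inconsistent and the LP is honestly infeasible — that is reported
as a status, never raised, and a nonzero band is the remedy for real data.

## ATP maintenance estimation

The classic chemostat protocol: at steady state μ equals the dilution rate
D, so per condition the measured exchange rates and μ = D are imposed on a
model whose growth-associated ATP demand has been removed, the maintenance
reaction's bounds are opened, and its maximal flux v_ATP(D) is recorded;
OLS of v_ATP on D gives GAM (slope) and NGAM (intercept), with r² and
per-point residuals reported.

Removing the biomass GAM term subtracts the largest multiple of the
maintenance reaction's stoichiometry consistent with the biomass ATP
coefficient. This is exact whenever the biomass reaction's ATP use is
maintenance-stoichiometric (ATP + H₂O → ADP + Pi), the standard
formulation.

Identifiability: the protocol reads maintenance off the energy balance and
therefore requires the culture to be energy-limited. If ATP is cheap
relative to carbon — in the toy network, whenever GAM falls below the
~24 ATP per glucose catabolic ceiling — growth pins the carbon balance
instead, surplus catabolism sets v_ATP, and the regression returns the
energetic ceiling rather than the truth. Recovery tests therefore use
energy-limited truth pairs; the default truth (GAM 75.79, NGAM 2.64, the
values carried by the toy model) is comfortably inside that regime.

## Chemostat growth benchmark

Per condition the measured rates are fixed (default equality; optional
band) and biomass is maximized; the score is
`100 × mean |μ_pred − D| / D` over feasible conditions, with infeasible
ones flagged and excluded. Relative error against D, averaged
arithmetically, yields a single percentage; the mean is order-invariant by
construction.

## Quasi-dynamic simulation

Each time point is an independent LP constrained by that point's measured
exchange rates (default band 5%; 0 for consistent synthetic data). The
observed specific antibiotic production rates are coupled into biomass:
the biomass reaction gains a drain of `rate/μ_ref` mmol·gDW⁻¹ per
antibiotic, with μ_ref the previous interval's predicted μ — so growing at
μ_ref reproduces the observed production exactly. The formulation divides
by μ and is singular at zero growth; below μ = 1e-6 h⁻¹ (and at the first
point, which has no predecessor) the antibiotic rates are imposed directly
as exchange constraints instead.

Biomass integrates exponentially with the interval-mean growth rate,
`X(t_{i+1}) = X(t_i)·exp(½(μ_i + μ_{i+1})Δt)`. The mean-μ rule is exact
for piecewise-linear μ(t), which is what linearly interpolated constraint
data produce, and it makes trajectories stable under grid refinement: a
left-endpoint rule would shift the predicted final biomass by roughly
`Δμ·Δt/4` across a growth-phase transition (≈9% under the default
synthetic conditions), an integration artifact rather than a model
property. The same integrator is shared by the synthetic generator, so
round-trip tests measure the solver, not the scheme. An infeasible point
contributes μ = 0 to its interval and is flagged.

The error metric is `100 × mean |X_pred − X_obs| / X_obs` over matched
points. No interpolation between measured times is performed by default:
the LP is solved only where data exist.

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuning knobs.

**Toy network** (`mini-coelicolor`, 21 reactions, 14 SCO-style genes with
genome positions spanning the chromosome): glucose, glutamate, phosphate,
O₂, CO₂ and two antibiotic exchanges; transport steps; lumped glycolysis
(2 ATP + 2 NADH per glucose), lumped pyruvate oxidation/TCA (1 ATP +
4 NADH + 3 CO₂ per pyruvate), an NADH dehydrogenase/oxidative-
phosphorylation step at P/O = 2 carrying two isoenzyme genes on an OR rule
(the nuo/ndh situation); ATP hydrolysis maintenance (lower bound NGAM =
2.64); a biomass reaction draining 8 pyruvate + 2 glutamate + 0.5
phosphate + GAM = 75.79 ATP per gDW; and two lumped secondary-metabolite
pathways standing in for γ-actinorhodin and undecylprodigiosin. Full
oxidation yields 24 ATP per glucose and the biomass precursor drain
forgoes 72 ATP per unit growth, so the optimum is analytically
`μ = (24·q_glc − NGAM)/(72 + GAM)` — the hand-derived oracle used in
tests. Transport reactions are elementally balanced and checked; lumped
cofactor reactions deliberately omit cofactor formulas and are exempt, as
are exchanges and biomass.

**Chemostat series**: for each dilution rate (default seven, 0.03–0.21
h⁻¹, a typical glucose-limited design), growth is fixed to D and glucose
uptake minimized; glucose, O₂, CO₂ and antibiotic exchange fluxes form the
record. **Fermenter series**: 20 points over 20–58 h; μ(t) holds 0.22 h⁻¹
through exponential phase, declines linearly over 30–34 h (the metabolic
switch; the kinks sit on the 2-h grid so interval-mean integration is
exact), and holds 0.04 h⁻¹ in stationary phase; antibiotic production
(0.05 / 0.03 mmol·gDW⁻¹·h⁻¹ for the two pathways) switches on at 38 h,
once μ is flat again — the drain coupling uses the previous interval's μ,
so this timing makes the noiseless round trip exact rather than merely
close. **Expression matrices**: per gene a positive affine transform of
its flux series, a seeded fraction of genes (among those with non-constant
flux) negated to form the anti-correlated cohort, Gaussian noise, then a
per-gene constant shift to positive values (correlation-preserving).
Measurement noise on rates is Gaussian, truncated to preserve the rate's
sign; an exactly-zero rate stays zero, since noise must not invent an
exchange the culture never had.

What the generators do *not* emulate: substrate depletion feedback (rates
are prescribed, not consumed), volumetric-to-specific rate conversion
noise, systematic assay bias, proteomics-style censoring beyond missing
values, or realistic genome annotation content. Passing round-trip tests
therefore demonstrates internal consistency of the methods, not predictive
accuracy on real fermentations.

## Expression–flux correlation

Per gene, the flux series is Σ|v| over its GPR-associated reactions —
absolute values because expression magnitude cannot encode direction (a
reversible reaction's sign flips would fabricate anti-correlation), sums
because a multi-reaction gene needs one number per time point. Pearson and
Spearman (average ranks on ties) come from `scipy.stats`; missing values
are dropped pairwise and `n_timepoints` reflects it; fewer than 3 complete
pairs or a constant series on either side makes the correlation undefined
and it is recorded as missing, never as zero. Classification: correlated
at ρ ≥ 0.3, anti-correlated at ρ ≤ −0.3, else uncorrelated. The variation
filter keeps genes with `(max − min)/min` strictly above the threshold
(default 0.25); a non-positive minimum makes the ratio undefined and the
gene is excluded and flagged. Summaries report medians over defined
values, 20-bin histograms on [−1, 1], and classification counts; records
order by genome position with unpositioned genes appended in id order and
flagged.

## I/O

SBML Level 3 Version 1 with fbc v2, via python-libsbml: `M_`/`R_`/`G_` id
prefixes, bounds as constant parameters, the objective as an fbc
objective, GPRs as gene-product associations, annotations as `bqbiol:is`
controlled-vocabulary URIs (`https://identifiers.org/<db>/<id>`, database
names preserved verbatim for losslessness), and fields with no SBML home
(genome position, protein length/mass/sequence, subsystem, the
ATP-maintenance designation) in notes as `key: value` lines. Files written
this way load in cobra unchanged. The tabular dialect is an XLSX workbook
or CSV directory with `reactions` / `metabolites` / `genes` / `model`
sheets; equations use `→` / `⇌` arrows (ASCII accepted), explicit bound
columns take precedence over the arrow, and annotation maps are JSON
cells. Experiment tables are TSV with `#` comment headers carrying units;
rate columns map to exchange ids through an alias map, and a direction map
can sign magnitude-only columns. Both model formats round-trip all typed
fields exactly (property-tested over randomized models).

## Problem sizes

Tests and the acceptance script run on the 21-reaction toy network with
seven chemostat conditions, 20 fermenter time points, 100-seed round-trip
sweeps and 200-replicate regression Monte-Carlo — sizes chosen so the
whole suite completes in well under a minute while every code path,
including the LP-oracle cross-checks against cobra, is exercised.

## Known limitations

- No flux variability analysis, sampling, MOMA/ROOM or knockout design;
  degenerate optima are handled by pFBA only.
- The maintenance fit assumes an energy-limited chemostat (see above) and
  a maintenance-stoichiometric biomass ATP term.
- The antibiotic-biomass coupling is a linear drain calibrated to the
  previous interval's growth rate; stationary-phase production is handled
  by direct exchange constraints, not by a kinetic model.
- Elemental balance checking requires formulas on all participants and
  skips exchanges/biomass; charge balance is not checked.
- SBML support targets Level 3 + fbc v2; legacy Level 2 dialects, .mat and
  JSON model formats are out of scope.
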