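# Methods

## Model

The method couples three layers.

**Constraint-based layer.** A stoichiometric model (S, bounds, biomass
objective) is solved per time step: first growth maximization (FBA), then
minimization of total flux at the fixed growth optimum (parsimonious FBA,
pFBA), which proxies minimal enzyme investment and is the flux
distribution the method reports and regulates on. Flux variability
analysis (FVA) optionally records, per reaction, the min/max flux over the
growth-optimal polytope; for FVA the parsimony step is omitted so the
intervals span the whole optimal space.

**Expression layer.** For each *balanced* reaction i, mRNA (RPKM) and
protein (mmol/gDCW) follow linear balance ODEs. Transcription has a
constitutive basal rate s_b,i and an activated rate s_a,i gated by a
binary demand signal; mRNA is lost to active degradation (γ_i, per
minute) and dilution (μ); protein is synthesized proportionally to mRNA
at s_P,i = τ/Λ_i and lost to dilution only — protein degradation is
negligible on the sub-hour time scale modeled. Λ_i is the *apparent
length* of the gene encoding the enzyme's largest subunit: the raw
coding length, plus one interribosomal spacing (72 bp) per copy when the
complex contains n > 1 copies of that subunit (n = 1 uses the raw
length; a flag enables the additive term for single copies too). The
inverse-length scaling encodes that ribosomes traverse the transcript at
finite speed, so bulky complexes respond slowly.

**Coupling.** Protein levels cap fluxes via b_i = k_cat,i·[P_i], and the
demand signal closes the loop: R_i = 1 iff |j_i| ≥ θ·b_i, with j_i the
parsimonious flux of the current step. The comparison is inclusive, so a
flux pinned at its bound always registers demand. For reversible balanced
reactions the bound caps both directions and demand reads |j|.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| θ | demand threshold | – | 0.6 | enzymes typically run above half-saturation; demand below ~60% of capacity does not warrant induction |
| τ | translation constant | bp·mmol·h⁻¹·RPKM⁻¹·gDCW⁻¹ | 0.6 | sets the RPKM→protein scale, not derivable from first principles because RPKM is a normalized unit |
| spacing | interribosomal distance | bp | 72 | ribosome footprint spacing on polysomes |
| Δt | SOA step | min | 0.5 | resolves the ~5–20 min expression transients |
| μ_anaerobic | basal-state dilution | h⁻¹ | model optimum (see below) | anaerobic batch growth; 0.26 h⁻¹ for the estimation module |
| k_cat | turnover numbers | s⁻¹ (numeric) | per-enzyme table | literature values |

**k_cat unit convention.** The turnover number is applied as a plain
numeric factor on protein in mmol/gDCW, giving bounds in mmol h⁻¹ gDCW⁻¹.
A literal s⁻¹→h⁻¹ conversion (×3600) would produce initial bounds of
order 10⁴ — far above any flux a cell carries — whereas the numeric
convention yields initial bounds (cyo ≈ 4.4, ndh ≈ 0.8, nuo ≈ 0.2) that
make the efficient branches limiting at the moment of aeration, which is
the regime of interest. The scaling is exposed as `kcat_unit_factor`.

**Mixed time units.** Transcription parameters are per minute (the unit
of the underlying RNA-seq sampling), growth and fluxes per hour. mRNA
updates run in minutes, protein and culture updates in hours; conversions
happen at the call boundaries and are covered by the integrator
cross-checks.

## Numerical scheme

Within one quasi-steady-state step, R and (for the protein update) mRNA
are held constant, making both ODE updates exact exponentials:
x' = x_ss + (x − x_ss)·e^(−k·Δt), with linear-growth branches when the
decay constant vanishes. Biomass integrates exponentially and external
concentrations use the closed-form ∫X dt over the step, floored at zero.
Fluxes at time t are solved under bounds from proteins at time t; the
demand evaluated on those fluxes drives expression over [t, t+Δt]
(solve → regulate → integrate). Infeasible steps (substrate exhaustion)
degrade to a dormant μ = 0 state instead of aborting.

The anaerobic initial condition is the R = 0 steady state of the
expression ODEs. By default the dilution rate used there is the model's
own anaerobic growth optimum, which makes the initial state an *exact*
fixed point of the anaerobic loop (state drift is zero to rounding);
a measured rate can be supplied instead, at the cost of a small initial
transient when it differs from the LP optimum.

**LP specifics.** LPs are solved through COBRApy/GLPK. Growth is pinned
to [μ*(1−10⁻⁶), μ*] to avoid numerical infeasibility. The pFBA default is
the L1 norm (linearized by the solver's irreversible flux split); an L2
(squared-flux) variant is provided as a dense SLSQP quadratic program,
warm-started from the L1 solution, and is intended for networks up to a
few hundred reactions. L1 optima can be degenerate; solver configuration
is pinned for reproducibility and, when FVA runs, balanced reactions
whose optimal-space interval is wider than 10⁻⁶ are logged.

**Demand-signal chattering.** The threshold regulation has no
hysteresis, so once a bound grows past j/θ the signal can toggle while
the bound hovers near the demand. Fluxes are unaffected (they stay
demand-limited), and the integrated culture state converges under step
refinement (< 1% on halving Δt), but pointwise mRNA trajectories of
chattering genes are switch-time quantized and should be read as
envelopes, not sample paths.

## Parameter estimation

The estimation model replaces the demand signal by a Heaviside activation
at a dead time T_d, giving a closed-form mRNA solution (continuous at
T_d, relaxing to (s_b+s_a)/(μ+γ)). s_b comes directly from inverting the
pre-shift steady state; γ and μ are fixed inputs (literature half-lives
and a measured growth rate). (s_a, T_d) minimize the (optionally
1/SD²-weighted) residual sum of squares. Because the model is linear in
s_a at fixed T_d, the search profiles T_d on a dense grid
(241 points over [0, t_max], ties toward smaller T_d) with the
conditionally optimal s_a in closed form — an effectively global search —
followed by one bounded local least-squares polish.

Confidence intervals for s_a use a residual bootstrap: residuals are
standardized by the fit weights (preserving heteroscedastic scale),
leverage-adjusted by 1/√(1−h_ii), resampled, and refitted; the 95%
interval is t_{n−2} × bootstrap SE centred on the estimate. Raw
percentile intervals of unadjusted residuals undercover substantially at
n ≈ 8 with two fitted parameters. A linearized (Jacobian) interval is
reported alongside. Flat series return s_a = 0 with a degeneracy flag
(T_d unidentifiable).

## Flux–expression correlation

Gene-level differential-expression calls are filtered on |fold change| ≥
1.25, mean logCPM ≥ 2 and FDR ≤ 0.05 (a stricter fold-change-2 profile is
available as a preset). Gene fold changes map to reactions through the
GPR: within an isoenzyme (AND-group) the subunit with the smallest
|logFC| caps the complex (sign preserved; a min-signed mode exists);
across isoenzymes (OR-groups) fold changes are averaged. Reactions
sharing an enzyme-set signature — the set of all genes in the GPR,
independent of tree shape — are lumped as Σ|v|, collapsing cofactor
variants of one enzyme; empty-GPR reactions are never lumped. A lumped
flux is called differential when |ΔΣ|v|| ≥ 0.25 mmol h⁻¹ gDCW⁻¹ *and*
the FVA intervals of the two conditions are disjoint (closed intervals;
touching endpoints overlap; an either-or mode is exposed). Association is
summarized by Spearman's ρ with an exact permutation p-value for n ≤ 10
(full enumeration, chunked) and the t-approximation otherwise, plus an
OLS line with pointwise 95% confidence band.

## Synthetic fixtures

The toy network (28 reactions) emulates the features the method probes,
not any organism quantitatively: lumped glycolysis (2 ATP + 2 NADH per
glucose), mixed-acid fermentation (formate/ethanol/acetate/lactate
outlets) so anaerobic growth is feasible, PDH and a TCA cycle with a
separate 2-oxoglutarate-dehydrogenase step, a glyoxylate-shunt bypass, a
malate:quinone oxidoreductase that skips NADH, and an electron transport
chain with paired efficient/less-efficient branches distinguished purely
by proton stoichiometry (4 vs 0 protons for the NADH dehydrogenases,
4 vs 2 for the oxidases, 4 protons per ATP). An oxaloacetate
decarboxylase provides the carbon exit from the TCA pool that net flux
through the glyoxylate shunt requires. The biomass reaction is a minimal
1 pyruvate + 114 ATP drain, chosen so the anaerobic growth optimum lands
at 0.26 h⁻¹ — anaerobic *E. coli* batch territory — with hand-checkable
yields (3 ATP/glucose fermentative ceiling → μ = 30/115). Default uptake
capacities are 10 (glucose) and 20 (O₂) mmol h⁻¹ gDCW⁻¹; the O₂:glucose
ratio of 2 ensures the aerobic optimum engages the TCA cycle rather than
being saturated by glycolytic NADH. By construction every designated MLE
reaction carries zero flux at the unconstrained aerobic parsimonious
optimum and strictly lowers the growth optimum when forced.

Expression fixtures are drawn from the Heaviside activation model with
multiplicative Gaussian noise (default σ = 5%, matching the
variance-grows-with-level character of RPKM data), floored at zero;
differential-expression tables plant an exact number of filter-passing
genes. All fixtures regenerate deterministically from (spec, seed).

What passing tests on these fixtures do *not* show: quantitative flux
values of a genome-scale network, realistic biomass composition, RNA-seq
count noise (the generator's noise is the fitted model plus Gaussian
perturbation, not negative-binomial counts), or dissolved-oxygen
dynamics (aeration is a step change of the O₂ bound).

## Problem sizes

Default simulations run 140 SOA steps (70 min at 0.5 min) on the
28-reaction network; the sensitivity sweeps use three θ values and a
doubled k_cat at the same horizon; integrator cross-checks use a
100-point random parameter grid; bootstrap-coverage assessment uses 100
repetitions of 200 bootstrap refits on 8 time points. These sizes were
chosen so the full behavior (pre-shift steady state, recruitment episode,
release, post-shift steady state) is visible while each check completes
in seconds.

## Known limitations

No post-transcriptional or allosteric regulation, no
polymerase/ribosome competition, no translation delay (translation rises
instantaneously with transcription, appropriate for co-transcriptional
bacterial translation). Only the configured balanced reactions carry
expression state — genome-wide expression is out of scope. L1-degenerate
parsimonious optima can make the realized demand depend on the solver's
vertex choice; this is pinned but not eliminated. The L2 parsimony mode
is toy-scale only. The demand rule evaluates R = 1 when j = b = 0; with
any positive basal transcription bounds stay positive and the case does
not arise.
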