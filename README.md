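# dddfba — demand-directed dynamic flux balance analysis

When a facultative anaerobe such as *E. coli* is suddenly aerated, the
enzymes of efficient aerobic metabolism (the proton-pumping NADH
dehydrogenase *nuo*, the high-pumping terminal oxidase *cyo*, the
oxidative TCA steps) are barely expressed and cannot immediately carry the
flux that growth maximization demands. Transcriptome time courses across
such shifts show the cell bridging the gap by transiently inducing
*metabolically less efficient* (MLE) enzymes — the non-pumping *ndh*, the
low-pumping oxidase *cyd*, the glyoxylate shunt — which conventional FBA
never uses.

`dddfba` implements a dynamic FBA variant that reproduces this behavior
mechanistically. For each *balanced* enzyme i it simulates mRNA and
protein by linear balance ODEs,

    d[mRNA_i]/dt = s_b,i + R_i(t)·s_a,i − (μ + γ_i)·[mRNA_i]
    d[P_i]/dt    = s_P,i·[mRNA_i] − μ·[P_i],        s_P,i = τ / Λ_i

switches the activated transcription rate on by a *flux-demand* signal

    R_i(t) = 1  iff  j_i(t) ≥ θ·b_i(t)

and caps the reaction's flux by the enzyme-capacity bound

    b_i(t) = k_cat,i·[P_i](t).

Each quasi-steady-state step of the batch simulation (1) maximizes growth,
(2) minimizes total flux (parsimonious FBA), (3) integrates biomass and
external metabolite concentrations analytically, and (4) recomputes uptake
and capacity bounds. Flux variability analysis (FVA) quantifies
alternative optima. Companion modules estimate transcription parameters
(s_b, s_a, dead time T_d) from RPKM time courses via the closed-form
solution of the Heaviside-activated mRNA balance, and correlate
enzyme-set-lumped flux differences with transcript fold changes
(Spearman rank + regression).

The package is aimed at systems biologists studying transitions between
metabolic regimes; it works with any SBML / BiGG-JSON model and ships a
self-contained synthetic toy network of facultative-anaerobe central
metabolism with paired efficient/MLE electron-transport branches.

## Worked example

```bash
dddfba toy --out toy.json --kinetics kinetics.tsv
dddfba simulate --model toy.json --kinetics kinetics.tsv --out run
```

or equivalently in Python:

```python
from dddfba import ScenarioConfig, simulate
from dddfba.synthetic_data import toy_model, default_kinetics
from dddfba.driver import episode_durations

traj = simulate(toy_model(), default_kinetics(),
                ScenarioConfig(horizon_min=70, t_aer_min=10))
print(episode_durations(traj, 0.5).to_string(index=False))
```

```
reaction  expression_episode_min  binding_min  initial_bound
   CYTBD                    11.0          9.5         10.424
   CYTBO                    21.5         12.5          4.408
   NADH5                    60.0         60.0          0.766
  NADH16                    60.0         60.0          0.198
   AKGDH                    56.0         56.0          0.032
     PDH                    56.0         56.0          0.121
```

Reading the output: the culture grows anaerobically for 10 min and is then
aerated. The efficient oxidase CYTBO starts with a small capacity bound
(4.4 mmol h⁻¹ gDCW⁻¹, from its low basal expression) and is pinned to that
bound for 12.5 min while its expression ramps up; during exactly that
window the MLE oxidase CYTBD — highly expressed anaerobically, hence a
large initial bound of 10.4 — carries the residual respiratory flux. Once
the CYTBO bound exceeds the oxygen-limited demand, the CYTBD flux drops to
zero and its demand signal (and mRNA) decays back toward the basal level:
transient recruitment of a less efficient enzyme, emerging purely from
growth maximization plus expression-capacity constraints. NADH16 (the
pumping dehydrogenase) stays capacity-limited for the whole hour, so the
non-pumping NADH5 remains in use — an overall efficiency loss. Growth
steps from 0.26 h⁻¹ (fermentative) to 0.64 h⁻¹ aerobically.

Parameter sensitivity (`dddfba sweep`): the regulatory threshold θ leaves
fluxes unchanged (< 10⁻¹⁴ relative) and only shortens expression episodes
as θ grows; initial bounds scale exactly linearly with the translation
constant τ; doubling an enzyme's k_cat shortens its bound-binding episode
(12.5 → 7.5 min for CYTBO).

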