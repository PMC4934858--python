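"""Self-contained synthetic fixtures: toy metabolic network and expression data.

The toy network is a deliberately small (28-reaction) caricature of
facultative-anaerobe central carbon metabolism built around the features
the dynamic method probes:

* lumped glycolysis feeding pyruvate, ATP and NADH;
* fermentative outlets (pyruvate-formate lyase, alcohol dehydrogenase,
  acetate kinase, lactate dehydrogenase) so anaerobic growth is feasible;
* pyruvate dehydrogenase and a TCA cycle with a separate 2-oxoglutarate
  dehydrogenase step, plus a glyoxylate-shunt bypass that skips the
  NADH/ATP-yielding steps (metabolically less efficient, MLE);
* an electron transport chain with *paired* branches: a proton-pumping
  NADH dehydrogenase vs a non-pumping one, and a high-pumping terminal
  oxidase vs a low-pumping one — the efficient member of each pair
  strictly dominates when capacity is unlimited;
* a malate:quinone oxidoreductase that bypasses NADH formation (MLE
  alternative NADH-reoxidation route);
* ATP synthase converting translocated protons to ATP, and a biomass
  reaction consuming pyruvate and ATP.

Proton-translocation stoichiometries and the biomass composition are
small integers chosen so that yields are hand-checkable; with the default
coefficients the anaerobic growth optimum is ~0.26 h^-1, in the range of
anaerobic E. coli batch growth.

Expression-side generators produce RPKM time courses from the
Heaviside-activated mRNA balance (the same closed form the estimator
fits) with multiplicative Gaussian noise, and differential-expression
tables with planted pass/fail labels.  Everything regenerates
deterministically from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .expression_dynamics import EnzymeKinetics
from .param_estimation import mrna_solution

#: Balanced reactions of the default scenario with their Table-style
#: kinetic parameters: (reaction, gene, length bp, copies, s_b, s_a,
#: gamma, kcat).  s_b/s_a in RPKM/min, gamma in 1/min, kcat numeric.
_DEFAULT_KINETICS = [
    ("CYTBD",  "cydA", 1569, 1,  116.3, 759.1,  0.187, 11.7),
    ("CYTBO",  "cyoB", 1992, 1,  2.4,   610.9,  0.210, 341.0),
    ("NADH5",  "ndh",  1305, 1,  5.9,   504.6,  0.210, 15.8),
    ("NADH16", "nuoG", 2727, 1,  25.1,  30.0,   10.68, 100.0),
    ("AKGDH",  "sucA", 2802, 12, 12.1,  143.1,  11.76, 49.0),
    ("PDH",    "aceE", 2664, 1,  48.1,  2334.0, 7.5,   21.9),
]


@dataclass
class ToySpec:
    """Parameters of the toy network.

    The efficiency ordering invariants (efficient branch translocates
    strictly more protons than its MLE partner) are validated on build.
    """

    atp_per_glycolysis: float = 2.0
    nadh_per_glycolysis: float = 2.0
    protons_efficient_nadh: float = 4.0   # NADH16 (nuo analog)
    protons_mle_nadh: float = 0.0         # NADH5 (ndh analog)
    protons_efficient_oxidase: float = 4.0  # CYTBO (cyo analog)
    protons_mle_oxidase: float = 2.0        # CYTBD (cyd analog)
    protons_per_atp: float = 4.0
    biomass_pyr: float = 1.0
    biomass_atp: float = 114.0
    glc_uptake: float = 10.0   # mmol h^-1 gDCW^-1
    o2_uptake: float = 20.0    # mmol h^-1 gDCW^-1 when aerated
    aerobic: bool = False      # default exported model is anaerobic
    seed: int = 0

    #: reactions whose enzyme expression is balanced in the dynamic loop
    balanced_reactions: tuple[str, ...] = (
        "CYTBD", "CYTBO", "NADH5", "NADH16", "AKGDH", "PDH")
    #: reactions that are metabolically less efficient by construction
    mle_reactions: tuple[str, ...] = ("CYTBD", "NADH5", "GLYX", "MDH2")

    def validate(self) -> None:
        if not self.protons_efficient_nadh > self.protons_mle_nadh:
            raise ValueError("efficient NADH dehydrogenase must pump more "
                             "protons than the MLE branch")
        if not self.protons_efficient_oxidase > self.protons_mle_oxidase:
            raise ValueError("efficient oxidase must pump more protons than "
                             "the MLE branch")
        if min(self.protons_per_atp, self.biomass_atp, self.biomass_pyr,
               self.glc_uptake, self.o2_uptake) <= 0:
            raise ValueError("stoichiometric parameters must be positive")


def toy_model(spec: ToySpec | None = None) -> cobra.Model:
    """Build the toy network as a :class:`cobra.Model`.

    The model ships anaerobic (O2 exchange closed) unless
    ``spec.aerobic``; the biomass reaction is the objective.  GPRs assign
    distinct gene sets per enzyme, including multi-subunit complexes and
    one isoenzyme pair, so enzyme-set lumping is exercised.
    """
    spec = spec or ToySpec()
    spec.validate()
    m = cobra.Model("toy_facultative")

    def met(mid, compartment):
        return cobra.Metabolite(mid, compartment=compartment)

    mets = {mid: met(mid, "e" if mid.endswith("_e") else "c") for mid in [
        "glc_e", "o2_e", "co2_e", "lac_e", "for_e", "etoh_e", "ac_e",
        "pyr_c", "accoa_c", "icit_c", "akg_c", "succoa_c", "succ_c",
        "mal_c", "oaa_c", "nadh_c", "atp_c", "q8_c", "q8h2_c", "hext_c",
    ]}

    s = spec

    def rxn(rid, stoich, lb, ub, gpr=""):
        r = cobra.Reaction(rid)
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        r.bounds = (lb, ub)
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    reactions = [
        # exchanges (negative flux = uptake)
        rxn("EX_glc_e", {"glc_e": -1}, -s.glc_uptake, 1000),
        rxn("EX_o2_e", {"o2_e": -1}, -s.o2_uptake if s.aerobic else 0.0, 1000),
        rxn("EX_co2_e", {"co2_e": -1}, 0, 1000),
        rxn("EX_lac_e", {"lac_e": -1}, 0, 1000),
        rxn("EX_for_e", {"for_e": -1}, 0, 1000),
        rxn("EX_etoh_e", {"etoh_e": -1}, 0, 1000),
        rxn("EX_ac_e", {"ac_e": -1}, 0, 1000),
        # glycolysis, lumped (no single enzyme => empty GPR)
        rxn("GLYC", {"glc_e": -1, "pyr_c": 2,
                     "atp_c": s.atp_per_glycolysis,
                     "nadh_c": s.nadh_per_glycolysis}, 0, 1000),
        # fermentative outlets
        rxn("PFL", {"pyr_c": -1, "accoa_c": 1, "for_e": 1}, 0, 1000, "pflB"),
        rxn("ALCD", {"accoa_c": -1, "nadh_c": -2, "etoh_e": 1}, 0, 1000, "adhE"),
        rxn("ACK", {"accoa_c": -1, "ac_e": 1, "atp_c": 1}, 0, 1000,
            "ackA or tdcD"),
        rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_e": 1}, 0, 1000, "ldhA"),
        # oxidative decarboxylation and TCA cycle
        rxn("PDH", {"pyr_c": -1, "accoa_c": 1, "nadh_c": 1, "co2_e": 1},
            0, 1000, "aceE and aceF and lpdA"),
        rxn("TCA1", {"accoa_c": -1, "oaa_c": -1, "icit_c": 1}, 0, 1000,
            "gltA and acnB"),
        rxn("ICDH", {"icit_c": -1, "akg_c": 1, "nadh_c": 1, "co2_e": 1},
            0, 1000, "icd"),
        rxn("AKGDH", {"akg_c": -1, "succoa_c": 1, "nadh_c": 1, "co2_e": 1},
            0, 1000, "sucA and sucB and lpdA"),
        rxn("SUCOAS", {"succoa_c": -1, "succ_c": 1, "atp_c": 1}, 0, 1000,
            "sucC and sucD"),
        # succinate dehydrogenase + fumarase, lumped
        rxn("SUCD", {"succ_c": -1, "q8_c": -1, "mal_c": 1, "q8h2_c": 1},
            0, 1000, "sdhA and sdhB"),
        rxn("MDH", {"mal_c": -1, "oaa_c": 1, "nadh_c": 1}, -1000, 1000, "mdh"),
        # malate:quinone oxidoreductase -- skips NADH, MLE
        rxn("MDH2", {"mal_c": -1, "q8_c": -1, "oaa_c": 1, "q8h2_c": 1},
            0, 1000, "mqo"),
        # oxaloacetate decarboxylase: carbon exit from the TCA pool
        rxn("OAADC", {"oaa_c": -1, "pyr_c": 1, "co2_e": 1}, 0, 1000, "eda"),
        # glyoxylate shunt (isocitrate lyase + malate synthase, lumped):
        # bypasses both decarboxylation steps and their NADH/ATP yield
        rxn("GLYX", {"icit_c": -1, "accoa_c": -1, "succ_c": 1, "mal_c": 1},
            0, 1000, "aceA and aceB"),
        # electron transport chain
        rxn("NADH16", {"nadh_c": -1, "q8_c": -1, "q8h2_c": 1,
                       "hext_c": s.protons_efficient_nadh}, 0, 1000,
            "nuoA and nuoB and nuoG and nuoN"),
        rxn("NADH5", {"nadh_c": -1, "q8_c": -1, "q8h2_c": 1,
                      "hext_c": s.protons_mle_nadh}, 0, 1000, "ndh"),
        rxn("CYTBO", {"q8h2_c": -1, "o2_e": -0.5, "q8_c": 1,
                      "hext_c": s.protons_efficient_oxidase}, 0, 1000,
            "cyoA and cyoB and cyoC and cyoD"),
        rxn("CYTBD", {"q8h2_c": -1, "o2_e": -0.5, "q8_c": 1,
                      "hext_c": s.protons_mle_oxidase}, 0, 1000,
            "cydA and cydB"),
        rxn("ATPS", {"hext_c": -s.protons_per_atp, "atp_c": 1}, 0, 1000,
            "atpA and atpB"),
        # biomass (objective): precursor + energy -> cells
        rxn("BIOMASS", {"pyr_c": -s.biomass_pyr, "atp_c": -s.biomass_atp},
            0, 1000),
    ]
    m.add_reactions(reactions)
    m.objective = "BIOMASS"
    return m


def default_kinetics() -> list[EnzymeKinetics]:
    """Kinetic parameters of the six balanced reactions.

    Values follow the published parameterization of the E. coli
    aerobic-shift enzymes (terminal oxidases cyd/cyo, NADH dehydrogenases
    ndh/nuo, 2-oxoglutarate and pyruvate dehydrogenase): transcription
    rates estimated from shift RNA-seq, degradation rates and turnover
    numbers from the literature.  The 2-oxoglutarate dehydrogenase complex
    carries 12 copies of its largest subunit, activating the
    apparent-gene-length correction.
    """
    return [EnzymeKinetics(reaction=r, gene=g, gene_length_bp=L, copies=c,
                           s_b=sb, s_a=sa, gamma=gam, kcat=kc)
            for r, g, L, c, sb, sa, gam, kc in _DEFAULT_KINETICS]


def parallel_route_model() -> cobra.Model:
    """Tiny LP fixture: one-step vs two-step parallel routes plus an
    identical reaction pair.

    A -> B either directly (SHORT) or via M (LONG1 + LONG2); B -> C through
    two stoichiometrically identical reactions DUP1/DUP2.  The objective
    drains C.  Used to probe parsimonious-FBA norm behavior and flux
    variability of interchangeable reactions.
    """
    m = cobra.Model("parallel_routes")
    a = cobra.Metabolite("a_c", compartment="c")
    b = cobra.Metabolite("b_c", compartment="c")
    mm = cobra.Metabolite("m_c", compartment="c")
    c = cobra.Metabolite("c_c", compartment="c")

    def rxn(rid, stoich, lb=0, ub=1000, gpr=""):
        r = cobra.Reaction(rid)
        r.add_metabolites(stoich)
        r.bounds = (lb, ub)
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    m.add_reactions([
        rxn("EX_a", {a: -1}, -10, 1000),
        rxn("SHORT", {a: -1, b: 1}, gpr="gS"),
        rxn("LONG1", {a: -1, mm: 1}, gpr="gL1"),
        rxn("LONG2", {mm: -1, b: 1}, gpr="gL2"),
        rxn("DUP1", {b: -1, c: 1}, gpr="gD1"),
        rxn("DUP2", {b: -1, c: 1}, gpr="gD2"),
        rxn("SINK_c", {c: -1}),
    ])
    m.objective = "SINK_c"
    return m


# ---------------------------------------------------------------------------
# Expression-side generators


@dataclass
class SyntheticSeriesSpec:
    """Ground-truth specification of synthetic RPKM time courses.

    ``genes`` maps gene id -> (s_b, s_a, t_d, gamma) in per-minute units;
    noise is multiplicative Gaussian with fraction ``sigma`` (RPKM variance
    grows with expression level), and negative draws are floored at zero.
    """

    genes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"cydA": (116.3, 759.1, 2.0, 0.187)})
    times_min: tuple[float, ...] = (-10.0, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0, 30.0)
    sigma: float = 0.05
    replicates: int = 1
    mu_per_min: float = 0.26 / 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if min(self.times_min) >= 0 or max(self.times_min) <= 0:
            raise ValueError("time grid must span pre- and post-shift samples")


def synth_expression(spec: SyntheticSeriesSpec | None = None) -> pd.DataFrame:
    """Generate RPKM time courses from the activation model plus noise.

    Returns a tidy frame (gene, time_min, replicate, rpkm, true_rpkm);
    ground-truth parameters stay available in ``spec.genes``.  With
    ``sigma = 0`` the output equals the closed-form solution exactly.
    """
    spec = spec or SyntheticSeriesSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times_min, dtype=float)
    rows = []
    for gene, (s_b, s_a, t_d, gamma) in spec.genes.items():
        truth = mrna_solution(times, s_b, s_a, t_d, gamma, spec.mu_per_min)
        for rep in range(spec.replicates):
            noisy = truth * (1.0 + rng.normal(0.0, spec.sigma, size=len(times)))
            noisy = np.clip(noisy, 0.0, None)
            for t, y, y0 in zip(times, noisy, truth):
                rows.append({"gene": gene, "time_min": t, "replicate": rep,
                             "rpkm": y, "true_rpkm": y0})
    return pd.DataFrame(rows)


def synth_de_table(n_genes: int = 20, n_pass: int = 5, seed: int = 0,
                   min_fc: float = 1.25, min_logcpm: float = 2.0,
                   max_fdr: float = 0.05) -> pd.DataFrame:
    """Differential-expression table with planted pass/fail labels.

    Exactly ``n_pass`` genes satisfy all three filter thresholds; the rest
    each violate at least one (cycling through low fold change, low
    abundance, and high FDR).  Columns: gene, logFC, logCPM, FDR,
    planted_pass.
    """
    if n_genes < 1 or not 0 <= n_pass <= n_genes:
        raise ValueError("need 1 <= n_genes and 0 <= n_pass <= n_genes")
    rng = np.random.default_rng(seed)
    min_abs_logfc = np.log2(min_fc)
    rows = []
    for i in range(n_genes):
        gene = f"g{i:03d}"
        if i < n_pass:
            logfc = rng.choice([-1, 1]) * rng.uniform(min_abs_logfc + 0.1, 3.0)
            logcpm = rng.uniform(min_logcpm + 0.5, 10.0)
            fdr = rng.uniform(0.0, max_fdr * 0.8)
            planted = True
        else:
            fail_mode = (i - n_pass) % 3
            logfc = (rng.uniform(-min_abs_logfc * 0.8, min_abs_logfc * 0.8)
                     if fail_mode == 0
                     else rng.choice([-1, 1]) * rng.uniform(min_abs_logfc + 0.1, 3.0))
            logcpm = (rng.uniform(-2.0, min_logcpm - 0.5) if fail_mode == 1
                      else rng.uniform(min_logcpm + 0.5, 10.0))
            fdr = (rng.uniform(max_fdr + 0.05, 1.0) if fail_mode == 2
                   else rng.uniform(0.0, max_fdr * 0.8))
            planted = False
        rows.append({"gene": gene, "logFC": float(logfc),
                     "logCPM": float(logcpm), "FDR": float(fdr),
                     "planted_pass": planted})
    return pd.DataFrame(rows)
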