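"""Demand-directed dynamic FBA: the quasi-steady-state simulation loop.

The simulation horizon is divided into short steps assumed to be in
quasi-steady state (static optimization approach).  Each step performs
four stages:

1. maximize the growth rate (FBA) under the current uptake and
   enzyme-capacity bounds;
2. minimize total flux at that growth optimum (parsimonious FBA) — the
   parsimonious fluxes are the reported flux distribution and the ones the
   demand signal reads;
3. integrate biomass and external metabolite concentrations over the step;
4. recompute bounds: substrate-uptake bounds from the new concentrations,
   and enzyme-capacity bounds b_i = kcat_i * [P_i] from the mRNA/protein
   balances advanced one (exact) step, with transcription switched by the
   demand signal R_i = [ |j_i| >= theta * b_i ].

Within a step, fluxes at time t are solved under bounds derived from
proteins at time t; the demand evaluated on those fluxes drives expression
over [t, t+dt].  An infeasible LP (e.g. after substrate exhaustion) yields
a dormant zero-growth step rather than an exception, so batch-end behavior
remains simulatable.

Aeration is modeled as a step change of the O2 exchange bound at a
configurable time; dissolved-oxygen dynamics are not modeled.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import cobra
import pandas as pd

from .expression_dynamics import (
    EnzymeKinetics, RegulatoryConfig, flux_bound, mrna_step, protein_step,
    regulatory_signal, steady_state_expression,
)
from .fba_core import FVAInterval, FluxSolution, fba, fva, pfba

logger = logging.getLogger(__name__)

#: Tolerance used to decide whether a flux sits on its capacity bound.
BINDING_TOL = 1e-6


class SetupError(RuntimeError):
    """The scenario cannot be initialized (e.g. anaerobically infeasible)."""


@dataclass
class CultureState:
    """Batch-culture state: biomass, external concentrations, time."""

    biomass: float                       # gDCW / L
    concentrations: dict[str, float]     # exchange-reaction id -> mmol / L
    time_min: float = 0.0

    def copy(self) -> "CultureState":
        return CultureState(self.biomass, dict(self.concentrations),
                            self.time_min)


@dataclass
class ExpressionState:
    """Per-balanced-reaction expression state."""

    mrna: dict[str, float]       # RPKM
    protein: dict[str, float]    # mmol / gDCW
    signal: dict[str, int]       # demand signal R in {0, 1}

    def copy(self) -> "ExpressionState":
        return ExpressionState(dict(self.mrna), dict(self.protein),
                               dict(self.signal))


@dataclass
class ScenarioConfig:
    """Configuration of one batch-shift scenario."""

    t_aer_min: float = 10.0          #: onset of aeration (min from start)
    horizon_min: float = 70.0
    glc_vmax: float = 10.0           #: maximal glucose uptake (mmol/h/gDCW)
    o2_vmax: float = 20.0            #: maximal O2 uptake once aerated
    uptake_kinetics: str = "fixed"   #: "fixed" or "michaelis-menten"
    km_mM: float = 0.5               #: K_M of the uptake system (MM mode)
    glucose_exchange: str = "EX_glc_e"
    oxygen_exchange: str = "EX_o2_e"
    biomass_init: float = 0.01       #: gDCW / L
    initial_concentrations: dict[str, float] = field(
        default_factory=lambda: {"EX_glc_e": 50.0})
    parsimony_norm: str = "l1"
    run_fva: bool = False
    fva_reactions: tuple[str, ...] | None = None   #: None = balanced set
    regulatory: RegulatoryConfig = field(default_factory=RegulatoryConfig)
    #: dilution rate for the initial anaerobic steady state; None derives it
    #: from the model's own anaerobic growth optimum (exact fixed point)
    mu_anaerobic_init: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_min <= 0:
            raise ValueError("horizon must be positive")
        if min(self.glc_vmax, self.o2_vmax) < 0:
            raise ValueError("uptake maxima must be non-negative")
        if self.uptake_kinetics not in {"fixed", "michaelis-menten"}:
            raise ValueError(f"unknown uptake kinetics {self.uptake_kinetics!r}")
        if self.uptake_kinetics == "michaelis-menten" and self.km_mM < 0:
            raise ValueError("K_M must be non-negative")


@dataclass
class Trajectory:
    """Time-indexed record of a simulation run."""

    times_min: list[float] = field(default_factory=list)
    fluxes: list[pd.Series] = field(default_factory=list)
    growth: list[float] = field(default_factory=list)
    bounds: list[dict[str, float]] = field(default_factory=list)
    mrna: list[dict[str, float]] = field(default_factory=list)
    protein: list[dict[str, float]] = field(default_factory=list)
    signal: list[dict[str, int]] = field(default_factory=list)
    biomass: list[float] = field(default_factory=list)
    concentrations: list[dict[str, float]] = field(default_factory=list)
    fva_intervals: list[list[FVAInterval]] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)

    def flux_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fluxes)
        df.index = pd.Index(self.times_min, name="time_min")
        return df

    def expression_frame(self) -> pd.DataFrame:
        rows = []
        for t, m, p, r, b in zip(self.times_min, self.mrna, self.protein,
                                 self.signal, self.bounds):
            for rid in m:
                rows.append({"time_min": t, "reaction": rid, "mrna_rpkm": m[rid],
                             "protein_mmol_gdcw": p[rid], "signal": r[rid],
                             "bound": b[rid]})
        return pd.DataFrame(rows)

    def culture_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations)
        df.insert(0, "biomass_gdcw_l", self.biomass)
        df.insert(1, "growth_rate_h", self.growth)
        df.index = pd.Index(self.times_min, name="time_min")
        return df

    def fva_frame(self) -> pd.DataFrame:
        rows = []
        for t, ivs in zip(self.times_min, self.fva_intervals):
            for iv in ivs:
                rows.append({"time_min": t, "reaction": iv.reaction,
                             "min": iv.minimum, "max": iv.maximum})
        return pd.DataFrame(rows)

    def write_tsvs(self, prefix: str) -> None:
        self.flux_frame().to_csv(f"{prefix}_fluxes.tsv", sep="\t")
        self.expression_frame().to_csv(f"{prefix}_expression.tsv", sep="\t",
                                       index=False)
        self.culture_frame().to_csv(f"{prefix}_culture.tsv", sep="\t")
        if self.fva_intervals:
            self.fva_frame().to_csv(f"{prefix}_fva.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stage helpers


def uptake_bound(concentration: float, vmax: float, kinetics: str = "fixed",
                 km: float = 0.5) -> float:
    """Uptake capacity (mmol/h/gDCW) as a function of external concentration.

    ``"fixed"``: vmax while substrate remains, zero once depleted.
    ``"michaelis-menten"``: vmax * C / (K_M + C).
    """
    if concentration < 0 or vmax < 0:
        raise ValueError("concentration and vmax must be non-negative")
    if kinetics == "fixed":
        return vmax if concentration > 0 else 0.0
    if kinetics == "michaelis-menten":
        if km < 0:
            raise ValueError("K_M must be non-negative")
        if concentration == 0:
            return 0.0
        return vmax * concentration / (km + concentration)
    raise ValueError(f"unknown uptake kinetics {kinetics!r}")


def update_culture(culture: CultureState, solution: FluxSolution,
                   dt_h: float) -> CultureState:
    """Integrate biomass and external concentrations over one step.

    Biomass grows exponentially at the step's growth rate mu; each tracked
    exchange metabolite with specific flux v changes by the analytically
    integrated amount v * X * (exp(mu dt) - 1)/mu (linear in dt when
    mu = 0).  Concentrations are floored at zero.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    mu = solution.growth_rate if solution.ok else 0.0
    X = culture.biomass
    if mu == 0.0:
        X_new = X
        weight = X * dt_h
    else:
        X_new = X * math.exp(mu * dt_h)
        weight = X * (math.exp(mu * dt_h) - 1.0) / mu
    conc = {}
    for rid, c in culture.concentrations.items():
        v = float(solution.fluxes.get(rid, 0.0)) if solution.ok else 0.0
        conc[rid] = max(0.0, c + v * weight)
    return CultureState(biomass=X_new, concentrations=conc,
                        time_min=culture.time_min + dt_h * 60.0)


def _apply_bounds(model: cobra.Model, config: ScenarioConfig,
                  culture: CultureState, bounds: dict[str, float],
                  aerated: bool) -> None:
    """Stage-4 bounds: uptake from concentrations, capacity from proteins."""
    glc = model.reactions.get_by_id(config.glucose_exchange)
    c_glc = culture.concentrations.get(config.glucose_exchange, math.inf)
    if math.isinf(c_glc):
        glc.lower_bound = -config.glc_vmax
    else:
        glc.lower_bound = -uptake_bound(c_glc, config.glc_vmax,
                                        config.uptake_kinetics, config.km_mM)
    o2 = model.reactions.get_by_id(config.oxygen_exchange)
    o2.lower_bound = -config.o2_vmax if aerated else 0.0
    for rid, b in bounds.items():
        rxn = model.reactions.get_by_id(rid)
        rxn.upper_bound = b
        if rxn.lower_bound < 0:  # reversible: capacity caps both directions
            rxn.lower_bound = -b


def initialize(model: cobra.Model, kinetics: list[EnzymeKinetics],
               config: ScenarioConfig,
               ) -> tuple[ExpressionState, CultureState, dict[str, float]]:
    """Anaerobic steady-state initial condition.

    All balanced enzymes start at the basal (R = 0) steady state of the
    expression ODEs at the anaerobic growth rate; capacity bounds follow
    from the steady-state proteins; the culture starts at the configured
    inoculum.  By default the dilution rate is the model's own anaerobic
    growth optimum, which makes the initial state an exact fixed point of
    the anaerobic loop; a measured rate can be supplied instead via
    ``config.mu_anaerobic_init``.
    """
    mu0 = config.mu_anaerobic_init
    with model as m:
        m.reactions.get_by_id(config.oxygen_exchange).lower_bound = 0.0
        m.reactions.get_by_id(config.glucose_exchange).lower_bound = -config.glc_vmax
        sol = fba(m)
        if not sol.ok or sol.growth_rate <= 0:
            raise SetupError(
                f"model infeasible or non-growing anaerobically ({sol.status})")
        if mu0 is None:
            mu0 = sol.growth_rate
    reg = config.regulatory
    mrna, protein, signal, bounds = {}, {}, {}, {}
    for kin in kinetics:
        m_ss, p_ss = steady_state_expression(kin, mu0, R=0, tau=reg.tau)
        mrna[kin.reaction] = m_ss
        protein[kin.reaction] = p_ss
        signal[kin.reaction] = 0
        bounds[kin.reaction] = flux_bound(kin.kcat, p_ss, reg.kcat_unit_factor)
    culture = CultureState(biomass=config.biomass_init,
                           concentrations=dict(config.initial_concentrations),
                           time_min=0.0)
    return ExpressionState(mrna, protein, signal), culture, bounds


def step(model: cobra.Model, expr: ExpressionState, culture: CultureState,
         kinetics: list[EnzymeKinetics], config: ScenarioConfig,
         dt_min: float, bounds: dict[str, float] | None = None,
         ) -> tuple[FluxSolution, ExpressionState, CultureState, dict[str, float]]:
    """One four-stage step of the demand-directed loop.

    Returns the parsimonious flux solution solved under the *incoming*
    bounds, plus the advanced expression state, culture state and the new
    capacity bounds.  An infeasible LP produces a dormant (mu = 0,
    zero-flux) solution.
    """
    if dt_min <= 0:
        raise ValueError("dt must be positive")
    reg = config.regulatory
    if bounds is None:
        bounds = {k.reaction: flux_bound(k.kcat, expr.protein[k.reaction],
                                         reg.kcat_unit_factor)
                  for k in kinetics}
    aerated = culture.time_min >= config.t_aer_min
    with model as m:
        _apply_bounds(m, config, culture, bounds, aerated)
        base = fba(m)
        if base.ok and base.growth_rate > 0:
            solution = pfba(m, base.growth_rate, norm=config.parsimony_norm)
            if not solution.ok:
                solution = base
        else:
            solution = FluxSolution(
                fluxes=pd.Series(0.0, index=[r.id for r in model.reactions]),
                growth_rate=0.0, objective_value=0.0, status="optimal")
            logger.info("dormant step at t=%.2f min (LP %s)",
                        culture.time_min, base.status)

    mu_h = solution.growth_rate
    new_expr = expr.copy()
    new_bounds = {}
    for kin in kinetics:
        rid = kin.reaction
        j = abs(float(solution.fluxes.get(rid, 0.0)))
        R = regulatory_signal(j, bounds[rid], reg.theta)
        m_new = mrna_step(expr.mrna[rid], R, kin, mu_h / 60.0, dt_min)
        p_new = protein_step(expr.protein[rid], expr.mrna[rid], kin, mu_h,
                             dt_min / 60.0, reg.tau)
        new_expr.signal[rid] = R
        new_expr.mrna[rid] = m_new
        new_expr.protein[rid] = p_new
        new_bounds[rid] = flux_bound(kin.kcat, p_new, reg.kcat_unit_factor)
    new_culture = update_culture(culture, solution, dt_min / 60.0)
    return solution, new_expr, new_culture, new_bounds


def simulate(model: cobra.Model, kinetics: list[EnzymeKinetics],
             config: ScenarioConfig) -> Trajectory:
    """Run the full scenario and record a :class:`Trajectory`.

    Each record at time t holds the fluxes solved under the bounds valid at
    t, those bounds, the expression state at t and the culture state at t.
    With ``config.run_fva`` the growth-optimal flux ranges of the balanced
    (or configured) reactions are recorded per step, with the parsimony
    stage omitted.
    """
    expr, culture, bounds = initialize(model, kinetics, config)
    fva_rxns = (list(config.fva_reactions) if config.fva_reactions is not None
                else [k.reaction for k in kinetics])
    traj = Trajectory()
    dt = config.regulatory.dt_min
    n_steps = int(round(config.horizon_min / dt))
    for _ in range(n_steps):
        t = culture.time_min
        solution, new_expr, new_culture, new_bounds = step(
            model, expr, culture, kinetics, config, dt, bounds)
        traj.times_min.append(t)
        traj.fluxes.append(solution.fluxes)
        traj.growth.append(solution.growth_rate)
        traj.bounds.append(dict(bounds))
        traj.mrna.append(dict(expr.mrna))
        traj.protein.append(dict(expr.protein))
        traj.signal.append(dict(new_expr.signal))  # R evaluated on these fluxes
        traj.biomass.append(culture.biomass)
        traj.concentrations.append(dict(culture.concentrations))
        if solution.growth_rate == 0.0 and not solution.fluxes.abs().sum():
            traj.events.append((t, "dormant"))
        if config.run_fva and solution.growth_rate > 0:
            aerated = t >= config.t_aer_min
            with model as m:
                _apply_bounds(m, config, culture, bounds, aerated)
                ivs = fva(m, solution.growth_rate, fva_rxns)
            traj.fva_intervals.append(ivs)
            for iv in ivs:
                if iv.reaction in bounds and iv.maximum - iv.minimum > 1e-6:
                    logger.debug("degenerate flux for %s at t=%.1f: FVA width %.3g",
                                 iv.reaction, t, iv.maximum - iv.minimum)
        expr, culture, bounds = new_expr, new_culture, new_bounds
    return traj


# ---------------------------------------------------------------------------
# Parameter-sweep harness


def episode_durations(traj: Trajectory, dt_min: float,
                      ) -> pd.DataFrame:
    """Per-reaction expression-episode and bound-binding durations (min).

    The expression episode is the total time the demand signal is on; the
    binding duration is the total time the parsimonious flux sits on the
    capacity bound (within :data:`BINDING_TOL` relative to max(1, b)).
    """
    rows = []
    if not traj.times_min:
        return pd.DataFrame(columns=["reaction", "expression_episode_min",
                                     "binding_min", "initial_bound"])
    for rid in traj.bounds[0]:
        expressed = sum(s[rid] for s in traj.signal) * dt_min
        binding = sum(
            1 for f, b in zip(traj.fluxes, traj.bounds)
            if b[rid] - abs(float(f.get(rid, 0.0))) <= BINDING_TOL * max(1.0, b[rid])
        ) * dt_min
        rows.append({"reaction": rid, "expression_episode_min": expressed,
                     "binding_min": binding, "initial_bound": traj.bounds[0][rid]})
    return pd.DataFrame(rows)


def parameter_sweep(model: cobra.Model, kinetics: list[EnzymeKinetics],
                    base_config: ScenarioConfig,
                    grid: dict) -> tuple[pd.DataFrame, dict]:
    """Run the scenario over a parameter grid.

    ``grid`` may contain ``"tau"`` and ``"theta"`` axes (lists of values)
    and a ``"kcat"`` axis: a dict mapping reaction id -> list of turnover
    numbers.  The cartesian product of all axes is simulated with otherwise
    identical configuration; the summary table lists, per grid point and
    balanced reaction, the initial bound, the expression-episode duration
    and the bound-binding duration.

    Returns ``(summary, trajectories)`` where ``trajectories`` maps the
    grid-point key (tau, theta, ((reaction, kcat), ...)) to its trajectory.
    """
    taus = grid.get("tau", [base_config.regulatory.tau])
    thetas = grid.get("theta", [base_config.regulatory.theta])
    kcat_grid = grid.get("kcat", {})
    if not taus or not thetas:
        raise ValueError("grid axes must be non-empty")
    kcat_axes = [[(rid, v) for v in values] for rid, values in kcat_grid.items()]
    kcat_points = list(itertools.product(*kcat_axes)) if kcat_axes else [()]

    rows = []
    trajectories = {}
    dt = base_config.regulatory.dt_min
    for tau, theta, kcat_over in itertools.product(taus, thetas, kcat_points):
        reg = replace(base_config.regulatory, tau=tau, theta=theta)
        config = replace(base_config, regulatory=reg)
        kins = []
        overrides = dict(kcat_over)
        for k in kinetics:
            kins.append(replace(k, kcat=overrides.get(k.reaction, k.kcat)))
        traj = simulate(model, kins, config)
        key = (tau, theta, kcat_over)
        trajectories[key] = traj
        summary = episode_durations(traj, dt)
        summary.insert(0, "tau", tau)
        summary.insert(1, "theta", theta)
        summary.insert(2, "kcat_overrides", repr(dict(kcat_over)))
        rows.append(summary)
    return pd.concat(rows, ignore_index=True), trajectories
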