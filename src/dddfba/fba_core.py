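"""The three linear programs the dynamic method composes.

* :func:`fba` — maximize the biomass (growth) objective subject to
  steady-state mass balance S·v = 0 and flux bounds.
* :func:`pfba` — parsimonious FBA: with growth pinned at its optimum,
  minimize total flux, either Σ|v| (L1, the default) or Σv² (L2).
* :func:`fva` — flux variability analysis: per-reaction min/max flux over
  the growth-optimal polytope.

All three operate on a :class:`cobra.Model`; the LPs are solved through the
model's configured solver (GLPK by default).  The L2 variant is a small
dense QP solved with SciPy and is intended for networks of at most a few
hundred reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import cobra
from cobra.flux_analysis.parsimonious import add_pfba
from cobra.util.array import create_stoichiometric_matrix
from cobra.util.solver import linear_reaction_coefficients

#: Relative slack used when pinning growth at mu*: the biomass flux is
#: constrained to [mu*(1 - GROWTH_TOL), mu*] to avoid numerical infeasibility.
GROWTH_TOL = 1e-6

#: Cap applied in place of infinite bounds (COBRA convention).
DEFAULT_BOUND = 1000.0


class InfeasibleError(RuntimeError):
    """Raised when an LP that is required to be feasible is not."""


@dataclass
class FluxSolution:
    """Result of one flux optimization.

    Attributes
    ----------
    fluxes:
        Flux per reaction id (mmol h^-1 gDCW^-1); empty if not optimal.
    growth_rate:
        Flux through the objective (biomass) reaction, h^-1.
    objective_value:
        Value of the optimized objective (equals ``growth_rate`` for plain
        FBA; total flux for pFBA).
    status:
        ``"optimal"``, ``"infeasible"`` or ``"unbounded"``.
    """

    fluxes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    growth_rate: float = float("nan")
    objective_value: float = float("nan")
    status: str = "optimal"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAInterval:
    """Feasible flux range of one reaction at fixed optimal growth."""

    reaction: str
    minimum: float
    maximum: float

    def contains(self, flux: float, tol: float = 1e-6) -> bool:
        return self.minimum - tol <= flux <= self.maximum + tol


def objective_reaction(model: cobra.Model) -> cobra.Reaction:
    """The single reaction carrying the (linear) objective."""
    coeffs = linear_reaction_coefficients(model)
    if len(coeffs) != 1:
        raise ValueError("model must have exactly one objective reaction")
    return next(iter(coeffs))


def _solution_from(model: cobra.Model, solution) -> FluxSolution:
    bio = objective_reaction(model).id
    return FluxSolution(
        fluxes=solution.fluxes.astype(float),
        growth_rate=float(solution.fluxes[bio]),
        objective_value=float(solution.objective_value),
        status="optimal",
    )


def fba(model: cobra.Model) -> FluxSolution:
    """Growth-maximizing flux balance analysis.

    Returns a solution with ``status`` set to ``"infeasible"`` or
    ``"unbounded"`` (and no flux vector) when the LP fails.
    """
    solution = model.optimize(objective_sense="maximize", raise_error=False)
    if solution.status != "optimal":
        return FluxSolution(status=solution.status)
    return _solution_from(model, solution)


def _fix_growth(model: cobra.Model, mu_star: float) -> None:
    bio = objective_reaction(model)
    lo = mu_star * (1.0 - GROWTH_TOL) if mu_star >= 0 else mu_star * (1.0 + GROWTH_TOL)
    bio.bounds = (lo, mu_star)


def pfba(model: cobra.Model, mu_star: float | None = None,
         norm: str = "l1") -> FluxSolution:
    """Parsimonious FBA: minimal total flux at fixed optimal growth.

    Parameters
    ----------
    mu_star:
        Growth rate to pin (h^-1).  ``None`` runs :func:`fba` first and uses
        its optimum.
    norm:
        ``"l1"`` minimizes Σ|v| (via the solver's irreversible flux split);
        ``"l2"`` minimizes Σv² (dense SciPy QP, small models only).

    The returned ``objective_value`` is the minimized total flux; the
    ``growth_rate`` equals ``mu_star`` up to the pinning tolerance.
    """
    if norm not in {"l1", "l2"}:
        raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
    if mu_star is None:
        base = fba(model)
        if not base.ok:
            return base
        mu_star = base.growth_rate
    if norm == "l2":
        return _pfba_l2(model, mu_star)
    bio = objective_reaction(model).id
    with model as m:
        _fix_growth(m, mu_star)
        add_pfba(m, fraction_of_optimum=1.0)
        solution = m.optimize(objective_sense="minimize", raise_error=False)
        if solution.status != "optimal":
            return FluxSolution(status=solution.status)
        return FluxSolution(
            fluxes=solution.fluxes.astype(float),
            growth_rate=float(solution.fluxes[bio]),
            objective_value=float(solution.fluxes.abs().sum()),
            status="optimal",
        )


def _pfba_l2(model: cobra.Model, mu_star: float) -> FluxSolution:
    """Minimize Σv² over {S v = 0, bounds, v_bio = mu*} with SLSQP.

    Warm-started from the L1 solution; adequate for toy-scale networks.
    """
    from scipy import optimize

    start = pfba(model, mu_star, norm="l1")
    if not start.ok:
        return start
    S = create_stoichiometric_matrix(model)
    rxn_ids = [r.id for r in model.reactions]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    lb = np.clip(lb, -DEFAULT_BOUND, DEFAULT_BOUND)
    ub = np.clip(ub, -DEFAULT_BOUND, DEFAULT_BOUND)
    i_bio = rxn_ids.index(objective_reaction(model).id)
    lb[i_bio] = ub[i_bio] = mu_star
    x0 = np.clip(start.fluxes.reindex(rxn_ids).to_numpy(), lb, ub)
    res = optimize.minimize(
        lambda v: float(v @ v), x0,
        jac=lambda v: 2.0 * v,
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda v: S @ v,
                      "jac": lambda v: S}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        return FluxSolution(status="infeasible")
    fluxes = pd.Series(res.x, index=rxn_ids)
    return FluxSolution(fluxes=fluxes, growth_rate=float(fluxes.iloc[i_bio]),
                        objective_value=float(res.x @ res.x), status="optimal")


def fva(model: cobra.Model, mu_star: float | None = None,
        reactions: Iterable[str] | None = None) -> list[FVAInterval]:
    """Flux variability analysis at fixed optimal growth.

    Each listed reaction is minimized and maximized over the polytope
    {S·v = 0, bounds, v_biomass = mu*}; the parsimony step is *not*
    applied, so the intervals span the whole growth-optimal space.
    """
    if mu_star is None:
        base = fba(model)
        if not base.ok:
            raise InfeasibleError(f"FBA status {base.status}; cannot run FVA")
        mu_star = base.growth_rate
    if reactions is None:
        reactions = [r.id for r in model.reactions]
    intervals: list[FVAInterval] = []
    with model as m:
        _fix_growth(m, mu_star)
        for rid in reactions:
            rxn = m.reactions.get_by_id(rid)
            bounds: list[float] = []
            for sense in ("minimize", "maximize"):
                m.objective = rxn
                sol = m.optimize(objective_sense=sense, raise_error=False)
                if sol.status != "optimal":
                    raise InfeasibleError(
                        f"FVA {sense} of {rid} at mu={mu_star:.6g}: {sol.status}")
                bounds.append(float(sol.objective_value))
            lo, hi = sorted(bounds)
            intervals.append(FVAInterval(rid, lo, hi))
    return intervals


def fva_frame(intervals: Sequence[FVAInterval]) -> pd.DataFrame:
    """FVA intervals as a DataFrame (reaction_id, min, max), TSV-ready."""
    return pd.DataFrame(
        {"reaction_id": [i.reaction for i in intervals],
         "min": [i.minimum for i in intervals],
         "max": [i.maximum for i in intervals]}
    )


def steady_state_residual(model: cobra.Model, solution: FluxSolution) -> float:
    """max |S·v| of a solution — should vanish for any optimal LP result."""
    S = create_stoichiometric_matrix(model)
    v = solution.fluxes.reindex([r.id for r in model.reactions]).to_numpy()
    return float(np.max(np.abs(S @ v)))
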