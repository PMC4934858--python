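"""Independent LP oracle: a from-scratch SciPy (HiGHS) formulation.

Builds the FBA/pFBA/FVA linear programs directly from a model's
stoichiometric structure, sharing no solver path with the package (which
goes through optlang/GLPK).  Used to cross-check objective values.
"""

import numpy as np
from scipy.optimize import linprog

CAP = 1000.0
GROWTH_TOL = 1e-6


def _arrays(model):
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    lb = np.empty(len(rxns))
    ub = np.empty(len(rxns))
    for j, r in enumerate(model.reactions):
        for met, coef in r.metabolites.items():
            S[mets[met.id], j] = coef
        lb[j] = max(r.lower_bound, -CAP)
        ub[j] = min(r.upper_bound, CAP)
    return S, rxns, lb, ub


def _objective_index(model, rxns):
    from cobra.util.solver import linear_reaction_coefficients

    (bio,) = linear_reaction_coefficients(model)
    return rxns.index(bio.id)


def oracle_fba(model):
    """(mu, flux dict) maximizing the biomass reaction."""
    S, rxns, lb, ub = _arrays(model)
    i_bio = _objective_index(model, rxns)
    c = np.zeros(len(rxns))
    c[i_bio] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None, None
    return -res.fun, dict(zip(rxns, res.x))


def oracle_min_total_flux(model, mu_star):
    """Minimal sum of |v| at exactly fixed growth (L1 pFBA objective value).

    Growth is pinned by equality so the comparison is not blurred by the
    implementation's pinning slack; pass the achieved growth rate.
    """
    S, rxns, lb, ub = _arrays(model)
    i_bio = _objective_index(model, rxns)
    lb = lb.copy(); ub = ub.copy()
    lb[i_bio] = mu_star
    ub[i_bio] = mu_star
    n = len(rxns)
    # variables [v, t] with t >= |v|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub = np.block([[np.eye(n), -np.eye(n)],    # v - t <= 0
                     [-np.eye(n), -np.eye(n)]])  # -v - t <= 0
    b_ub = np.zeros(2 * n)
    A_eq = np.hstack([S, np.zeros_like(S)])
    bounds = list(zip(lb, ub)) + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.fun


def oracle_fva(model, mu_star, reactions):
    """{reaction: (min, max)} over the growth-fixed polytope."""
    S, rxns, lb, ub = _arrays(model)
    i_bio = _objective_index(model, rxns)
    lb = lb.copy(); ub = ub.copy()
    lb[i_bio] = mu_star * (1 - GROWTH_TOL)
    ub[i_bio] = mu_star
    out = {}
    for rid in reactions:
        j = rxns.index(rid)
        vals = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rxns))
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lb, ub)), method="highs")
            assert res.success, f"oracle FVA failed for {rid}"
            vals.append(sign * res.fun)
        out[rid] = (min(vals), max(vals))
    return out
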