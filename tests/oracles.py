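"""Independently coded brute-force LP oracles used to cross-check the solver.

These formulations are deliberately different from the production solver:
they use net-flux variables with scipy.optimize.linprog (HiGHS) instead of
a split-variable GLPK problem, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from evofba.model import StoichiometricModel


def oracle_max_growth(
    model: StoichiometricModel,
    caps: dict[str, float],
    mutable: list[str],
    budget: float,
) -> float:
    """Stage-1 optimum by brute force: maximise biomass flux.

    Variables: net fluxes x (nr) plus one uptake helper u_e >= max(-x_e, 0)
    per mutable exchange, with sum(u) <= budget.
    """
    nr = model.n_reactions
    ne = len(mutable)
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for ex in mutable:
        j = model.reaction_index(ex)
        lb[j] = -float(caps.get(ex, 0.0))

    n = nr + ne
    c = np.zeros(n)
    c[model.reaction_index(model.biomass_reaction)] = -1.0  # maximise

    A_eq = np.hstack([model.stoichiometry.toarray(), np.zeros((model.n_metabolites, ne))])
    b_eq = np.zeros(model.n_metabolites)

    # u_e >= -x_e  <=>  -x_e - u_e <= 0 ; sum u <= budget
    A_ub = np.zeros((ne + 1, n))
    for k, ex in enumerate(mutable):
        A_ub[k, model.reaction_index(ex)] = -1.0
        A_ub[k, nr + k] = -1.0
    A_ub[ne, nr:] = 1.0
    b_ub = np.zeros(ne + 1)
    b_ub[ne] = budget

    bounds = [(lb[j], ub[j]) for j in range(nr)] + [(0.0, budget)] * ne
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        if res.status == 2:  # infeasible
            return 0.0
        raise RuntimeError(f"oracle LP failed: {res.message}")
    return float(-res.fun)


def oracle_min_total_flux(
    model: StoichiometricModel,
    caps: dict[str, float],
    mutable: list[str],
    budget: float,
    mu: float,
    mu_tol: float = 1e-9,
) -> float:
    """Stage-2 optimum by brute force: minimal total |flux| at growth mu.

    Variables: net fluxes x plus s >= |x| per reaction plus the budget
    helpers; minimise sum(s).
    """
    nr = model.n_reactions
    ne = len(mutable)
    bio = model.reaction_index(model.biomass_reaction)
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for ex in mutable:
        j = model.reaction_index(ex)
        lb[j] = -float(caps.get(ex, 0.0))
    lb[bio] = max(mu - mu_tol, lb[bio])
    ub[bio] = max(ub[bio], mu)

    n = nr + nr + ne  # x, s, u
    c = np.zeros(n)
    c[nr : 2 * nr] = 1.0

    A_eq = np.hstack(
        [model.stoichiometry.toarray(), np.zeros((model.n_metabolites, nr + ne))]
    )
    b_eq = np.zeros(model.n_metabolites)

    rows = []
    rhs = []
    for j in range(nr):  # x_j - s_j <= 0 and -x_j - s_j <= 0
        r = np.zeros(n)
        r[j], r[nr + j] = 1.0, -1.0
        rows.append(r)
        rhs.append(0.0)
        r = np.zeros(n)
        r[j], r[nr + j] = -1.0, -1.0
        rows.append(r)
        rhs.append(0.0)
    for k, ex in enumerate(mutable):  # -x_e - u_e <= 0
        r = np.zeros(n)
        r[model.reaction_index(ex)], r[2 * nr + k] = -1.0, -1.0
        rows.append(r)
        rhs.append(0.0)
    r = np.zeros(n)  # sum u <= budget
    r[2 * nr :] = 1.0
    rows.append(r)
    rhs.append(budget)

    bounds = (
        [(lb[j], ub[j]) for j in range(nr)]
        + [(0.0, None)] * nr
        + [(0.0, budget)] * ne
    )
    res = linprog(
        c, A_ub=np.array(rows), b_ub=np.array(rhs), A_eq=A_eq, b_eq=b_eq,
        bounds=bounds, method="highs",
    )
    if not res.success:
        raise RuntimeError(f"oracle stage-2 LP failed: {res.message}")
    return float(res.fun)
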