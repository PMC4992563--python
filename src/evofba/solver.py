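"""Two-stage budgeted FBA solver.

Each per-step optimisation solves, on one persistent GLPK problem:

stage 1
    maximise the biomass flux subject to steady state (S v = 0), default
    bounds, per-exchange uptake caps, and an explicit budget row limiting
    the *summed uptake* over the mutable exchanges (carbon sources plus
    oxygen) to the global capacity ``budget`` (40 mmol/gDW/h by default).

stage 2
    fix the biomass flux at its stage-1 optimum (to within 1e-9) and
    minimise the total absolute flux (parsimonious tie-break), returning
    the stage-2 flux vector.

Every reaction is represented by a forward/reverse variable pair
(v = v+ - v-), which makes the uptake budget a plain linear row over the
reverse parts of the mutable exchange columns and makes stage 2 an
ordinary LP.  The problem is built once per (model, mutable set, budget);
per-call work is bound updates plus two warm-started simplex solves, which
is what makes minute-resolution dynamic FBA over hundreds of serial
transfer cycles affordable.

Sign adapter: internally fluxes use the toolchain convention (negative
exchange flux = uptake).  :attr:`FBASolution.exchange_fluxes` is the single
place the simulator-facing convention (positive = uptake) is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import swiglpk as glpk

from .model import StoichiometricModel

__all__ = ["FBASolution", "BudgetedFBASolver", "SolverError", "solve_fba"]

#: Tolerance for fixing the stage-1 optimum in stage 2.
GROWTH_FIX_TOL = 1e-9


class SolverError(RuntimeError):
    """GLPK failed for a reason other than plain infeasibility."""


@dataclass
class FBASolution:
    """Result of one two-stage solve.

    ``exchange_fluxes`` is signed with **uptake positive** (secretion
    negative); ``fluxes`` (populated only when requested) keeps the raw
    toolchain sign convention, aligned with ``model.reactions``.
    """

    status: str  # "optimal" | "infeasible"
    growth_rate: float
    exchange_fluxes: dict[str, float]
    fluxes: np.ndarray | None = None
    total_absolute_flux: float = field(default=np.nan)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class BudgetedFBASolver:
    """Persistent GLPK problem for one model / mutable set / budget."""

    def __init__(
        self,
        model: StoichiometricModel,
        mutable_exchanges: Sequence[str],
        budget: float,
    ) -> None:
        unknown = set(mutable_exchanges) - set(model.exchange_reactions)
        if unknown:
            raise ValueError(f"mutable ids are not exchanges: {sorted(unknown)}")
        overlap = set(mutable_exchanges) & model.unlimited_exchanges
        if overlap:
            raise ValueError(f"mutable exchanges cannot be unlimited: {sorted(overlap)}")
        if budget <= 0:
            raise ValueError("budget must be positive")

        self.model = model
        self.mutable_exchanges = list(mutable_exchanges)
        self.budget = float(budget)

        self._nr = model.n_reactions
        self._nm = model.n_metabolites
        self._bio = model.reaction_index(model.biomass_reaction)
        self._ex_cols = {ex: model.reaction_index(ex) for ex in model.exchange_reactions}
        self._mut_cols = [model.reaction_index(ex) for ex in self.mutable_exchanges]
        self._build()

    # -- problem construction -----------------------------------------
    def _build(self) -> None:
        m, nr, nm = self.model, self._nr, self._nm
        glpk.glp_term_out(glpk.GLP_OFF)
        lp = self._lp = glpk.glp_create_prob()
        glpk.glp_set_prob_name(lp, f"evofba:{m.model_id}")
        glpk.glp_add_rows(lp, nm + 1)
        for i in range(nm):
            glpk.glp_set_row_bnds(lp, i + 1, glpk.GLP_FX, 0.0, 0.0)
        self._budget_row = nm + 1
        glpk.glp_set_row_bnds(lp, self._budget_row, glpk.GLP_UP, 0.0, self.budget)

        # columns: 1..nr forward parts, nr+1..2nr reverse parts
        glpk.glp_add_cols(lp, 2 * nr)
        coo = m.stoichiometry.tocoo()
        nnz = 2 * coo.nnz + len(self._mut_cols)
        ia, ja, ar = glpk.intArray(nnz + 1), glpk.intArray(nnz + 1), glpk.doubleArray(nnz + 1)
        k = 0
        for i, j, v in zip(coo.row, coo.col, coo.data):
            k += 1
            ia[k], ja[k], ar[k] = int(i) + 1, int(j) + 1, float(v)
            k += 1
            ia[k], ja[k], ar[k] = int(i) + 1, nr + int(j) + 1, float(-v)
        for j in self._mut_cols:
            k += 1
            ia[k], ja[k], ar[k] = self._budget_row, nr + j + 1, 1.0
        glpk.glp_load_matrix(lp, k, ia, ja, ar)

        # net flux v_j = fwd_j - rev_j with fwd in [max(lb,0), max(ub,0)] and
        # rev in [max(-ub,0), max(-lb,0)]: preserves positive lower bounds
        # (maintenance fluxes) as well as irreversibility.
        self._fwd_lb = np.maximum(m.lower_bounds, 0.0)
        self._fwd_ub = np.maximum(m.upper_bounds, 0.0)
        self._rev_lb = np.maximum(-m.upper_bounds, 0.0)
        self._rev_ub = np.maximum(-m.lower_bounds, 0.0)
        mut = set(self._mut_cols)
        for j in range(nr):
            self._set_col_range(j + 1, self._fwd_lb[j], self._fwd_ub[j])
            # mutable uptake starts closed; opened per-call by the caps
            if j in mut:
                self._set_col(nr + j + 1, 0.0)
            else:
                self._set_col_range(nr + j + 1, self._rev_lb[j], self._rev_ub[j])

        self._parm = glpk.glp_smcp()
        glpk.glp_init_smcp(self._parm)
        self._parm.msg_lev = glpk.GLP_MSG_OFF
        self._obj_is_stage2 = False
        glpk.glp_set_obj_dir(lp, glpk.GLP_MAX)
        glpk.glp_set_obj_coef(lp, self._bio + 1, 1.0)

    def _set_col(self, col: int, ub: float) -> None:
        if ub <= 0.0:
            glpk.glp_set_col_bnds(self._lp, col, glpk.GLP_FX, 0.0, 0.0)
        else:
            glpk.glp_set_col_bnds(self._lp, col, glpk.GLP_DB, 0.0, ub)

    def _set_col_range(self, col: int, lo: float, hi: float) -> None:
        if hi <= lo:
            glpk.glp_set_col_bnds(self._lp, col, glpk.GLP_FX, lo, lo)
        else:
            glpk.glp_set_col_bnds(self._lp, col, glpk.GLP_DB, lo, hi)

    def _simplex(self) -> int:
        ret = glpk.glp_simplex(self._lp, self._parm)
        if ret != 0:
            # basis went stale; rebuild and retry cold once
            glpk.glp_adv_basis(self._lp, 0)
            ret = glpk.glp_simplex(self._lp, self._parm)
            if ret != 0:
                raise SolverError(f"GLPK simplex failed with code {ret}")
        return glpk.glp_get_status(self._lp)

    # -- stage toggling ------------------------------------------------
    def _enter_stage2(self, mu: float) -> None:
        lp, nr = self._lp, self._nr
        glpk.glp_set_obj_dir(lp, glpk.GLP_MIN)
        for c in range(1, 2 * nr + 1):
            glpk.glp_set_obj_coef(lp, c, 1.0)
        lo = max(mu - GROWTH_FIX_TOL, self._fwd_lb[self._bio])
        hi = max(self._fwd_ub[self._bio], mu)
        glpk.glp_set_col_bnds(self._lp, self._bio + 1, glpk.GLP_DB, lo, hi)
        self._obj_is_stage2 = True

    def _leave_stage2(self) -> None:
        lp, nr = self._lp, self._nr
        glpk.glp_set_obj_dir(lp, glpk.GLP_MAX)
        for c in range(1, 2 * nr + 1):
            glpk.glp_set_obj_coef(lp, c, 0.0)
        glpk.glp_set_obj_coef(lp, self._bio + 1, 1.0)
        self._set_col_range(self._bio + 1, self._fwd_lb[self._bio], self._fwd_ub[self._bio])
        self._obj_is_stage2 = False

    # -- public API ----------------------------------------------------
    def solve(
        self,
        uptake_bounds: Mapping[str, float],
        full_fluxes: bool = False,
    ) -> FBASolution:
        """Run the two-stage solve under the given per-exchange uptake caps.

        ``uptake_bounds`` maps mutable exchange ids to maximum uptake
        rates (mmol/gDW/h, >= 0).  Omitted mutable exchanges are closed.
        An infeasible stage 1 (e.g. maintenance flux unsatisfiable with
        no carbon) yields ``status="infeasible"`` with zero growth and
        zero fluxes: the organism simply does not grow this step.
        """
        lp, nr = self._lp, self._nr
        mut_set = set(self.mutable_exchanges)
        unknown = set(uptake_bounds) - mut_set
        if unknown:
            raise ValueError(f"caps given for non-mutable exchanges: {sorted(unknown)}")
        if self._obj_is_stage2:  # defensive: a previous call raised mid-way
            self._leave_stage2()

        for ex in self.mutable_exchanges:
            cap = float(uptake_bounds.get(ex, 0.0))
            if cap < 0 or not np.isfinite(cap):
                raise ValueError(f"uptake cap for {ex} must be finite and >= 0, got {cap}")
            self._set_col(nr + self._ex_cols[ex] + 1, cap)

        status = self._simplex()
        if status in (glpk.GLP_NOFEAS, glpk.GLP_INFEAS):
            return self._zero_solution(full_fluxes)
        if status != glpk.GLP_OPT:
            raise SolverError(f"stage-1 LP ended with GLPK status {status}")
        mu = max(glpk.glp_get_obj_val(lp), 0.0)

        self._enter_stage2(mu)
        try:
            status = self._simplex()
            if status != glpk.GLP_OPT:
                raise SolverError(f"stage-2 LP ended with GLPK status {status}")
            total_abs = glpk.glp_get_obj_val(lp)
            fluxes = self._extract(full_fluxes)
        finally:
            self._leave_stage2()

        ex_fluxes = self._exchange_view()
        return FBASolution(
            status="optimal",
            growth_rate=mu,
            exchange_fluxes=ex_fluxes,
            fluxes=fluxes,
            total_absolute_flux=total_abs,
        )

    def zero_solution(self, full_fluxes: bool = False) -> FBASolution:
        """The no-growth solution (used when nothing can be consumed)."""
        return self._zero_solution(full_fluxes)

    def _zero_solution(self, full_fluxes: bool) -> FBASolution:
        return FBASolution(
            status="infeasible",
            growth_rate=0.0,
            exchange_fluxes={ex: 0.0 for ex in self.model.exchange_reactions},
            fluxes=np.zeros(self._nr) if full_fluxes else None,
            total_absolute_flux=0.0,
        )

    def _net(self, j: int) -> float:
        lp, nr = self._lp, self._nr
        return glpk.glp_get_col_prim(lp, j + 1) - glpk.glp_get_col_prim(lp, nr + j + 1)

    def _extract(self, full_fluxes: bool) -> np.ndarray | None:
        if not full_fluxes:
            return None
        return np.array([self._net(j) for j in range(self._nr)])

    def _exchange_view(self) -> dict[str, float]:
        # the one sign flip: simulator convention is uptake-positive
        return {ex: -self._net(j) for ex, j in self._ex_cols.items()}


def solve_fba(
    model: StoichiometricModel,
    uptake_bounds: Mapping[str, float],
    mutable_exchanges: Sequence[str] | None = None,
    budget: float = 40.0,
    full_fluxes: bool = False,
) -> FBASolution:
    """One-shot two-stage budgeted FBA solve.

    Convenience wrapper that builds a :class:`BudgetedFBASolver` for a
    single call; simulations should hold a solver instance instead so the
    underlying LP is reused.
    """
    mutable = (
        list(mutable_exchanges) if mutable_exchanges is not None
        else model.mutable_exchanges()
    )
    return BudgetedFBASolver(model, mutable, budget).solve(
        uptake_bounds, full_fluxes=full_fluxes
    )
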