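"""Inner flux-balance optimization.

Standard FBA is the linear program

    v* = argmax_v c'v   s.t.  S v = 0,  v_min <= v <= v_max,

solved here with the HiGHS backend of :func:`scipy.optimize.linprog`. The
parsimonious variant (pFBA) adds a second stage that, holding the first-stage
objective within a relative tolerance of its optimum, minimizes total absolute
flux via the usual split into forward/backward parts.

Medium composition enters exclusively through :func:`apply_medium`, which
rewrites the upper bounds of import reactions (uptake-positive convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "FluxObjective",
    "FluxSolution",
    "apply_medium",
    "make_combined_objective",
    "solve_fba",
    "solve_pfba",
]

#: solver feasibility/optimality tolerance passed to HiGHS
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class FluxObjective:
    """Linear flux objective ``c'v`` — e.g. biomass, or biomass:production mix."""

    c: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.c, float)
        object.__setattr__(self, "c", c)
        if not np.any(c != 0):
            raise ValueError("objective has no nonzero weight")


@dataclass(frozen=True)
class FluxSolution:
    """Outcome of an inner LP solve."""

    v_star: np.ndarray | None
    objective_value: float
    status: str  # optimal | infeasible | unbounded | failed
    total_flux: float | None = None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, model: MetabolicModel, reaction_id: str) -> float:
        if self.v_star is None:
            raise ValueError(f"no flux vector: solve ended with status {self.status}")
        return float(self.v_star[model.reaction_index(reaction_id)])


def apply_medium(
    model: MetabolicModel, medium_bounds: Mapping[str, float]
) -> MetabolicModel:
    """Return a copy of ``model`` with import upper bounds set from a medium.

    Listed import reactions get bounds ``[0, value]``; an absent nutrient is
    encoded by value 0. Imports not listed keep their configured bounds. The
    input model is never mutated.
    """
    v_min = model.v_min.copy()
    v_max = model.v_max.copy()
    for rid, bound in medium_bounds.items():
        if rid not in model.exchange_ids:
            raise KeyError(f"{rid!r} is not a nutrient-import reaction")
        if bound < 0:
            raise ValueError(f"negative medium bound {bound} for {rid!r}")
        j = model.reaction_index(rid)
        v_min[j] = 0.0
        v_max[j] = float(bound)
    return model.with_bounds(v_min, v_max)


def make_combined_objective(
    model: MetabolicModel,
    biomass_weight: float,
    production_weight: float = 0.0,
) -> FluxObjective:
    """Weighted biomass:production objective, e.g. 99:1 or 95:5 ratios.

    Weights are normalized to sum to one, so ratios may be given directly
    (``99, 1`` and ``0.99, 0.01`` are equivalent).
    """
    if biomass_weight <= 0 or production_weight < 0:
        raise ValueError("weights must be positive (production weight may be 0)")
    total = biomass_weight + production_weight
    wb, wp = biomass_weight / total, production_weight / total
    c = np.zeros(model.n_reactions)
    c[model.reaction_index(model.biomass_reaction)] = wb
    if wp > 0:
        if model.production_reaction is None:
            raise ValueError(
                "production weight > 0 but the model defines no production reaction"
            )
        c[model.reaction_index(model.production_reaction)] = wp
    return FluxObjective(c=c, description=f"biomass:production {wb:g}:{wp:g}")


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _linprog(c, A_eq, b_eq, bounds, tol):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )


def solve_fba(
    model: MetabolicModel,
    objective: FluxObjective,
    tol: float = DEFAULT_TOL,
) -> FluxSolution:
    """Maximize ``c'v`` over the flux polytope.

    The returned vertex is whichever the solver reports; alternate optima are
    possible (use :func:`solve_pfba` for a canonical representative).
    """
    n = model.n_reactions
    if objective.c.shape != (n,):
        raise ValueError("objective length disagrees with model")
    bounds = list(zip(model.v_min, model.v_max))
    res = _linprog(-objective.c, model.S, np.zeros(model.n_metabolites), bounds, tol)
    status = _STATUS.get(res.status, "failed")
    if status == "optimal":
        v = np.asarray(res.x, float)
        return FluxSolution(
            v_star=v,
            objective_value=float(objective.c @ v),
            status="optimal",
            total_flux=float(np.abs(v).sum()),
        )
    if status == "unbounded":
        ray = [
            model.reaction_ids[j]
            for j in range(n)
            if objective.c[j] != 0 and np.isinf(model.v_max[j])
        ]
        msg = f"unbounded objective; unbounded-ray candidates: {ray or 'unknown'}"
        return FluxSolution(v_star=None, objective_value=np.nan, status="unbounded", message=msg)
    return FluxSolution(
        v_star=None, objective_value=np.nan, status=status, message=str(res.message)
    )


def solve_pfba(
    model: MetabolicModel,
    objective: FluxObjective,
    optimality_tolerance: float = 1e-6,
    tol: float = DEFAULT_TOL,
) -> FluxSolution:
    """Parsimonious FBA: minimal total |flux| among near-optimal solutions.

    Stage 1 solves standard FBA; stage 2 minimizes ``sum |v|`` subject to
    ``c'v >= (1 - optimality_tolerance) * optimum`` (an inequality, robust to
    round-off) using the split ``v = p - q`` with ``p, q >= 0``.
    """
    first = solve_fba(model, objective, tol=tol)
    if not first.optimal:
        return first

    n = model.n_reactions
    m = model.n_metabolites
    # variables [p; q], v = p - q
    S = model.S.tocsc()
    A_eq = sparse.hstack([S, -S], format="csc")
    b_eq = np.zeros(m)
    # bound splitting: p in [max(v_min,0), max(v_max,0)], q in [max(-v_max,0), max(-v_min,0)]
    p_lo = np.maximum(model.v_min, 0.0)
    p_hi = np.maximum(model.v_max, 0.0)
    q_lo = np.maximum(-model.v_max, 0.0)
    q_hi = np.maximum(-model.v_min, 0.0)
    bounds = list(zip(p_lo, p_hi)) + list(zip(q_lo, q_hi))

    floor = (1.0 - optimality_tolerance) * first.objective_value
    # c'(p-q) >= floor  as  -c'p + c'q <= -floor
    A_ub = sparse.csr_matrix(np.concatenate([-objective.c, objective.c])[None, :])
    res = linprog(
        np.ones(2 * n),
        A_ub=A_ub,
        b_ub=np.array([-floor]),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(
            v_star=None,
            objective_value=np.nan,
            status=status,
            message=f"pFBA stage 2: {res.message}",
        )
    x = np.asarray(res.x, float)
    v = x[:n] - x[n:]
    return FluxSolution(
        v_star=v,
        objective_value=float(objective.c @ v),
        status="optimal",
        total_flux=float(np.abs(v).sum()),
    )
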