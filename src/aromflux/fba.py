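"""Flux balance analysis: condition setup, LP solve, flux variability.

The engine maximizes the biomass reaction flux subject to steady state
(S·v = 0) and flux bounds, using scipy's HiGHS solver.  With the substrate
uptake fixed to its measured maximum, maximizing biomass flux is equivalent
to maximizing the biomass yield.  Because LP optima are generally degenerate,
any statement about whether a reaction "is active" should use the
flux-variability ranges (:func:`flux_variability`), never a single optimal
flux vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

#: Flux below this magnitude (mmol·gDW⁻¹·h⁻¹) is reported as zero.
FLUX_EPS = 1e-6

#: Non-growth-associated maintenance default, mmol ATP·gDW⁻¹·h⁻¹ (E. coli K-12).
DEFAULT_NGAM = 8.39
#: Growth-associated maintenance default, mmol ATP·gDW⁻¹ (E. coli K-12);
#: embedded in the biomass reaction, surfaced here as explicit configuration.
DEFAULT_GAM = 59.81

ACCEPTORS = ("nitrate", "oxygen")


class ConditionError(ValueError):
    """Raised when a growth condition references missing exchanges."""


class SolverError(RuntimeError):
    """Raised when the LP solver fails for reasons other than infeasibility."""


@dataclass
class Condition:
    """One growth condition: carbon source, electron acceptor, maintenance.

    Uptake maxima are positive magnitudes in mmol·gDW⁻¹·h⁻¹; the engine sets
    exchange lower bounds to their negatives (imports are negative exchange
    fluxes).  The non-selected acceptor's exchange is closed entirely.
    """

    label: str
    substrate_exchange: str
    substrate_uptake_max: float
    acceptor: str
    acceptor_exchange: str
    acceptor_uptake_max: float
    ngam: float = DEFAULT_NGAM
    gam: float = DEFAULT_GAM
    closed_exchanges: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.acceptor not in ACCEPTORS:
            raise ConditionError(f"unknown acceptor {self.acceptor!r}")
        if self.substrate_uptake_max < 0 or self.acceptor_uptake_max < 0:
            raise ConditionError("uptake maxima must be >= 0")


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    condition: Condition | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction [min, max] flux at (near-)optimal biomass objective."""

    ranges: dict[str, tuple[float, float]]
    condition_label: str = ""
    objective_value: float = float("nan")
    objective_fraction: float = 1.0


def apply_condition(
    model: MetabolicModel,
    condition: Condition,
    *,
    other_acceptor_exchanges: tuple[str, ...] = (),
) -> MetabolicModel:
    """Return a bounded copy of *model* configured for *condition*.

    Opens the substrate and selected acceptor exchanges for uptake, closes the
    exchanges named in ``condition.closed_exchanges`` and
    ``other_acceptor_exchanges`` (the rival acceptor), and fixes any
    maintenance reaction to ``condition.ngam``.
    """
    out = model.copy()
    rxn_ids = set(out.reaction_ids)
    for rid in (condition.substrate_exchange, condition.acceptor_exchange):
        if rid not in rxn_ids:
            raise ConditionError(f"exchange {rid!r} not found in model")
    sub = out.reaction(condition.substrate_exchange)
    sub.lower_bound = -condition.substrate_uptake_max
    acc = out.reaction(condition.acceptor_exchange)
    acc.lower_bound = -condition.acceptor_uptake_max
    acc.upper_bound = 0.0
    for rid in tuple(condition.closed_exchanges) + tuple(other_acceptor_exchanges):
        if rid == condition.acceptor_exchange:
            continue
        if rid not in rxn_ids:
            raise ConditionError(f"exchange {rid!r} not found in model")
        r = out.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    for r in out.reactions:
        if r.category == "maintenance":
            r.lower_bound = condition.ngam
            r.upper_bound = condition.ngam
    return out


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _linprog(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    return res


def solve_fba(model: MetabolicModel, condition: Condition | None = None) -> FluxSolution:
    """Maximize the biomass objective subject to S·v = 0 and flux bounds."""
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective_id)] = -1.0  # maximize
    res = _linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds)
    if res.status == 2:
        return FluxSolution({}, float("nan"), "infeasible", condition)
    if res.status == 3:
        return FluxSolution({}, float("inf"), "unbounded", condition)
    if res.status != 0:
        raise SolverError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(model.reaction_ids, (float(v) for v in res.x)))
    return FluxSolution(fluxes, float(-res.fun), "optimal", condition)


def flux_variability(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    *,
    condition_label: str = "",
    slack: float = 1e-9,
) -> FluxRange:
    """Min/max flux per reaction holding the objective at a fraction of optimum.

    ``objective_fraction`` is in (0, 1]; the default 1.0 explores the optimal
    face only (plus a tiny numerical slack).
    """
    if not 0.0 < objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in (0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise SolverError(f"FBA status {base.status}; cannot compute variability")
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    obj_idx = model.reaction_ids.index(model.objective_id)
    # objective >= fraction * optimum, expressed as -v_obj <= -(target)
    target = objective_fraction * base.objective_value - slack
    A_ub = np.zeros((1, n))
    A_ub[0, obj_idx] = -1.0
    b_ub = np.array([-target])
    b_eq = np.zeros(S.shape[0])
    ranges: dict[str, tuple[float, float]] = {}
    for j, rid in enumerate(model.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        lo = _linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, A_ub=A_ub, b_ub=b_ub)
        hi = _linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, A_ub=A_ub, b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise SolverError(f"variability LP failed for reaction {rid!r}")
        ranges[rid] = (float(lo.fun), float(-hi.fun))
    return FluxRange(
        ranges=ranges,
        condition_label=condition_label,
        objective_value=base.objective_value,
        objective_fraction=objective_fraction,
    )


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """max |S·v| over metabolites; should be ~0 for an optimal solution."""
    if not solution.optimal:
        raise ValueError("solution is not optimal")
    S = stoichiometric_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in model.reaction_ids])
    return float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0


def biomass_carbon_yield(
    solution: FluxSolution,
    model: MetabolicModel,
    *,
    substrate_exchange: str | None = None,
    tol: float = FLUX_EPS,
) -> float:
    """Percent of consumed substrate carbon incorporated into biomass (C/C).

    Requires exactly one carbon source to be imported; if several
    carbon-containing exchanges carry inward flux, pass ``substrate_exchange``
    explicitly or an error is raised.
    """
    if not solution.optimal:
        raise ValueError("solution is not optimal")
    by_id = {m.id: m for m in model.metabolites}
    open_sources = []
    for r in model.reactions:
        if r.category != "boundary":
            continue
        (mid,) = r.stoichiometry
        met = by_id[mid]
        carbon = met.formula.get("C", 0.0) if met.formula else 0.0
        if carbon > 0 and solution.fluxes.get(r.id, 0.0) < -tol:
            open_sources.append((r.id, carbon, solution.fluxes[r.id]))
    if substrate_exchange is None:
        if len(open_sources) != 1:
            raise ValueError(
                "need exactly one open carbon source; imports seen on "
                f"{[rid for rid, _, _ in open_sources]}; pass substrate_exchange explicitly"
            )
        _, n_c, flux = open_sources[0]
    else:
        match = [t for t in open_sources if t[0] == substrate_exchange]
        if not match:
            raise ValueError(f"no carbon import on {substrate_exchange!r}")
        _, n_c, flux = match[0]
    uptake_c = -flux * n_c  # mmol C·gDW⁻¹·h⁻¹
    bio = model.reaction(model.objective_id)
    v_bio = solution.fluxes[model.objective_id]
    net_bio_c = 0.0
    for mid, coeff in bio.stoichiometry.items():
        met = by_id[mid]
        carbon = met.formula.get("C", 0.0) if met.formula else 0.0
        net_bio_c += -coeff * carbon  # consumed precursors count positive
    if uptake_c <= 0:
        raise ValueError("no carbon uptake; yield undefined")
    return 100.0 * net_bio_c * v_bio / uptake_c
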