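"""Constraint-based simulation: FBA, MOMA, media, deletion panels.

FBA maximizes the biomass objective over the steady-state flux polytope
{v : S v = 0, lb <= v <= ub} (a linear program, solved with HiGHS through
scipy).  MOMA predicts a mutant's flux state as the Euclidean projection of
the wild-type flux distribution onto the mutant's polytope — a strictly
convex quadratic program with a unique minimizer, solved here by a dense
primal active-set method (exact KKT solves, finite termination).  The
wild-type reference used by MOMA is made unique by an L2 tie-break among
growth-optimal flux vectors.

Unbounded fluxes are encoded as +/-1000 mmol/gDCW/h (the model dialect's
infinity convention), which keeps every program bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import INFINITY_BOUND, MetabolicModel, apply_gene_deletion

__all__ = [
    "MediumDefinition",
    "FluxDistribution",
    "SolverError",
    "set_medium",
    "stoichiometric_matrix",
    "fba",
    "moma",
    "wildtype_reference",
    "simulate_deletion_panel",
    "single_reaction_essentiality",
]

#: feasibility tolerance on S v = 0 (scaled)
EPS_EQ = 1e-6
#: feasibility tolerance on bounds
EPS_BND = 1e-9
#: growth values below this are reported as exactly zero
GROWTH_FLOOR = 1e-9


class SolverError(RuntimeError):
    """A numerical solve failed; carries the solver status message."""


@dataclass(frozen=True)
class MediumDefinition:
    """Uptake bounds defining a minimal medium with one carbon source.

    ``free_exchanges`` are the mineral-salt style exchanges whose uptake is
    left unconstrained.  ``oxygen_exchange`` may be None for models without
    an explicit oxygen boundary.
    """

    condition_id: str
    carbon_exchange: str
    carbon_uptake_max: float = 10.0
    oxygen_uptake_max: float = 20.0
    oxygen_exchange: str | None = None
    free_exchanges: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.carbon_uptake_max < 0 or self.oxygen_uptake_max < 0:
            raise ValueError("uptake maxima must be non-negative")


@dataclass
class FluxDistribution:
    """A steady-state flux vector with its biomass objective value."""

    strain_id: str
    condition_id: str
    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"

    def as_array(self, reaction_order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_order])


def set_medium(model: MetabolicModel, medium: MediumDefinition) -> MetabolicModel:
    """Apply a medium: open the carbon/oxygen/free uptakes, close the rest.

    Secretion (upper bounds) is unconstrained for every exchange reaction.
    """
    exchange_ids = [r for r in model.reaction_ids if model.is_exchange(r)]
    named = {medium.carbon_exchange} | set(medium.free_exchanges)
    if medium.oxygen_exchange is not None:
        named.add(medium.oxygen_exchange)
    unknown = named - set(exchange_ids)
    if unknown:
        raise KeyError(
            f"medium names reactions that are not exchanges of this model: {sorted(unknown)}"
        )
    bounds: dict[str, tuple[float, float]] = {}
    for rxn_id in exchange_ids:
        if rxn_id == medium.carbon_exchange:
            lb = -medium.carbon_uptake_max
        elif rxn_id == medium.oxygen_exchange:
            lb = -medium.oxygen_uptake_max
        elif rxn_id in medium.free_exchanges:
            lb = -INFINITY_BOUND
        else:
            lb = 0.0
        bounds[rxn_id] = (lb, INFINITY_BOUND)
    return model.with_bounds(bounds)


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S (metabolites x reactions) in model order."""
    met_pos = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            S[met_pos[met], j] = coef
    return S


def _bounds_arrays(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return lb, ub


def _flux_distribution(model, v, strain_id, condition_id) -> FluxDistribution:
    obj = float(v[model.reaction_ids.index(model.objective_reaction)])
    if abs(obj) < GROWTH_FLOOR:
        obj = 0.0
    return FluxDistribution(
        strain_id=strain_id,
        condition_id=condition_id,
        fluxes={r: float(x) for r, x in zip(model.reaction_ids, v)},
        objective_value=obj,
        status="optimal",
    )


def _infeasible(model, strain_id, condition_id) -> FluxDistribution:
    return FluxDistribution(
        strain_id=strain_id,
        condition_id=condition_id,
        fluxes={r: 0.0 for r in model.reaction_ids},
        objective_value=0.0,
        status="infeasible",
    )


# ---------------------------------------------------------------------------
# FBA (linear program)
# ---------------------------------------------------------------------------

def fba(
    model: MetabolicModel,
    strain_id: str = "WT",
    condition_id: str = "",
) -> FluxDistribution:
    """Maximize the biomass objective over the steady-state polytope.

    Returns status "infeasible" (growth 0 by convention) when the polytope is
    empty.  Among alternate optima the deterministic HiGHS vertex is returned;
    callers needing a reproducible representative use ``wildtype_reference``.
    """
    S = stoichiometric_matrix(model)
    lb, ub = _bounds_arrays(model)
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_reaction)] = -1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return _infeasible(model, strain_id, condition_id)
    if not res.success:
        raise SolverError(f"FBA solve failed: {res.message}")
    return _flux_distribution(model, res.x, strain_id, condition_id)


# ---------------------------------------------------------------------------
# Dense primal active-set QP:  min 1/2 ||v - w||^2  s.t.  A v = b, lb<=v<=ub
# ---------------------------------------------------------------------------

def _feasible_point(A, b, lb, ub) -> np.ndarray | None:
    res = linprog(
        np.zeros(A.shape[1]),
        A_eq=A,
        b_eq=b,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2 or res.x is None:
        return None
    if not res.success:
        raise SolverError(f"feasibility solve failed: {res.message}")
    return np.clip(res.x, lb, ub)


def solve_projection_qp(
    A: np.ndarray,
    b: np.ndarray,
    w: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray | None:
    """Euclidean projection of ``w`` onto {v : A v = b, lb <= v <= ub}.

    Primal active-set method with dense KKT solves.  The objective is
    strictly convex, so the returned minimizer is unique.  Returns None when
    the polytope is empty.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    v = _feasible_point(A, b, lb, ub)
    if v is None:
        return None
    working: list[tuple[int, int]] = []  # (index, 0=lower/1=upper)
    for j in range(n):
        if lb[j] == ub[j] or v[j] <= lb[j] + 1e-9:
            working.append((j, 0))
        elif v[j] >= ub[j] - 1e-9:
            working.append((j, 1))
    n_eq = A.shape[0]
    for _ in range(max_iter):
        rows = [A]
        rhs = [b - A @ v]
        for j, side in working:
            e = np.zeros(n)
            e[j] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([(lb[j] if side == 0 else ub[j]) - v[j]]))
        Aw = np.vstack(rows)
        bw = np.concatenate(rhs)
        g = v - w
        m = Aw.shape[0]
        kkt = np.block([[np.eye(n), Aw.T], [Aw, np.zeros((m, m))]])
        sol, *_ = np.linalg.lstsq(kkt, np.concatenate([-g, bw]), rcond=None)
        d, lam = sol[:n], sol[n:]
        if np.linalg.norm(d, np.inf) < tol:
            # At the minimizer of the equality-restricted problem: check the
            # bound multipliers (lower bounds require mu <= 0, upper mu >= 0).
            drop, worst = None, tol
            for k, (j, side) in enumerate(working):
                if lb[j] == ub[j]:
                    continue  # fixed variable, never released
                mu = lam[n_eq + k]
                bad = mu if side == 0 else -mu
                if bad > worst:
                    drop, worst = k, bad
            if drop is None:
                return v
            working.pop(drop)
            continue
        alpha, block = 1.0, None
        in_working = {j for j, _ in working}
        for j in range(n):
            if j in in_working:
                continue
            if d[j] > tol:
                a = (ub[j] - v[j]) / d[j]
                if a < alpha:
                    alpha, block = a, (j, 1)
            elif d[j] < -tol:
                a = (lb[j] - v[j]) / d[j]
                if a < alpha:
                    alpha, block = a, (j, 0)
        v = v + max(alpha, 0.0) * d
        if block is not None and alpha < 1.0:
            working.append(block)
    raise SolverError("active-set QP did not converge")


# ---------------------------------------------------------------------------
# MOMA and the wild-type reference
# ---------------------------------------------------------------------------

def moma(
    mutant_model: MetabolicModel,
    wildtype_flux: FluxDistribution,
    strain_id: str = "mutant",
) -> FluxDistribution:
    """Minimization of metabolic adjustment.

    Returns the unique minimizer of sum_j (v_j - v_j^wt)^2 over the mutant's
    steady-state polytope.  The biomass value is read off the flux vector,
    never re-optimized.  The distance runs over all reactions, exchanges
    included.
    """
    order = mutant_model.reaction_ids
    if set(order) != set(wildtype_flux.fluxes):
        raise ValueError("wild-type flux distribution has a different reaction set")
    S = stoichiometric_matrix(mutant_model)
    lb, ub = _bounds_arrays(mutant_model)
    w = wildtype_flux.as_array(order)
    v = solve_projection_qp(S, np.zeros(S.shape[0]), w, lb, ub)
    if v is None:
        return _infeasible(mutant_model, strain_id, wildtype_flux.condition_id)
    return _flux_distribution(mutant_model, v, strain_id, wildtype_flux.condition_id)


def wildtype_reference(
    model: MetabolicModel,
    condition_id: str = "",
) -> FluxDistribution:
    """Unique wild-type flux reference for MOMA.

    The FBA optimum is refined by minimizing ||v||_2 at the fixed optimal
    growth rate: strictly convex, so alternate FBA optima (e.g. equivalent
    parallel routes) collapse to one reproducible representative in which
    tied routes share flux equally.
    """
    opt = fba(model, strain_id="WT", condition_id=condition_id)
    if opt.status != "optimal":
        return opt
    S = stoichiometric_matrix(model)
    lb, ub = _bounds_arrays(model)
    n = len(model.reactions)
    obj_row = np.zeros(n)
    obj_row[model.reaction_ids.index(model.objective_reaction)] = 1.0
    A = np.vstack([S, obj_row[None, :]])
    b = np.concatenate([np.zeros(S.shape[0]), [opt.objective_value]])
    v = solve_projection_qp(A, b, np.zeros(n), lb, ub)
    if v is None:  # cannot happen: the FBA optimum is feasible
        raise SolverError("L2 refinement infeasible at the FBA optimum")
    return _flux_distribution(model, v, "WT", condition_id)


def simulate_deletion_panel(
    model: MetabolicModel,
    gene_list: Sequence[str],
    media: Sequence[MediumDefinition],
    replicates: int = 3,
) -> list[FluxDistribution]:
    """MOMA flux distributions for every (gene, medium) pair.

    Each deletion is simulated ``replicates`` times against that medium's
    wild-type reference and the flux vectors averaged elementwise; with the
    deterministic solvers used here the replicates are identical, and the
    parameter is kept for interface fidelity with triplicate-averaged runs.
    Infeasible deletions yield all-zero fluxes and growth 0.
    """
    unknown = set(gene_list) - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene(s) in panel: {sorted(unknown)}")
    out: list[FluxDistribution] = []
    for medium in media:
        conditioned = set_medium(model, medium)
        wt = wildtype_reference(conditioned, condition_id=medium.condition_id)
        for gene in gene_list:
            try:
                mutant = apply_gene_deletion(conditioned, {gene})
                runs = [
                    moma(mutant, wt, strain_id=gene) for _ in range(max(replicates, 1))
                ]
            except SolverError as exc:
                raise SolverError(
                    f"deletion panel failed at gene {gene!r}, medium "
                    f"{medium.condition_id!r}: {exc}"
                ) from exc
            mean_flux = {
                r: float(np.mean([run.fluxes[r] for run in runs]))
                for r in model.reaction_ids
            }
            status = runs[0].status
            obj = float(np.mean([run.objective_value for run in runs]))
            out.append(
                FluxDistribution(
                    strain_id=gene,
                    condition_id=medium.condition_id,
                    fluxes=mean_flux,
                    objective_value=obj if status == "optimal" else 0.0,
                    status=status,
                )
            )
    return out


def single_reaction_essentiality(
    model: MetabolicModel,
    medium: MediumDefinition,
    method: str = "fba",
    threshold: float = 0.05,
) -> dict[str, bool]:
    """Essentiality call for every reaction under one medium.

    Each reaction in turn is bounded to [0, 0] and growth recomputed by FBA
    or MOMA (against the wild-type reference); a reaction is essential when
    mutant growth falls below ``threshold`` times wild-type growth.
    """
    if method not in ("fba", "moma"):
        raise ValueError(f"unknown essentiality method {method!r}")
    conditioned = set_medium(model, medium)
    wt = wildtype_reference(conditioned, condition_id=medium.condition_id)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ValueError(
            "wild-type growth is zero on this medium; essentiality undefined"
        )
    calls: dict[str, bool] = {}
    for rxn_id in conditioned.reaction_ids:
        ko = conditioned.with_bounds({rxn_id: (0.0, 0.0)})
        if method == "fba":
            mut = fba(ko, strain_id=f"d{rxn_id}", condition_id=medium.condition_id)
        else:
            mut = moma(ko, wt, strain_id=f"d{rxn_id}")
        calls[rxn_id] = mut.objective_value < threshold * wt.objective_value
    return calls
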