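"""Constraint-based optimization: FBA, cycle-free FBA, linear MOMA,
knockouts, essentiality scans, gap-fill pruning and phenotype phase planes.

All linear programs share the steady-state constraint ``N v = 0`` with the
model's flux bounds and are solved with the HiGHS solvers behind
:func:`scipy.optimize.linprog`.  Fluxes below ``ZERO_TOL`` in magnitude are
reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelValidationError, evaluate_gene_rule

__all__ = [
    "FluxState",
    "KnockoutResult",
    "PhasePlane",
    "GapfillPruneResult",
    "solve_fba",
    "solve_cycle_free",
    "solve_linear_moma",
    "flux_variability",
    "gene_knockout_growth",
    "essentiality_scan",
    "prune_gapfill_reactions",
    "phase_plane",
]

#: reported-zero tolerance for fluxes (LP numerics)
ZERO_TOL = 1e-6
#: tolerance used when classifying a reaction as blocked
BLOCKED_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxState:
    """One steady-state flux vector.

    ``flux`` maps reaction ids to values in mmol h-1 gDCW-1 (the biomass
    reaction carries h-1).  ``objective_value`` and ``status`` report the
    solver outcome honestly: on infeasible/unbounded problems no flux vector
    is fabricated and ``flux`` is empty.
    """

    flux: dict[str, float]
    objective_value: float
    status: Literal["optimal", "infeasible", "unbounded", "error"]
    objective_id: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.flux[rid] for rid in reaction_ids])


@dataclass
class KnockoutResult:
    gene: str
    growth_ratio: float
    method: Literal["fba", "moma"]
    wild_type_growth: float
    knockout_growth: float


@dataclass
class GapfillPruneResult:
    retained: list[str]
    discarded: list[str]
    model: MetabolicModel


def _clean(x: float) -> float:
    return 0.0 if abs(x) < ZERO_TOL else float(x)


def _run_lp(model: MetabolicModel, c: np.ndarray, *, a_ub=None, b_ub=None,
            extra_bounds: dict[str, tuple[float, float]] | None = None):
    """Solve min c.v subject to N v = 0 and the model bounds.

    ``extra_bounds`` temporarily overrides per-reaction bounds (intersection
    is NOT taken; the override wins, as used by clamping scans).
    """
    rids = model.reaction_ids
    S = model.stoichiometric_matrix()
    bounds = []
    for rid in rids:
        if extra_bounds and rid in extra_bounds:
            bounds.append(extra_bounds[rid])
        else:
            rxn = model.reactions[rid]
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    n = len(rids)
    if a_ub is not None:
        c_full = c
    else:
        c_full = c[:n] if len(c) > n else c
    res = linprog(
        c_full,
        A_eq=S if a_ub is None else np.hstack([S, np.zeros((S.shape[0], len(c) - n))]),
        b_eq=np.zeros(S.shape[0]),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=bounds if a_ub is None else bounds + [(0, None)] * (len(c) - n),
        method="highs",
    )
    return res, rids


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: Literal["max", "min"] = "max",
) -> FluxState:
    """Flux balance analysis: optimize one reaction's flux at steady state.

    Returns an optimal vertex of ``{N v = 0, lb <= v <= ub}``.  Alternate
    optima are possible; use :func:`solve_cycle_free` when a representative
    loopless vector is needed.
    """
    obj = objective_id or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise ModelValidationError(f"objective reaction {obj!r} not in model")
    rids = model.reaction_ids
    c = np.zeros(len(rids))
    c[rids.index(obj)] = -1.0 if direction == "max" else 1.0
    res, rids = _run_lp(model, c)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxState({}, float("nan"),
                         status if status in ("infeasible", "unbounded") else "error",
                         objective_id=obj)
    flux = {rid: _clean(v) for rid, v in zip(rids, res.x)}
    return FluxState(flux, flux[obj], "optimal", objective_id=obj)


def solve_cycle_free(model: MetabolicModel, objective_id: str | None = None) -> FluxState:
    """Cycle-free FBA: an FBA optimum post-processed to strip internal cycles.

    Stage one is plain FBA.  Stage two minimizes the summed absolute internal
    flux subject to (i) steady state, (ii) every exchange flux fixed to its
    stage-one value, (iii) the objective flux fixed, and (iv) each internal
    flux confined to the closed interval between 0 and its stage-one value
    (a sign-preserving shrink).  The objective value is preserved exactly and
    no internal flux magnitude can grow, so thermodynamically infeasible
    loops that carry removable circulating flux are drained to zero.
    """
    obj = objective_id or model.objective_reaction_id
    first = solve_fba(model, obj)
    if not first.ok:
        return first
    rids = model.reaction_ids
    exchange_ids = {r.id for r in model.exchanges()}
    extra: dict[str, tuple[float, float]] = {}
    c = np.zeros(len(rids))
    for i, rid in enumerate(rids):
        v = first.flux[rid]
        if rid in exchange_ids or rid == obj:
            extra[rid] = (v, v)
        else:
            extra[rid] = (min(0.0, v), max(0.0, v))
            c[i] = np.sign(v)  # |v_i| == sign(v_i) * v_i on the shrunk box
    res, _ = _run_lp(model, c, extra_bounds=extra)
    if res.status != 0:  # fall back to the stage-one vertex (degenerate numerics)
        return first
    flux = {rid: _clean(v) for rid, v in zip(rids, res.x)}
    return FluxState(flux, flux[obj], "optimal", objective_id=obj)


def solve_linear_moma(model_ko: MetabolicModel, reference: FluxState) -> FluxState:
    """Linearized minimization of metabolic adjustment.

    Minimizes the L1 distance ``sum_i |v_i - v_ref_i|`` subject to the
    knockout model's constraints, via auxiliary variables ``d_i >= |v_i -
    v_ref_i|``.  The returned state carries the achieved flux through the
    reference's objective reaction as its objective value, and the attained
    L1 distance in ``moma_distance``.
    """
    if not reference.ok:
        raise ValueError("MOMA requires an optimal reference flux state")
    rids = model_ko.reaction_ids
    missing = [rid for rid in rids if rid not in reference.flux]
    if missing:
        raise ValueError(f"reference lacks fluxes for reactions {missing[:5]}")
    n = len(rids)
    ref = np.array([reference.flux[rid] for rid in rids])
    # variables x = [v (n), d (n)]; minimize sum d
    c = np.concatenate([np.zeros(n), np.ones(n)])
    eye = np.eye(n)
    a_ub = np.vstack([
        np.hstack([eye, -eye]),    # v - d <= ref
        np.hstack([-eye, -eye]),   # -v - d <= -ref
    ])
    b_ub = np.concatenate([ref, -ref])
    res, _ = _run_lp(model_ko, c, a_ub=a_ub, b_ub=b_ub)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxState({}, float("nan"),
                         status if status in ("infeasible", "unbounded") else "error",
                         objective_id=reference.objective_id)
    flux = {rid: _clean(v) for rid, v in zip(rids, res.x[:n])}
    obj = reference.objective_id
    state = FluxState(flux, flux.get(obj, float("nan")), "optimal", objective_id=obj)
    state.moma_distance = _clean(res.fun)
    return state


def flux_variability(
    model: MetabolicModel, reaction_ids: Iterable[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-reaction feasible flux range (min, max) under current bounds."""
    rids = model.reaction_ids
    targets = list(reaction_ids) if reaction_ids is not None else rids
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        lo = solve_fba(model, rid, "min")
        hi = solve_fba(model, rid, "max")
        if not (lo.ok and hi.ok):
            raise RuntimeError(f"flux variability failed on {rid!r}: model infeasible")
        out[rid] = (lo.objective_value, hi.objective_value)
    return out


def _delete_genes(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    ko = model.copy()
    for rxn in ko.reactions.values():
        if not evaluate_gene_rule(rxn.gene_rule, genes, known_genes=model.genes):
            rxn.bounds = (0.0, 0.0)
    return ko


def gene_knockout_growth(
    model: MetabolicModel,
    gene: str,
    method: Literal["fba", "moma"] = "fba",
    wild_type: FluxState | None = None,
) -> KnockoutResult:
    """Growth after a single in-silico gene knockout.

    Reactions whose gene rule evaluates inactive are clamped to zero flux.
    ``method="fba"`` reoptimizes growth; ``method="moma"`` minimizes the L1
    adjustment from the wild-type cycle-free FBA reference and reports the
    growth the adjusted state achieves.
    """
    if gene not in model.genes:
        raise KeyError(f"unknown gene {gene!r}")
    if wild_type is None:
        wild_type = solve_cycle_free(model)
    if not wild_type.ok or wild_type.objective_value <= 0:
        raise ValueError("wild-type model must grow before knockouts are scanned")
    ko = _delete_genes(model, [gene])
    if method == "fba":
        state = solve_fba(ko)
    elif method == "moma":
        state = solve_linear_moma(ko, wild_type)
    else:
        raise ValueError(f"unknown knockout method {method!r}")
    growth = state.objective_value if state.ok else 0.0
    growth = max(growth, 0.0)
    return KnockoutResult(
        gene=gene,
        growth_ratio=growth / wild_type.objective_value,
        method=method,
        wild_type_growth=wild_type.objective_value,
        knockout_growth=growth,
    )


def essentiality_scan(
    model: MetabolicModel,
    method: Literal["fba", "moma"] = "fba",
    threshold: float = 0.01,
) -> set[str]:
    """Genes whose single knockout drops growth below ``threshold`` x wild type."""
    wild_type = solve_cycle_free(model)
    essential = set()
    for gene in model.genes:
        result = gene_knockout_growth(model, gene, method, wild_type=wild_type)
        if result.growth_ratio < threshold:
            essential.add(gene)
    return essential


def prune_gapfill_reactions(
    model: MetabolicModel,
    candidate_ids: Sequence[str],
    threshold: float = 0.01,
) -> GapfillPruneResult:
    """Leave-one-out pruning of gap-fill candidate reactions.

    Each candidate is removed singly from the full model; it is retained iff
    its removal drops growth below ``threshold`` times the full model's
    growth (i.e. it is essential to in-silico biomass production).  The
    returned model has the discarded candidates removed.
    """
    base = solve_fba(model)
    if not base.ok or base.objective_value <= 0:
        raise ValueError("model with all candidates included must grow")
    retained, discarded = [], []
    for rid in candidate_ids:
        if rid not in model.reactions:
            raise KeyError(f"candidate reaction {rid!r} not in model")
        probe = model.copy()
        probe.reactions[rid].bounds = (0.0, 0.0)
        state = solve_fba(probe)
        growth = state.objective_value if state.ok else 0.0
        if growth < threshold * base.objective_value:
            retained.append(rid)
        else:
            discarded.append(rid)
    pruned = model.copy()
    for rid in discarded:
        del pruned.reactions[rid]
    return GapfillPruneResult(retained=retained, discarded=discarded, model=pruned)


@dataclass
class PhasePlane:
    """A two-uptake phenotype phase plane.

    ``objective_values[i, j]`` is the optimized objective with reaction A
    clamped to uptake magnitude ``grid_a[i]`` and reaction B to
    ``grid_b[j]``; infeasible cells hold 0 with ``feasible[i, j]`` False.
    ``ridge_slope`` is the through-origin slope of the B-magnitude that
    maximizes the objective at each A-magnitude (the optimal-ratio line).
    """

    reaction_a: str
    reaction_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    objective_values: np.ndarray
    feasible: np.ndarray
    ridge_b: np.ndarray = field(default=None)
    ridge_slope: float = float("nan")


def phase_plane(
    model: MetabolicModel,
    rxn_a: str,
    rxn_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    objective_id: str | None = None,
) -> PhasePlane:
    """Optimize the objective over a grid of two clamped exchange uptakes.

    Each axis reaction is clamped (``lb = ub = -magnitude``); grids carry
    non-negative uptake magnitudes.
    """
    for rid in (rxn_a, rxn_b):
        if rid not in model.reactions or not model.reactions[rid].is_exchange:
            raise ModelValidationError(f"phase plane axis {rid!r} must be an exchange reaction")
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.size == 0 or grid_b.size == 0 or (grid_a < 0).any() or (grid_b < 0).any():
        raise ValueError("phase plane grids must be non-empty, non-negative magnitudes")
    obj = objective_id or model.objective_reaction_id
    values = np.zeros((grid_a.size, grid_b.size))
    feasible = np.zeros_like(values, dtype=bool)
    work = model.copy()
    for i, a in enumerate(grid_a):
        work.reactions[rxn_a].bounds = (-a, -a)
        for j, b in enumerate(grid_b):
            work.reactions[rxn_b].bounds = (-b, -b)
            state = solve_fba(work, obj)
            if state.ok:
                values[i, j] = max(state.objective_value, 0.0)
                feasible[i, j] = True
    ridge_b = np.array([
        grid_b[np.argmax(values[i])] if feasible[i].any() else np.nan
        for i in range(grid_a.size)
    ])
    mask = (grid_a > 0) & ~np.isnan(ridge_b) & (values.max(axis=1) > ZERO_TOL)
    if mask.any():
        slope = float(np.dot(grid_a[mask], ridge_b[mask]) / np.dot(grid_a[mask], grid_a[mask]))
    else:
        slope = float("nan")
    return PhasePlane(rxn_a, rxn_b, grid_a, grid_b, values, feasible, ridge_b, slope)
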