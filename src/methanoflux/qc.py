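"""Model quality checks: blocked reactions and orphan (no-GPR) reactions."""

from __future__ import annotations

from dataclasses import dataclass

from .model import MetabolicModel
from .solvers import BLOCKED_TOL, flux_variability, solve_fba

__all__ = ["ModelQcReport", "model_qc"]


@dataclass
class ModelQcReport:
    """Sets of reaction ids flagged by quality control.

    ``clamped_reaction_ids`` are reactions purposely bounded to exactly zero
    flux (lb = ub = 0); ``blocked_reaction_ids`` additionally includes
    reactions that cannot carry flux under the current bounds for structural
    reasons (min and max feasible flux both zero).  Orphans carry no
    gene-protein-reaction association.
    """

    blocked_reaction_ids: set[str]
    clamped_reaction_ids: set[str]
    orphan_reaction_ids: set[str]
    exchange_orphan_ids: set[str]


def model_qc(model: MetabolicModel) -> ModelQcReport:
    """Report blocked, clamped and orphan reactions.

    Blocked status is determined by per-reaction min/max optimization under
    the current bounds (|flux| < 1e-9 counts as zero), so the result is
    invariant to reaction order and to positive scaling of all bounds.
    Raises if the model itself is infeasible.
    """
    probe = solve_fba(model)
    if probe.status == "infeasible":
        raise ValueError("model is infeasible under current bounds; cannot scan")
    clamped = {
        r.id
        for r in model.reactions.values()
        if r.lower_bound == 0.0 and r.upper_bound == 0.0
    }
    open_ids = [rid for rid in model.reaction_ids if rid not in clamped]
    ranges = flux_variability(model, open_ids)
    blocked = set(clamped)
    for rid, (lo, hi) in ranges.items():
        if abs(lo) < BLOCKED_TOL and abs(hi) < BLOCKED_TOL:
            blocked.add(rid)
    orphan = {r.id for r in model.reactions.values() if r.gene_rule.is_empty}
    exchange = {r.id for r in model.exchanges()}
    return ModelQcReport(
        blocked_reaction_ids=blocked,
        clamped_reaction_ids=clamped,
        orphan_reaction_ids=orphan,
        exchange_orphan_ids=orphan & exchange,
    )
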