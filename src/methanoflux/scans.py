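"""Integrative FBA scans: measurement-parametrized models, pathway flux
summaries, oxygen-to-methane ratio scans, excretion-fraction profiles,
growth-excretion coupling scans, and PCA of normalized flux states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import FluxEstimateSet
from .model import MetabolicModel, ModelValidationError
from .solvers import ZERO_TOL, FluxState, solve_cycle_free, solve_fba

__all__ = [
    "ParametrizedModel",
    "ScanResult",
    "PathwayFluxSummary",
    "FluxPcaResult",
    "parametrize_model",
    "summarize_pathway_flux",
    "ratio_scan",
    "excretion_fraction_profile",
    "coupling_scan",
    "flux_state_pca",
]


@dataclass
class ParametrizedModel:
    """A model with measured-flux CI99 bounds imposed on mapped reactions."""

    model: MetabolicModel
    overrides: dict[str, tuple[float, float]]
    provenance: str = ""

    def solve(self, objective_id: str | None = None) -> FluxState:
        """Cycle-free FBA on the parametrized model."""
        return solve_cycle_free(self.model, objective_id)


def parametrize_model(
    model: MetabolicModel,
    estimates: FluxEstimateSet,
    mapping: Mapping[str, str],
    provenance: str = "",
) -> ParametrizedModel:
    """Impose measured flux CI99 intervals as reaction bounds.

    ``mapping`` links estimate names to reaction ids; the key ``"growth"``
    maps the measured growth rate onto the biomass reaction.  Estimated
    fluxes follow the sign convention of the estimators (uptake negative),
    so the CI99 interval is applied directly as (lower, upper) bounds.
    Raises with the offending constraint names if the intervals are jointly
    infeasible.
    """
    out = model.copy()
    overrides: dict[str, tuple[float, float]] = {}
    for name, rid in mapping.items():
        if rid not in out.reactions:
            raise ModelValidationError(f"mapped reaction {rid!r} not in model")
        if name == "growth":
            est = estimates.growth_rate
        elif name in estimates.fluxes:
            est = estimates.fluxes[name]
        else:
            raise KeyError(f"no estimate named {name!r}")
        out.reactions[rid].bounds = (est.ci_lower, est.ci_upper)
        overrides[rid] = (est.ci_lower, est.ci_upper)
    state = solve_fba(out)
    if state.status == "infeasible":
        culprits = []
        for rid in overrides:
            probe = out.copy()
            probe.reactions[rid].bounds = model.reactions[rid].bounds
            if solve_fba(probe).ok:
                culprits.append(rid)
        raise ModelValidationError(
            "measured-flux intervals are jointly infeasible; relaxing any of "
            f"{culprits or sorted(overrides)} restores feasibility"
        )
    return ParametrizedModel(model=out, overrides=overrides, provenance=provenance)


@dataclass
class PathwayFluxSummary:
    """Mean absolute flux per pathway tag and over the whole network.

    Values are stored untransformed; any log-display offset is a plotting
    concern, never applied here.
    """

    pathway_means: dict[str, float]
    network_mean: float


def summarize_pathway_flux(state: FluxState, model: MetabolicModel) -> PathwayFluxSummary:
    """Arithmetic mean of |flux| per pathway tag and network-wide."""
    if not state.ok:
        raise ValueError("pathway summary requires an optimal flux state")
    groups: dict[str, list[float]] = {}
    all_values: list[float] = []
    for rid, rxn in model.reactions.items():
        v = abs(state.flux.get(rid, 0.0))
        tag = rxn.pathway or "unassigned"
        groups.setdefault(tag, []).append(v)
        all_values.append(v)
    return PathwayFluxSummary(
        pathway_means={tag: float(np.mean(vs)) for tag, vs in groups.items()},
        network_mean=float(np.mean(all_values)),
    )


@dataclass
class ScanResult:
    """Objective values over a grid of one controlled variable.

    ``objective_values[obj][i]`` is the optimum with the controlled
    reaction clamped at ``grid[i]``; infeasible points carry 0 with
    ``feasible[obj][i]`` False.
    """

    variable: str
    grid: np.ndarray
    objective_values: dict[str, np.ndarray]
    feasible: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def argmax(self, objective: str) -> float:
        """Grid value at which ``objective`` is maximal (first maximizer)."""
        return float(self.grid[int(np.argmax(self.objective_values[objective]))])


def ratio_scan(
    model: MetabolicModel,
    ch4_flux: float = 10.0,
    o2_grid: Sequence[float] | None = None,
    objectives: Sequence[str] = ("biomass_c",),
    ch4_exchange: str = "EX_ch4_e",
    o2_exchange: str = "EX_o2_e",
) -> ScanResult:
    """Scan the oxygen uptake flux at a fixed methane uptake flux.

    The methane exchange is clamped (lb = ub) at ``-ch4_flux``; for each
    oxygen grid magnitude the oxygen exchange is clamped likewise and each
    objective is maximized independently.  The default grid has 701 points
    over [0, 30] mmol h-1 gDCW-1.  The grid is reported both as oxygen flux
    and as the oxygen:methane ratio.
    """
    if o2_grid is None:
        o2_grid = np.linspace(0.0, 30.0, 701)
    o2_grid = np.asarray(o2_grid, dtype=float)
    if not np.all(np.diff(o2_grid) > 0):
        raise ValueError("oxygen grid must be strictly increasing")
    for obj in objectives:
        if obj not in model.reactions:
            raise ModelValidationError(f"objective reaction {obj!r} not in model")
    work = model.copy()
    work.reactions[ch4_exchange].bounds = (-ch4_flux, -ch4_flux)
    values = {obj: np.zeros(o2_grid.size) for obj in objectives}
    feas = {obj: np.zeros(o2_grid.size, dtype=bool) for obj in objectives}
    for i, o2 in enumerate(o2_grid):
        work.reactions[o2_exchange].bounds = (-o2, -o2)
        for obj in objectives:
            state = solve_fba(work, obj)
            if state.ok:
                values[obj][i] = max(state.objective_value, 0.0)
                feas[obj][i] = True
    return ScanResult(
        variable=f"{o2_exchange} uptake magnitude",
        grid=o2_grid,
        objective_values=values,
        feasible=feas,
        metadata={
            "ch4_flux": ch4_flux,
            "ratio_grid": o2_grid / ch4_flux,
            "ch4_exchange": ch4_exchange,
            "o2_exchange": o2_exchange,
        },
    )


def excretion_fraction_profile(
    scan: ScanResult,
    metabolites: Mapping[str, str] | Sequence[str] = (
        "EX_co2_e",
        "EX_for_e",
        "EX_ac_e",
    ),
) -> pd.DataFrame:
    """Per-ratio fractions of the independently maximized excretion fluxes.

    At each grid point the fraction of metabolite m is its maximum
    excretion flux divided by the sum over the listed metabolites'
    maxima; where the denominator is zero the fractions are NaN and
    ``defined`` is False.  Fractions sum to 1 wherever defined.
    """
    if isinstance(metabolites, Mapping):
        names, rids = list(metabolites), list(metabolites.values())
    else:
        rids = list(metabolites)
        names = rids
    missing = [rid for rid in rids if rid not in scan.objective_values]
    if missing:
        raise KeyError(f"scan lacks max-excretion objectives for {missing}")
    fluxes = np.vstack([scan.objective_values[rid] for rid in rids])
    total = fluxes.sum(axis=0)
    defined = total > ZERO_TOL
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(defined, fluxes / np.where(defined, total, 1.0), np.nan)
    out = pd.DataFrame(
        {name: fractions[k] for k, name in enumerate(names)},
        index=pd.Index(scan.metadata.get("ratio_grid", scan.grid), name="ratio"),
    )
    out["defined"] = defined
    return out


def coupling_scan(
    model: MetabolicModel,
    excretion_exchange: str,
    n_levels: int = 500,
    uptake_bound: float = 10.0,
    ch4_exchange: str = "EX_ch4_e",
    o2_exchange: str = "EX_o2_e",
    objective_id: str | None = None,
) -> ScanResult:
    """Growth-versus-excretion coupling curve.

    Both gas uptakes are bounded (lb, ub) = (-uptake_bound, 0), so the
    model adjusts its own oxygen:methane uptake ratio; the excretion flux
    is clamped at each of ``n_levels`` evenly spaced values from 0 to its
    unconstrained maximum, and growth is maximized at each level.
    """
    if excretion_exchange not in model.reactions or not model.reactions[
        excretion_exchange
    ].is_exchange:
        raise ModelValidationError(
            f"{excretion_exchange!r} is not an exchange reaction of the model"
        )
    work = model.copy()
    work.reactions[ch4_exchange].bounds = (-uptake_bound, 0.0)
    work.reactions[o2_exchange].bounds = (-uptake_bound, 0.0)
    top_state = solve_fba(work, excretion_exchange)
    if not top_state.ok:
        raise ValueError(f"cannot establish maximal excretion of {excretion_exchange!r}")
    top = max(top_state.objective_value, 0.0)
    grid = np.linspace(0.0, top, n_levels)
    obj = objective_id or model.objective_reaction_id
    values = np.zeros(grid.size)
    feas = np.zeros(grid.size, dtype=bool)
    for i, level in enumerate(grid):
        work.reactions[excretion_exchange].bounds = (level, level)
        state = solve_fba(work, obj)
        if state.ok:
            values[i] = max(state.objective_value, 0.0)
            feas[i] = True
    return ScanResult(
        variable=f"{excretion_exchange} clamp level",
        grid=grid,
        objective_values={obj: values},
        feasible={obj: feas},
        metadata={
            "excretion_exchange": excretion_exchange,
            "uptake_bound": uptake_bound,
            "unconstrained_max": top,
            "objective": obj,
        },
    )


@dataclass
class FluxPcaResult:
    """PCA of methane-normalized flux states.

    ``scores`` is samples x components, ``loadings`` reactions x
    components (orthonormal columns), ``explained_variance_ratio`` the
    per-component variance fractions.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    labels: list[str]

    def top_loadings(self, component: int = 0, n: int = 5) -> pd.Series:
        col = self.loadings.columns[component]
        return self.loadings[col].abs().sort_values(ascending=False).head(n)


def flux_state_pca(
    states: Mapping[str, FluxState],
    ch4_exchange: str = "EX_ch4_e",
    ch4_fluxes: Mapping[str, float] | None = None,
    scale: bool = False,
    n_components: int | None = None,
) -> FluxPcaResult:
    """PCA of flux vectors normalized to the methane-specific uptake rate.

    Each state's flux vector is divided by its methane uptake magnitude
    (taken from the state itself, or from ``ch4_fluxes`` when supplied),
    centered, optionally unit-variance scaled, and decomposed with a
    covariance-mode PCA.  All states must share one reaction set.
    """
    if len(states) < 2:
        raise ValueError("PCA needs at least two flux states")
    labels = list(states)
    reaction_sets = {label: frozenset(s.flux) for label, s in states.items()}
    common = reaction_sets[labels[0]]
    for label, rset in reaction_sets.items():
        if rset != common:
            raise ValueError(
                f"flux state {label!r} has a different reaction set; "
                "states must share one model"
            )
    rids = sorted(common)
    rows = []
    for label in labels:
        state = states[label]
        if ch4_fluxes is not None and label in ch4_fluxes:
            ch4 = abs(ch4_fluxes[label])
        else:
            ch4 = abs(state.flux.get(ch4_exchange, 0.0))
        if ch4 <= ZERO_TOL:
            raise ValueError(f"state {label!r} has no methane uptake to normalize by")
        rows.append(state.vector(rids) / ch4)
    X = np.vstack(rows)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    from sklearn.decomposition import PCA

    k = n_components or min(len(labels) - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return FluxPcaResult(
        scores=pd.DataFrame(scores, index=labels, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=rids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        labels=labels,
    )
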