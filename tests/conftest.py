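"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methanoflux import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_reduced_network,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_model() -> MetabolicModel:
    return build_reduced_network()


@pytest.fixture()
def fresh_reduced_model(reduced_model) -> MetabolicModel:
    return reduced_model.copy()


def make_chain_model() -> MetabolicModel:
    """EX_a -> (a -> b) -> EX_b, uptake capped at 10."""
    model = MetabolicModel(
        model_id="chain",
        metabolites=[Metabolite("a", compartment="e"), Metabolite("b", compartment="e")],
    )
    model.add_reaction(Reaction("EX_a", {"a": -1}, -10, 0, is_exchange=True))
    model.add_reaction(Reaction("conv", {"a": -1, "b": 1}, 0, 1000))
    model.add_reaction(Reaction("EX_b", {"b": -1}, 0, 1000, is_exchange=True))
    model.objective_reaction_id = "EX_b"
    return model


@pytest.fixture()
def chain_model() -> MetabolicModel:
    return make_chain_model()


# ---------------------------------------------------------------------------
# independent FBA oracle: brute-force basic-feasible-solution enumeration
# ---------------------------------------------------------------------------


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-8) -> list[np.ndarray]:
    """All basic feasible solutions of {S v = 0, lb <= v <= ub}.

    A vertex fixes n - rank(S) variables at one of their bounds and solves
    the equality system for the rest; candidates violating feasibility are
    discarded.  Exponential — only for tiny systems.
    """
    n = S.shape[1]
    r = np.linalg.matrix_rank(S)
    vertices: list[np.ndarray] = []
    for basic in itertools.combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        A = S[:, basic]
        if np.linalg.matrix_rank(A) < r:
            continue
        for choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            rhs = -S[:, nonbasic] @ np.array(choice) if nonbasic else np.zeros(S.shape[0])
            x_basic, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            v[list(basic)] = x_basic
            v[nonbasic] = choice
            if np.max(np.abs(S @ v)) > tol * (1 + np.max(np.abs(v))):
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            vertices.append(v)
    return vertices


def brute_force_fba(model: MetabolicModel, objective_id: str) -> float:
    """Best objective over all enumerated vertices (independent of HiGHS)."""
    S = model.stoichiometric_matrix()
    rids = model.reaction_ids
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return float("nan")
    j = rids.index(objective_id)
    return max(v[j] for v in vertices)


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """A random bounded, feasible model with <= 8 reactions.

    Zero flux is always feasible (all bounds straddle 0) and all bounds are
    finite, so the LP is neither infeasible nor unbounded.
    """
    n_mets = rng.integers(2, 5)
    n_rxns = rng.integers(3, 9)
    model = MetabolicModel(model_id="random")
    for i in range(n_mets):
        model.add_metabolite(Metabolite(f"m{i}"))
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            coef = rng.integers(-2, 3)
            if coef:
                stoich[f"m{i}"] = float(coef)
        if not stoich:
            stoich[f"m{rng.integers(0, n_mets)}"] = 1.0
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        model.add_reaction(Reaction(f"r{j}", stoich, lb, ub))
    model.objective_reaction_id = f"r{rng.integers(0, n_rxns)}"
    return model
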