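"""Four facets of network stability evaluated at ecological equilibrium.

* persistence — percentage of the initial species pool with abundance above
  the extinction threshold at equilibrium (both guilds pooled).
* feasibility — percentage of growth-rate replicates whose persistence
  exceeds 98% (tolerating the loss of one species in communities of more
  than 50 species, none otherwise).
* resilience — ``-max(Re(lambda))`` of the Jacobian of the system restricted
  to surviving species; inverse of the return time after a small
  perturbation.
* robustness — mean percentage of the remaining community surviving the
  forced removal of one surviving hummingbird, after re-equilibration.

Undefined metrics (no survivors, no surviving hummingbird, singleton
community) are returned as ``None`` and must be written as missing values,
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import MonthlyInteractionTable
from .dynamics import (
    CommunityState,
    EquilibriumResult,
    ModelParameters,
    MutualismSystem,
    integrate_to_equilibrium,
)
from .seasonal import SeasonalStructure

__all__ = [
    "StabilityReport",
    "persistence",
    "feasibility",
    "jacobian_at",
    "resilience",
    "robustness",
]


@dataclass
class StabilityReport:
    persistence_pct: float
    diversity: int
    resilience: float | None
    robustness_pct: float | None
    resilience_defined: bool
    robustness_defined: bool


def persistence(result: EquilibriumResult) -> float:
    """Percentage of initial species surviving (strictly above threshold)."""
    n_total = result.survivors_p.size + result.survivors_h.size
    return 100.0 * result.n_survivors / n_total


def feasibility(persistences) -> float:
    """Percentage of replicates with persistence strictly greater than 98%."""
    values = np.asarray(list(persistences), dtype=float)
    if values.size == 0:
        raise ValueError("feasibility requires at least one persistence value")
    return 100.0 * float((values > 98.0).sum()) / values.size


def jacobian_at(
    result: EquilibriumResult,
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
    params: ModelParameters,
    *,
    rel_step: float = 1e-6,
    system: MutualismSystem | None = None,
) -> np.ndarray | None:
    """Jacobian of the dynamics restricted to surviving species.

    Central finite differences on the full right-hand side with extinct
    species pinned at 0; because the competition coefficients are
    state-dependent, numerical differentiation captures their product-rule
    terms automatically.  Returns ``None`` when there are no survivors.
    """
    sys = system if system is not None else MutualismSystem(table.I, structure)
    y0 = np.concatenate([result.state.H, result.state.P])
    alive = np.concatenate([result.survivors_h, result.survivors_p])
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return None

    def g(z: np.ndarray) -> np.ndarray:
        y = y0.copy()
        y[idx] = z
        return sys.rhs_flat(0.0, y, params)[idx]

    z0 = y0[idx]
    J = np.empty((idx.size, idx.size))
    for m in range(idx.size):
        h = max(rel_step, rel_step * abs(z0[m]))
        zp, zm = z0.copy(), z0.copy()
        zp[m] += h
        zm[m] -= h
        J[:, m] = (g(zp) - g(zm)) / (2.0 * h)
    return J


def resilience(
    result: EquilibriumResult,
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
    params: ModelParameters,
    *,
    system: MutualismSystem | None = None,
) -> float | None:
    """-max(Re(lambda)) of the surviving-subsystem Jacobian; None if no survivors."""
    J = jacobian_at(result, table, structure, params, system=system)
    if J is None:
        return None
    return float(-np.max(np.linalg.eigvals(J).real))


def robustness(
    result: EquilibriumResult,
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
    params: ModelParameters,
    *,
    include_removed: bool = False,
    system: MutualismSystem | None = None,
    **integrate_kwargs,
) -> float | None:
    """Mean survival after single hummingbird removals, re-equilibrated.

    For each surviving hummingbird ``j``, its abundance is set to 0 and the
    system is integrated onward from the perturbed equilibrium state until a
    new equilibrium is reached.  Each experiment scores
    ``100 * survivors among the pre-removal survivors (excluding j) /
    (pre-removal survivors - 1)``; the removed species is a forced, not a
    secondary, extinction (set ``include_removed=True`` to count it).
    Undefined (``None``) when no hummingbird survives or when the community
    has a single surviving species.
    """
    sys = system if system is not None else MutualismSystem(table.I, structure)
    birds = np.flatnonzero(result.survivors_h)
    n_before = result.n_survivors
    if birds.size == 0 or n_before <= 1:
        return None
    baseline_alive = np.concatenate([result.survivors_h, result.survivors_p])
    scores = []
    for j in birds:
        H = result.state.H.copy()
        H[j] = 0.0
        res2 = integrate_to_equilibrium(
            table,
            structure,
            params,
            initial_state=CommunityState(H=H, P=result.state.P.copy()),
            system=sys,
            **integrate_kwargs,
        )
        after = np.concatenate([res2.survivors_h, res2.survivors_p])
        removed = np.zeros_like(after)
        removed[j] = True
        survived = after & baseline_alive & ~removed
        if include_removed:
            scores.append(100.0 * survived.sum() / n_before)
        else:
            scores.append(100.0 * survived.sum() / (n_before - 1))
    return float(np.mean(scores))
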