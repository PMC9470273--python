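"""Equilibrium network descriptors: connectance, interaction overlap,
total abundance and diversity.

Connectance is the mean of the phenology-corrected network matrix
``N = I * O`` over surviving species.  Interaction overlap is the mean of the
within-guild competition matrices Omega and Theta recomputed on the surviving
sub-community with every abundance set to 1 — a measure of effective
within-guild competition (functional redundancy) independent of abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import MonthlyInteractionTable
from .dynamics import EquilibriumResult, MutualismSystem
from .seasonal import SeasonalStructure

__all__ = [
    "IndexReport",
    "restrict_to_survivors",
    "connectance",
    "interaction_overlap",
    "total_abundance",
    "diversity",
]


@dataclass
class IndexReport:
    connectance: float | None
    interaction_overlap: float | None
    total_abundance: float
    diversity: int


def restrict_to_survivors(
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
    survivors_p: np.ndarray,
    survivors_h: np.ndarray,
) -> tuple[np.ndarray, SeasonalStructure]:
    """Backbone and overlap arrays restricted to surviving species."""
    mp = np.flatnonzero(survivors_p)
    mh = np.flatnonzero(survivors_h)
    I = table.I[np.ix_(mp, mh)]
    sub = SeasonalStructure(
        O=structure.O[np.ix_(mp, mh)],
        Mh=structure.Mh[np.ix_(mp, mh, mh)],
        Mp=structure.Mp[np.ix_(mh, mp, mp)],
    )
    return I, sub


def connectance(
    result: EquilibriumResult,
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
) -> float | None:
    """Mean of N = I * O over surviving species; None if a guild died out."""
    if not (result.survivors_p.any() and result.survivors_h.any()):
        return None
    I, sub = restrict_to_survivors(table, structure, result.survivors_p, result.survivors_h)
    return float((I * sub.O).mean())


def interaction_overlap(
    result: EquilibriumResult,
    table: MonthlyInteractionTable,
    structure: SeasonalStructure,
    *,
    include_diagonal: bool = True,
) -> float | None:
    """Mean of Omega and Theta (pooled) at unit abundances over survivors.

    Diagonal (self-overlap) entries are included by default; set
    ``include_diagonal=False`` to average off-diagonal pairs only.
    """
    if not (result.survivors_p.any() and result.survivors_h.any()):
        return None
    I, sub = restrict_to_survivors(table, structure, result.survivors_p, result.survivors_h)
    sys = MutualismSystem(I, sub)
    Om = sys.omega(np.ones(sys.n_plants))
    Th = sys.theta(np.ones(sys.n_birds))
    if include_diagonal:
        pooled = np.concatenate([Om.ravel(), Th.ravel()])
    else:
        off = lambda M: M[~np.eye(M.shape[0], dtype=bool)]
        pooled = np.concatenate([off(Om), off(Th)])
        if pooled.size == 0:
            return None
    return float(pooled.mean())


def total_abundance(result: EquilibriumResult) -> float:
    """Sum of surviving hummingbird and flower abundances (productivity)."""
    return float(result.state.H[result.survivors_h].sum() + result.state.P[result.survivors_p].sum())


def diversity(result: EquilibriumResult) -> int:
    """Number of surviving species (persistence expressed as a count)."""
    return result.n_survivors
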