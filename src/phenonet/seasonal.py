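"""Seasonal-structure indices: phenological overlaps among and within guilds.

From the monthly counts of a community, three objects encode its seasonal
structure:

* ``O`` (n_plants x n_birds) — among-guild overlap between a plant's
  flowering schedule and a hummingbird's activity schedule; it scales the
  per-capita strength of their mutualistic interaction.
* ``Mh`` (n_plants x n_birds x n_birds) — ``Mh[i, k, j]`` is the overlap of
  hummingbirds ``k`` and ``j`` on plant ``i``; it drives competition among
  hummingbirds for that plant.
* ``Mp`` (n_birds x n_plants x n_plants) — ``Mp[j, k, i]`` analogously for
  plants competing for hummingbird ``j``.

Normalization convention (default, ``"printed"``): plant phenologies are
normalized to sum 1 over months, hummingbird phenologies by their monthly
maximum.  Under this convention all entries lie in [0, 1]; note that under
uniform identical phenologies ``Mh = 1`` while ``Mp = 1/12`` because both
plant factors in ``Mp`` are sum-normalized.  A fully symmetric alternative
(``"symmetric"``: focal-guild partner normalized by sum, the competing pair
by max, in both arrays) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import MonthlyInteractionTable

__all__ = [
    "SeasonalStructure",
    "within_guild_overlaps",
    "among_guild_overlap",
    "compute_seasonal_structure",
    "flatten",
    "flattened_structure",
    "randomize_seasonal_structure",
    "export_structure",
    "load_structure",
]


@dataclass
class SeasonalStructure:
    """Overlap arrays O (among guilds) and Mh, Mp (within guilds)."""

    O: np.ndarray  # (n_p, n_h)
    Mh: np.ndarray  # (n_p, n_h, n_h)
    Mp: np.ndarray  # (n_h, n_p, n_p)

    @property
    def n_plants(self) -> int:
        return self.O.shape[0]

    @property
    def n_birds(self) -> int:
        return self.O.shape[1]

    def copy(self) -> "SeasonalStructure":
        return SeasonalStructure(self.O.copy(), self.Mh.copy(), self.Mp.copy())


def _normalized_phenologies(table: MonthlyInteractionTable):
    """Plant rows normalized to sum 1; bird rows normalized by their max."""
    p_sum = table.Fp.sum(axis=1)
    h_max = table.Fh.max(axis=1)
    if (p_sum == 0).any() or (h_max == 0).any():
        raise ValueError("a species has an all-zero phenology; overlaps undefined")
    return table.Fp / p_sum[:, None], table.Fh / h_max[:, None]


def among_guild_overlap(table: MonthlyInteractionTable) -> np.ndarray:
    """Among-guild overlap O[i, j] = sum_m (Fp_i/sum) * (Fh_j/max)."""
    pw, hw = _normalized_phenologies(table)
    return pw @ hw.T


def within_guild_overlaps(
    table: MonthlyInteractionTable, convention: str = "printed"
) -> tuple[np.ndarray, np.ndarray]:
    """Within-guild overlap arrays (Mh, Mp).

    ``Mh[i, k, j] = sum_m (Fp_i/sum) (Fh_k/max) (Fh_j/max)`` and, under the
    default printed convention,
    ``Mp[j, k, i] = sum_m (Fh_j/max) (Fp_k/sum) (Fp_i/sum)``.
    """
    pw, hw = _normalized_phenologies(table)
    Mh = np.einsum("im,km,jm->ikj", pw, hw, hw)
    if convention == "printed":
        Mp = np.einsum("jm,km,im->jki", hw, pw, pw)
    elif convention == "symmetric":
        # partner bird sum-normalized, competing plants max-normalized
        h_sum = table.Fh / table.Fh.sum(axis=1)[:, None]
        p_max = table.Fp / table.Fp.max(axis=1)[:, None]
        Mp = np.einsum("jm,km,im->jki", h_sum, p_max, p_max)
    else:
        raise ValueError(f"unknown overlap convention {convention!r}")
    return Mh, Mp


def compute_seasonal_structure(
    table: MonthlyInteractionTable, convention: str = "printed"
) -> SeasonalStructure:
    """All three overlap arrays for a community."""
    Mh, Mp = within_guild_overlaps(table, convention=convention)
    return SeasonalStructure(O=among_guild_overlap(table), Mh=Mh, Mp=Mp)


def flatten(structure: SeasonalStructure) -> SeasonalStructure:
    """No-seasonality variant: every overlap entry set to 1."""
    return SeasonalStructure(
        np.ones_like(structure.O), np.ones_like(structure.Mh), np.ones_like(structure.Mp)
    )


def flattened_structure(n_plants: int, n_birds: int) -> SeasonalStructure:
    """All-ones structure for given guild sizes (no-seasonality mode)."""
    return SeasonalStructure(
        np.ones((n_plants, n_birds)),
        np.ones((n_plants, n_birds, n_birds)),
        np.ones((n_birds, n_plants, n_plants)),
    )


def randomize_seasonal_structure(
    table: MonthlyInteractionTable,
    seed: int | np.random.Generator | None = None,
    unit: str = "profiles",
) -> MonthlyInteractionTable:
    """Null model: shuffle phenologies among species, keeping the backbone.

    ``unit="profiles"`` (default) permutes whole monthly profiles (rows of
    ``Fp`` among plants and of ``Fh`` among hummingbirds, independently), so
    the multiset of profiles per guild is conserved.  ``unit="cells"``
    instead shuffles the positive monthly counts within each guild's
    positive-cell mask.  ``I`` is never modified; per-pair counts are dropped
    because they no longer correspond to the shuffled marginals.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out.pair_counts = None
    if unit == "profiles":
        out.Fp = table.Fp[rng.permutation(table.n_plants)]
        out.Fh = table.Fh[rng.permutation(table.n_birds)]
    elif unit == "cells":
        for F in (out.Fp, out.Fh):
            mask = F > 0
            vals = F[mask]
            F[mask] = rng.permutation(vals)
    else:
        raise ValueError(f"unknown randomization unit {unit!r}")
    out.validate()
    return out


def export_structure(structure: SeasonalStructure, path) -> None:
    """Cache the overlap arrays to a single ``.npz`` archive."""
    np.savez(path, O=structure.O, Mh=structure.Mh, Mp=structure.Mp)


def load_structure(path) -> SeasonalStructure:
    with np.load(path) as data:
        return SeasonalStructure(O=data["O"], Mh=data["Mh"], Mp=data["Mp"])
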