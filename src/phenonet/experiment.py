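"""Factorial simulation design: communities x replicates x alpha x c x modes.

Each replicate draws one growth-rate vector per guild (one Beta shape ``b``
per guild) which is shared across every mutualism strength, competition
strength and seasonal mode of that replicate — the with/without-seasonality
contrast is paired on identical growth rates.  The ``randomized`` mode
reshuffles the monthly phenology profiles among species (one fresh
permutation per community x replicate) while keeping the binary backbone.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import COMMUNITY_PRESETS, CommunityPreset, generate_community
from .dynamics import (
    ModelParameters,
    MutualismSystem,
    VARIANTS,
    apply_variant,
    integrate_to_equilibrium,
    sample_growth_rates,
)
from .indices import connectance, interaction_overlap, total_abundance
from .seasonal import compute_seasonal_structure, flatten, randomize_seasonal_structure
from .stability import feasibility, persistence, resilience, robustness

__all__ = [
    "DesignSpec",
    "MODES",
    "PAPER_ALPHA_LEVELS",
    "PAPER_C_LEVELS",
    "enumerate_design",
    "run_design",
    "relative_change",
    "paired_relative_changes",
    "feasibility_table",
]

MODES = ("empirical", "flattened", "randomized")
PAPER_ALPHA_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
PAPER_C_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

KEY_COLUMNS = ["community", "replicate", "alpha", "c", "mode"]


def _breadth_from_cfg(value):
    if isinstance(value, (list, tuple)):
        return tuple(float(v) for v in value)
    return float(value)


def _derived_seed(master_seed: int, *key) -> int:
    """Deterministic per-task seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class DesignSpec:
    """One factorial simulation design."""

    communities: list[CommunityPreset]
    n_replicates: int = 250
    alpha_levels: tuple = PAPER_ALPHA_LEVELS
    c_levels: tuple = PAPER_C_LEVELS
    modes: tuple = ("flattened", "empirical")
    variant: str = "none"
    master_seed: int = 0
    phenology_breadth: float | tuple = (1.5, 3.0)

    def validate(self) -> None:
        if not self.communities:
            raise ValueError("design needs at least one community")
        for preset in self.communities:
            preset.validate()
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.alpha_levels or not self.c_levels:
            raise ValueError("alpha_levels and c_levels must be nonempty")
        if any(a < 0 for a in self.alpha_levels) or any(c < 0 for c in self.c_levels):
            raise ValueError("alpha and c levels must be >= 0")
        if not self.modes or any(m not in MODES for m in self.modes):
            raise ValueError(f"modes must be a nonempty subset of {MODES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def n_rows(self) -> int:
        return (
            len(self.communities)
            * self.n_replicates
            * len(self.alpha_levels)
            * len(self.c_levels)
            * len(self.modes)
        )

    @classmethod
    def paper_full(cls, master_seed: int = 0) -> "DesignSpec":
        """The study-scale design: 11 communities x 250 x 7 x 7 x 2 modes."""
        return cls(communities=list(COMMUNITY_PRESETS.values()), master_seed=master_seed)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        communities = []
        for item in cfg["communities"]:
            if isinstance(item, str):
                communities.append(COMMUNITY_PRESETS[item])
            else:
                communities.append(CommunityPreset(**item))
        return cls(
            communities=communities,
            n_replicates=int(cfg.get("n_replicates", 250)),
            alpha_levels=tuple(cfg.get("alpha_levels", PAPER_ALPHA_LEVELS)),
            c_levels=tuple(cfg.get("c_levels", PAPER_C_LEVELS)),
            modes=tuple(cfg.get("modes", ("flattened", "empirical"))),
            variant=cfg.get("variant", "none"),
            master_seed=int(cfg.get("master_seed", 0)),
            phenology_breadth=_breadth_from_cfg(cfg.get("phenology_breadth", (1.5, 3.0))),
        )

    def to_yaml(self, path) -> None:
        cfg = {
            "communities": [
                {
                    "name": p.name,
                    "n_plants": p.n_plants,
                    "n_birds": p.n_birds,
                    "target_links": p.target_links,
                }
                for p in self.communities
            ],
            "n_replicates": self.n_replicates,
            "alpha_levels": list(self.alpha_levels),
            "c_levels": list(self.c_levels),
            "modes": list(self.modes),
            "variant": self.variant,
            "master_seed": self.master_seed,
            "phenology_breadth": list(self.phenology_breadth)
            if isinstance(self.phenology_breadth, tuple)
            else self.phenology_breadth,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def enumerate_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a design into its configuration table (one row per simulation).

    Growth-rate seeds are attached per (community, replicate) so that every
    alpha, c and mode of a replicate shares the same growth rates, and
    randomization seeds per (community, replicate) so the null model uses one
    fresh permutation per replicate.
    """
    spec.validate()
    rows = []
    for preset, rep, a, c, mode in itertools.product(
        spec.communities,
        range(spec.n_replicates),
        spec.alpha_levels,
        spec.c_levels,
        spec.modes,
    ):
        rows.append(
            {
                "community": preset.name,
                "replicate": rep,
                "alpha": a,
                "c": c,
                "mode": mode,
                "community_seed": _derived_seed(spec.master_seed, 1, zlib.crc32(preset.name.encode()) & 0xFFFF),
                "growth_seed": _derived_seed(spec.master_seed, 2, zlib.crc32(preset.name.encode()) & 0xFFFF, rep),
                "permutation_seed": _derived_seed(
                    spec.master_seed, 3, zlib.crc32(preset.name.encode()) & 0xFFFF, rep
                ),
            }
        )
    return pd.DataFrame(rows)


METRIC_COLUMNS = [
    "persistence_pct",
    "diversity",
    "resilience",
    "robustness_pct",
    "connectance",
    "interaction_overlap",
    "total_abundance",
]


def run_design(
    spec: DesignSpec,
    *,
    metrics: tuple = ("persistence", "resilience", "robustness", "indices"),
    out_path=None,
    resume: bool = False,
    progress: bool = False,
    integrate_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Execute a design and return the long results table.

    One row per (community, replicate, alpha, c, mode) with all requested
    stability metrics and network indices; undefined metrics are missing
    values (NaN), never 0.  Deterministic given ``spec.master_seed``.  With
    ``resume=True`` and an existing ``out_path``, already-computed rows are
    kept and skipped.
    """
    spec.validate()
    ikw = dict(integrate_kwargs or {})

    done: pd.DataFrame | None = None
    done_keys: set = set()
    if resume and out_path is not None and Path(out_path).exists():
        done = pd.read_csv(out_path)
        done_keys = set(map(tuple, done[KEY_COLUMNS].itertuples(index=False, name=None)))

    iterator = None
    if progress:
        from tqdm import tqdm

        iterator = tqdm

    rows = []
    for preset in spec.communities:
        community_seed = _derived_seed(spec.master_seed, 1, zlib.crc32(preset.name.encode()) & 0xFFFF)
        table = generate_community(preset, spec.phenology_breadth, seed=community_seed)
        struct_emp = compute_seasonal_structure(table)
        struct_flat = flatten(struct_emp)
        systems = {
            "empirical": MutualismSystem(table.I, struct_emp),
            "flattened": MutualismSystem(table.I, struct_flat),
        }
        structures = {"empirical": struct_emp, "flattened": struct_flat}

        rep_range = range(spec.n_replicates)
        if iterator is not None:
            rep_range = iterator(rep_range, desc=preset.name)
        for rep in rep_range:
            growth_seed = _derived_seed(spec.master_seed, 2, zlib.crc32(preset.name.encode()) & 0xFFFF, rep)
            rng = np.random.default_rng(growth_seed)
            r_h, b_birds = sample_growth_rates(preset.n_birds, rng, return_b=True)
            r_p, b_plants = sample_growth_rates(preset.n_plants, rng, return_b=True)

            if "randomized" in spec.modes:
                permutation_seed = _derived_seed(
                    spec.master_seed, 3, zlib.crc32(preset.name.encode()) & 0xFFFF, rep
                )
                table_rand = randomize_seasonal_structure(table, permutation_seed)
                structures["randomized"] = compute_seasonal_structure(table_rand)
                systems["randomized"] = MutualismSystem(table.I, structures["randomized"])

            for a, c, mode in itertools.product(spec.alpha_levels, spec.c_levels, spec.modes):
                if (preset.name, rep, a, c, mode) in done_keys:
                    continue
                params = apply_variant(
                    ModelParameters(alpha=a, c=c, r_p=r_p, r_h=r_h, seasonal_mode=mode),
                    spec.variant,
                )
                row = {
                    "community": preset.name,
                    "replicate": rep,
                    "alpha": a,
                    "c": c,
                    "mode": mode,
                    "variant": spec.variant,
                    "seed": growth_seed,
                    "b_plants": b_plants,
                    "b_birds": b_birds,
                    "converged": False,
                    "residual": np.nan,
                    "error": "",
                    **{col: np.nan for col in METRIC_COLUMNS},
                }
                try:
                    res = integrate_to_equilibrium(
                        table, structures[mode], params, system=systems[mode], **ikw
                    )
                    row["converged"] = bool(res.converged)
                    row["residual"] = res.residual
                    row["persistence_pct"] = persistence(res)
                    row["diversity"] = res.n_survivors
                    if "indices" in metrics:
                        row["connectance"] = connectance(res, table, structures[mode])
                        row["interaction_overlap"] = interaction_overlap(
                            res, table, structures[mode]
                        )
                        row["total_abundance"] = total_abundance(res)
                    if "resilience" in metrics and res.n_survivors > 0:
                        row["resilience"] = resilience(
                            res, table, structures[mode], params, system=systems[mode]
                        )
                    if "robustness" in metrics:
                        row["robustness_pct"] = robustness(
                            res, table, structures[mode], params, system=systems[mode], **ikw
                        )
                except Exception as err:  # record and continue the batch
                    row["error"] = f"{type(err).__name__}: {err}"
                    warnings.warn(
                        f"simulation failed for {preset.name} rep={rep} "
                        f"alpha={a} c={c} mode={mode}: {err}",
                        stacklevel=2,
                    )
                rows.append(row)

    records = pd.DataFrame(rows)
    if done is not None and len(done):
        records = pd.concat([done, records], ignore_index=True)
    if out_path is not None:
        records.to_csv(out_path, index=False)
    return records


def relative_change(metric_with: float, metric_without: float) -> float:
    """Percent change of a metric due to seasonal structure; NaN when the
    without-seasonality baseline is 0 (division undefined)."""
    if metric_without == 0 or not np.isfinite(metric_without):
        return float("nan")
    return 100.0 * (metric_with - metric_without) / metric_without


def paired_relative_changes(
    records: pd.DataFrame,
    metric: str,
    with_mode: str = "empirical",
    without_mode: str = "flattened",
) -> pd.DataFrame:
    """Per-(community, replicate, alpha, c) relative change of one metric.

    Pairs rows differing only in seasonal mode (the paired design guarantees
    identical growth rates within a pair).
    """
    keys = ["community", "replicate", "alpha", "c"]
    w = records[records["mode"] == with_mode].set_index(keys)[metric]
    wo = records[records["mode"] == without_mode].set_index(keys)[metric]
    joined = pd.DataFrame({"with": w, "without": wo}).dropna(subset=["with", "without"])
    joined["relative_change"] = [
        relative_change(a, b) for a, b in zip(joined["with"], joined["without"])
    ]
    return joined.reset_index()


def feasibility_table(records: pd.DataFrame) -> pd.DataFrame:
    """Feasibility per (community, alpha, c, mode): % of replicates with
    persistence above 98%."""
    grouped = records.groupby(["community", "alpha", "c", "mode"])["persistence_pct"]
    out = grouped.apply(lambda s: feasibility(s.values)).rename("feasibility_pct")
    return out.reset_index()
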