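"""Synthetic plant-hummingbird communities and the long-format interaction CSV.

A community is a bipartite backbone ``I`` (plants x hummingbirds) plus
month-resolved interaction counts for each species: ``Fp[i, m]`` is the
average number of interactions of plant ``i`` in month ``m`` and ``Fh[j, m]``
the same for hummingbird ``j``.  Months are 1-based in files and 0-based
internally.

The generator emulates tropical plant-hummingbird communities: every species
has a unimodal within-year (circular) phenology, the backbone is connected,
and links preferentially join species whose phenologies co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_MONTHS = 12

__all__ = [
    "MonthlyInteractionTable",
    "CommunityPreset",
    "COMMUNITY_PRESETS",
    "generate_community",
    "read_long_csv",
    "write_long_csv",
]


@dataclass
class MonthlyInteractionTable:
    """Binary backbone plus monthly interaction counts for one community.

    Parameters
    ----------
    plant_labels, bird_labels
        Species identifiers (row order of ``I``/``Fp`` and column order of
        ``I`` / row order of ``Fh`` respectively).
    I
        Binary matrix (n_plants x n_birds); ``I[i, j] = 1`` iff plant ``i``
        and hummingbird ``j`` ever interact.
    Fp, Fh
        Nonnegative monthly count matrices (n_plants x 12, n_birds x 12).
    pair_counts
        Optional (n_plants x n_birds x 12) per-pair monthly counts.  Present
        when the table was generated or read from a long CSV; it is what the
        long-format writer serializes.  ``Fp``/``Fh`` are its marginals then.
    """

    plant_labels: list[str]
    bird_labels: list[str]
    I: np.ndarray
    Fp: np.ndarray
    Fh: np.ndarray
    pair_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.Fp = np.asarray(self.Fp, dtype=float)
        self.Fh = np.asarray(self.Fh, dtype=float)
        if self.pair_counts is not None:
            self.pair_counts = np.asarray(self.pair_counts, dtype=float)

    @property
    def n_plants(self) -> int:
        return self.I.shape[0]

    @property
    def n_birds(self) -> int:
        return self.I.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.I.sum())

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n_p, n_h = self.I.shape
        if n_p < 1 or n_h < 1:
            raise ValueError("community must contain at least one species per guild")
        if len(self.plant_labels) != n_p or len(self.bird_labels) != n_h:
            raise ValueError("label lengths do not match matrix shape")
        if not np.isin(self.I, (0.0, 1.0)).all():
            raise ValueError("I must be binary")
        if (self.I.sum(axis=1) == 0).any():
            raise ValueError("I has a plant with no partner (all-zero row)")
        if (self.I.sum(axis=0) == 0).any():
            raise ValueError("I has a hummingbird with no partner (all-zero column)")
        for name, F, n in (("Fp", self.Fp, n_p), ("Fh", self.Fh, n_h)):
            if F.shape != (n, N_MONTHS):
                raise ValueError(f"{name} must have shape ({n}, {N_MONTHS})")
            if not np.isfinite(F).all() or (F < 0).any():
                raise ValueError(f"{name} must be finite and nonnegative")
            if (F.sum(axis=1) == 0).any():
                raise ValueError(f"{name} has a species with an empty phenology")

    def copy(self) -> "MonthlyInteractionTable":
        return MonthlyInteractionTable(
            list(self.plant_labels),
            list(self.bird_labels),
            self.I.copy(),
            self.Fp.copy(),
            self.Fh.copy(),
            None if self.pair_counts is None else self.pair_counts.copy(),
        )

    def equivalent(self, other: "MonthlyInteractionTable", tol: float = 1e-9) -> bool:
        """Same species, backbone and marginal counts, up to species order
        (pair-level detail ignored)."""
        if sorted(self.plant_labels) != sorted(other.plant_labels):
            return False
        if sorted(self.bird_labels) != sorted(other.bird_labels):
            return False
        pi = [other.plant_labels.index(p) for p in self.plant_labels]
        hi = [other.bird_labels.index(b) for b in self.bird_labels]
        return (
            np.array_equal(self.I, other.I[np.ix_(pi, hi)])
            and np.allclose(self.Fp, other.Fp[pi], atol=tol)
            and np.allclose(self.Fh, other.Fh[hi], atol=tol)
        )


@dataclass(frozen=True)
class CommunityPreset:
    """Target richness and link count for one synthetic community."""

    name: str
    n_plants: int
    n_birds: int
    target_links: int

    def validate(self) -> None:
        if min(self.n_plants, self.n_birds, self.target_links) < 1:
            raise ValueError("preset dimensions must be >= 1")
        if self.target_links > self.n_plants * self.n_birds:
            raise ValueError(
                f"preset {self.name!r}: target_links={self.target_links} exceeds "
                f"{self.n_plants} x {self.n_birds} possible links"
            )
        if self.target_links < max(self.n_plants, self.n_birds):
            raise ValueError(
                f"preset {self.name!r}: target_links={self.target_links} cannot give "
                "every species a partner"
            )


#: The 11 study communities (plant richness, hummingbird richness, unique links).
COMMUNITY_PRESETS: dict[str, CommunityPreset] = {
    p.name: p
    for p in (
        CommunityPreset("Alaspungo", 40, 7, 113),
        CommunityPreset("LasGralarias", 59, 13, 163),
        CommunityPreset("Maquipucuna", 65, 17, 238),
        CommunityPreset("MashpiCapuchin", 43, 15, 100),
        CommunityPreset("MashpiLaguna", 41, 17, 126),
        CommunityPreset("Sachatamia", 44, 10, 125),
        CommunityPreset("SantaLuciaLower", 71, 22, 221),
        CommunityPreset("SantaLuciaUpper", 55, 14, 235),
        CommunityPreset("UnPocoDelChoco", 46, 13, 130),
        CommunityPreset("Verdecocha", 46, 14, 138),
        CommunityPreset("Yanacocha", 32, 11, 101),
    )
}


def _wrapped_kernel(peak: int, breadth: float, floor: float = 0.05) -> np.ndarray:
    """Unimodal circular phenology over 12 months, peak value 1.

    Values below ``floor`` (relative to the peak) are truncated to exact 0 so
    species have genuine off-months.
    """
    m = np.arange(N_MONTHS)
    d = np.abs(m - peak)
    d = np.minimum(d, N_MONTHS - d)
    k = np.exp(-(d**2) / (2.0 * breadth**2))
    k[k < floor] = 0.0
    return k


def _circular_midpoint(a: int, b: int) -> int:
    """Month halfway between two peak months on the 12-month circle."""
    d = (b - a) % N_MONTHS
    if d > N_MONTHS // 2:
        d -= N_MONTHS
    return int((a + d / 2.0) % N_MONTHS) % N_MONTHS


def _sample_backbone(
    w: np.ndarray, target_links: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary backbone with ``target_links`` ones and no empty row/column.

    When the budget allows (links >= n_p + n_h - 1) the backbone is connected:
    a random spanning structure is grown by attaching each unattached species
    to an already attached partner.  Attachment and link-addition weights are
    the product of phenological co-occurrence ``w`` and the partners' current
    degrees (preferential attachment), which reproduces the nested,
    heavy-tailed degree structure characteristic of empirical mutualistic
    networks: generalist hubs accumulate most links.
    """
    n_p, n_h = w.shape
    I = np.zeros((n_p, n_h))
    wpos = w + 1e-6  # keep zero-overlap pairs selectable as a last resort

    def _choice(p: np.ndarray) -> int:
        return int(rng.choice(len(p), p=p / p.sum()))

    if target_links >= n_p + n_h - 1:
        # spanning attachment: connected by construction
        i0 = int(rng.integers(n_p))
        j0 = _choice(wpos[i0])
        I[i0, j0] = 1.0
        att_p, att_h = [i0], [j0]
        free_p = [i for i in range(n_p) if i != i0]
        free_h = [j for j in range(n_h) if j != j0]
        while free_p or free_h:
            pick = int(rng.integers(len(free_p) + len(free_h)))
            if pick < len(free_p):
                i = free_p.pop(pick)
                deg = I[:, att_h].sum(axis=0)
                j = att_h[_choice(wpos[i, att_h] * (1.0 + deg))]
                att_p.append(i)
            else:
                j = free_h.pop(pick - len(free_p))
                deg = I[att_p, :].sum(axis=1)
                i = att_p[_choice(wpos[att_p, j] * (1.0 + deg))]
                att_h.append(j)
            I[i, j] = 1.0
    else:
        # covering assignment only (connectivity not affordable)
        big_is_p = n_p >= n_h
        big, small = (n_p, n_h) if big_is_p else (n_h, n_p)
        partners = rng.permutation(small)
        for s, big_idx in enumerate(rng.permutation(big)):
            j = partners[s % small]
            if big_is_p:
                I[big_idx, j] = 1.0
            else:
                I[j, big_idx] = 1.0

    # top up one link at a time, rich-get-richer on both endpoints
    need = target_links - int(I.sum())
    if need < 0:  # cannot happen given preset validation
        raise RuntimeError("backbone construction overshot the link budget")
    for _ in range(need):
        deg_p = I.sum(axis=1)
        deg_h = I.sum(axis=0)
        W = wpos * np.outer(1.0 + deg_p, 1.0 + deg_h) * (1.0 - I)
        k = _choice(W.ravel())
        I.ravel()[k] = 1.0
    return I


def generate_community(
    preset: CommunityPreset,
    phenology_breadth: float | tuple[float, float] = (1.5, 3.0),
    seed: int | np.random.Generator | None = None,
    *,
    kernel_floor: float = 0.05,
    max_retries: int = 20,
) -> MonthlyInteractionTable:
    """Generate a synthetic community matching a richness/link preset.

    Each species gets a unimodal circular phenology (peak month uniform,
    wrapped bell-shaped kernel with standard deviation ``phenology_breadth``
    months, truncated to exact zero below ``kernel_floor`` of the peak) and a
    lognormal interaction intensity.  ``phenology_breadth`` may be a single
    value or a ``(plant, bird)`` pair; the default makes hummingbird activity
    curves (3 months) broader than flowering curves (1.5 months), as resident
    tropical hummingbirds forage across much of the year while flowering is
    pulsed.  Links preferentially join species whose phenologies co-occur,
    and per-pair monthly counts are distributed along the product of the two
    phenology kernels, so the resulting seasonal structure is nontrivial but
    plausible.

    Identical seeds give bit-identical tables.
    """
    preset.validate()
    if np.isscalar(phenology_breadth):
        breadth_p = breadth_h = float(phenology_breadth)
    else:
        breadth_p, breadth_h = map(float, phenology_breadth)
    for b in (breadth_p, breadth_h):
        if not 1.0 <= b <= 12.0:
            raise ValueError("phenology_breadth must lie in [1, 12] months")
    rng = np.random.default_rng(seed)
    n_p, n_h = preset.n_plants, preset.n_birds

    last_err: Exception | None = None
    for _ in range(max_retries):
        peaks_p = rng.integers(0, N_MONTHS, size=n_p)
        peaks_h = rng.integers(0, N_MONTHS, size=n_h)
        kp = np.stack([_wrapped_kernel(p, breadth_p, kernel_floor) for p in peaks_p])
        kh = np.stack([_wrapped_kernel(p, breadth_h, kernel_floor) for p in peaks_h])
        inten_p = rng.lognormal(mean=1.0, sigma=0.8, size=n_p)
        inten_h = rng.lognormal(mean=1.0, sigma=0.8, size=n_h)

        w = kp @ kh.T  # phenological co-occurrence, used as link weights
        I = _sample_backbone(w, preset.target_links, rng)

        counts = np.zeros((n_p, n_h, N_MONTHS))
        for i, j in zip(*np.nonzero(I)):
            prof = kp[i] * kh[j]
            if prof.sum() == 0.0:
                # forced link between temporally disjoint species: place the
                # interaction at the month halfway between the two peaks
                prof = np.zeros(N_MONTHS)
                prof[_circular_midpoint(int(peaks_p[i]), int(peaks_h[j]))] = 1.0
            scale = np.sqrt(inten_p[i] * inten_h[j]) * rng.lognormal(0.0, 0.3)
            counts[i, j] = scale * prof / prof.sum()

        table = MonthlyInteractionTable(
            plant_labels=[f"plant_{i + 1}" for i in range(n_p)],
            bird_labels=[f"bird_{j + 1}" for j in range(n_h)],
            I=I,
            Fp=counts.sum(axis=1),
            Fh=counts.sum(axis=0),
            pair_counts=counts,
        )
        try:
            table.validate()
        except ValueError as err:  # pragma: no cover - construction guarantees validity
            last_err = err
            continue
        return table
    raise RuntimeError(
        f"could not generate a valid community for preset {preset.name!r} "
        f"after {max_retries} attempts: {last_err}"
    )


REQUIRED_COLUMNS = ("plant", "hummingbird", "month", "count")


def read_long_csv(path) -> MonthlyInteractionTable:
    """Read a long-format interaction CSV (plant, hummingbird, month, count).

    ``I[i, j] = 1`` iff any record for the pair has a positive count;
    ``Fp[i, m]`` sums counts of plant ``i`` over its partners in month ``m``
    (and analogously for ``Fh``).  Species with no positive record are
    dropped.  Months are 1-based in the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for row_idx, rec in df.iterrows():
        m = rec["month"]
        if not (float(m).is_integer() and 1 <= int(m) <= 12):
            raise ValueError(f"{path}: row {row_idx}: month {m!r} outside 1-12")
        cnt = float(rec["count"])
        if not np.isfinite(cnt) or cnt < 0:
            raise ValueError(f"{path}: row {row_idx}: negative or non-finite count {cnt!r}")

    plants = list(dict.fromkeys(df["plant"].astype(str)))
    birds = list(dict.fromkeys(df["hummingbird"].astype(str)))
    p_idx = {p: i for i, p in enumerate(plants)}
    h_idx = {b: j for j, b in enumerate(birds)}

    counts = np.zeros((len(plants), len(birds), N_MONTHS))
    for rec in df.itertuples(index=False):
        counts[p_idx[str(rec.plant)], h_idx[str(rec.hummingbird)], int(rec.month) - 1] += float(
            rec.count
        )

    keep_p = counts.sum(axis=(1, 2)) > 0
    keep_h = counts.sum(axis=(0, 2)) > 0
    if not keep_p.any() or not keep_h.any():
        raise ValueError(f"{path}: no species with a positive interaction record")
    counts = counts[keep_p][:, keep_h]
    plants = [p for p, k in zip(plants, keep_p) if k]
    birds = [b for b, k in zip(birds, keep_h) if k]

    table = MonthlyInteractionTable(
        plant_labels=plants,
        bird_labels=birds,
        I=(counts.sum(axis=2) > 0).astype(float),
        Fp=counts.sum(axis=1),
        Fh=counts.sum(axis=0),
        pair_counts=counts,
    )
    table.validate()
    return table


def write_long_csv(table: MonthlyInteractionTable, path) -> None:
    """Write a table to the long CSV format (months 1-based).

    Requires per-pair counts (tables from :func:`generate_community` or
    :func:`read_long_csv` carry them) consistent with the backbone.
    """
    if table.pair_counts is None:
        raise ValueError("table has no per-pair counts; cannot serialize to long format")
    has_count = table.pair_counts.sum(axis=2) > 0
    if not np.array_equal(has_count.astype(float), table.I):
        raise ValueError("pair counts are inconsistent with the binary backbone I")
    rows = []
    for i, j, m in zip(*np.nonzero(table.pair_counts)):
        rows.append(
            {
                "plant": table.plant_labels[i],
                "hummingbird": table.bird_labels[j],
                "month": int(m) + 1,
                "count": table.pair_counts[i, j, m],
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
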