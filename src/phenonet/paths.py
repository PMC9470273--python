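"""Path analysis: attributing seasonal-structure effects on stability to
mediating network variables.

For each retained (alpha, c) combination, a set of chained linear mixed
models (random intercept per community) estimates standardized effects along
a directed acyclic structure::

    seasonal -> diversity
    seasonal, diversity -> connectance, interaction_overlap, total_abundance
    seasonal + all mediators -> resilience   (and separately -> robustness)

Diversity is treated as upstream of the other three mediators; the three are
not linked among themselves.  All variables (including the binary seasonal
indicator) are z-scored within the (alpha, c) subset, so coefficients are
standardized effects and indirect effects are products of coefficients along
paths.  Marginal r² is the variance explained by fixed effects alone,
conditional r² adds the community random intercept (Nakagawa-Schielzeth).

This directed structure is a documented reconstruction of the attribution
scheme; alternative mediator-mediator links are deliberately not searched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PathModelSpec",
    "PathResult",
    "select_combinations",
    "fit_path_analysis",
    "simulate_path_records",
]

DEFAULT_MEDIATORS = ("diversity", "connectance", "interaction_overlap", "total_abundance")
DEFAULT_RESPONSES = ("resilience", "robustness_pct")


@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic path structure for the attribution stage."""

    exogenous: str = "seasonal"
    mediators: tuple = DEFAULT_MEDIATORS
    responses: tuple = DEFAULT_RESPONSES
    grouping: str = "community"
    upstream_mediator: str = "diversity"

    def parents(self) -> dict[str, list[str]]:
        """Parent set of every endogenous variable."""
        out: dict[str, list[str]] = {}
        for m in self.mediators:
            if m == self.upstream_mediator or self.upstream_mediator not in self.mediators:
                out[m] = [self.exogenous]
            else:
                out[m] = [self.exogenous, self.upstream_mediator]
        for r in self.responses:
            out[r] = [self.exogenous, *self.mediators]
        return out

    def paths_to(self, response: str) -> list[tuple[str, ...]]:
        """All directed paths from the exogenous variable to a response."""
        paths = [(self.exogenous, response)]
        for m in self.mediators:
            paths.append((self.exogenous, m, response))
        if self.upstream_mediator in self.mediators:
            for m in self.mediators:
                if m != self.upstream_mediator:
                    paths.append((self.exogenous, self.upstream_mediator, m, response))
        return paths


@dataclass
class PathResult:
    """Edge coefficients, fit quality and indirect effects of one path analysis."""

    edges: pd.DataFrame  # source, target, coefficient, pvalue, method
    r2: dict  # target -> (marginal, conditional)
    indirect: pd.DataFrame  # response, path, effect
    n_records: int
    dropped: list[str] = field(default_factory=list)

    def coefficient(self, source: str, target: str) -> float:
        sel = self.edges[(self.edges["source"] == source) & (self.edges["target"] == target)]
        if sel.empty:
            return float("nan")
        return float(sel["coefficient"].iloc[0])


def select_combinations(records: pd.DataFrame) -> list[tuple[float, float]]:
    """(alpha, c) combinations retained for path analysis.

    Keeps combinations with mean persistence strictly between 20% and 90%
    (modes pooled) and excludes the no-competition control c = 0.
    """
    means = records.groupby(["alpha", "c"])["persistence_pct"].mean()
    kept = []
    for (a, c), m in means.items():
        if c == 0:
            continue
        if 20.0 < m < 90.0:
            kept.append((float(a), float(c)))
    return sorted(kept)


def _zscore(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=0)


def _fit_one(
    data: pd.DataFrame, target: str, parents: list[str], grouping: str, method: str
) -> tuple[pd.Series, pd.Series, float, float, str]:
    """Fit one endogenous variable; returns (coefs, pvalues, r2m, r2c, method)."""
    X = sm.add_constant(data[parents])
    y = data[target]
    if method == "mixed":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=data[grouping])
                res = model.fit(reml=True)
            var_re = float(np.asarray(res.cov_re).ravel()[0])
            var_e = float(res.scale)
            if not np.isfinite(var_re) or var_re < 0:
                raise np.linalg.LinAlgError("singular random-effects covariance")
            beta = res.fe_params
            fixed_pred = X.values @ beta.values
            var_f = float(np.var(fixed_pred))
            denom = var_f + var_re + var_e
            r2m = var_f / denom
            r2c = (var_f + var_re) / denom
            return (
                beta.drop("const"),
                res.pvalues[beta.index].drop("const"),
                r2m,
                r2c,
                "mixed",
            )
        except (np.linalg.LinAlgError, ValueError) as err:
            warnings.warn(
                f"mixed model for {target!r} failed ({err}); falling back to OLS",
                stacklevel=2,
            )
    res = sm.OLS(y, X).fit()
    coefs = res.params.drop("const")
    return coefs, res.pvalues.drop("const"), float(res.rsquared), float(res.rsquared), "ols"


def fit_path_analysis(
    records: pd.DataFrame,
    spec: PathModelSpec = PathModelSpec(),
    *,
    method: str = "mixed",
) -> PathResult:
    """Fit the chained regressions of the path model on one (alpha, c) subset.

    Rows with zero persistence are removed (stability undefined there); all
    variables are standardized within the subset.  Zero-variance variables
    are dropped with a warning; singular mixed fits fall back to plain OLS.
    """
    if method not in ("mixed", "ols"):
        raise ValueError("method must be 'mixed' or 'ols'")
    df = records.copy()
    if "persistence_pct" in df.columns:
        df = df[df["persistence_pct"] > 0]
    variables = [spec.exogenous, *spec.mediators, *spec.responses]
    df = df.dropna(subset=[v for v in variables if v in df.columns])
    if spec.grouping not in df.columns:
        raise ValueError(f"records lack the grouping column {spec.grouping!r}")
    if df[spec.grouping].nunique() < 2 and method == "mixed":
        raise ValueError("path analysis needs records from at least 2 communities")

    dropped = [v for v in variables if df[v].std(ddof=0) == 0]
    if dropped:
        warnings.warn(f"zero-variance variable(s) dropped from the path model: {dropped}")
    keep = [v for v in variables if v not in dropped]

    z = df[keep].apply(_zscore)
    z[spec.grouping] = df[spec.grouping].values

    edge_rows = []
    r2: dict[str, tuple[float, float]] = {}
    for target, parents in spec.parents().items():
        if target in dropped:
            continue
        parents = [p for p in parents if p not in dropped]
        if not parents:
            continue
        coefs, pvals, r2m, r2c, used = _fit_one(z, target, parents, spec.grouping, method)
        r2[target] = (r2m, r2c)
        for p in parents:
            edge_rows.append(
                {
                    "source": p,
                    "target": target,
                    "coefficient": float(coefs[p]),
                    "pvalue": float(pvals[p]),
                    "method": used,
                }
            )
    edges = pd.DataFrame(edge_rows)

    coef_map = {(e["source"], e["target"]): e["coefficient"] for e in edge_rows}
    indirect_rows = []
    for resp in spec.responses:
        if resp in dropped:
            continue
        for path in spec.paths_to(resp):
            effect = 1.0
            ok = True
            for s, t in zip(path[:-1], path[1:]):
                if (s, t) not in coef_map:
                    ok = False
                    break
                effect *= coef_map[(s, t)]
            if ok:
                indirect_rows.append(
                    {
                        "response": resp,
                        "path": " -> ".join(path),
                        "kind": "direct" if len(path) == 2 else "indirect",
                        "effect": effect,
                    }
                )
    indirect = pd.DataFrame(indirect_rows)
    return PathResult(edges=edges, r2=r2, indirect=indirect, n_records=len(df), dropped=dropped)


def simulate_path_records(
    n: int,
    coefficients: dict[tuple[str, str], float],
    *,
    spec: PathModelSpec = PathModelSpec(),
    n_communities: int = 11,
    sigma_community: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate records from a known linear path model (for validation).

    The exogenous seasonal indicator is a balanced ±1 contrast (unit
    variance); each endogenous variable is the specified linear combination
    of its standardized parents plus a community random intercept
    (``sigma_community``) and Gaussian noise scaled so its total variance is
    ~1, keeping the generating coefficients on the standardized scale.
    Unspecified edges have coefficient 0.
    """
    rng = np.random.default_rng(seed)
    community = rng.integers(n_communities, size=n)
    data = pd.DataFrame(
        {
            spec.grouping: [f"community_{k}" for k in community],
            spec.exogenous: rng.permutation(np.resize([-1.0, 1.0], n)),
        }
    )
    for target, parents in spec.parents().items():
        betas = np.array([coefficients.get((p, target), 0.0) for p in parents])
        explained = float(betas @ betas)
        var_re = sigma_community**2
        sigma_e = np.sqrt(max(1.0 - explained - var_re, 0.05))
        intercepts = rng.normal(0.0, sigma_community, size=n_communities)[community]
        data[target] = (
            data[parents].values @ betas + intercepts + rng.normal(0.0, sigma_e, size=n)
        )
    data["persistence_pct"] = 50.0
    data["alpha"] = 1.0
    data["c"] = 1.0
    return data
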