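# phenonet

Seasonal structure and the multidimensional stability of mutualistic
networks.

Plant–pollinator interactions are usually analysed as networks aggregated
over a whole year, which hides the fact that partners must co-occur in time
to interact. `phenonet` is a simulation pipeline for asking what that
within-year ("seasonal") organization of interactions does to community
stability. It targets plant–hummingbird communities: bipartite networks in
which both guilds depend obligately on the mutualism, and species within a
guild compete for mutualistic partners they share **at the same time of
year**.

The pipeline, intended for theoretical community ecologists:

1. builds communities (synthetic, matching the richness/link structure of
   11 sampled tropical plant–hummingbird networks shipped as presets, or
   read from a long-format CSV of monthly interaction counts),
2. derives the seasonal structure — among-guild phenological overlaps
   `O_ij` and within-guild overlaps `Mh_ikj`, `Mp_jki` from monthly counts,
3. integrates a bipartite dynamical model to ecological equilibrium,
4. measures four facets of stability — feasibility, persistence,
   resilience, robustness — plus network indices (connectance, interaction
   overlap, total abundance, diversity),
5. contrasts paired simulations with / without / with-randomized seasonal
   structure over a factorial grid of mutualism strength α and competition
   strength c, and
6. attributes the seasonal effects on resilience and robustness to
   mediating network variables with mixed-model path analyses.

## The model

For hummingbird `j` (and symmetrically for plant `i`):

    dH_j/dt = H_j ( r_j + α Σ_i I_ij O_ij P_i
                          ─────────────────────────────────────────────
                          1 + β Σ_i I_ij O_ij P_i + c Σ_k Ω_kj H_k
                    − Σ_k cs_jk H_k )

Growth rates are negative (obligate mutualism), drawn per replicate as
`r = −½·Beta(1, b)`, `b ~ exp(U(log 0.3, log 15))`. The benefit saturates
with handling time β (default 0.8) and is degraded by within-guild
competitors through the abundance-weighted, seasonally resolved
competition matrix

    Ω_kj = Σ_i P_i I_ij I_ik Mh_ikj / Σ_i I_ij O_ij P_i  ∈ [0, 1].

Removing the seasonal structure sets every overlap to 1. Persistence is the
% of species above the 1e-5 extinction threshold at equilibrium;
feasibility the % of replicates with persistence > 98%; resilience
`−max Re(λ)` of the survivor-restricted Jacobian; robustness the mean %
of the remaining community surviving single hummingbird removals after
re-equilibration. See `docs/methods.md` for every convention and numerical
choice.

## Worked example

```python
import phenonet as pn
from phenonet.experiment import DesignSpec, run_design, paired_relative_changes

# a small seasonal community and its overlap structure
table = pn.generate_community(pn.COMMUNITY_PRESETS["Yanacocha"], seed=0)
structure = pn.compute_seasonal_structure(table)
print(f"{table.n_plants} plants x {table.n_birds} hummingbirds, "
      f"{table.n_links} links; mean overlap O = {structure.O.mean():.3f}")

# one simulation with, one without seasonal structure (same growth rates)
params = pn.ModelParameters(alpha=2.0, c=2.0,
                            r_p=pn.sample_growth_rates(32, 1),
                            r_h=pn.sample_growth_rates(11, 2))
with_s  = pn.integrate_to_equilibrium(table, structure, params)
without = pn.integrate_to_equilibrium(table, pn.flatten(structure), params)
print(f"persistence with seasonal structure:    {pn.persistence(with_s):.1f}%")
print(f"persistence without seasonal structure: {pn.persistence(without):.1f}%")
print(f"resilience with: {pn.resilience(with_s, table, structure, params):.4f}")

# a paired mini-design and the cell-level seasonal effect
spec = DesignSpec(communities=[pn.COMMUNITY_PRESETS["Yanacocha"]],
                  n_replicates=10, alpha_levels=(2.0,), c_levels=(2.0,),
                  modes=("flattened", "empirical"), master_seed=0)
records = run_design(spec, metrics=("persistence", "indices"))
changes = paired_relative_changes(records, "persistence_pct")
print(f"mean paired relative change at (alpha=2, c=2): "
      f"{changes['relative_change'].mean():+.1f}%")
```

prints

```
32 plants x 11 hummingbirds, 101 links; mean overlap O = 0.585
persistence with seasonal structure:    100.0%
persistence without seasonal structure: 86.0%
resilience with: 0.0173
mean paired relative change at (alpha=2, c=2): +28.1%
```

With strong mutualism and strong competition for partners, accounting for
the seasonal structure lets more species coexist (here +28% persistence
relative to the aseasonal baseline): spreading interactions over the year
relieves competition more than it weakens the mutualistic benefit. At weak
mutualism the balance reverses and seasonal structure costs persistence.

A command-line interface wraps the same functions
(`phenonet generate-community | metrics | simulate | compare |
path-analysis`); design YAMLs for a desk-scale and the full study-scale
grid are in `configs/`.

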