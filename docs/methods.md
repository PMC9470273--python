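# Methods

This note documents the model, the indices, the numerical choices and the
synthetic-data generator behind `phenonet`, and states what the shipped tests
do and do not demonstrate.

## The community model

Two guilds interact: hummingbirds (abundances `H_j`, individuals) and plants
(abundances `P_i`, flowers produced over a year). Mutualism is obligate —
intrinsic growth rates `r` are negative for every species — so persistence is
possible only through the mutualistic benefit. For hummingbird `j`:

    dH_j/dt = H_j * ( r_j
                      + α Σ_i I_ij O_ij P_i / (1 + β Σ_i I_ij O_ij P_i + c Σ_k Ω_kj H_k)
                      − Σ_k cs_{j,k} H_k )

and symmetrically for plants with the plant–plant competition matrix Θ and
`H ↔ P` swapped. The terms:

* `I` — binary backbone: who ever interacts with whom.
* `O_ij ∈ [0, 1]` — among-guild phenological overlap; scales the per-capita
  interaction strength, so temporally mismatched partners help each other
  less.
* `α ≥ 0` — mutualism strength; `β ≥ 0` — handling time, saturating the
  benefit (default 0.8); `c ≥ 0` — maximum strength of competition for
  mutualistic partners.
* `Ω_kj ∈ [0, 1]` — competition imposed by hummingbird `k` on `j` through
  shared plants at shared times, inside the benefit denominator: crowding by
  within-guild competitors degrades the rate at which partners can be
  exploited. The placement in the denominator follows the model's verbal
  description (benefit "decreases with the abundance of within-guild
  competitors"); an additive competition variant is deliberately not
  implemented.
* `cs` — competition for space, independent of mutualism: intra-specific
  `cs_intra = 1`, inter-specific `cs_inter = 0` by default.

The competition coefficients are abundance-weighted and state-dependent:

    Ω_kj = Σ_i P_i I_ij I_ik Mh_ikj / Σ_i I_ij O_ij P_i

with `Mh_ikj` the within-guild overlap of birds `k` and `j` on plant `i`
(below), and Θ analogous. When the focal species' denominator is zero (no
abundance-weighted partners remain) its coefficient column is set to 0; its
benefit is then 0 and it decays at rate `r − cs·X`, the forced behaviour for
an obligate mutualist. Because `Mh_ikj ≤ O_ij`, all coefficients stay in
[0, 1] under the default overlap convention.

## Seasonal-structure indices

From monthly interaction counts `Fp[i, m]` (plant `i`, month `m`) and
`Fh[j, m]`:

    O_ij    = Σ_m (Fp_im / Σ_m Fp_im) (Fh_jm / max_m Fh_jm)
    Mh_ikj  = Σ_m (Fp_im / Σ_m Fp_im) (Fh_km / max_m Fh_km) (Fh_jm / max_m Fh_jm)
    Mp_jki  = Σ_m (Fh_jm / max_m Fh_jm) (Fp_km / Σ_m Fp_km) (Fp_im / Σ_m Fp_im)

Plant curves are normalized to sum 1 over months, bird curves by their
monthly maximum. This asymmetric convention is the default (`"printed"`).
Note its consequence: under identical constant phenologies `Mh = 1` but
`Mp = 1/12`, because both plant factors in `Mp` are sum-normalized — plant–
plant competition is intrinsically weaker than bird–bird competition under
this convention. Since this is a genuinely open reading, a fully symmetric
alternative (`convention="symmetric"`: the shared partner sum-normalized,
the competing pair max-normalized) is implemented for sensitivity analysis;
the default is the convention exactly as the equations print it, and is not
silently switched. Under the symmetric convention Θ entries are not
guaranteed ≤ 1.

Removing the seasonal structure ("flattened" mode) sets every entry of `O`,
`Mh`, `Mp` to 1; `flatten()` and an all-ones structure built directly are
interchangeable, and the pipeline treats them as the same mode by
construction.

The randomization null keeps `I` fixed and permutes whole monthly profiles
among species within each guild (plants and hummingbirds independently, one
fresh permutation per community × replicate). Shuffling whole profiles is a
species relabelling as far as the overlap arrays are concerned, which is the
tested invariant. An alternative unit (`"cells"`: shuffle positive monthly
values within the positive-cell mask) is available behind a flag.

## Growth rates

Each guild in each replicate draws one Beta shape parameter
`b ~ exp(U(log 0.3, log 15))`, then species rates `r = −1/2 · Beta(a=1, b)`,
bounding rates in [−0.5, 0] while spanning distributions from
near-degenerate-at-0 to widely spread. One `b` per guild per replicate
("drawn independently" is read as per guild). The growth-rate vector of a
replicate is shared across every (α, c) cell and every seasonal mode, so
with/without comparisons are paired on identical conditions.

Two assumption-relaxing variants are pure parameter transforms applied
before integration: `shifted_r` recentres plant rates at their median (half
the plants become partially independent of hummingbirds); `absolute_r_cs`
takes `|r|` for plants and sets `cs_inter = 0.05`.

## Integration to equilibrium

`scipy.integrate.solve_ivp` (LSODA, rtol 1e-6, atol 1e-12) in successive
windows; the first window is 1000 model-time units and windows grow
geometrically (factor 1.5, budget 20 windows, total ≈ 6.6e6 time units).
Geometric growth is deliberate: the sampler occasionally produces growth
rates within ~1e-6 of zero, whose decay to the extinction threshold takes
~1e6 time units — a fixed 20 × 1000 budget provably misclassifies such
species. After each window, species at or below the extinction threshold
(1e-5) are clamped to exactly 0 (configurable; clamping prevents numerical
resurrection). Termination: max |dX/dt| over surviving species < 1e-10.
The tolerance sits at threshold² on purpose — a species in slow quadratic
self-limited decay just above the threshold has |dX/dt| ≈ X², so any looser
tolerance (e.g. 1e-8) misclassifies a dying species at X ≈ 3e-5 as an
equilibrated survivor. All windowing and tolerance settings are arguments.

Integrator failures are flagged on the result, never raised out of a batch.

## Stability metrics

* **Persistence** — % of the initial species pool strictly above the 1e-5
  threshold at equilibrium, guilds pooled. Expressed as a count it is
  **diversity**.
* **Feasibility** — % of growth-rate replicates with persistence > 98%
  within a (community, α, c, mode) cell. The 98% cut tolerates the loss of
  one species in communities of more than 50 species and none otherwise.
* **Resilience** — `−max Re(λ)` of the Jacobian of the dynamics restricted
  to survivors, built by central finite differences (step
  `max(1e-6, 1e-6·|x|)`) on the full right-hand side: Ω and Θ are
  state-dependent, and numerical differentiation captures their
  product-rule terms automatically. Undefined (missing, never 0) without
  survivors.
* **Robustness** — for each surviving hummingbird, set it to 0 and
  re-integrate *from the perturbed equilibrium state* (continuation, not
  re-initialization) until a new equilibrium; score the % of the other
  pre-removal survivors that remain; average over removals. The removed
  species is a forced extinction, not a response, so it is excluded from
  the denominator (`include_removed=True` switches to the inclusive
  accounting). Only hummingbirds are removed, to bound cost; survival is
  assessed over both guilds. Undefined when no hummingbird survives or only
  one species remains.

## Network indices (at equilibrium, survivors only)

* **Connectance** — mean of `N = I ∘ O` over surviving rows/columns; with a
  flattened structure this reduces to the binary connectance of the
  surviving backbone.
* **Interaction overlap** — mean of Ω and Θ pooled, recomputed on the
  surviving sub-community with all abundances set to 1: an
  abundance-independent measure of within-guild functional redundancy.
  Diagonal (self) entries are included by default — the definition says
  "all terms" — with an exclusion flag.
* **Total abundance** — Σ of surviving abundances (productivity proxy).

## Synthetic communities

The generator emulates the 11 sampled plant–hummingbird communities at the
statistical level: richness and link counts from the community table
(shipped as named presets), unimodal within-year phenologies, and a sparse
connected backbone biased toward temporally co-occurring and well-connected
partners.

* Phenologies: wrapped (circular) Gaussian kernel over 12 months, peak month
  uniform; values below 5% of the peak truncated to exact 0 so species have
  genuine off-months. Breadth is guild-specific by default — plants sd 1.5
  months (pulsed flowering, ~3–5 active months), hummingbirds sd 3.0 months
  (resident foragers active much of the year). Species-level intensities are
  lognormal.
* Backbone: a random spanning structure first (guaranteeing no empty
  row/column, and connectivity whenever links ≥ n_p + n_h − 1), then
  remaining links one at a time with probability ∝ phenological
  co-occurrence × (1 + degree) of both endpoints. The preferential term
  reproduces the nested, heavy-tailed degree structure characteristic of
  empirical mutualistic networks; without it, synthetic communities lack
  generalist hubs and collapse near-identically in both seasonal modes at
  weak mutualism, which no empirical community does.
* Per-pair monthly counts are laid along the product of the two kernels
  (with a midpoint-month fallback for forced links between disjoint
  phenologies), and the species-level matrices `Fp`, `Fh` are their
  marginals — so generated tables are always consistent with the long
  (plant, hummingbird, month, count) CSV format and round-trip through it.

What the generator does **not** emulate: multi-year sampling noise,
elevation/site covariates, true empirical degree sequences, modularity
beyond what preferential attachment induces, or phenology shapes other than
unimodal. Passing tests therefore demonstrate the pipeline's behaviour on
communities with realistic coarse structure, not reproduction of any
empirical community's numbers.

## Experiment grid

The full factorial design is communities × replicates × α × c × modes with
α, c ∈ {0, 0.5, …, 3}; at study scale (11 × 250 × 7 × 7 × 2) that is 269,500
simulations and 5,500 per (α, c) slice. All seeds derive deterministically
from one master seed (community backbones, growth rates, null-model
permutations), rows record every metric with undefined values as missing,
and a partial results file can be resumed. Relative change of a metric due
to seasonal structure is `100 · (with − without)/without`, undefined when
the baseline is 0.

## Path analysis

For each (α, c) with mean persistence strictly between 20% and 90% (modes
pooled; the no-competition control c = 0 excluded), a set of chained linear
mixed models with a community random intercept estimates standardized
effects along the directed structure

    seasonal → diversity
    seasonal, diversity → connectance, interaction_overlap, total_abundance
    seasonal + all mediators → resilience | robustness (separate equations)

Diversity is placed upstream of the other three mediators; the three are
not linked among themselves. This DAG is a documented reconstruction of the
attribution scheme (the placement of diversity is supported by the
diversity→abundance→resilience mediation argument); no structure search is
performed. Rows with zero persistence are dropped (stability undefined),
all variables — including the binary seasonal indicator — are z-scored
within the subset, so coefficients are standardized effects, a path's
indirect effect is the exact product of its edge coefficients, and in the
degenerate single-predictor OLS case the coefficient equals the sample
correlation. Marginal r² is var(fixed)/(var(fixed)+var(intercept)+var(resid));
conditional r² adds the intercept variance to the numerator. Singular mixed
fits fall back to OLS with a warning; zero-variance variables are dropped
with a warning.

## Problem sizes used by the shipped tests and acceptance script

Chosen as the package's own desk-scale defaults: oracle checks on ≤ 4-species
instances; the collapse experiment on a 20 × 8 community × 20 replicates;
the seasonal-contrast experiment on two study presets (Alaspungo 40 × 7,
Yanacocha 32 × 11) × 25 replicates, comparing (α = 0.5, c = 0), where
benefit weakening dominates and seasonal structure lowers persistence, with
(α = 2, c = 2), where competition relief dominates and it raises
persistence; path-model recovery on 5,000 simulated records. At
(α = 0.5, c = 2) the two forces nearly cancel in these synthetic
communities (measured mean effect slightly positive), so the clean
weak-mutualism contrast is taken at c = 0.

## Known limitations

* No adaptive foraging, rewiring, or demographic stochasticity; months are
  the only temporal resolution.
* The exact published forms of the among-guild overlap and the robustness
  accounting are not available from the main text; both are reconstructed
  and the alternatives are exposed as options.
* Resilience uses a finite-difference Jacobian; step size is not adapted to
  extreme abundance scales beyond the relative-step rule.
* The path analysis assumes linear Gaussian relations among z-scored
  variables; it is an attribution device, not a causal discovery method.
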