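# Methods

## Model and assumptions

`metacoex` studies competition for one limiting resource in `N` discrete
patches coupled by global dispersal. Per species `j`: mortality `m_j ≥ 0`
(1/time), establishment coefficient `b_j > 0` (per resource per time),
resource cost per recruit `Q_j > 0`, and retention fraction `p_j ∈ [0,1]`.
A fraction `1 − p_j` of propagules enters a common pool spread uniformly
over all patches, natal patch included — there is no distance structure,
which is the appropriate limit when typical dispersal distances exceed the
grain of resource heterogeneity. Establishment consumes `Q_j` resource
units per recruit and is the only resource sink in the baseline model;
variants add a linear resource loss (rate `loss ≥ 0`) or replace the
linear establishment response `g(R) = R` by the slope-preserving Monod
form `g(R) = R/(1 + R/k)` with a common half-saturation constant `k`
(the linear model is the `k → ∞` limit). Dynamics are deterministic ODEs;
there is no demographic stochasticity and no local spatial structure.

A single resident with `m > 0` has the closed-form equilibrium
`n*_x = S_x/(Qm)`, `R*ᵐ_x = m S_x / (b (p S_x + (1−p)⟨S⟩))`. Equilibrium
density is independent of retention; the residual resource pivots around
`R* = m/b` at the mean-supply patch, rising above it in rich patches for
dispersive species. A species with `m = 0` has no stationary state — its
density grows without bound while the resource field decays toward zero —
and the closed form refuses it; see "degenerate strategies" below.

## Mechanism partition

Local growth is written as `r_jx = E_jx − C_jx + γ_j E_jx C_jx` with the
species environment response `E_jx` and competition response
`C_jx = m_j + b_j p_j C_x + b_j (1−p_j)⟨C⟩_x`, where `C_x = −g(R_x)`.
Because supply variation reaches individuals only through the resource,
`E_jx ≡ 0`, and because the growth rate is additively separable, `γ_j = 0`;
both are represented as computed arrays/coefficients, not shortcuts, so
the vanishing of the derived components is an arithmetic outcome.

The metacommunity growth rate is the individual-weighted mean
`r̃ = ⟨r ν⟩_x = ⟨r⟩_x + cov(r, ν)_x`, with `ν_jx = n_jx/⟨n_j⟩_x` and the
population (1/N) covariance convention throughout. Differencing invader
against resident and scaling resident terms by `q_ir = b_i/b_r` gives the
per-generation partition ΔE, ΔC, ΔI, Δκ. Choices that were genuinely open,
and how they were fixed:

- **`q_ir = b_i/b_r`** is the unique scaling under which the `⟨C⟩` terms
  cancel and ΔC reduces to the interpretable `b_i (R*_i − R*_r)`.
- **`C*_i`**, the competition the invader would face at the residents'
  no-variation equilibrium, is `m_i − b_i R*_r`. With it,
  `r̃′/b_i = R*_r − R*_i` and `ΔN = ΔC − C*_i = 0` exactly — consistent
  with the partition identity; the opposite sign choice for ΔC would break
  the identity and is treated as an error.
- **Relative supply deviations** `s_x = S_x/⟨S⟩ − 1` (mean zero), so
  `var(s)` is the squared coefficient of variation. Under this convention
  the exact covariance computation and the closed form
  `Δκ/b_i ≈ var(s)(1−p_r)² R*_r (p_i/(1−p_i) − p_r/(1−p_r))` agree to
  leading order: the implementation's variance-ladder test drives
  `approx/exact → 1` monotonically as `var(s) → 0`. A small-variance
  perturbation expansion (invader distribution
  `ν_i ≈ 1 + s (1−p_r)/(1−p_i)`) reproduces the closed form analytically.
- The invader's spatial distribution `ν_i` is the Perron eigenvector of
  the invasion operator, scaled to mean one; a numerically non-unique
  dominant eigenvalue raises a tie-break warning.

With several residents, resident-side terms are weighted by relative
metacommunity abundance; the `r̃′/ΔN` split needs a single resident's `R*`
and is reported as NaN otherwise. The partition identity
`r̃_i = ΔE − ΔC + ΔI + Δκ` then still holds because every resident's own
metacommunity growth is zero at the joint equilibrium.

## Invasion analysis

An invader at vanishing density has no resource feedback, so its dynamics
are linear on the frozen resident field: matrix entries
`A_xy = δ_xy(−m_i + b_i p_i g(R̂_x)) + b_i (1−p_i) g(R̂_x)/N`. `A` is
Metzler, hence has a real dominant eigenvalue with a non-negative
eigenvector (asserted at runtime); that eigenvalue is the invasion growth
rate, and it coincides exactly with the partition total when both are
evaluated on the same field (the identity-to-1e-6 test is conservative;
agreement is at round-off). Self-invasion gives rate zero because the
resident's equilibrium density vector is a positive kernel eigenvector.
Mutual invasion (both reciprocal rates positive) is the coexistence
criterion; exclusion and founder-control verdicts follow the sign pattern.

## Steady-state integration

Stiff-safe adaptive integration (LSODA with an analytic Jacobian) in
geometrically growing chunks, hard horizon `1e5` time units (3e5 for
community batteries), `rtol 1e-8 / atol 1e-10`. Convergence is declared on
the **resource field** — `max_x |dR_x/dt|/S_x < 1e-8` — because
zero-mortality parameterisations never have stationary densities while
their resource field stabilises in this relative sense, and invasion
analysis consumes only the field. Densities below `1e-9` of the
metacommunity mean are zeroed at output (the extinction floor). Survivor
counting in many-species experiments additionally requires stationary
per-species totals (relative rate `< 1e-6`) and prunes below-floor species
between chunks: near-neutral strategies sort out slowly, and counting at
mere resource stationarity would inflate survivor numbers with transient
losers. Integration accuracy is validated against the closed-form
equilibrium to `1e-6` relative error.

## Tradeoff manifold, assembly, and degenerate strategies

Strategies trade competitive ability against retention:
`R*(p) = Z + p^τ` (retention orientation) or `Z + (1−p)^τ` (dispersed
orientation), with traits `m = b R*(p)`. The linear preset is the
retention-orientation manifold with `Z = 0, τ = 1` (`R* = p`; in terms of
the dispersed fraction `d = 1 − p` this reads `R* = 1 − d`). Only the
retention orientation carries a genuine tension — the better competitor
disperses more and under-depletes rich patches, which a retentive,
competitively inferior strategy can exploit via growth-density covariance;
in the dispersed orientation the retainer is superior on both components
and invasion is strictly one-sided.

Sequential assembly scans a strategy grid (default 101 points on [0,1],
endpoints included) for invaders with positive eigenvalue growth rate into
the current residents' steady state. The best candidate is **admitted**
only if every current resident can re-invade the community formed with the
candidate (mutual invasion) and the candidate resists exclusion by its
adjacent grid strategies; otherwise residents may be **substituted** by an
adjacent strategy that invades a community the resident cannot re-enter
(a discrete trait-substitution step; a swap that would collapse the
community is rejected). The procedure stops when neither addition nor
substitution is possible, with a 200-step cap against cycles; candidate
order (by descending growth rate) makes assembly deterministic.

Strategies with `R*(p) = 0` deserve care. Such a species is immortal:
alone it drives every patch's resource toward zero without ever reaching a
steady state, so under the finite-horizon rule its *achieved* field is a
few 1e-4 of the `R*` scale and nothing can invade it, while it invades
every regular resident. On manifolds whose `R*` range touches zero
(`Z = 0`) the assembly therefore cascades deterministically into that
extreme and terminates with a **single** strategy, from any start — the
tests compute exactly this. A two-strategy community is the honest
endpoint whenever the manifold has a positive `R*` floor: with e.g.
`Z = 0.3` on the 20-patch log-normal field, assembly ends at the two
strategy extremes `{p = 0, p = 1}` from every start, the pair passes the
reciprocal-invasion test, simultaneous competition of 30 strategies leaves
exactly that pair, and no third strategy can join — the two-species
ceiling of growth-density covariance. Sub-linear tradeoffs (`τ < 1`)
behave like floored manifolds once the zero-mortality point is excluded
from sampling, and reach two survivors; super-linear tradeoffs (`τ > 1`)
leave one; resource-loss and Monod variants never exceed two.

## Synthetic supply fields

`generate_supply(N, mu, sigma, seed)` draws `S_x = exp(Normal(mu, sigma))`
— the study setting is `N = 20`, `LogNormal(1, 1.5)` read as log-scale
mean and standard deviation (an arithmetic-moment convention is available
by flag, since "(mean, sd)" is ambiguous for log-normals). With 20 patches
the realized `var(s)` scatters widely (≈0.5–12 across seeds) around the
heavy-tailed theoretical value; results that depend on the realized draw
(e.g. which strategies a given field lets coexist) are therefore always
reported per seed. The generator emulates static, uncorrelated
patch-to-patch supply variation only: no temporal variation, no spatial
autocorrelation, no measurement noise — so passing tests speak to the
model's internal consistency, not to field data.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: randomized
partition batteries of 100 trait pairs on 20 patches (closed-form resident
equilibria make these seconds-fast); pairwise invasibility on 21/41-point
grids with 2× refinement checks; assembly on 41-point grids from five
starts; community batteries of K = 30 strategies with 3–5 replicates per
variant (10 replicates and 101-point grids remain the library defaults).

## Known limitations

- The partition's closed-form comparisons (`r̃′`, ΔN) are single-resident;
  multi-resident partitions report r̃ and Δκ with abundance-weighted
  resident terms.
- The Δκ closed form is singular at full retention and inaccurate at the
  study's own heterogeneity levels (it overestimates the exact covariance
  by ~40% already at `var(s) ≈ 0.15`); use the exact partition away from
  the small-variance regime.
- Assembly's "similar strategies" test is the discrete two-neighbour rule;
  continuous-trait (canonical-equation) dynamics are out of scope.
- Communities containing a zero-mortality strategy have no stationary
  state; all conclusions about them are statements about achieved
  finite-horizon states under the stated convergence rule.
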