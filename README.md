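# metacoex

Coexistence analysis for plant metacommunities competing for a single,
spatially heterogeneous resource.

## The problem

Spatial environmental heterogeneity is often invoked to explain plant
diversity, but it matters *what* varies. When patches differ in a
non-resource factor, species can specialise on different parts of the
gradient and many species may coexist through the spatial storage effect.
When patches differ in the **supply rate of a shared resource**, every
species grows best in the same (resource-rich) patches, and the scope for
coexistence is much narrower. `metacoex` implements a patch-structured
consumer–resource model that makes this precise, partitions invasion
growth rates into the classical variation-dependent coexistence
mechanisms, and runs invasion and community-assembly analyses on a
competition–dispersal tradeoff.

## The model

Across patches `x = 1..N`, plant densities `n_jx` and resource
concentrations `R_x` follow

    dn_jx/dt = −m_j n_jx + b_j R_x (p_j n_jx + (1 − p_j) ⟨n_j⟩_x)
    dR_x/dt  = S_x − Σ_j Q_j b_j R_x (p_j n_jx + (1 − p_j) ⟨n_j⟩_x)

where `m_j` is mortality, `b_j R_x` the resource-dependent establishment
rate, `Q_j` the resource cost per recruit, `p_j` the fraction of propagules
retained in the natal patch (the rest are redistributed uniformly over all
patches), `S_x` the patch supply rate, and `⟨·⟩_x` a patch mean. A single
species equilibrates at `n*_jx = S_x/(Q_j m_j)` with residual resource

    R*ᵐ_jx = m_j S_x / (b_j (p_j S_x + (1 − p_j) ⟨S⟩_x)),

the dispersal-modified analogue of the classical `R* = m_j/b_j`: widely
dispersing species under-deplete rich patches (net seed exporters), leaving
room there for a more retentive, competitively inferior species.

The metacommunity-scale low-density growth rate of an invader `i` against
residents `r` decomposes, per generation, into

    r̃_i / b_i = ΔE − ΔC + ΔI + Δκ

with ΔE the average-environment difference, ΔC the competition difference
(= `R*_i − R*_r` here), ΔI the spatial storage effect, and Δκ the
growth-density covariance. Because supply variation acts only through the
shared resource, the species environment response is identically zero and
**ΔE, ΔI and the relative nonlinearity ΔN vanish structurally**: growth-
density covariance is the only variation-dependent mechanism, with the
small-variance closed form

    Δκ/b_i ≈ var(s) (1 − p_r)² R*_r (p_i/(1−p_i) − p_r/(1−p_r)),

`s` being the relative supply deviations. Invasion rates are computed
exactly as the dominant eigenvalue of the invader's patch-coupled linear
growth operator on the residents' steady-state resource field.

## Worked example

Partition an invader's growth rate against a resident on a 20-patch
log-normal supply field (first trait row is the invader):

```bash
metacoex partition --traits pair.csv --n-patches 20 --seed 11 --out part.csv
```

with `pair.csv` holding invader (m=0.5, b=1, Q=1, p=0.8) and resident
(m=0.4, b=1, Q=1, p=0.3) prints

```json
{
  "delta_E": 0.0,
  "delta_C": 0.09999999999999995,
  "delta_I": 0.0,
  "delta_kappa": 0.3053375794389093,
  "delta_N": -2.7755575615628914e-17,
  "r_prime": -0.09999999999999998,
  "q_ir": 1.0,
  "r_tilde": 0.20533757943890937,
  "eigenvalue_rate": 0.2053375794389099
}
```

Read: the invader pays a competitive penalty (`r̃′ = R*_r − R*_i = −0.1`
per generation) but, by retaining 80% of its seeds against the resident's
30%, gains `Δκ = +0.305` from concentrating in under-depleted rich
patches — a positive overall invasion rate (`r̃ = 0.205`), which matches
the independent eigenvalue computation to nine digits. The environment,
storage-effect and relative-nonlinearity components are zero to machine
precision.

Other entry points: `metacoex simulate | equilibria | invade | pip |
assemble | community | figures` (see `--help`), or use the library
directly (`metacoex.sequential_assembly`, `metacoex.run_experiment`, ...).

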