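# infomech

Probabilistic inversion toolkit for mechanical characterization of
soft-tissue-like materials from stress-controlled tensile tests.  Given a
measured stress–strain record, it answers three questions at once:

1. **What are the material constants?** — posterior reconstruction of the
   parameters of a hypothesized constitutive law, with marginal densities,
   modes, medians and error bars.
2. **Which constitutive law should I trust?** — plausibility ranking of
   competing model classes by normalized evidence, with an automatic Occam
   penalty for unnecessary parameters.
3. **How should I run the test?** — information-gain scanning over candidate
   experimental designs (here, the test duration).

## The model

The framework works with *information densities*: unnormalized nonnegative
plausibility measures `f(x)` (zero = impossible), combined across independent
sources by logical conjunction `f1 AND f2 = f1·f2` and disjunction
`f1 OR f2 = f1 + f2`.  Dropping the normalization axiom makes the machinery
equivalent to Bayesian inference with a uniform prior — up to one constant —
once all parameters are *Jeffreys type*: positive quantities (moduli,
viscosities) mapped logarithmically onto a unit cube,

    ũ = ln(m / m_inf) / ln(m_sup / m_inf) ∈ [0, 1].

With Gaussian measurement noise (covariance `Co`) and optional Gaussian model
error (`Cm`), conjoining experiment and model and marginalizing the
observation space leaves the posterior weight `exp(−J)` with the misfit

    J(M) = ½ Σᵢⱼ (εᵢˢⁱᵐ(M) − εᵢᵒᵇˢ) [(Co+Cm)⁻¹]ᵢⱼ (εⱼˢⁱᵐ(M) − εⱼᵒᵇˢ).

Evidence of a model class `Hk` is the plain Monte-Carlo integral
`I_k = mean exp(−J)` over its unit cube (N = 2¹⁶ by default); plausibilities
are `p(Hk) = I_k / Σ I_j`.  Design quality of a candidate test `S` is scored
by the same integral on data synthesized at that design, normalized to `p(S)`
over the scanned grid, with the entropy terms `p log p` reported alongside.

Five candidate constitutive laws are built in, all Maxwell-type (elastic
spring in series with a dashpot, strain ε = ε_e + ε_v, dε_v/dt = σ/η):

| id | parameters | elastic law | dashpot |
|----|-----------|-------------|---------|
| H1 | μ, η, A    | σ = με + Aε² | η |
| H2 | μ, η       | σ = με       | η |
| H3 | μ          | σ = με       | — |
| H4 | μ, η, A, D | σ = με + Aε² + Dε³ | η |
| H5 | μ, A       | σ = με + Aε² | aging, η(t) = 3μt |

`A` and `D` are Landau-type higher-order elastic constants used in
biomechanical characterization.  The reference experiment is a triangular
stress protocol 0 → 1 MPa → 0 over 2 s, sampled every 0.1 s (21 points),
with Gaussian strain noise equivalent to 10 kPa of stress.

## Worked example

```python
import infomech as im

# synthesize the reference experiment: H1 truth mu=1 MPa, eta=10 MPa*s, A=15 kPa
obs = im.generate("H1", im.DEFAULT_TRUTH, im.DEFAULT_PROTOCOL, seed=1)

ps = im.reconstruct("H1", obs, seed=1)           # 2^16 Monte-Carlo samples
for p in ("mu", "eta", "A"):
    c = im.marginal_1d(ps, p)
    print(f"{p:>3}: mode {c.mode:.4g}  median {c.median:.4g}  std {c.std:.4g}")

rank = im.rank(["H1", "H2", "H3", "H4", "H5"], obs, seed=1)
for row in rank.table():
    print(f"{row['hypothesis']}: {row['percent']:.1f}%")
```

prints

```
 mu: mode 1e+06  median 1.003e+06  std 1.189e+04
eta: mode 1.029e+07  median 1.004e+07  std 4.955e+05
  A: mode 6371  median 6471  std 1.123e+04
H1: 41.0%
H2: 30.7%
H3: 0.0%
H4: 28.3%
H5: 0.0%
```

The shear modulus is recovered to a fraction of a percent and the viscosity
to ~3% of the generating values (1 MPa, 10 MPa·s).  The nonlinearity A is
only weakly identified by 21 noisy points — its marginal is a broad hump
whose peak wanders by a factor ~2–3 across noise realizations (here 6.4 kPa
against a generating 15 kPa, within its own ±1 std bar).  The ranking puts
the generating model first, annihilates the purely elastic H3 and the aging
H5, and keeps the nested H2/H4 competitive because the weak nonlinearity is
cheap to absorb or ignore — see `docs/methods.md` for why this closeness is
structural.

The same workflows are available from the shell:

```sh
infomech simulate-data --hypothesis H1 --mu 1MPa --eta 10MPa·s --A 15kPa \
    --T 1.0 --dt 0.1 --noise stress:10kPa --seed 42 --out obs.csv
infomech reconstruct --hypothesis H1 --data obs.csv --out posterior/
infomech rank-models --data obs.csv --hypotheses H1,H2,H3,H4,H5
infomech optimize-design --hypothesis H1 --range 0.2:5 --points 25
infomech demo --seed 7 --out demo/        # full pipeline, one summary JSON
```

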