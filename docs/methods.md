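# Methods

## Inference model

All inference runs on unnormalized information densities.  A density
`f(x) ≥ 0` encodes plausibility (0 = impossible); independent sources about
the same variables combine by conjunction (pointwise product) and
disjunction (pointwise sum).  Because no total-mass axiom is imposed,
normalization constants appear only where a probability is actually needed
(model ranking, design scanning), and there only as one division by a
Monte-Carlo integral.  With a uniform (noninformative) density on a bounded
parameter space, the construction coincides with Bayesian inference up to a
single constant; `tests/test_information.py` verifies this ratio is constant
to 1e-10 against an independently assembled Gaussian-likelihood posterior.

**Jeffreys parametrization.**  Moduli and viscosities are positive scale
parameters: stiffness vs compliance is an arbitrary choice, so the
noninformative density must be invariant under inversion.  Every parameter
is therefore mapped logarithmically from its admissible range
`[m_inf, m_sup]` onto [0, 1]; the unit cube carries the uniform density, and
physical samples are log-uniform.  Crucially, every hypothesis's cube has
noninformative mass exactly 1 regardless of dimension, which is what makes
evidences of 1-, 2-, 3- and 4-parameter model classes comparable and yields
the automatic Occam penalty.

**Gaussian particularization.**  Observation noise is Gaussian with diagonal
covariance `Co` (per-sample strain variances recorded by the generator or
supplied with external data); model error `Cm` defaults to zero but is
accepted (diagonal or full).  The misfit is the plain discrete sum over the
sampled instants,

    J(M) = ½ rᵀ (Co + Cm)⁻¹ r,

with no `dt` weighting: the sampled instants are independent information
sources, and a uniform `dt` factor would only rescale every `J` — invisible
to parameter reconstruction but not to evidence ratios, so the convention is
fixed here once.  Posterior weight is `exp(−J)`; evidence is its unit-cube
mean (plain Monte Carlo, N = 2¹⁶ default).  Evidence accumulation is done in
the log domain (shift by `J_min`), so an arbitrarily bad model class reports
a finite log-evidence instead of underflowing to zero, and rankings among
uniformly poor candidates remain defined.

## Constitutive models and forward solver

Five scalar Maxwell-type laws (see README table).  The stress history is the
known triangular protocol, so the dashpot rate `σ(t)/η(t)` never depends on
the state and the viscous strain is a pure quadrature: it is integrated by
the trapezoidal (Heun) rule on an internal grid of step `dt_int = 1e-3 s`
and interpolated to the sample instants.  For the aging dashpot of H5,
`η(t) = 3μt`, the rate `σ/(3μt)` has a removable singularity at `t = 0`
(the loading ramp gives the finite limit `σ_max/(3μT)`), which the
quadrature uses as the initial integrand value.  H5 is implemented as a hard
substitution of `η(t)` into the H1 dynamics — the only executable reading of
"H1 combined with a phenomenological viscosity law".

The nonlinear elastic spring `σ = με + Aε² (+ Dε³)` is inverted by Newton
iteration started from the linear solution `σ/μ`.  On the admissible region
(μ > 0, A, D ≥ 0, σ ≥ 0) the polynomial is strictly increasing and convex
for ε ≥ 0, so the iteration descends monotonically from an overestimate and
the selected root is the unique branch continuous with the linear limit; a
clip at zero guards rounding.  Roots are validated against `numpy.roots` in
the tests.  The batch path solves each distinct stress level only once (the
triangular protocol revisits every level on unloading) and skips the solve
entirely for linear-elastic laws.

Integrator checks: the linear Maxwell model has a closed-form piecewise
solution under the triangle; the solver matches it to sup-error < 1e-4 at
the default step, and the nesting relations (H4|D→0 = H1, H1|A→0 = H2,
H2|η→∞ → H3) hold to tight tolerances.

## Synthetic experiment

The generator reproduces the reference study conditions: truth H1 with
μ = 1 MPa, η = 10 MPa·s, A = 15 kPa; stress-controlled triangle 0 → 1 MPa →
0 over 2T = 2 s; samples every 0.1 s (21 instants); i.i.d. Gaussian strain
noise.  The study's noise statement admits two readings — an absolute
standard deviation quoted as 10 kPa of equivalent stress, and "10% per
datum".  Both are implemented (`stress`, `relative` modes, plus a plain
`absolute` mode); the default is the stress-equivalent reading,
`sd_ε = 10 kPa / μ = 0.01`, chosen because it is the generative statement
and because under the relative reading the nonlinearity A (whose imprint on
the strain curve is at most `A/μ ≈ 1.5%`) would be far below the noise floor
at every sample, leaving nothing for the reconstruction or the ranking to
resolve.  The relative mode applies an absolute floor (default 1e-3 strain)
so the zero-strain endpoints keep positive variance.

Per-sample variances used for generation are recorded on the observation
set and reused as `Co` during inference (self-consistent noise model).  The
generator does **not** emulate correlated or drifting sensor noise, stress
ramp imperfections, or model discrepancy between data-generating and fitted
physics beyond the hypothesis choice itself — so green tests certify the
statistical machinery under a correctly specified noise model, not
robustness to real instrument pathology.

## Parameter bounds

The study never states its admissible ranges; recovery quality and evidence
ratios both depend on them.  Defaults are one decade each way around the
reference truth (μ ∈ [0.1, 10] MPa, η ∈ [1, 100] MPa·s, A, D ∈ [1.5, 150]
kPa), keeping the truth at each cube's centre; all bounds are configurable.
Narrower ranges concentrate the Monte-Carlo sample and sharpen evidence
estimates but presume more prior knowledge.

## Estimators and numerical choices

* **Marginals**: weighted histograms of the normalized coordinate, 64 bins,
  normalized to unit area on [0, 1], lightly smoothed (3-bin moving
  average).  The reported mode is the smoothed peak refined by parabolic
  vertex interpolation: with the default noise the μ posterior (relative sd
  well below 1%) is narrower than one bin, and a bin-centre mode would carry
  a fixed half-bin (~3.7%) quantization error larger than the posterior
  standard deviation.  The literal peak-bin centre and the maximum-weight
  sample are both exposed (`mode_bin`, `mode_raw`).  Medians and standard
  deviations are weighted statistics of the physical values.
* **Common random numbers**: every reconstruction at a given seed draws one
  (N, 4) unit-cube sample and each hypothesis uses the columns of its
  active parameters.  Evidence *ratios* between nested model classes then
  share the coordinates of their common parameters, removing most of the
  Monte-Carlo noise from Occam comparisons while leaving each individual
  evidence a plain MC estimate.
* **Point estimate**: maximum-weight sample (ties broken by lowest index)
  for the joint mode; per-parameter marginal modes alongside.
* **2-D slices**: `exp(−J)` on a regular normalized lattice with the
  remaining parameters clamped at their marginal modes — a profile view, not
  a marginal.
* **Degenerate inputs**: forward failures become `J = +∞` (zero weight,
  never an abort); an all-zero-weight sample raises an explicit
  falsification signal, as does an all-zero evidence set in ranking.

## Design scanning

No data exist when a design is chosen, so "the experiment at design T" is
synthesized: for each grid duration (default 25 log-spaced values over
[0.2, 5] s, sampling interval fixed at the sensor's 0.1 s), observations are
generated from the reference truth with the declared noise, and the gain
f(T) is the evidence of the fitted hypothesis, averaged over 8 independent
noise replicates to tame scan variance.  Gains normalize to p(T); the
entropy terms `p log p` (literal, signed) and the Shannon total are reported
in a configurable log base.  Two optimality criteria are selectable: argmax
p(T) (default) and argmax of the entropy-term magnitude −p log p (which
peaks where p = 1/e); ties resolve to the shortest, cheapest test.

A structural property of this gain, visible in the tests: every additional
constrained sample multiplies the expected evidence by roughly e^(−1/2)
(each well-modelled datum contributes ~½ to the expected misfit), so f(T)
decays essentially monotonically with duration and the scan's optimum sits
at the short end of the grid.  Under this definition a short test maximizes
the *plausibility of agreement*, not the posterior concentration; users who
want classical experimental design (minimum posterior volume) should read
the per-design evidences inversely.  This behaviour is intrinsic to scoring
designs by an unnormalized evidence; it does not depend on the noise mode or
the replicate count.

## Known limitations

* The nonlinearity A is weakly identified by 21 samples at the default
  noise: its elastic imprint (≤1.5% of strain) is partially degenerate with
  a viscosity shift on the loading branch (both grow ~t²), so its marginal
  is a broad hump whose peak moves by a factor ~2–3 between noise
  realizations, and the μ–A slice shows a strongly correlated ridge.
  Reported error bars carry that width honestly.
* For the same reason, the evidence gap between the generating H1 and the
  nested H2/H4 is small and realization-dependent; only structurally wrong
  classes (H3, H5) are decisively falsified.  This is the expected behaviour
  of evidence-based selection when the extra physics sits at the noise
  floor.
* Plain Monte Carlo with sharply concentrated posteriors leaves few
  effective samples per run; N = 2¹⁶ matches the reference configuration,
  and no importance sampling or quasi-random scheme is layered on top by
  design.  Evidence standard errors are reported so users can judge.
* Only scalar uniaxial laws and a scalar design variable (duration) are
  implemented; tensorial constitutive models, strain-controlled protocols
  and sensor-placement optimization are out of scope.
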