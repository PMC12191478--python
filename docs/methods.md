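# Methods

## Scope and model system

The package analyzes Maillard browning kinetics in a sugarcane-juice
model system: sucrose 12.475, fructose 0.441, glucose 0.514 g/100 mL
with trace lysine, histidine and proline, evaporated under vacuum at
60–90 °C and sampled over a ~30 min run.  Concentrations are expressed
per gram of dissolved solids (g/g DS for sugars, µg/g DS for reaction
products), which normalizes out the concentration increase caused by
water removal.  Only the model system is represented; real juice adds
polyphenols, metal ions and a full amino-acid spectrum whose effects are
outside this package's scope.

## Simple-order kinetics

Responses are fitted to the three classical integrated rate laws by
ordinary least squares on the linearized form: C vs t (zero order),
ln C vs t (first order), and (1/C − 1/C₀) vs t through the origin with
C₀ anchored to the first observation (second order — the integrated form
is a difference from C₀, so a free intercept is not part of the model).
Times are stored in minutes and converted to hours before regression, so
rate constants are in h⁻¹.  R² is computed on the regressed scale and
the best order is the one with maximal R², ties broken toward the lower
order.  Linearized OLS (rather than nonlinear least squares) is the
standard of the food-kinetics literature and is what published rate
constants in this domain derive from.

Arrhenius analysis regresses ln|k| on 1/T (T in kelvin, offset 273.15
exactly); Eₐ = −slope·R with R = 8.314 J mol⁻¹ K⁻¹, reported in kJ/mol
with the slope's standard error scaled the same way.  The absolute value
admits rate constants of decreasing responses (e.g. lightness), whose
magnitudes grow with temperature like any rate; mixing signs within one
regression is rejected.  Activation energies are derived from the
zero-order rate-constant columns for every response — recomputation
shows the published values derive from that column even for responses
whose best-fitting order is first.  For the melanoidin response the
literature reports 22.276 kJ/mol in text and 22.353 ± 6.875 in tabular
form; regression over the printed rate constants gives 22.354, and the
package always reports its computed value.

## The melanoidin-formation network

Eleven species — sucrose, glucose, fructose, the 1,2-enediol, 3-DG,
5-HMF, GO, MGO, CML, CEL, melanoidins — are connected by fifteen
elementary steps, each pseudo-first-order in a single substrate
(amino-acid availability is absorbed into the rate constant, including
for the AGE-forming steps that chemically require lysine).  The
mass-action system is therefore linear, dy/dt = M(k)·y, with M a Metzler
matrix: nonnegative initial states provably stay nonnegative, and
melanoidins, a pure sink, are nondecreasing.

Two unit conventions matter.  Each species keeps its measurement unit
(sugars g/g DS, products µg/g DS, the enediol a dimensionless latent),
so the rate constants are unit-bearing and absorb substrate→product
scale conversions — this is the only reading under which the published
constants (k₈ ≈ 3×10⁴ h⁻¹ next to k₇ ≈ 10⁻² h⁻¹) are coherent, and it is
adopted rather than inventing unprinted conversion factors.  A
consequence is that with those constants the 3-DG and 5-HMF pools are
quasi-steady at very low absolute level; the synthetic data generated by
the model are self-consistent, but absolute intermediate levels should
not be read as physical µg/g values.

Integration uses an implicit stiff method (Radau, analytic constant
Jacobian M, rtol 10⁻⁸, atol 10⁻¹² × the largest initial value) — the
rate constants span seven orders of magnitude.  Because the system is
linear, the exact solution y(t) = expm(M·t)·y₀ is also implemented; it
serves as an independent cross-check of the solver (they agree within
10⁻⁶ relative, normalized per species by its trajectory maximum) and as
the fast propagator inside estimation loops, where it is both faster and
more accurate than step-wise integration.  Negative excursions within
solver tolerance are clipped to zero; larger ones abort with the failing
time.  Temperature enters only by selecting a rate-constant set; each
temperature is modeled independently, with no Arrhenius coupling inside
the ODE and no boiling-point ramp during evaporation.

## Multi-response estimation

The objective is weighted least squares over all observed responses,
with default weights 1/(mean observed value)² per response: residuals
become dimensionless, so g/g-scale sugars and µg/g-scale traces
contribute comparably.  The 1,2-enediol is unobservable and never
contributes residuals; its dynamics are constrained only through
downstream species.  The initial state is anchored to the t = 0 sample
(latent and unobserved species start at zero).

Optimization runs in log₁₀-parameter space — the natural scaling for
constants spanning seven decades — with box bounds [10⁻⁷, upper], upper
10⁶ for the two dehydration steps k₈/k₁₅, 10³ for the retro-aldol and
AGE steps k₁₀/k₁₃, 10² otherwise (an order of magnitude above the
largest published magnitudes).  Sixteen starts by default: one
deterministic central start at the mid-log point plus fifteen seeded
log-uniform draws, each refined by bounded trust-region least squares
(scipy `least_squares`/trf, ftol 10⁻¹⁴); the lowest-cost optimum wins.
The seed is mandatory, so fits replay exactly.

Uncertainty: the published analysis reports Bayesian 95% highest-
posterior-density ranges from multi-response software that is not
reproducible here; the package approximates them frequentistly.  The
linearized method uses a forward-difference Jacobian J of the weighted
residuals at the estimate, half-width 1.96·√diag(pinv(JᵀJ)·s²) with
s² = SSR/(n−p); a pseudoinverse keeps singular information matrices from
raising.  The bootstrap method refits ≥ 200 (configurable)
row-resampled-residual datasets from the point estimate and takes
percentile intervals.  A parameter is flagged *indeterminate* when any
of three symptoms holds: its scale-free sensitivity ‖J·k‖/√n falls below
10⁻⁴ (a factor-e change moves the dimensionless model output by less
than 10⁻⁴ RMS, far below any plausible measurement precision), its
estimate is pinned at a box bound, or its half-width is at least as
large as the estimate.  On data generated from the published 90 °C
constants this flags sucrose hydrolysis (true rate nil), the
enediol→glucose back reaction (invisible with the enediol unmeasured)
and the negligible CML/CEL→melanoidin steps, reproducing the published
indeterminacy pattern.

### Identifiability

Noise-free synthetic data from the 90 °C constants are recovered
essentially exactly (objective < 10⁻¹⁴; all identifiable parameters
within a few per mille).  Under realistic 5% noise a soft degeneracy
appears: the latent enediol's scale can be traded between its formation
constants (k₃, k₅) and its consumption constants (k₂, k₄, k₆) with only
a second-order effect on observables, so k₆ and the enolization
constants are poorly determined from noisy single-run data even though
the strongly observed steps (k₉, k₁₀, k₁₁, k₁₃) stay within ~10–25%.
This is a property of the experimental design (the enediol cannot be
quantified), not of the optimizer, and is the structural reason the
published intervals on those steps are wide.

## Synthetic data

The generator emulates the study design: forward simulation of the
published per-temperature network constants from the model-system recipe
(sugars divided by the total weighed solids to obtain g/g DS; products
and the latent start at zero), sampled at 0–30 min in 5 min steps (the
exact experimental grid is unpublished; the figures' resolution suggests
~5 min intervals), with multiplicative Gaussian noise of configurable CV
truncated at zero — the error structure of triplicate chromatographic
and colorimetric assays.  Default CV 0.05 is a modeling choice; the
study reports only triplicate ± values, not assay CVs.  The latent
enediol is dropped from generated tables by default, mimicking real
data.  Amino acids are not state variables (their availability is inside
the pseudo-first-order constants) and are recorded in the bundle
manifest only.  What the generator does *not* emulate: Brix increase and
volume loss during evaporation (the per-DS basis already normalizes
these), matrix effects of real juice, temperature drift, and
between-replicate batch effects.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to real-juice chemistry.

## Problem sizes and numerical choices

Test-suite and acceptance-script experiments use the study-scale design
throughout: 7 time points, 10 observed responses, 16 multistarts for the
headline recovery experiment (reduced to 4–8 starts and 40 bootstrap
resamples in auxiliary cross-checks, which probe agreement rather than
precision).  Oracle comparisons draw rate constants log-uniformly over
10⁻³–10⁴ h⁻¹, spanning the published stiffness range.  Tie-breaks and
edge rules are fixed and documented: perceivability bands are half-open
with boundaries assigned upward; model-selection ties go to the lower
order; timecourse files store full-precision `repr` values so round
trips are bit-exact.

## Known limitations

* The published network rate constants themselves cannot be reproduced
  from raw data (the experimental multi-response timecourses are not
  published at full precision); the package validates by parameter
  recovery on synthetic data plus the qualitative pathway orderings
  (k₈ ≫ k₇, k₁₀ ≫ k₉, k₁₃ > k₁₁, k₁₅ ≫ k₁₂, k₁₄).
* Frequentist intervals approximate the published Bayesian HPD ranges;
  coverage can differ for strongly nonlinear or bounded parameters.
* No reverse reactions, no temperature ramp, no real-juice matrix
  effects, no color-space conversions (instrument L\*a\*b\* values are
  taken as given).
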