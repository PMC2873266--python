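# Methods

## The stochastic model

`mshaz` implements multistage carcinogenesis models as a continuous-time
multitype branching process over a lattice of cell compartments
`I_(α, β, d)`, with `α ∈ {0, …, k−1}` the accumulated cancer-stage
mutations, `d ∈ {0, …, r}` the committed destabilization (genomic
instability, GI) type and `β` the level within that type (`β = 0` iff
`d = 0`, else `1 ≤ β ≤ m_d`).  The assumptions, in order of importance:

1. **Somatic Darwinian evolution / conditional independence.**  Given its
   ancestry and the parameter history, every cell evolves independently.
   This is what makes the process a branching process, the hazard
   computable from single-cell generating functions, and the Monte-Carlo
   simulator decomposable clone by clone.  It is a modelling idealization:
   real tissue is spatially organized (e.g. intestinal crypts) and cells
   communicate; nothing in this package represents such interactions.
2. **Irreversibility and exclusivity.**  Both mutation classes are
   irreversible, and a lineage committed to GI type `d` can never express
   another type (the pattern observed for chromosomal versus
   microsatellite instability in colorectal cancer).
3. **Deterministic stem-cell pool.**  The susceptible pool holds exactly
   `X(t)` cells at age `t`; it is not itself a birth–death process.  The
   pool seeds the lattice: initiations form an inhomogeneous Poisson
   process with intensity `X(t)·[M(0,0,0)(t) + Σ_d A((0,0,0)→d)(t)]`.
   Division and death rates on the root compartment are therefore
   meaningless and rejected by validation.
4. **Detection.**  A cell with `k` cancer-stage mutations is malignant
   (absorbing), and the first malignant cell defines the subject's event
   time, optionally plus a fixed latency lag.  A stochastic
   tumour-growth/detection phase can instead be expressed inside the
   family by giving the penultimate stage a positive division rate.

Per-cell transitions from `I_(α, β, d)` at age `t`: symmetric division at
`G(α,β,d)(t)`, death/differentiation at `D(α,β,d)(t)`, asymmetric
division into a daughter plus an `(α+1, β, d)` cell at `M(α,β,d)(t)`, and
asymmetric division into a daughter plus a cell one destabilization level
up at `A(α,β,d)(t)` (from the uncommitted plane, one schedule per target
type; `A ≡ 0` once `β = m_d`).  First commitment maps `(α,0,0) →
(α,1,d)`: levels start at 1 once committed, which removes degenerate
"type-d with zero levels" states — the simpler models are encoded as
`r = 0`, not as a type with `m_d = 0`.

All rates are **piecewise-constant right-continuous step functions of
age** (`RateSchedule`), so a perturbation "at age t0" acts on `[t0, ∞)`.
This is sufficient for every analysis the package targets (instantaneous
perturbations, exposure windows, age-varying baseline rates);
continuously varying rates are out of scope.

`initial_fractions` places the age-0 stem cells across compartments; mass
outside the root expresses the two-populations-at-birth variant (e.g. a
subpopulation carrying one mutation from birth, as in heritable cancer
syndromes).  Those cells form `round(X(0)·fraction)` independent founder
clones.

## Hazard computation

Let `φ_c[t, s]` be the probability that one cell in non-malignant
compartment `c` at age `s` has no malignant descendant by age `t` (the
partial probability generating function evaluated at the point whose
malignant coordinate is 0, all others 1).  The Kolmogorov backward
equations, assembled from the per-cell transitions (daughter PGFs
multiply under conditional independence), are, writing `ρ = G+D+M+ΣA` and
suppressing arguments,

    dφ_c/ds = ρ φ_c − [G φ_c² + D + M φ_c φ_up + Σ_j A_j φ_c φ_tgt_j],

with `φ ≡ 0` for the malignant class and `φ_c[t, t] = 1`.  The survivor
function of a subject is

    S(t) = exp(−H(t)),
    H(t) = ∫₀ᵗ X(u)[M₀(u)(1−φ_up(t,u)) + Σ_d A_d(u)(1−φ_(0,1,d)(t,u))]du
           + Σ_c N_c · (−log φ_c[t, 0]),

(the pool integral plus founder-clone terms) and `h(t) = dH/dt` brings in
`∂φ/∂t`, which satisfies the `t`-derivative of the backward system.  Two
augmentation variables `g(t, s)` and `K(t, s)` accumulate exactly these
integrals during the backward sweep, so that `h(t) = g(t, 0)` (plus
`X·M₀` itself when `k = 1`, where initiation is malignancy) and
`H(t) = K(t, 0)`, with `K(t, t) = 0`.

**Numerical formulation.**  The engine integrates `χ = 1 − φ` and
`w = ∂χ/∂t` rather than `φ`:

    dχ_c/ds = (D−G) χ_c + G χ_c² − M (1−χ_c) χ_up − Σ_j A_j (1−χ_c) χ_tgt_j,

with `χ = 1` on the malignant class.  The two systems are algebraically
identical, but in the small-rate multistage regime `1 − φ` can be of
order 1e-40: `φ` itself would round to exactly 1.0 in double precision
while `χ` retains full relative accuracy.  For the same reason the
default absolute tolerance is tiny (`atol = 1e-60`), making the
integrator's error control effectively *relative, component by
component*; `rtol = 1e-8` by default.  Integration pieces are split at
every schedule breakpoint so rate discontinuities never fall inside a
solver step (explicit Runge–Kutta via `scipy.integrate.solve_ivp`; the
dynamics, with per-year rates below ~1, are not stiff on a 110-year
span).

Two execution paths produce identical results (tested against each
other):

* **backward** — one ODE solve in `s` from `s = t` down to 0 per
  requested age: the general algorithm, valid for any schedules.
* **homogeneous** — when every schedule is constant the process is
  time-homogeneous, `φ[t, s] = φ[t−s, 0]`, the `∂/∂t` block is not needed
  (`h(t) = X[M₀ χ_up(t) + Σ_d A_d χ_(0,1,d)(t)]` directly), and a single
  forward solve over the whole age range yields the entire curve.  Chosen
  automatically for constant specs.

Hazard values in `[−1e-12, 0)` are round-off and clipped to zero; larger
negatives raise an error rather than being hidden.  A fixed detection
latency `L` shifts the reported curve: `h(t) = h_raw(t − L)`, zero before
`L`.  The default grid is ages 0–110 in steps of 0.25 years.

## Monte-Carlo oracle

`simulate_cohort` is an exact event-driven simulation of the same
process, sharing only the compiled rate arrays with the engine — an
independent check of both the backward-equation derivation and its
numerics.  Waiting times are exponential in the current total clone
propensity; when a waiting time would cross a schedule breakpoint the
clock advances to the breakpoint and the draw is repeated (exact by
memorylessness), so there is no time-discretization bias.  Clones
terminate on extinction, first malignancy, the horizon, or the subject's
current earliest malignancy time (later events cannot matter).
Supercritical clones are legitimate clonal expansion; a configurable
1e6-cell cap guards runtime and raises an error naming the
fastest-growing compartment's net growth rate.

Seed contract: subject `i` uses an independent stream keyed
`(master_seed, i)` through `numpy.random.SeedSequence`, so results are
reproducible, cohorts can be split or extended without correlating
subjects, and a full cohort equals the concatenation of seeded halves
(tested exactly).  Kernels are numba-compiled; 20,000 subjects across the
eight-spec battery run in seconds.

The engine/oracle agreement test compares engine survival with the
empirical cumulative incidence of 20,000 subjects per battery spec at
every grid age against the 95% Dvoretzky–Kiefer–Wolfowitz band
(`ε = sqrt(ln(2/0.05)/2n) ≈ 0.0096`).

## Perturbation studies

`perturbation_jump` measures the instantaneous hazard response to
multiplying one parameter schedule by a factor on `[t0, ∞)`.  The
reported quantity is the discontinuity of the *excess* hazard across
`t0`, normalized by the pre-perturbation hazard:

    J = |[h_p − h_b](t0+ε) − [h_p − h_b](t0−ε)| / h_b(t0−ε),  ε = 1e-3 y.

Differencing against the unperturbed curve removes the smooth baseline
drift `h′(t0)·2ε/h ≈ 1e-4`, which would otherwise swamp the genuinely
delayed responses (order 1e-8 here); the excess is identically zero below
`t0`, so `J` isolates the step itself.  With `ε = 1e-3` years and a
threshold of 1e-6 the classification is sharp across the study battery:
last-stage conversion `M(k−1)` steps the hazard by approximately
`factor − 1` (a true discontinuity: the terminal boundary condition
itself changes), `M(k−2)`, `G(k−1)`, `D(k−1)` respond within the `ε`
window (measured jumps ~1e-4–1e-3), while everything earlier measures
below ~1e-7.  Consequently the smallest stage count with a
perturbation-silent parameter is `k = 3`: in a two-stage model every
parameter is within one stage of malignancy.  Jump computations use the
backward path for both curves with `rtol = 1e-10` so solver error cancels
in the difference.

`excess_risk_decay` follows `h_perturbed − h_baseline` after a transient
exposure window.  The decay-study models use intermediate-cell net
*inactivation* `G = 0.05, D = 0.17` per year (net −0.12/y): clones
initiated during the window are cleared on a ~decade scale, and with two
intermediate stages the clearance acts as a cascade (excess ~
`t·e^(−0.12 t)`), which still brings the age-110 excess below 1% of its
peak.  With promotion-dominant parameters (net +0.01/y, as in the oracle
battery) the excess relaxes only on a ~10³-year scale — the relaxation
property is asymptotic in age and a lifetime horizon can only exhibit it
in a clearance-dominated regime; this is a property of the models, not of
the implementation.

## Inference and identifiability

The population incidence rate is equated with the model hazard
(rare-disease assumption; depletion of the at-risk pool by prevalent
cases is ignored), so a band `[lo, hi)` with `PY` person-years has
expected cases `PY·(H(hi) − H(lo))/(hi − lo)` — the band *average* via
cumulative-hazard differences, exact for piecewise-constant person-years,
rather than a midpoint approximation.  Case counts are Poisson;
`loglik` returns −∞ when data sit in a zero-expectation band.  A Pearson
`X²/dof` quasi-likelihood scale is available descriptively
(`overdispersion_scale`); it never reweights the likelihood.

`fit` maximizes the Poisson likelihood over log-transformed schedule
constants (L-BFGS-B), from the supplied values plus Latin-hypercube
multistarts (default 8) across the bounds — the log scale and multistart
guard against the gentle ridges implied by parameter redundancy.

`sensitivity_matrix` builds `S[i, j] = ∂h(t_i)/∂log θ_j` by central
finite differences (relative step 1e-4) and `numerical_rank` counts
singular values above `tol_ratio` (default 1e-6) times the largest.  The
sensitivity solves default to `rtol = 1e-12`: an exact redundancy's
singular value is limited by finite-difference and solver error, and this
tolerance puts that floor near 1e-9 relative — two to three decades below
the threshold and well separated from genuine combinations.  For the
two-stage clonal expansion model the analysis returns rank 3 of the five
parameters (two redundancies); for GI models with `r` destabilization
types it respects the bound `rank ≤ p − (r + 1)`.  Two caveats are
inherent: (i) these hazard families are *sloppy* — singular values decay
rapidly, so "estimable" combinations near any finite threshold can be
practically unestimable from realistic data; the identifiability study
model therefore uses a conversion-dominant parameterization
(`M1 = 1e-2`/cell-y) in which all three estimable combinations leave a
resolvable imprint and the spectral gap (~4e-2 versus ~1e-9) is stable
across grid density and thresholds 1e-8–1e-4; (ii) a finite age grid
can in principle misstate the estimable count at extreme parameter
corners — the rank is a local, numerical diagnosis, not a theorem.

`generate_synthetic_incidence` draws Poisson tables from a model's own
hazard on the standard layout (eighteen 5-year bands, ages 0–90, default
1e8 person-years per band, seeded).  It emulates the *structure* of
registry tables, not their messiness: no overdispersion, no cohort or
period effects, no age-specific population sizes, no competing mortality.
Tests passing on these tables therefore validate the estimation
machinery, not robustness to real registry artefacts.

## Study battery and problem sizes

The eight-spec battery (`mshaz.battery`) covers all four family labels
and the two-populations feature, with initiation fluxes `X·M(0)` of
0.01–1 per year, net intermediate growth between −0.02 and +0.05 per
year, and lifetime cumulative incidences of about 0.3%–40%, so the
Monte-Carlo comparison has power without runaway clones.  Standard
problem sizes: 20,000-subject cohorts for oracle agreement, 10,000 for
single-distribution checks, ages 1–100 (step 1) for sensitivity grids,
20 seeds for recovery studies.  The parameter-recovery study generates
tables from a two-stage initiation model (`X = 1e7`, `M0 = M1 = 1e-6`)
and recovers the identifiable product `X·M0·M1` through a fit of the free
initiation rate.

## Limitations

No Bayesian fitting with informative priors; no cohort/period effects or
heritable/sporadic stratification; no spatial (crypt) structure or
cell–cell interaction; no post-malignancy tumour-growth, angiogenesis or
cell-cycle modelling (beyond the penultimate-stage device); continuous
rate variation only via fine piecewise-constant schedules.
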