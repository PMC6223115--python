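# Methods

## Model

Spine-head volume `V` (µm³) is treated as a one-dimensional stochastic
process on `[V_min, V_max] = [0.01, 1.0]` µm³ observed every 2 days. All
rates in the package are expressed per 2-day interval; the annotation "per
day" that sometimes accompanies drift values in the literature is treated
as the same per-interval unit, since every estimator in the chain operates
on 2-day differences.

Two fluctuation components with very different timescales are modelled
separately:

* **Fast component** — minute-scale, zero-mean volume fluctuations (actin
  remodelling plus measurement error). They are *observation noise*: they
  decorate each measurement but carry no memory between sessions. Their
  amplitude is the SD of the difference of two closely spaced
  measurements, `σ_fast(V) = 0.115 V^(2/3) + 0.0051`; consequently the
  per-observation noise SD is `σ_fast(V)/√2`.
* **Slow component** — the day-scale process that determines growth,
  shrinkage and elimination: per-interval increments with mean
  `μ(V) = −0.12 V^(2/3) + 0.029` and SD
  `σ_slow(V) = a·(V^(2/3) − 0.06) + 0.02` (`a` = 0.198 wild type, 0.278
  Fmr1 knockout; the anchor abscissa 0.06 is `0.015^(2/3)` rounded). Both
  components share the quadrature law `σ² = σ_fast² + σ_slow²`.

The exponent 2/3 (surface-area scaling) is fixed, not fitted.

The slow law admits two consistent readings, and the package implements
both:

1. **Discrete transition kernel** (what the data define): per 2-day
   interval, `V' | V ~ N(V + μ(V), σ_slow(V)²)`, folded at `V_max`, with
   elimination when the step lands at or below `V_min`. All quantities a
   2-day imaging protocol can measure live at this resolution.
2. **Continuous embedding**: the Itô diffusion
   `dV = μ(V) dt + σ_slow(V) dW` with `Var[W] = 1` per interval, reflecting
   at `V_max` and reflecting or absorbing at `V_min`. This is the natural
   object for Fokker–Planck analysis.

The two readings agree on the stationary distribution to well below a
percent but differ measurably on two points, both deliberate:

* **Elimination.** The continuous first-passage probability over one
  interval (absorbing boundary, stationary initial condition) is 5.69%
  (WT) / 10.42% (KO). The discrete-observation rate — the probability
  that the *next observation* falls below `V_min`,
  `E = 100 ∫ f(y) Φ((V_min − y − μ(y))/σ_slow(y)) dy` — is 3.81% / 6.88%.
  A first passage between sessions is unobservable; a spine that dips
  below threshold and recovers by the next session is never scored as
  eliminated. The discrete-observation functional is therefore the model
  analogue of a measured 2-day elimination rate and is the headline
  prediction; the first-passage functional is retained as the
  mathematically standard absorbing-boundary quantity and as the target of
  the Monte-Carlo/PDE cross-validation.
* **Finite-interval moments.** Over a full interval the continuous
  diffusion's conditional SD is shrunk below `σ_slow(V₀)` by mean
  reversion (`μ'(V) ≈ −0.12` per interval at mid volumes, giving an SD
  factor ≈ 0.92–0.94). Since the coefficient laws are *defined* as
  per-interval statistics, the synthetic-cohort generator advances latent
  volumes with the discrete kernel by default (`latent_step="discrete"`);
  the continuous embedding (`latent_step="sde"`) is available for studies
  of the embedding itself.

## Fokker–Planck numerics

The transition solver discretizes the conservative form
`∂p/∂t = −∂J/∂V`, `J = μp − ∂(Dp)/∂V`, `D = σ_slow²/2`, by finite volumes
on a uniform grid with half-width boundary cells, Scharfetter–Gummel
(exponentially fitted) face fluxes in `q = Dp`, and Crank–Nicolson time
stepping (sparse LU, one factorization per solve). Consequences:

* reflecting boundaries conserve the trapezoidal mass to machine
  precision (< 1e-12 per step, asserted < 1e-6 in tests);
* the scheme upwinds automatically as `D → 0`, so degenerate
  advection-dominated configurations remain stable;
* the discrete zero-flux stationary state coincides with
  `stationary_density()`, which evaluates `exp(∫ 2μ/σ² dV)/σ²` using the
  same face-averaged O(h²) quadrature — the stationary density is the
  solver's exact fixed point, not merely close to it.

Defaults: 4000 grid nodes, 2000 time steps per interval. Doubling both
changes the elimination rate by < 0.001 percentage points (tolerance
0.05). The closed-form stationary means were additionally cross-checked
against adaptive quadrature (`scipy.integrate.quad`): 0.133324 µm³ (WT),
0.136022 µm³ (KO), converged to the digits shown.

Absorbing boundaries are imposed as a Dirichlet row (`p(V_min) = 0`);
survival is the trapezoidal integral of the evolved density. Dirac initial
conditions excite Crank–Nicolson's marginally damped stiff modes; for such
initial data use time steps ≤ 0.025 interval (the tests do).

## Langevin simulation

Euler–Maruyama under the Itô convention, coefficients frozen at the
pre-step state (clamped into the domain), fold reflection at the
boundaries, default `dt = 0.005` interval (~14 min of model time). With an
absorbing boundary, paths that step across `V_min` are absorbed, and
surviving steps are additionally absorbed with the Brownian-bridge
within-step crossing probability `exp(−2(v₀−V_min)(v₁−V_min)/(σ²dt))`;
without this correction the discrete scheme underestimates first passage
by ~0.4 percentage points at the default step, which would exceed the
Monte-Carlo error at the oracle sample sizes (10⁵ paths). With it, the
Monte-Carlo absorbed fraction matches the PDE rate within sampling error
(5.69% vs 5.69% for WT at 10⁵ paths). Ensembles are bit-reproducible for
a fixed seed; the random stream is consumed uniformly so that survival
does not perturb later draws.

## Calibration

The fluorescence profile of a calibration sphere (homogeneous GFP-filled
ball of radius `R`, Gaussian PSF with `σ_x = 0.24` µm, `σ_z = 0.91` µm —
0.56 / 2.1 µm FWHM) reduces analytically: the auxiliary axial integral
contributes `√(2π)σ_z`, the axial ball extent gives the chord length, and
the angular part of the lateral blur gives a modified Bessel factor,
leaving a single radial integral evaluated by Gauss–Legendre quadrature
after the substitution `ρ = R sin t` (which removes the edge singularity;
120 nodes, ~1e-6 relative accuracy against the direct four-fold
integral). Amplitude and radius are fitted by unweighted least squares
(`scipy.optimize.least_squares`); the noise model of real profile
measurements is unknown, so no weighting is attempted. A fit that
explains < 20% of the profile variance is rejected as non-peak-like.
Volume conversion is linear: `V = F · (V/F)_calib / s_session`, with
per-session factors normalizing day-to-day expression changes and
negative background-subtracted fluorescence clipped to zero with a
warning. Synthetic z-stacks are rendered with the same analytic
blurred-ball quadrature per voxel (pixel 0.124 µm, z-step 0.4 µm), so
summed fluorescence equals `A·4/3πR³` to sampling accuracy and the
z-projected profile round-trips through the fitter within one pixel.

## Estimation

Transitions are all (spine, session, session+interval) volume pairs;
pairs ending in an elimination are diverted to the turnover path (the
volume change to an invisible spine is undefined). Transitions are sorted
by starting volume and grouped into fixed-count bins (32 per bin for 2-day
data, 30 for 10-min data; a remainder below half a bin merges into the
previous bin). Per bin: mean change, SD about the bin mean with the
population divisor `N`, representative volume = median starting volume,
chi-square 95% interval for the SD, SEM for the mean. The fast law is an
unconstrained line through the 10-min bin SDs (drift fitted as zero); the
slow SDs are `√(σ² − σ_fast²)` clipped at zero (clipped bins flagged); the
slow slope is a one-parameter least-squares line constrained through the
anchor `(0.015^(2/3), 0.02)` — the smallest bin's median volume and
typical SD, chosen because small spines dominate turnover; the drift line
is unconstrained and pooled across groups. Group slopes are compared by a
no-intercept linear model in anchored coordinates with a group×slope
interaction (statsmodels OLS t-test); elimination fractions are compared
per dendrite by Mann–Whitney U; volume distributions by
Kolmogorov–Smirnov.

## Synthetic cohorts

`generate_cohort` emulates the study design: two groups (754 / 878 spines
on 15 / 20 dendrites in 5 mice each, labels assigned round-robin), five
sessions at 2-day spacing, initial latent volumes drawn from each group's
stationary density, latent advance by the discrete kernel with
elimination at `V_min` (an eliminated spine appears once more with volume
0 and `eliminated=True`, then its series ends), and per-observation fast
noise `N(0, σ_fast(V)/√2)` truncated at zero. A 10-min mode freezes the
latent volume and emits 7 observations (fast-noise only, drift zero); a
fixed-tissue mode emits constant volumes (the no-fluctuation control). An
off-by-default top-up option replaces eliminated spines with fresh
stationary draws to keep cohort size constant. No spine-formation process
is modelled, matching the elimination-only model; filopodia are assumed
pre-excluded from the tables.

What the generator does **not** emulate: registration and segmentation
artifacts, hierarchical dendrite/animal variance components (the model has
none), volume-dependent detection failures, and real spines' excursions
beyond 1.0 µm³. Passing tests therefore certify the internal consistency
of model, estimators and solvers — not the fidelity of any of these
simplifications to real tissue.

### Estimator attenuation — expected, not a bug

Applying the estimation chain to cohorts generated from known laws
recovers slow slopes ~10–15% *below* the generating values (e.g. WT
0.17–0.18 vs 0.198; the fast slope recovers ~0.104 vs 0.115) and a
somewhat steepened drift line. Three mechanisms, all shared with real
measurements: (i) errors-in-variables — binning by noise-contaminated
observed volumes flattens any volume-dependence; (ii) excluding
elimination-ending transitions truncates the lower tail of ΔV in the
smallest bins; (iii) fold reflection at `V_max` compresses the top bins.
Because the published coefficient laws are themselves measurement-level
fits of noisy volumes, re-measuring synthetic data generated from those
laws attenuates a second time; the recovery loop is inherently open by
about the attenuation factor. The package reports recovered slopes as
estimated, without correction.

## Parameters and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| `V_min`, `V_max` | 0.01, 1.0 | µm³ | volumes outside this range are rare; `V_min` doubles as elimination threshold |
| slow slope `a` | 0.198 WT / 0.278 KO | µm³ per √interval per `V^(2/3)` | anchored fits of the 2-day SDs |
| anchor | (0.015 µm³, 0.02 µm³) | — | median volume / typical SD of the smallest bin |
| drift | −0.12 `V^(2/3)` + 0.029 | µm³ per interval | pooled fit, shared between groups; zero at 0.12 µm³ |
| fast law | 0.115 `V^(2/3)` + 0.0051 | µm³ | SD of 10-min volume differences, shared between groups |
| bin sizes | 32 (2-day), 30 (10-min) | spines | fixed-count pooling of similar-volume spines |
| FP grid | 4000 × 2000 | nodes × steps/interval | refinement-stable to < 0.001 pp in elimination |
| SDE step | 0.005 | interval | boundary bias below Monte-Carlo noise at 10⁵ paths |
| cohort scale | 754/878 spines, 5 sessions | — | study design scale |

Test and acceptance problem sizes are scaled to run quickly while keeping
every statistical conclusion stable: 12 recovery replicates and 10 power
replicates in the test suite, 50 recovery replicates in the acceptance
script, 10⁵ paths for the Monte-Carlo/PDE cross-check, 3000 paths for the
long-run histogram check.

## Known limitations

* The recovery loop is attenuated as described above; any check that
  expects exact closure of generate→estimate will flag it.
* The discrete-observation and first-passage elimination functionals
  bracket the truth for any real observation protocol; the package makes
  the choice explicit rather than blending them.
* The Crank–Nicolson stepper is not L-stable; Dirac initial data need the
  smaller time steps noted above.
* No spine formation: long simulations only deplete cohorts (top-up mode
  sidesteps this without modelling genesis).
* The calibration stage models an isolated spherical calibration spine;
  overlapping structures are flagged, not unmixed.
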