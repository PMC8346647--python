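# Methods

## Model

`pyrodaem` analyses slow (constant heating rate) pyrolysis of biomass
constituents with the distributed activation energy model (DAEM): the sample
is a continuum of independent, irreversible first-order reactions whose
activation energies E follow a probability density F(E).  Under a linear
program T(t) = T₀ + βt the conversion rate per Kelvin of one
pseudo-component is

    dx/dT = ∫₀^∞ (k₀/β) · exp[ −( E/(RT) + (k₀/β) ∫_{T₀}^{T} e^{−E/(RT′)} dT′ ) ] · F(E) dE

and a sample with N pseudo-components (distinct decomposition stages) is the
mixture Σᵢ cᵢ·dx/dT|ᵢ with contribution fractions cᵢ on the probability
simplex.  Conversion is mass-based, x = (m₀ − m)/(m₀ − m∞), with m₀ and m∞
taken at the analysis-window boundaries.

Four F(E) families are supported — Gaussian, Logistic, Gumbel and Cauchy —
each parameterized by a location Ē and scale σ.  At equal (Ē, σ) their mode
heights order as Gaussian 1/(σ√2π) > Gumbel 1/(eσ) > Cauchy 1/(πσ) >
Logistic 1/(4σ); `matched_sigma` provides the closed-form scale ratios that
equalize the modes for shape comparisons.  The Gumbel is the only skewed
family.  The Logistic density is the standard sech² form, the only member of
its family that is a normalized probability density.

The frequency factor is fixed at k₀ = 1.67 × 10¹³ s⁻¹ for every component
(overridable per component).  Fixing k₀ defeats the kinetic compensation
effect — many (k₀, E) pairs produce near-identical rate curves — so the
fitted Ē values are comparable across samples and studies.

### Assumptions

* first-order kinetics within each energy channel; no reverse reactions;
* the sample follows the programmed temperature (low β minimizes thermal
  lag; the direction of the lag is still testable: raising β raises the
  apparent peak temperature);
* no transport limitation inside the pellet, no gas-phase chemistry;
* DSC is qualitative: only the sign and location of heat-flow events are
  interpreted, never calorimetric magnitudes.

## Numerics

* **Internal units** J mol⁻¹ and Kelvin everywhere; °C and kJ mol⁻¹ only in
  files, reports and the CLI.
* **Inner temperature integral** by cumulative trapezoid on a refined grid
  (step ≤ 0.25 K) merged with the output grid, cached per grid during
  fitting.  The exponential-integral closed form
  ∫e^{−a/T}dT = T·e^{−a/T} − a·E₁(a/T) is kept as an independent test
  oracle only.  The trapezoid's relative error scales as (E/(RT²))²h²/12 —
  ≈ 2×10⁻⁵ at the cellulose peak, tested against the closed form at 2×10⁻⁴
  down to 400 K where the integral is ~10⁻²³.
* **Outer energy integral**: 201 equally spaced nodes with trapezoid
  weights on a truncated support from the family quantile function
  (coverage 0.9999; weights renormalized to 1).  The Cauchy family has no
  finite variance and its 0.9999-coverage interval (±6366σ) cannot be
  resolved by equally spaced nodes, so it uses a built-in finite truncation
  of coverage 0.98 (±31.8σ).  Energies are floored at 1 kJ mol⁻¹ (negative
  activation energies are unphysical); for heavy-tailed or very broad
  distributions the floor can cut real lower-tail mass, which the
  renormalization absorbs.
* **Degenerate scales**: σ < 1 J mol⁻¹ collapses to a delta distribution
  (single energy node), avoiding catastrophic node clustering; the printed
  lignin parameter sets contain σ values down to 2.3 J mol⁻¹, just above
  this regime.
* **Overflow**: exponents are clipped at ±700 so extreme parameters
  underflow to zero rather than propagate non-finite values.
* **Peak location** is the grid argmax refined by a parabola through the
  three surrounding points.  The Kissinger condition
  E·β/(R·Tp²) = k₀·e^{−E/(R·Tp)} links a peak temperature to an energy;
  the inversion E = R·Tp·W(k₀Tp/β) (Lambert W) seeds the fits.

## Fitting

The objective is the unweighted residual dx/dT|exp − dx/dT|sim, minimized
by bounded trust-region least squares (`scipy.optimize.least_squares`,
method `trf`, 2-point Jacobians).  Per component the free parameters are
(Ē, σ) within [50, 350] and [0.001, 60] kJ mol⁻¹ (bounds pad the
62–271 kJ mol⁻¹ range reported for lignocellulosic pyrolysis and are
config-exposed); the N fractions are represented by N−1 unconstrained
logits mapped through a softmax, so Σcᵢ = 1 holds by construction in every
iterate and in every reported result.

Initialization detects up to N prominent DTG peaks (prominence ≥ 2 % of
span, width ≥ 5 K, separation ≥ 10 K), inverts the Kissinger condition for
each peak's Ē, estimates σ from the part of the observed half-height width
exceeding the intrinsic single-reaction width, and sets fractions from
segment areas.  Missing peaks are padded on the high-temperature shoulder;
a peakless curve falls back to quantile-spaced temperatures (flagged).
One deterministic start is followed by up to `max_restarts` seeded
restarts (log-normal factor 0.05 on Ē and σ, Dirichlet on fractions);
the best residual norm wins, and remaining restarts are skipped once a
start reproduces the data to numerical exactness (residual RMS below 10⁻⁷
of the peak rate).  Everything is deterministic given (data, config, seed).
Iterations are capped (default 150 main evaluations per start) to bound
runtime; goodness of fit is R² = 1 − SS_res/SS_tot.

`fit_daem` accepts either one DTG curve or a list of replicate curves; in
the latter case the replicate residual vectors are concatenated so both
runs constrain the parameters jointly, and R² is computed over the pooled
points.  The pipeline entry point instead averages replicates first
(matching the averaged curves shown in thermogram figures); both routes
are exposed.

`model_scan` fits every (component count, family) combination and sorts by
R²; ties within 10⁻⁴ break toward fewer components (parsimony).

## DTG/DSC concordance

The pseudo-component count is rationalized by comparing mass-loss and
heat-flow structure.  DTG peaks are detected with prominence ≥ 5 % of span,
width ≥ 8 K and separation ≥ 15 K.  Thermal events are located from the
DSC-derivative channel: its median is removed (cancelling a linear
baseline drift), it is integrated back to a drift-free heat-flow shape,
and significant local maxima and minima of that shape are taken — an
endothermic dip riding on a broad exothermic hump is an event even though
the heat flow never changes sign there.  An extremum must additionally
deviate from the curve's quiescent level (lower/upper quartile) in its own
direction, which rejects the recovery shoulder between two adjacent dips.
Events within 15 °C of a DTG peak are matched; the suggested count is
DTG peaks plus unmatched DSC events.  Stages that move heat but little
mass (char decomposition) are counted this way even when the mixture DTG
shows them only as shoulders — which is precisely the argument for using
DSC alongside TGA.

Windows are classified endothermic/exothermic from the sign of the mean
heat flow (exothermic positive), with an ambiguity band of three standard
errors of the curve's short-scale noise (MAD of first differences).

## Preprocessing

Savitzky–Golay smoothing (window 21, order 3 by default, `mode="interp"`
edge handling) is applied once to the mass and heat-flow channels before
differentiation — never twice, since aggressive filtering can erase minor
DTG peaks.  Derivatives are central differences on the (de-duplicated,
possibly non-uniform) grid.  The analysis window is 200–600 °C: below
200 °C moisture and light volatiles dominate and are excluded from x by
defining m₀ at the window start.  Replicates are interpolated to the
intersection range at 0.5 K, mass-normalized per run (sample loadings
differ), and averaged point-wise.

## Synthetic data generator

`synthetic` emulates the study conditions: 5 °C min⁻¹ from 22 to 600 °C,
10–20 mg loadings, two replicates per experiment, and the printed kinetic
parameter tables as ground truth (cellulose: one component per family;
lignin: four).  The mass channel is m₀ − (m₀−m∞)·x(T) plus Gaussian point
noise (default SD 0.1 % of m₀).  The heat-flow channel is the signed sum
of per-component rates, β·Σ signᵢ·magᵢ·cᵢ·(dx/dT|ᵢ), plus a linear
baseline drift (0.05 mW per 100 K) and point noise (0.01 mW).  Signs
follow the published thermodynamic assignments (cellulose endothermic;
lignin stages 1 and 4 endothermic-leaning, 2 and 3 exothermic).
Magnitudes are arbitrary units chosen once so that each stage is a
discernible fluctuation of the curve with relative sizes resembling the
published thermograms (1200, 800, 2400, 3000 for lignin stages 1–4;
1200 for cellulose); no calorimetric meaning is attached.

What the generator does *not* emulate: moisture loss below 200 °C, heat
transfer lag inside the pellet, instrument baseline curvature beyond a
linear drift, and autocorrelated noise.  Passing round-trip tests
therefore shows the estimator is correct and well-conditioned under the
model's own assumptions plus realistic point noise — not that the model
is a complete description of a physical instrument record.

## Problem sizes and defaults

Analysis grid 200–600 °C at 0.5 K (801 points); inner integration grid
≤ 0.25 K; 201 energy nodes per component; fits use up to 150 main
evaluations per start and 3 restarts (tests and the acceptance script use
0–3 restarts depending on the case).  The dense verification oracle uses
4001 energy nodes with the closed-form inner integral.  Round-trip
tolerances follow the recovery tests: Ē within 0.5 kJ mol⁻¹ (single
component), 2 kJ mol⁻¹ (four overlapping components), fractions within
0.05.

## Known limitations

* The residual is unweighted, as defined; heteroscedastic instrument
  noise is not modelled.
* k₀ is not estimated; results are conditional on the chosen value.
* No uncertainty quantification beyond restart spread.
* Family comparison is by R² only; no information criteria.
* The Cauchy family's truncation makes its σ parameter partly a
  truncation-dependent quantity; with the printed near-degenerate Cauchy
  scales this has no practical effect.
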