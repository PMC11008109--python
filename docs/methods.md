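# Methods

## Model and assumptions

The package treats a dilute, ideal solution in thermodynamic equilibrium of
macromolecules A, fluorescent dyes B and fluorescent complexes C formed in
A + B ⇌ C. Concentration fluctuations about equilibrium obey linearized
reaction–diffusion equations with pseudo-first-order rates k_A = k₊C̄_B,
k_B = k₊C̄_A, k_C = k₋. Two structural assumptions are load-bearing:

* the macromolecule and the complex share one diffusion coefficient D, and
  the dye is strictly faster (D < D_B; the package refuses D ≥ D_B and the
  equal-coefficient approximation itself becomes questionable above
  D/D_B ≈ 0.3);
* the illumination profile is 3D Gaussian with beam radius L and axial size
  H = ωL, giving the single-species correlation
  G_s(χ) = 1/((1+χ)√(1+χ/ω²)), χ = t/τ, τ = L²/4D. The 2D limit ω → ∞ is
  supported (axial factor 1).

Under detailed balance the transformation to species 1/2/3 diagonalizes the
initial covariances with effective concentrations C̄₂ = C̄_B,
C̄₃ = (β/(1−β))C̄_B and C̄₁ = (k_A/k₃₂)²(C̄_A+C̄_C), which satisfy
C̄₁ + C̄₃ = C̄_C; the total brightness Q₁N̄₁+Q₂N̄₂+Q₃N̄₃ equals
Q_BN̄_B + Q_CN̄_C, so the amplitude of G(t) is the familiar FCS amplitude.
Equilibrium consistency of the inputs (C̄_C/(C̄_AC̄_B) = k₊/k₋ to 1e−10
relative) is a contract, not something repaired silently.

Index convention: the pair label "i′j′" means *end state i′, start state
j′*; this is the convention in which (1−β)G₃₂(t) = βG₂₃(t) holds exactly.

## Occupation-time densities

For a two-state chain (2 → 3 at k₂₃, 3 → 2 at k₃₂) over a window t, with
a = k₂₃t, b = k₃₂t and the Skellam pmf S(n; μ₁, μ₂) evaluated at
μ₁ = a(1−ρ), μ₂ = bρ:

    Φ₂₂ = e^{−a} δ(ρ)   + b S(+1)        Φ₃₂ = a S(0)
    Φ₃₃ = e^{−b} δ(1−ρ) + a S(−1)        Φ₂₃ = b S(0)

Each integrates to the corresponding transition probability ("mass"); the
normalized cross densities coincide. Numerically the continuous parts are
evaluated with exponentially scaled Bessel functions so that the combined
exponent −a(1−ρ)−bρ+ζ ≤ 0 (ζ = 2√(abρ(1−ρ))) never overflows, up to
Rt ~ 1e8. These forms were validated against exact-event (Gillespie)
Monte Carlo of the chain: masses, binned histograms and first two moments
agree within Monte Carlo error at all tested (Rt, β).

**Moments.** The conditional moments ⟨ρ⟩ and ⟨ρ²⟩ per pair have closed
forms, rational in (β, θ = Rt, e^{−θ}), obtained by solving the moment ODEs
of the tilted two-state propagator symbolically and transcribing the result.
Their numerators vanish to third/fourth order at θ → 0, so below θ = 0.5 the
implementation switches to direct Gauss–Legendre quadrature of the defining
convolution integrals (M1_ij(θ) = ∫₀^θ P_i3(θ−x)P_3j(x)dx and its nested
second-moment analogue). Every integrand there is a product of transition
probabilities — nonnegative, no cancellation at any θ — so this path is
accurate to machine precision where the closed forms are not. The two paths
agree to ~1e−12 across the switch. (A small-θ series would serve the same
purpose; the quadrature needs no hand-derived coefficients and is equally
fast at the problem sizes involved.)

Asymptotically ⟨ρ⟩ → β and σ² → 2β(1−β)/θ, both with O(1/θ) corrections;
the large-Rt Gaussian approximant uses exactly this mean and variance (the
saddle point of the Bessel asymptotics sits exactly at ρ = β).

## Exact averages and the moment expansion

The exact route computes ⟨G_s(t/τ_ρ)⟩ as

    atom₀·G_s(t/τ_B) + atom₁·G_s(t/τ_D) + ∫₀¹ Φ_cont(ρ) G_s(t/τ_ρ) dρ .

The density is analytic in ρ (the apparent √ singularities cancel), so
composite Gauss–Legendre quadrature converges spectrally: a single 200-node
panel for Rt ≤ 50, and for larger Rt a 200-node panel over
β ± 12σ (σ = √(2β(1−β)/Rt)) flanked by 64-node side panels. Verified
against scipy's adaptive quadrature to < 1e−9 absolute and against Monte
Carlo occupation averaging to within statistical error.

**The closed-form route treats the endpoint atoms exactly and expands only
the continuous part** around its own conditional mean:

    mass_c [ G_s(χ_c) + ½ G_s″(χ_c) (t/τ_Δ)² σ_c² ] ,
    1/τ_c = (1−⟨ρ⟩_c)/τ_B + ⟨ρ⟩_c/τ_D ,   1/τ_Δ = 1/τ_B − 1/τ_D ,

exactly two terms. This is a deliberate design decision: expanding the full
density (atoms included) around its atom-shifted mean is markedly worse
whenever an atom carries weight, because the density is then bimodal — the
measured worst error roughly doubles and the validity boundary at
τ_B/τ_D = 1/6 drops to about 1.05 instead of the ~1.8–1.9 obtained with
atom separation, which is also the value consistent with the published
boundary. The first-order variant keeps only the first term and is adequate
for fast reactions.

Rigorous bracketing: since ρ ↦ G_s(t/τ_ρ) is increasing and convex, every
exact average lies between the Jensen lower bound mass·G_s(t/τ_pair) and
the chord upper bound mass·[(1−⟨ρ⟩)G_s(t/τ_B) + ⟨ρ⟩G_s(t/τ_D)]; the bound
amplitudes are monotone combinations of e^{−k₂₃t} and e^{−k₃₂t} through the
masses, atoms and means. The test suite asserts the bracketing on a
(Rt, β) grid.

## Validity machinery

The accuracy ε_a of the expansion is the maximum of |Δ_r| =
|(approx − exact)/exact| over the pairs {22, 23, 33} and a 48-point log lag
grid spanning [1e−2, 1e3]τ_B; lags where the exact average has decayed
below 1e−12 are excluded (the ratio there is 0/0 noise). The concentration
rate γ = √(k₂₃k₃₂), expressed through (β, v), is minimized over β at
β_min = τ_D/(τ_D+τ_B) with γ_min = 2/(v√(τ_Bτ_D)) ∝ 1/v — this is what
makes a single boundary value v_L(τ_B/τ_D) meaningful.

`limiting_v` bisects on v (2% resolution, geometric midpoints) with an inner
maximization over a 25-point β grid refined near β_min. With the required
accuracy ε = 0.01 and ω = 5 this yields v_L(1/6) ≈ 1.79 (ω = 3: 1.61,
ω = 7: 1.85) and v_L⁰(1/6) ≈ 0.11 for the first-order variant — an order of
magnitude smaller, as expected.

**A known ambiguity at small τ_B/τ_D.** At τ_B/τ_D = 0.001 the unrestricted
β scan is dominated by the hybrid region (β ≈ 0.9–0.99, k₃₂ ≪ k₂₃), where
the component averages genuinely degrade (verified against Monte Carlo)
even though their weighted contribution to G(t) often does not; the scanned
boundary lands near 0.23. Evaluating instead at the single worst-γ point
β_min = 1/(1+τ_B/τ_D) — the argument that motivates the boundary in the
first place — gives v_L(0.001) ≈ 0.48. No single recipe makes both
reference values come out simultaneously; the package defaults to the full
scan (the conservative choice) and exposes `beta_mode="beta_min"` for the
worst-γ convention. Users working in the hybrid regime should judge
applicability through `classify_regime` and the raw ε_a rather than v_L
alone.

`classify_regime` labels a parameter point (pure diffusion, hybrid,
reaction-dominant, slow reaction, fast reaction, effective-diffusion-ok,
intermediate) with "≪" operationalized as a factor of 10; labels are
advisory and the diagnostics always carry the raw numbers, because a large
v does not automatically invalidate the expansion when the affected average
enters G(t) with a small coefficient.

## Limit curves

* **Effective diffusion** (R → ∞): two-component form with coefficients D
  and D_β = (1−β)D_B + βD, concentrations N̄₁ and N̄₂+N̄₃, yields Q_C and
  Q_β = Q_B(1−β) + Q_Cβ. The exact engine converges to it with error
  ~1/(Rτ_B) (tested at Rτ_B = 1e4, agreement < 1e−3).
* **Slow reaction** (τ_Bk₂₃, τ_Dk₃₂ ≪ 1, t ≪ 1/γ): the two-component curve
  plus corrections proportional to k₂₃t involving
  J(t) = ∫₀¹G_s(t/τ_ρ)dρ (64-node quadrature). Corrections verified to
  scale exactly linearly in k₂₃ and to track the exact engine to 1e−3.
* **Fast diffusion** (D = 0, τ_B → 0): the G_s-weighted mean occupation
  ⟨ρ⟩_s replaces the integral; atoms keep their analytic weights, so the
  bound-dye component decays as e^{−k₃₂t} (reaction-dominant behaviour).
  The continuous density is evaluated with the exact Bessel form at ⟨ρ⟩_s
  rather than its Gaussian asymptote — same structure, strictly more
  accurate (within 5% of the exact engine for t > 10/γ at Rτ_B = 1e−3).
  The crossover to effective diffusion is t_t = 4β²(1−β)²/(R²τ_B); it does
  not occur for D ≠ 0, and the method refuses mobile sites.

## Synthetic data and fitting

`synthesize_curve` evaluates any engine route on a log-spaced lag grid
(64 points per decade by default, the spacing of hardware correlators) and
adds seeded Gaussian noise, either proportional (sd = c·G, default study
level c = 0.01, typical of well-averaged confocal FCS) or additive. It
emulates the *shape* and marginal noise level of measured correlograms but
not the lag-correlated noise of real multi-tau correlators, nor afterpulsing
or triplet blinking; passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to instrument
artifacts.

Fitting is weighted least squares (weights 1/σ when provided, else uniform
— with uniform weights on correlated FCS noise the reported asymptotic
errors are indicative only). Internal coordinates are logs of positive
parameters and (log R, logit β) for the rate pair, which are near-orthogonal
for FCS curves and enforce positivity without constrained solvers;
multi-start (default 8 seeded log-perturbed restarts) guards against local
minima. Standard errors come from the Gauss–Newton covariance scaled by the
reduced χ², delta-transformed to the reporting coordinates; a parameter
whose standard error exceeds its estimate is flagged non-identifiable
(e.g. R fitted to effective-diffusion data, which depends only on β).
Recovery at the reference point (1/6, 0.5, v = 1), 1% proportional noise,
n = 256: k₂₃ and k₃₂ within 3 reported standard errors across 20 seeds.

## Problem sizes and numerical defaults

Defaults chosen once for desk-scale runs: 48-lag accuracy grids, 25-point β
scan, 2% bisection resolution, 200/64-node quadrature panels, Monte Carlo
oracles at 1e5–1e6 paths (statistical checks use 3-standard-error bands),
recovery studies at 20 seeds × 256 points. The acceptance script reports
the boundary values at ω = 5.

## Known limitations

* Three distinct diffusion coefficients (D_A ≠ D_C) are out of scope; the
  model is restricted to D/D_B < 0.3.
* No photophysics (triplet blinking), no non-Gaussian point-spread
  functions, no submicrometer-particle corrections, no raw photon-stream
  correlation.
* The v_L boundary at very small τ_B/τ_D depends on the β-scan convention
  (see above).
* Asymptotic fit errors assume independent Gaussian noise per lag.
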