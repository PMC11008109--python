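# fcsreact

Autocorrelation functions for fluorescence correlation spectroscopy (FCS) of
reversibly binding systems, with coupled reaction–diffusion dynamics.

## The problem

A fluorescent small molecule (dye, *B*) binds a macromolecule (*A*) to form a
fluorescent complex (*C*):

    A + B ⇌ C        (forward k₊, backward k₋)

FCS measures the normalized autocorrelation G(t) of fluorescence fluctuations
from a diffraction-limited 3D-Gaussian focal volume (beam radius *L*, axial
size *H*, aspect ratio ω = H/L). When the chemical relaxation rate
R = k₂₃ + k₃₂ — where k₂₃ = k₊C̄_A is the per-dye binding rate and
k₃₂ = k₊C̄_B + k₋ the effective release rate — is much faster or much slower
than the diffusion rates 1/τ_B = 4D_B/L² and 1/τ_D = 4D/L², classical
closed forms exist (effective diffusion, two-component diffusion). At
**intermediate rates** G(t) genuinely depends on the rate constants, and that
is the regime this package covers.

## The model

With equal macromolecule/complex diffusion coefficients (D ≪ D_B), a linear
transformation decouples the fluctuation dynamics into a freely diffusing
species 1 and a two-state dye (2 = free, 3 = bound) exchanging at rates k₂₃,
k₃₂. Over a lag t a dye spends a random fraction ρ of the time bound and
therefore diffuses with D_ρ = (1−ρ)D_B + ρD. The component correlation
functions are exact occupation-time averages of the single-species ACF
G_s(χ) = 1/((1+χ)√(1+χ/ω²)):

    G_{i'j'}(t) = ⟨ G_s(t/τ_ρ) ⟩_{Φ_{i'j'}(t,·)} ,    τ_ρ = L²/4D_ρ ,

where Φ_{i'j'}(t, ρ) is the occupation-fraction density of a two-state Markov
chain conditioned on the start and end states: endpoint atoms e^{−k₂₃t},
e^{−k₃₂t} (no-transition paths) plus a continuous part built from the Skellam
distribution (modified Bessel functions I₀, I₁). The full curve combines the
components with the species quantum yields (Q₁ = Q₃ = Q_C, Q₂ = Q_B) and mean
molecule numbers, so a brighter, dimmer, or equally bright complex are all
supported.

Two evaluation routes:

* **exact** — Gauss quadrature of the continuous density against G_s(t/τ_ρ),
  atoms handled analytically (reference quality, ~1e−12 accuracy);
* **moment expansion** — atoms analytic plus a two-term Taylor expansion of
  the continuous part around its mean occupation; a closed form in elementary
  functions, accurate to better than 1% whenever the validity parameter
  v = 1/(k₂₃τ_B) + 1/(k₃₂τ_D) is below a boundary v_L(τ_B/τ_D) that the
  package computes.

Limiting regimes (effective diffusion, two-component diffusion, slow
reaction with O(k₂₃) coupling corrections, fast diffusion with immobile
binding sites, pure diffusion / hybrid / reaction-dominant classification)
are provided as dedicated curves and diagnostics.

## Worked example

```python
import numpy as np
from fcsreact import from_dimensionless, full_acf, classify_regime
from fcsreact.fitio import synthesize_curve
from fcsreact.model import FcsReactionModel

# an intermediate-rate point: tau_B/tau_D = 1/6, bound fraction 1/2, v = 1
p = from_dimensionless(tau_ratio=1/6, beta=0.5, v=1.0, omega=5.0)
print(p.scheme.k23)           # 5.833e+04  (per-second binding rate, R tau_B = 7/3)

lags = p.diffusion.tau_B * np.array([0.1, 1.0, 10.0, 100.0])
print(full_acf(lags, p, method="exact"))
# G(2 us) = 0.4680, G(20 us) = 0.3224, G(200 us) = 0.0688, G(2 ms) = 0.0048

diag = classify_regime(p, compute_boundaries=False)
print(diag.label, diag.epsilon_a)   # intermediate 0.0050

# recover the rates from a noisy synthetic correlogram
curve = synthesize_curve(p, method="moment_expansion",
                         noise_model=("proportional", 0.01), seed=42, n=256)
fixed = dict(tau_B=p.diffusion.tau_B, tau_D=p.diffusion.tau_D,
             N1=p.N_bar("1"), N2=p.N_bar("2"), q=1.0, omega=5.0)
res = FcsReactionModel(curve, fixed=fixed).fit(start=dict(k23=1e5, k32=3e4))
print(res.summary())
```

The fit report (truth k₂₃ = k₃₂ = 5.833e4 s⁻¹):

```
reduced chi^2:    0.8876
parameter           estimate         std err
k23                  58962.3        2.18e+03
k32                    58906        2.22e+03
```

Both rates are recovered well within one standard error; the reduced χ²
near 1 confirms the noise model. `G(t)` values above are what
`full_acf(..., method="exact")` printed; the moment expansion agrees with
them to 0.5% at this point (that is `epsilon_a`).

A thin CLI wraps the same library: `fcsreact eval`, `fcsreact validity`,
`fcsreact vl-curve`, `fcsreact fit` (see `fcsreact --help`).

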