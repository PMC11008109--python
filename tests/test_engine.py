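import warnings
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import quad

from fcsreact import engine as en
from fcsreact import occupation as oc
from fcsreact.oracles import sample_occupation
from fcsreact.params import from_dimensionless
from fcsreact.single import effective_diffusion_acf, gs, two_component_acf


def _degenerate_reduced(p, ratio=1.0):
    """Duck-typed reduced view with equal diffusion coefficients."""
    r = en._rp(p)
    return SimpleNamespace(**{**r.__dict__, "tau_ratio": ratio})


class TestExactAverage:
    def test_equal_coefficients_degenerate(self, fig_point):
        # D = D_B: tau_rho is constant, so the average is mass * gs(t/tau)
        r = _degenerate_reduced(fig_point)
        t = 2.0 * r.tau_B
        for pair in oc.PAIRS:
            mass = oc._mass(pair, r.R * t, r.beta)
            expected = mass * float(gs(t / r.tau_B, r.omega))
            assert en.exact_average_gs(pair, t, r) == pytest.approx(expected, rel=1e-9)

    def test_matches_adaptive_quadrature(self, fig_point):
        p = fig_point
        r = en._rp(p)
        for tfac in (0.05, 1.0, 30.0, 300.0):
            t = tfac * r.tau_B
            for pair in oc.PAIRS:
                d = oc.occupation_density(pair, t, p.scheme)
                cont = quad(
                    lambda rho: d.density(rho)
                    * gs(en._chi_of_rho(np.asarray(rho), t / r.tau_B, r.tau_ratio), r.omega),
                    0.0, 1.0, limit=400, epsabs=1e-12, epsrel=1e-11,
                )[0]
                ref = (
                    d.atom0 * gs(t / r.tau_B, r.omega)
                    + d.atom1 * gs(t / r.tau_B * r.tau_ratio, r.omega)
                    + cont
                )
                assert en.exact_average_gs(pair, t, p) == pytest.approx(ref, abs=1e-9)

    def test_bracketed_by_convexity_bounds(self):
        p = from_dimensionless(1 / 6, 0.5, 1.0)
        for theta in (0.5, 2.0, 10.0):
            t = theta / p.scheme.R
            for pair in oc.PAIRS:
                lo, hi = en.average_gs_bounds(pair, t, p)
                val = en.exact_average_gs(pair, t, p)
                assert lo - 1e-12 <= val <= hi + 1e-12

    def test_matches_markov_averaging(self, fig_point):
        p = fig_point
        r = en._rp(p)
        t = 3.0 / p.scheme.R
        samp = sample_occupation(p.scheme, t, 2, 200_000, seed=2)
        chi = en._chi_of_rho(samp.rho, t / r.tau_B, r.tau_ratio)
        for pair, end in (("22", 2), ("32", 3)):
            y = np.where(samp.end_state == end, gs(chi, r.omega), 0.0)
            se = y.std(ddof=1) / np.sqrt(y.size)
            assert abs(y.mean() - en.exact_average_gs(pair, t, p)) < 3 * se


class TestExpansionAverages:
    def test_second_term_is_positive_correction(self, fig_point):
        # gs'' > 0, so the two-term value always exceeds the one-term value
        t = 2.0 * fig_point.diffusion.tau_B
        for pair in oc.PAIRS:
            a2 = en.approx_average_gs(pair, t, fig_point)
            a1 = en.first_order_average_gs(pair, t, fig_point)
            assert a2 >= a1

    def test_fast_reaction_limit_recovers_effective_components(self):
        # R -> inf: averages tend to the stationary weights times gs(t/tau_beta)
        p = from_dimensionless(1 / 6, 0.4, 1e-4)       # R tau_B ~ 5e4
        d, s = p.diffusion, p.scheme
        beta = s.beta
        tau_beta_inv = (1 - beta) / d.tau_B + beta * d.tau_D_inv
        t = 1.0 * d.tau_B
        g_eff = float(gs(t * tau_beta_inv, 5.0))
        for pair, w in (("22", 1 - beta), ("23", 1 - beta), ("32", beta), ("33", beta)):
            assert en.approx_average_gs(pair, t, p) == pytest.approx(w * g_eff, rel=1e-3)
            assert en.first_order_average_gs(pair, t, p) == pytest.approx(w * g_eff, rel=1e-3)

    def test_expansion_accurate_at_reference_point(self, fig_point):
        # two-term expansion within 1% of exact over the full decay
        t_grid = fig_point.diffusion.tau_B * np.logspace(-2, 3, 30)
        for t in t_grid:
            for pair in ("22", "23", "33"):
                ex = en.exact_average_gs(pair, float(t), fig_point)
                if ex < 1e-12:
                    continue
                ap = en.approx_average_gs(pair, float(t), fig_point)
                assert abs(ap / ex - 1) < 0.01


class TestComponents:
    def test_initial_condition_delta(self, fig_point):
        t_grid = np.concatenate([[0.0], fig_point.diffusion.tau_B * np.logspace(-2, 2, 5)])
        comps = en.component_acfs(t_grid, fig_point, "exact")
        assert comps.G22[0] == comps.G33[0] == 1.0
        assert comps.G23[0] == comps.G32[0] == 0.0
        assert comps.G11[0] == 1.0

    @pytest.mark.parametrize("method", ["exact", "moment_expansion", "effective"])
    def test_cross_identity(self, fig_point, method):
        beta = fig_point.scheme.beta
        t_grid = fig_point.diffusion.tau_B * np.logspace(-2, 3, 20)
        comps = en.component_acfs(t_grid, fig_point, method)
        assert (1 - beta) * comps.G32 == pytest.approx(beta * comps.G23, abs=1e-9)

    def test_components_bounded(self, fig_point):
        t_grid = fig_point.diffusion.tau_B * np.logspace(-3, 3, 25)
        comps = en.component_acfs(t_grid, fig_point, "exact")
        for arr in (comps.G11, comps.G22, comps.G23, comps.G32, comps.G33):
            assert np.all(arr >= -1e-12) and np.all(arr <= 1 + 1e-12)

    def test_method_validation(self, fig_point):
        t = fig_point.diffusion.tau_B * np.logspace(-1, 1, 5)
        with pytest.raises(ValueError, match="method"):
            en.component_acfs(t, fig_point, "slow_reaction")
        with pytest.raises(ValueError):
            en.component_acfs(t[::-1], fig_point, "exact")

    def test_auto_selects_exact_for_small_grids(self, fig_point):
        t = fig_point.diffusion.tau_B * np.logspace(-1, 1, 8)
        comps = en.component_acfs(t, fig_point, "auto")
        assert comps.method == "exact"


class TestFullAcf:
    def test_amplitude_matches_combination(self, fig_point):
        p = fig_point
        b = p.brightness
        amp = (b.Q_B**2 * p.N_bar("B") + b.Q_C**2 * p.N_bar("C")) / p.n_bar**2
        g0 = en.full_acf(np.array([1e-10 * p.diffusion.tau_B]), p, "exact")[0]
        assert g0 == pytest.approx(amp, rel=1e-6)

    def test_monotone_decay(self, fig_point):
        t = en.default_time_grid(fig_point, 1e-2, 1e3, per_decade=8)
        g = en.full_acf(t, fig_point, "exact")
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 0.01 * g[0]

    def test_effective_limit_at_large_R(self):
        p = from_dimensionless(1 / 6, 0.5, 7 / 3 * 1e-4)   # R tau_B = 1e4
        t = p.diffusion.tau_B * np.logspace(-2, 2, 25)
        ge = en.full_acf(t, p, "exact")
        gf = effective_diffusion_acf(t, p)
        assert np.max(np.abs(ge / gf - 1)) < 1e-3

    def test_equal_yields_fast_reaction_is_classical_effective(self):
        # Q_B = Q_C and R -> inf: single effective-diffusion component plus
        # the macromolecule term
        p = from_dimensionless(1 / 6, 0.5, 1e-4, Q_B=1.0, Q_C=1.0)
        t = p.diffusion.tau_B * np.logspace(-2, 2, 15)
        assert en.full_acf(t, p, "exact") == pytest.approx(
            effective_diffusion_acf(t, p), rel=2e-3
        )

    def test_dilute_complex_single_species_curve(self):
        # C_C -> 0: the curve collapses to the free-dye component
        p = from_dimensionless(1 / 6, 1e-5, 0.5, Q_B=1.0, Q_C=0.7)
        t = p.diffusion.tau_B * np.logspace(-2, 2, 15)
        expected = gs(t / p.diffusion.tau_B, 5.0) / p.N_bar("B")
        assert en.full_acf(t, p, "exact") == pytest.approx(expected, rel=1e-3)


class TestSlowReaction:
    def test_matches_exact_in_regime(self):
        p = from_dimensionless(1 / 6, 0.5, 2000.0)   # tau_B k23 ~ 1e-3
        s, d = p.scheme, p.diffusion
        assert s.k23 * d.tau_B < 1e-3 and s.k32 * d.tau_D < 5e-3
        gamma = s.gamma
        t = d.tau_B * np.logspace(-2, 1, 20)
        t = t[t < 0.1 / gamma]
        g_slow = en.slow_reaction_acf(t, p)
        g_exact = en.full_acf(t, p, "exact")
        assert np.max(np.abs(g_slow / g_exact - 1)) < 1e-3

    def test_corrections_linear_in_k23(self):
        # residual against the two-component curve doubles with k23
        t_ref = None
        residuals = []
        for v in (4000.0, 2000.0):                   # k23 doubles as v halves
            p = from_dimensionless(1 / 6, 0.5, v)
            t = p.diffusion.tau_B * np.logspace(-1, 0.5, 8)
            res = en.slow_reaction_acf(t, p) - two_component_acf(t, p)
            residuals.append(res)
        ratio = residuals[1] / residuals[0]
        assert ratio == pytest.approx(np.full_like(ratio, 2.0), rel=1e-6)

    def test_warns_outside_regime(self, fig_point):
        t = fig_point.diffusion.tau_B * np.array([0.1, 1.0])
        with pytest.warns(UserWarning, match="regime"):
            en.slow_reaction_acf(t, fig_point)


class TestFastDiffusion:
    def test_transition_time_value(self):
        p = from_dimensionless(0.0, 0.5, 10.0)
        s, d = p.scheme, p.diffusion
        expected = 0.25 / (s.R**2 * d.tau_B)
        assert en.transition_time(p) == pytest.approx(expected, rel=1e-12)

    def test_transition_time_diverges_as_tau_B_shrinks(self):
        tts = []
        for tau_B in (2e-5, 2e-6, 2e-7):
            p = from_dimensionless(0.0, 0.5, 10.0, tau_B=tau_B)
            # hold R fixed by keeping v*tau_B product: rebuild with same R
            tts.append(en.transition_time(p) * p.scheme.R**2)
        assert tts[0] < tts[1] < tts[2]

    def test_requires_immobile_sites(self, fig_point):
        with pytest.raises(ValueError, match="immobile"):
            en.transition_time(fig_point)
        t = fig_point.diffusion.tau_B * np.array([1.0])
        with pytest.raises(ValueError, match="immobile"):
            en.fast_diffusion_acf(t, fig_point)

    def test_matches_exact_engine_at_long_times(self):
        # tau_B * R = 1e-3, D = 0; compare for t > 10/gamma
        p = from_dimensionless(0.0, 0.5, 2000.0)
        s, d = p.scheme, p.diffusion
        assert s.R * d.tau_B == pytest.approx(1e-3, rel=1e-10)
        t = np.logspace(1, 2.5, 8) / s.gamma
        g_fd = en.fast_diffusion_acf(t, p)
        g_ex = en.full_acf(t, p, "exact")
        assert np.max(np.abs(g_fd / g_ex - 1)) < 0.05
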