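import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import poisson, skellam

from fcsreact import occupation as oc
from fcsreact.oracles import sample_occupation
from fcsreact.params import from_dimensionless


@pytest.fixture(scope="module")
def scheme():
    return from_dimensionless(1 / 6, 0.35, 1.0).scheme


def _quad_moments(pair, t, scheme):
    """Independent oracle: atoms + adaptive quadrature of the density."""
    d = oc.occupation_density(pair, t, scheme)
    m0 = quad(d.density, 0, 1, limit=300)[0] + d.atom0 + d.atom1
    m1 = quad(lambda r: r * d.density(r), 0, 1, limit=300)[0] + d.atom1
    m2 = quad(lambda r: r * r * d.density(r), 0, 1, limit=300)[0] + d.atom1
    return m0, m1 / m0, m2 / m0


class TestSkellam:
    def test_normalization(self):
        n = np.arange(-200, 201)
        assert oc.skellam_pmf(n, 3.0, 7.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_poisson_limit(self):
        n = np.arange(-5, 40)
        got = oc.skellam_pmf(n, 4.0, 0.0)
        expected = np.where(n >= 0, poisson.pmf(np.maximum(n, 0), 4.0), 0.0)
        assert got == pytest.approx(expected, abs=1e-14)

    def test_mean_against_poisson_difference_sampling(self, rng):
        a, b = 5.0, 2.0
        draws = rng.poisson(a, 10**6) - rng.poisson(b, 10**6)
        se = draws.std(ddof=1) / 1000.0
        n = np.arange(-60, 100)
        mean = float(np.sum(n * oc.skellam_pmf(n, a, b)))
        assert mean == pytest.approx(a - b, abs=1e-10)
        assert abs(draws.mean() - mean) < 3 * se

    def test_matches_scipy_dual_route(self):
        n = np.arange(-20, 21)
        for a, b in [(0.5, 3.0), (10.0, 10.0), (200.0, 150.0)]:
            assert oc.skellam_pmf(n, a, b) == pytest.approx(
                skellam.pmf(n, a, b), rel=1e-10
            )

    def test_large_parameters_finite(self):
        val = oc.skellam_pmf(0, 1e6, 1e6)
        assert np.isfinite(val) and val > 0

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            oc.skellam_pmf(0, -1.0, 2.0)


class TestPhiDensities:
    def test_cross_symmetry_normalized(self, scheme):
        t = 10.0 / scheme.R
        rho = np.array([0.1, 0.3, 0.5, 0.9])
        p23 = oc.phi("23", t, rho, scheme, normalized=True)
        p32 = oc.phi("32", t, rho, scheme, normalized=True)
        assert p23 == pytest.approx(p32, rel=1e-12)

    def test_rho_domain_enforced(self, scheme):
        with pytest.raises(ValueError):
            oc.phi("22", 1e-4, [1.2], scheme)

    def test_concentration_with_rt(self):
        # densities sharpen around beta as Rt grows (Fig-1 behaviour)
        scheme = from_dimensionless(1 / 6, 0.5, 1.0).scheme
        var10 = oc.phi_moments("23", 10 / scheme.R, scheme)
        var100 = oc.phi_moments("23", 100 / scheme.R, scheme)
        sig10, sig100 = var10[3], var100[3]
        assert sig100 < sig10
        assert var100[1] == pytest.approx(scheme.beta, abs=0.02)

    def test_matches_markov_simulation(self, scheme):
        # histogram of simulated occupation fractions vs atoms + density
        t = 5.0 / scheme.R
        n_paths = 200_000
        samp = sample_occupation(scheme, t, start_state=2, n_paths=n_paths, seed=11)
        for pair, end in (("22", 2), ("32", 3)):
            sel = samp.conditioned(end)
            d = oc.occupation_density(pair, t, scheme)
            # atom mass (pair 22 only): fraction of paths with rho == 0
            if pair == "22":
                p_atom = np.mean(sel == 0.0) * sel.size / n_paths
                se = np.sqrt(d.atom0 * (1 - d.atom0) / n_paths)
                assert abs(p_atom - d.atom0) < 3 * se
            # binned continuous part
            edges = np.linspace(0.0, 1.0, 11)
            interior = sel[(sel > 0) & (sel < 1)]
            hist = np.histogram(interior, edges)[0] / n_paths
            for k in range(10):
                prob = quad(d.density, edges[k], edges[k + 1], limit=200)[0]
                se = np.sqrt(max(prob * (1 - prob), 1e-12) / n_paths)
                assert abs(hist[k] - prob) < 3 * se + 1e-4


class TestMoments:
    @pytest.mark.parametrize("pair", oc.PAIRS)
    def test_closed_forms_match_quadrature(self, pair):
        scheme = from_dimensionless(1 / 6, 0.3, 1.0).scheme
        t = 3.0 / scheme.R
        m0, m1, m2 = _quad_moments(pair, t, scheme)
        mass, mean, mean2, sigma = oc.phi_moments(pair, t, scheme)
        assert mass == pytest.approx(m0, abs=1e-8)
        assert mean == pytest.approx(m1, abs=1e-8)
        assert mean2 == pytest.approx(m2, abs=1e-8)
        assert sigma**2 == pytest.approx(mean2 - mean**2, abs=1e-12)

    def test_moments_match_markov_monte_carlo(self):
        scheme = from_dimensionless(1 / 6, 0.7, 1.0).scheme
        t = 1.0 / scheme.R
        samp = sample_occupation(scheme, t, start_state=2, n_paths=300_000, seed=5)
        for pair, end in (("22", 2), ("32", 3)):
            sel = samp.conditioned(end)
            _, mean, mean2, _ = oc.phi_moments(pair, t, scheme)
            se1 = sel.std(ddof=1) / np.sqrt(sel.size)
            se2 = (sel**2).std(ddof=1) / np.sqrt(sel.size)
            assert abs(sel.mean() - mean) < 3 * se1
            assert abs((sel**2).mean() - mean2) < 3 * se2

    def test_large_rt_asymptotics(self):
        # <rho> - beta and sigma^2 decay as 1/Rt
        scheme = from_dimensionless(1 / 6, 0.3, 1.0).scheme
        beta = scheme.beta
        vals = []
        for theta in (1e3, 1e4):
            t = theta / scheme.R
            _, mean, _, sigma = oc.phi_moments("22", t, scheme)
            vals.append(((mean - beta) * theta, sigma**2 * theta))
        assert vals[0][0] == pytest.approx(vals[1][0], rel=0.05)
        assert vals[0][1] == pytest.approx(2 * beta * (1 - beta), rel=0.05)

    def test_variance_nonnegative_all_pairs(self):
        scheme = from_dimensionless(1 / 6, 0.5, 1.0).scheme
        for theta in np.logspace(-6, 6, 25):
            for pair in oc.PAIRS:
                _, mean, mean2, sigma = oc.phi_moments(pair, theta / scheme.R, scheme)
                assert mean2 - mean**2 >= -1e-15

    def test_masses_monotone_and_conserved(self, scheme):
        ts = np.logspace(-3, 3, 40) / scheme.R
        m22 = np.array([oc.phi_mass("22", t, scheme) for t in ts])
        m32 = np.array([oc.phi_mass("32", t, scheme) for t in ts])
        m33 = np.array([oc.phi_mass("33", t, scheme) for t in ts])
        m23 = np.array([oc.phi_mass("23", t, scheme) for t in ts])
        # start-state probability conservation
        assert m22 + m32 == pytest.approx(np.ones_like(ts), abs=1e-14)
        assert m33 + m23 == pytest.approx(np.ones_like(ts), abs=1e-14)
        # monotonic relaxation toward the stationary weights (saturating
        # exactly once exp(-Rt) underflows)
        assert np.all(np.diff(m22) <= 0) and np.all(np.diff(m32) >= 0)
        assert m22[0] > m22[-1] and m32[0] < m32[-1]

    def test_quadrature_and_closed_paths_agree_at_switch(self):
        for beta in (0.1, 0.5, 0.9):
            for theta in (0.3, 0.5, 0.9):
                q = oc._moments_quad(theta, beta)
                c = oc._moments_closed(theta, beta)
                for pair in oc.PAIRS:
                    mass = oc._mass(pair, theta, beta)
                    assert q[pair][0] / mass == pytest.approx(c[pair][0], abs=1e-11)
                    assert q[pair][1] / mass == pytest.approx(c[pair][1], abs=1e-11)


class TestAsymptoticForms:
    def test_gaussian_center_and_tv_distance(self):
        scheme = from_dimensionless(1 / 6, 0.5, 1.0).scheme
        t = 100.0 / scheme.R
        rho = np.linspace(1e-4, 1 - 1e-4, 2001)
        exact = oc.phi("23", t, rho, scheme)
        asym = oc.phi_gaussian_asymptotic("23", t, rho, scheme)
        tv = 0.5 * np.trapezoid(np.abs(exact - asym), rho) / oc.phi_mass("23", t, scheme)
        assert tv < 0.05
        assert rho[np.argmax(asym)] == pytest.approx(scheme.beta, abs=0.01)

    def test_gaussian_variance_scales_inversely_with_rt(self):
        scheme = from_dimensionless(1 / 6, 0.5, 1.0).scheme
        widths = []
        for theta in (100.0, 400.0):
            t = theta / scheme.R
            rho = np.linspace(0, 1, 4001)
            dens = oc.phi_gaussian_asymptotic("23", t, rho, scheme)
            m = np.trapezoid(dens, rho)
            mu = np.trapezoid(rho * dens, rho) / m
            var = np.trapezoid((rho - mu) ** 2 * dens, rho) / m
            widths.append(var)
        assert widths[0] / widths[1] == pytest.approx(4.0, rel=0.10)

    def test_warns_below_threshold(self, scheme):
        with pytest.warns(UserWarning, match="Rt"):
            oc.phi_gaussian_asymptotic("22", 1.0 / scheme.R, [0.5], scheme)

    def test_small_rt_form_matches_exact(self):
        scheme = from_dimensionless(1 / 6, 0.4, 1.0).scheme
        t = 1e-3 / scheme.R
        rho = np.linspace(0.01, 0.99, 50)
        for pair in oc.PAIRS:
            exact = oc.phi(pair, t, rho, scheme)
            approx = oc.phi_small_Rt(pair, t, rho, scheme)
            assert approx == pytest.approx(exact, abs=1e-4)

    def test_small_rt_mass_structure(self):
        scheme = from_dimensionless(1 / 6, 0.4, 1.0).scheme
        # Phi_22 collapses onto its rho = 0 atom when no transitions occur
        t = 1e-6 / scheme.R
        d = oc.occupation_density("22", t, scheme)
        assert d.atom0 == pytest.approx(1.0, abs=1e-5)
        assert d.mass == pytest.approx(1.0, abs=1e-6)
        # cross mass is O(Rt): ratio test over a decade
        m_2 = oc.phi_mass("23", 1e-2 / scheme.R, scheme)
        m_3 = oc.phi_mass("23", 1e-3 / scheme.R, scheme)
        assert m_2 / m_3 == pytest.approx(10.0, rel=0.01)
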