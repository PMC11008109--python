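"""Occupation-fraction probability densities of the two-state dye.

Over a lag interval of length ``t`` a dye molecule switches between its free
state (2) and its bound state (3) with rates ``k23`` (2 -> 3) and ``k32``
(3 -> 2).  The fraction ``rho`` of the interval spent bound determines the
effective diffusion coefficient ``D_rho = (1-rho) D_B + rho D`` with which
the molecule moves during that interval, so the joint law of ``rho`` and the
end state -- the density ``Phi_{i'j'}(t, rho)`` for end state ``i'`` given
start state ``j'`` -- is what couples reaction and diffusion in the exact
autocorrelation function.

With ``a = k23 t``, ``b = k32 t`` and the Skellam probability
``S(n; mu1, mu2)`` of the difference of two independent Poisson counts, the
densities have closed forms built from ``S`` at ``n = 0, +-1`` evaluated at
``mu1 = a (1-rho)``, ``mu2 = b rho``::

    Phi_22(t, rho) = exp(-a) delta(rho)     + b S(+1; a(1-rho), b rho)
    Phi_33(t, rho) = exp(-b) delta(1 - rho) + a S(-1; a(1-rho), b rho)
    Phi_32(t, rho) =                          a S( 0; a(1-rho), b rho)
    Phi_23(t, rho) =                          b S( 0; a(1-rho), b rho)

(the atoms are the no-transition paths).  Each density integrates to the
corresponding two-state transition probability ("mass"); after dividing by
the mass, the two cross densities coincide: ``Phi_23 = Phi_32``.

Index convention: pair ``"i'j'"`` means *end state i', start state j'*, so
``mass("32", t) = P(bound at t | free at 0) = beta (1 - exp(-R t))``.

Conditional moments ``<rho>`` and ``<rho^2>`` have closed forms, rational in
``(theta = R t, beta, exp(-theta))``; their numerators vanish to high order
at ``theta -> 0``, so below ``theta = 0.5`` they are evaluated instead by
Gauss-Legendre quadrature of the defining convolution integrals, whose
integrands are products of transition probabilities and therefore free of
cancellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss
from numpy.typing import ArrayLike, NDArray
from scipy.special import ive

from .params import ReactionScheme

__all__ = [
    "skellam_pmf",
    "phi",
    "phi_mass",
    "phi_moments",
    "phi_gaussian_asymptotic",
    "phi_small_Rt",
    "occupation_density",
    "OccupationDensity",
    "PAIRS",
]

PAIRS = ("22", "23", "32", "33")

#: Below this value of theta = R t the closed-form moment fractions lose
#: precision to cancellation and the quadrature path is used instead.
MOMENT_QUAD_THRESHOLD = 0.5

_GL_NODES, _GL_WEIGHTS = leggauss(40)


# ----------------------------------------------------------------------------
# Skellam distribution
# ----------------------------------------------------------------------------

def skellam_pmf(n: ArrayLike, a: float, b: float) -> NDArray[np.float64]:
    """Probability that a Poisson(a) count exceeds a Poisson(b) count by n.

    Evaluated through the exponentially scaled modified Bessel function, so
    the result stays finite for ``a, b`` up to ~1e8.  For ``b = 0`` (or
    ``a = 0``) the distribution degenerates to a (reflected) Poisson law.
    """
    if a < 0 or b < 0:
        raise ValueError(f"Skellam parameters must be >= 0, got a={a}, b={b}")
    n = np.asarray(n)
    if not np.issubdtype(n.dtype, np.integer):
        nr = np.rint(n)
        if np.any(nr != n):
            raise ValueError("n must be integer")
        n = nr.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        if b == 0.0:
            out = np.where(n >= 0, np.exp(_log_poisson(np.maximum(n, 0), a)), 0.0)
            return np.where((n == 0) & (a == 0.0), 1.0, out)
        if a == 0.0:
            out = np.where(n <= 0, np.exp(_log_poisson(np.maximum(-n, 0), b)), 0.0)
            return out
        zeta = 2.0 * np.sqrt(a * b)
        # exp(-(a+b)) I_|n|(zeta) (a/b)^{n/2}, with I via ive to avoid overflow
        logp = (
            zeta - (a + b)
            + 0.5 * n * (np.log(a) - np.log(b))
            + np.log(ive(np.abs(n), zeta))
        )
        return np.exp(logp)


def _log_poisson(k: NDArray, mu: float) -> NDArray:
    from scipy.special import gammaln

    if mu == 0.0:
        return np.where(k == 0, 0.0, -np.inf)
    return k * np.log(mu) - mu - gammaln(k + 1.0)


# ----------------------------------------------------------------------------
# Densities
# ----------------------------------------------------------------------------

def _check_pair(pair: str) -> str:
    pair = str(pair)
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}, got {pair!r}")
    return pair


def _phi_cont(pair: str, theta: float, beta: float, rho: NDArray) -> NDArray:
    """Continuous part of the mass-weighted density, vectorized in rho."""
    a = beta * theta
    b = (1.0 - beta) * theta
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    mu1 = a * (1.0 - rho)
    mu2 = b * rho
    zeta = 2.0 * np.sqrt(mu1 * mu2)
    # combined exponent -mu1 - mu2 + zeta <= 0 everywhere: use scaled Bessel
    expo = np.exp(zeta - mu1 - mu2)
    if pair == "32":
        return a * ive(0, zeta) * expo
    if pair == "23":
        return b * ive(0, zeta) * expo
    if pair == "22":
        # b * S(1) = sqrt(a b (1-rho)/rho) I_1; finite limit 0 at rho -> 0+? no:
        # ~ rho^{-1/2} * I_1(~rho^{1/2}) -> a*b*(1-rho) * [I_1(z)/z] finite.
        z = zeta
        i1_over_z = np.where(z > 0, ive(1, z) / np.where(z > 0, z, 1.0), 0.5)
        return 2.0 * a * b * (1.0 - rho) * i1_over_z * expo
    # pair == "33"
    z = zeta
    i1_over_z = np.where(z > 0, ive(1, z) / np.where(z > 0, z, 1.0), 0.5)
    return 2.0 * a * b * rho * i1_over_z * expo


def phi(
    pair: str,
    t: float,
    rho: ArrayLike,
    scheme: ReactionScheme,
    normalized: bool = False,
) -> NDArray[np.float64]:
    """Continuous part of Phi_{pair}(t, rho) (atoms excluded; see
    :func:`occupation_density` for the full object).

    By default mass-weighted, i.e. ``atom + integral = transition
    probability``; with ``normalized=True`` the density is divided by its
    mass, the convention in which ``Phi_23 == Phi_32`` pointwise.
    """
    pair = _check_pair(pair)
    if t <= 0:
        raise ValueError("t must be positive")
    theta = scheme.R * t
    val = _phi_cont(pair, theta, scheme.beta, np.asarray(rho, dtype=float))
    if normalized:
        val = val / _mass(pair, theta, scheme.beta)
    return val


def _mass(pair: str, theta: float, beta: float) -> float:
    """Two-state transition probability P(end i' | start j')."""
    em1 = -np.expm1(-theta)        # 1 - exp(-theta)
    if pair == "22":
        return 1.0 - beta * em1
    if pair == "33":
        return 1.0 - (1.0 - beta) * em1
    if pair == "32":
        return beta * em1
    return (1.0 - beta) * em1      # "23"


def phi_mass(pair: str, t: float, scheme: ReactionScheme) -> float:
    """Total mass (atoms + continuous part) of Phi_{pair}(t, .)."""
    pair = _check_pair(pair)
    return _mass(pair, scheme.R * t, scheme.beta)


def _atoms(pair: str, theta: float, beta: float) -> tuple[float, float]:
    """Point masses at rho = 0 and rho = 1 (the no-transition paths)."""
    a = beta * theta
    b = (1.0 - beta) * theta
    if pair == "22":
        return float(np.exp(-a)), 0.0
    if pair == "33":
        return 0.0, float(np.exp(-b))
    return 0.0, 0.0


# ----------------------------------------------------------------------------
# Moments
# ----------------------------------------------------------------------------

def _propagator(x: NDArray, beta: float) -> tuple[NDArray, NDArray, NDArray, NDArray]:
    """Entries of the two-state propagator at dimensionless time x = R u.

    Returns (p22, p23, p32, p33) with p_{ij} = P(end i | start j).
    """
    e = np.exp(-x)
    p22 = 1.0 - beta + beta * e
    p23 = (1.0 - beta) * (1.0 - e)
    p32 = beta * (1.0 - e)
    p33 = beta + (1.0 - beta) * e
    return p22, p23, p32, p33


def _moments_quad(theta: float, beta: float) -> dict[str, tuple[float, float]]:
    """Mass-weighted raw moments (E[rho 1_end], E[rho^2 1_end]) by quadrature.

    Uses M1_ij(theta) = (1/theta) * int_0^theta P_i3(theta-x) P_3j(x) dx and
    the analogous nested integral for the second moment; every integrand is a
    product of probabilities, so this path has no cancellation and is used
    for small theta.
    """
    # nodes on [0, theta]
    x = 0.5 * theta * (_GL_NODES + 1.0)
    w = 0.5 * theta * _GL_WEIGHTS
    p22x, p23x, p32x, p33x = _propagator(x, beta)
    p22u, p23u, p32u, p33u = _propagator(theta - x, beta)

    # M1_ij = int P_i3(theta-x) P_3j(x) dx, in units where rho = X/t: /theta
    m1 = {
        "22": np.sum(w * p23u * p32x),
        "23": np.sum(w * p23u * p33x),
        "32": np.sum(w * p33u * p32x),
        "33": np.sum(w * p33u * p33x),
    }

    # M1_3j(x) at the outer nodes, by inner quadrature on [0, x]
    #   y_{k,i} = x_i * (nodes+1)/2
    y = 0.5 * np.outer(_GL_NODES + 1.0, x)            # (40, 40): inner x outer
    wy = 0.5 * np.outer(_GL_WEIGHTS, x)
    _, _, p32y, p33y = _propagator(y, beta)
    _, _, _, p33xy = _propagator(x[None, :] - y, beta)
    m1_32_x = np.sum(wy * p33xy * p32y, axis=0)       # M1_32(x_i)
    m1_33_x = np.sum(wy * p33xy * p33y, axis=0)

    m2 = {
        "22": 2.0 * np.sum(w * p23u * m1_32_x),
        "23": 2.0 * np.sum(w * p23u * m1_33_x),
        "32": 2.0 * np.sum(w * p33u * m1_32_x),
        "33": 2.0 * np.sum(w * p33u * m1_33_x),
    }
    out = {}
    for pair in PAIRS:
        out[pair] = (m1[pair] / theta, m2[pair] / theta**2)
    return out


def _moments_closed(theta: float, beta: float) -> dict[str, tuple[float, float]]:
    """Conditional <rho>, <rho^2> from the closed forms (theta >= ~0.5)."""
    b = beta
    th = theta
    Em = np.exp(-th)
    r1 = {}
    r2 = {}
    r1["22"] = (b * (Em * (b * th + 2 * b - th - 2) + b * th - 2 * b - th + 2)) / (
        th * (-Em * b + b - 1)
    )
    r1["23"] = (Em * (b * th + 2 * b - th - 1) + b * th - 2 * b + 1) / (th * (1 - Em))
    r1["32"] = r1["23"]
    r1["33"] = (
        Em * (b**2 * th + 2 * b**2 - 2 * b * th - 2 * b + th) + b**2 * th - 2 * b**2 + 2 * b
    ) / (th * (-Em * (b - 1) + b))
    r2["22"] = (
        b
        * (
            -Em
            * (
                b**2 * th**2 + 6 * b**2 * th + 12 * b**2
                - 2 * b * th**2 - 10 * b * th - 18 * b
                + th**2 + 4 * th + 6
            )
            + b**2 * th**2 - 6 * b**2 * th + 12 * b**2
            - b * th**2 + 8 * b * th - 18 * b
            - 2 * th + 6
        )
    ) / (th**2 * (-Em * b + b - 1))
    r2["23"] = (
        -Em
        * (
            b**2 * th**2 + 6 * b**2 * th + 12 * b**2
            - 2 * b * th**2 - 8 * b * th - 12 * b
            + th**2 + 2 * th + 2
        )
        + b**2 * th**2 - 6 * b**2 * th + 12 * b**2
        + 4 * b * th - 12 * b + 2
    ) / (th**2 * (1 - Em))
    r2["32"] = r2["23"]
    r2["33"] = (
        -Em
        * (
            b**3 * th**2 + 6 * b**3 * th + 12 * b**3
            - 3 * b**2 * th**2 - 12 * b**2 * th - 18 * b**2
            + 3 * b * th**2 + 6 * b * th + 6 * b
            - th**2
        )
        + b**3 * th**2 - 6 * b**3 * th + 12 * b**3
        + 6 * b**2 * th - 18 * b**2 + 6 * b
    ) / (th**2 * (-Em * (b - 1) + b))
    return {p: (r1[p], r2[p]) for p in PAIRS}


def _conditional_moments(theta: float, beta: float) -> dict[str, tuple[float, float]]:
    """Conditional first/second moments of rho for each pair."""
    if theta < 1e-12:
        # exact Rt -> 0 limits: a 2->3 (3->2) path switches once, at a
        # uniform time, so rho is uniform; the diagonal pairs stay put.
        return {"22": (0.0, 0.0), "33": (1.0, 1.0),
                "23": (0.5, 1.0 / 3.0), "32": (0.5, 1.0 / 3.0)}
    if theta < MOMENT_QUAD_THRESHOLD:
        raw = _moments_quad(theta, beta)
        return {p: (raw[p][0] / _mass(p, theta, beta), raw[p][1] / _mass(p, theta, beta))
                for p in PAIRS}
    return _moments_closed(theta, beta)


def continuous_moments(theta: float, beta: float, pair: str) -> tuple[float, float, float, float]:
    """Mass and conditional moments of the *continuous part* of Phi_{pair}.

    Returns ``(mass_c, mean_rho_c, mean_rho2_c, sigma_c)`` where ``mass_c``
    excludes the endpoint atoms.  These are the moments entering the
    moment-expansion average, in which the atoms are handled exactly (a
    Taylor expansion around a mean that mixes an endpoint atom with a
    continuous bump would be poor whenever the atom carries weight).
    """
    pair = _check_pair(pair)
    atom0, atom1 = _atoms(pair, theta, beta)
    mass = _mass(pair, theta, beta)
    mass_c = mass - atom0 - atom1
    if mass_c <= 1e-14:
        # no transitions at this lag: the density is (numerically) all atom
        return 0.0, beta, beta * beta, 0.0
    m1, m2 = _conditional_moments(theta, beta)[pair]
    # convert full-density conditional moments to continuous-part ones
    # (the atom at rho=1 contributes 1 to both raw moments)
    m1c = min(max((m1 * mass - atom1) / mass_c, 0.0), 1.0)
    m2c = min(max((m2 * mass - atom1) / mass_c, 0.0), 1.0)
    var = max(m2c - m1c * m1c, 0.0)
    return mass_c, m1c, m2c, float(np.sqrt(var))


def phi_moments(pair: str, t: float, scheme: ReactionScheme) -> tuple[float, float, float, float]:
    """Return ``(mass, mean_rho, mean_rho2, sigma)`` of Phi_{pair}(t, .).

    ``mean_rho`` and ``mean_rho2`` are conditional on the (start, end) pair;
    ``mass`` is the two-state transition probability.  As ``R t -> inf`` the
    mean tends to ``beta`` and ``sigma^2`` to ``2 beta (1-beta)/(R t)``, both
    with O(1/Rt) corrections.
    """
    pair = _check_pair(pair)
    if t <= 0:
        raise ValueError("t must be positive")
    theta = scheme.R * t
    beta = scheme.beta
    m1, m2 = _conditional_moments(theta, beta)[pair]
    var = max(m2 - m1 * m1, 0.0)
    return _mass(pair, theta, beta), float(m1), float(m2), float(np.sqrt(var))


# ----------------------------------------------------------------------------
# Asymptotic and small-Rt forms
# ----------------------------------------------------------------------------

def phi_gaussian_asymptotic(
    pair: str, t: float, rho: ArrayLike, scheme: ReactionScheme
) -> NDArray[np.float64]:
    """Large-Rt Gaussian approximant of the mass-weighted density.

    From the asymptotic expansion of the Bessel functions the exact density
    concentrates around ``rho = beta`` with variance ``2 beta (1-beta)/(Rt)``;
    all four pairs share this leading-order shape and differ only through
    their masses.  Intended for ``Rt >~ 50``; below that a warning is issued.
    """
    pair = _check_pair(pair)
    theta = scheme.R * t
    beta = scheme.beta
    if theta < 50.0:
        warnings.warn(
            f"Gaussian asymptotic density requested at Rt = {theta:.3g} < 50; "
            "the approximation degrades for broad distributions",
            stacklevel=2,
        )
    rho = np.asarray(rho, dtype=float)
    var = 2.0 * beta * (1.0 - beta) / theta
    dens = np.exp(-0.5 * (rho - beta) ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    return _mass(pair, theta, beta) * dens


def phi_small_Rt(
    pair: str, t: float, rho: ArrayLike, scheme: ReactionScheme
) -> NDArray[np.float64]:
    """Leading small-Rt form of the continuous density (I0 ~ 1, I1 ~ zeta/2).

    With ``k_rho = (1-rho) k23 + rho k32``::

        Phi_22 ~ a b (1-rho) exp(-t k_rho)    (+ atom exp(-a) at rho = 0)
        Phi_33 ~ a b rho     exp(-t k_rho)    (+ atom exp(-b) at rho = 1)
        Phi_32 ~ a           exp(-t k_rho)
        Phi_23 ~ b           exp(-t k_rho)
    """
    pair = _check_pair(pair)
    if t <= 0:
        raise ValueError("t must be positive")
    a = scheme.k23 * t
    b = scheme.k32 * t
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    decay = np.exp(-(a * (1.0 - rho) + b * rho))
    if pair == "22":
        return a * b * (1.0 - rho) * decay
    if pair == "33":
        return a * b * rho * decay
    if pair == "32":
        return a * decay
    return b * decay


# ----------------------------------------------------------------------------
# Bundled density object
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupationDensity:
    """Atoms, continuous part and moments of one Phi_{i'j'}(t, .)."""

    pair: str
    t: float
    atom0: float
    atom1: float
    density: Callable[[ArrayLike], NDArray[np.float64]]
    mass: float
    mean_rho: float
    mean_rho2: float
    sigma: float


def occupation_density(pair: str, t: float, scheme: ReactionScheme) -> OccupationDensity:
    """Construct the full :class:`OccupationDensity` for one pair at lag t."""
    pair = _check_pair(pair)
    if t <= 0:
        raise ValueError("t must be positive")
    theta = scheme.R * t
    beta = scheme.beta
    atom0, atom1 = _atoms(pair, theta, beta)
    mass, m1, m2, sigma = phi_moments(pair, t, scheme)

    def density(rho: ArrayLike) -> NDArray[np.float64]:
        return _phi_cont(pair, theta, beta, np.asarray(rho, dtype=float))

    return OccupationDensity(
        pair=pair, t=t, atom0=atom0, atom1=atom1, density=density,
        mass=mass, mean_rho=m1, mean_rho2=m2, sigma=sigma,
    )
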