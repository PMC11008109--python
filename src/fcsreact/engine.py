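"""Assembly of the full autocorrelation function G(t).

The transformed reaction-diffusion system consists of a freely diffusing
species 1 and the two-state dye (species 2 free, species 3 bound).  The
component correlation functions are occupation-fraction averages of the
single-species ACF,

    G_11(t) = G_s(t/tau_D),
    G_{i'j'}(t) = < G_s(t/tau_rho) >_{Phi_{i'j'}(t, .)},   i',j' in {2,3},

with the mass-weighted densities of :mod:`fcsreact.occupation` (the average
therefore carries the two-state transition probability as its prefactor, so
that G_{i'j'}(0) = delta_{i'j'}).  The full ACF combines the components with
the species-1/2/3 quantum yields and mean molecule numbers:

    G(t) = [Q_1^2 N_1 G_11 + Q_2^2 N_2 G_22 + Q_3^2 N_3 G_33
            + Q_2 Q_3 (N_3 G_23 + N_2 G_32)] / n_bar^2 .

Two routes evaluate the averages.  Both treat the endpoint atoms of the
densities (the no-transition paths) analytically; they differ in the
continuous part: the exact route integrates it by Gauss quadrature, the
closed-form route replaces it by a two-term Taylor expansion around its
conditional mean occupation,

    <G_s>_cont ~ mass_c * [ G_s(t/tau_{i'j'})
                            + (1/2) G_s''(t/tau_{i'j'}) (t/tau_Delta)^2 sigma_c^2 ],

    1/tau_{i'j'} = (1 - <rho>_c)/tau_B + <rho>_c/tau_D,
    1/tau_Delta  = 1/tau_B - 1/tau_D,

plus the slow-reaction and fast-diffusion specializations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from numpy.polynomial.legendre import leggauss
from numpy.typing import ArrayLike, NDArray

from . import occupation as oc
from .params import ModelParams
from .single import effective_diffusion_acf, gs, gs_dd, two_component_acf

__all__ = [
    "AcfComponents",
    "exact_average_gs",
    "approx_average_gs",
    "first_order_average_gs",
    "average_gs_bounds",
    "component_acfs",
    "full_acf",
    "slow_reaction_acf",
    "fast_diffusion_acf",
    "transition_time",
    "default_time_grid",
    "METHODS",
]

METHODS = (
    "exact",
    "moment_expansion",
    "first_order",
    "effective",
    "two_component",
    "slow_reaction",
    "fast_diffusion",
)

_NODES200, _WEIGHTS200 = leggauss(200)
_NODES64, _WEIGHTS64 = leggauss(64)

#: Rt above which the rho-quadrature switches to a peak-resolving composite rule.
_PEAK_SPLIT_RT = 50.0


def _rp(params) -> SimpleNamespace:
    """Reduced parameter view used by the engine.

    Accepts a :class:`ModelParams` or any object already exposing the reduced
    attributes (used internally by the fitting layer).
    """
    if isinstance(params, ModelParams):
        s, d, b = params.scheme, params.diffusion, params.brightness
        return SimpleNamespace(
            tau_B=d.tau_B, tau_ratio=d.tau_ratio, beta=s.beta, R=s.R,
            omega=params.volume.omega,
            N1=params.N_bar("1"), N2=params.N_bar("2"), N3=params.N_bar("3"),
            Q1=b.Q_1, Q2=b.Q_2, Q3=b.Q_3,
        )
    return SimpleNamespace(
        tau_B=params.tau_B, tau_ratio=params.tau_ratio, beta=params.beta,
        R=params.R, omega=params.omega,
        N1=params.N1, N2=params.N2, N3=params.N3,
        Q1=params.Q1, Q2=params.Q2, Q3=params.Q3,
    )


def default_time_grid(params, t_min: float = 1e-3, t_max: float = 1e4,
                      per_decade: int = 64) -> NDArray[np.float64]:
    """Log-spaced lag grid in units of tau_B, matching FCS correlator spacing."""
    r = _rp(params)
    n_dec = np.log10(t_max / t_min)
    n = max(2, int(round(n_dec * per_decade)) + 1)
    return r.tau_B * np.logspace(np.log10(t_min), np.log10(t_max), n)


# ----------------------------------------------------------------------------
# rho averages of G_s(t/tau_rho)
# ----------------------------------------------------------------------------

def _chi_of_rho(rho: NDArray, chi_B: float, ratio: float) -> NDArray:
    """t/tau_rho = chi_B [(1 - rho) + rho tau_B/tau_D]."""
    return chi_B * (1.0 - rho * (1.0 - ratio))


def _rho_panels(theta: float, beta: float) -> list[tuple[float, float, NDArray, NDArray]]:
    """Quadrature panels (lo, hi, nodes, weights) resolving the density peak."""
    if theta <= _PEAK_SPLIT_RT:
        return [(0.0, 1.0, _NODES200, _WEIGHTS200)]
    sig = np.sqrt(2.0 * beta * (1.0 - beta) / theta)
    lo = max(0.0, beta - 12.0 * sig)
    hi = min(1.0, beta + 12.0 * sig)
    panels = []
    if lo > 0.0:
        panels.append((0.0, lo, _NODES64, _WEIGHTS64))
    panels.append((lo, hi, _NODES200, _WEIGHTS200))
    if hi < 1.0:
        panels.append((hi, 1.0, _NODES64, _WEIGHTS64))
    return panels


def _integrate_cont(pair: str, theta: float, beta: float, f) -> float:
    """Integral over (0,1) of the continuous density times a smooth factor f(rho)."""
    total = 0.0
    for lo, hi, nodes, wts in _rho_panels(theta, beta):
        half = 0.5 * (hi - lo)
        rho = lo + half * (nodes + 1.0)
        w = half * wts
        total += float(np.sum(w * oc._phi_cont(pair, theta, beta, rho) * f(rho)))
    return total


def exact_average_gs(pair: str, t: float, params) -> float:
    """Mass-weighted exact average  <G_s(t/tau_rho)>_{Phi_pair}.

    Atom contributions enter analytically as ``atom0 G_s(t/tau_B)`` and
    ``atom1 G_s(t/tau_D)``; the continuous part is integrated with composite
    Gauss-Legendre quadrature (the density is analytic in rho, and for
    Rt > 50 a dedicated panel resolves the peak at rho ~ beta).  Absolute
    accuracy is at the 1e-12 level, comfortably below the 1e-9 contract.
    """
    r = _rp(params)
    theta = r.R * t
    chi_B = t / r.tau_B
    atom0, atom1 = oc._atoms(pair, theta, r.beta)
    val = atom0 * float(gs(chi_B, r.omega)) + atom1 * float(gs(chi_B * r.tau_ratio, r.omega))
    val += _integrate_cont(
        pair, theta, r.beta,
        lambda rho: gs(_chi_of_rho(rho, chi_B, r.tau_ratio), r.omega),
    )
    return val


class _SchemeView:
    """Duck-typed stand-in carrying only (R, beta, k23, k32) for occupation calls."""

    def __init__(self, R: float, beta: float):
        self.R = R
        self.beta = beta
        self.k23 = beta * R
        self.k32 = (1.0 - beta) * R


def _scheme_view(r) -> _SchemeView:
    return _SchemeView(r.R, r.beta)


def _expansion_average(pair: str, t: float, r, order: int) -> float:
    """Moment-expansion average with the endpoint atoms handled exactly.

    The atoms (no-transition paths) contribute ``atom0 G_s(t/tau_B)`` and
    ``atom1 G_s(t/tau_D)`` analytically, exactly as in the exact route; only
    the continuous part of the density is replaced by its Taylor expansion
    around the continuous-part mean occupation::

        mass_c * [ G_s(chi_c) + 0.5 G_s''(chi_c) (t/tau_Delta)^2 sigma_c^2 ]

    (``order=1`` keeps the first term only).  Expanding the full density
    instead would be markedly worse whenever an atom carries weight, because
    the density is then bimodal.
    """
    theta = r.R * t
    chi_B = t / r.tau_B
    atom0, atom1 = oc._atoms(pair, theta, r.beta)
    val = atom0 * float(gs(chi_B, r.omega)) + atom1 * float(gs(chi_B * r.tau_ratio, r.omega))
    mass_c, m1c, _, sigma_c = oc.continuous_moments(theta, r.beta, pair)
    if mass_c > 0.0:
        chi_c = float(_chi_of_rho(np.asarray(m1c), chi_B, r.tau_ratio))
        term = float(gs(chi_c, r.omega))
        if order >= 2:
            t_over_tau_delta = chi_B * (1.0 - r.tau_ratio)
            term += 0.5 * float(gs_dd(chi_c, r.omega)) * (t_over_tau_delta * sigma_c) ** 2
        val += mass_c * term
    return val


def approx_average_gs(pair: str, t: float, params) -> float:
    """Two-term moment expansion of the exact average (atoms exact).

    Exactly two terms in ``rho - <rho>`` for the continuous part; the
    higher-order terms are dropped by construction.
    """
    return _expansion_average(pair, t, _rp(params), order=2)


def first_order_average_gs(pair: str, t: float, params) -> float:
    """First term of the expansion only (atoms exact).

    The pair diffusion times are time dependent through the conditional mean
    occupation; adequate for fast reactions (v below the first-order boundary).
    """
    return _expansion_average(pair, t, _rp(params), order=1)


def average_gs_bounds(pair: str, t: float, params) -> tuple[float, float]:
    """Rigorous lower/upper bounds on the exact mass-weighted average.

    ``rho -> G_s(t/tau_rho)`` is increasing and convex, so Jensen's
    inequality gives the lower bound ``mass G_s(t/tau_pair)`` and the chord
    bound gives ``mass [(1-<rho>) G_s(t/tau_B) + <rho> G_s(t/tau_D)]``.  The
    amplitudes are monotone functions of ``exp(-t k23)`` and ``exp(-t k32)``
    through the masses, atoms and conditional means.
    """
    r = _rp(params)
    theta = r.R * t
    mass, m1, _, _ = oc.phi_moments(pair, t, _scheme_view(r))
    chi_B = t / r.tau_B
    lower = mass * float(gs(_chi_of_rho(np.asarray(m1), chi_B, r.tau_ratio), r.omega))
    upper = mass * (
        (1.0 - m1) * float(gs(chi_B, r.omega)) + m1 * float(gs(chi_B * r.tau_ratio, r.omega))
    )
    return lower, upper


# ----------------------------------------------------------------------------
# Components and assembly
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class AcfComponents:
    """Component correlation functions on a lag grid plus the assembled G."""

    t_grid: NDArray[np.float64]
    G11: NDArray[np.float64]
    G22: NDArray[np.float64]
    G23: NDArray[np.float64]
    G32: NDArray[np.float64]
    G33: NDArray[np.float64]
    G: NDArray[np.float64]
    method: str


_AVERAGERS = {
    "exact": exact_average_gs,
    "moment_expansion": approx_average_gs,
    "first_order": first_order_average_gs,
}


def _component_pairs(t_grid: NDArray, params, method: str) -> dict[str, NDArray]:
    r = _rp(params)
    out = {p: np.empty_like(t_grid) for p in oc.PAIRS}
    if method == "effective":
        # R -> inf limit: Phi -> delta(rho - beta) for every pair; the mass
        # prefactors collapse to their long-time limits for t > 0.
        chi_beta = (t_grid / r.tau_B) * (1.0 - r.beta * (1.0 - r.tau_ratio))
        g = gs(chi_beta, r.omega)
        lim = {"22": 1.0 - r.beta, "33": r.beta, "23": 1.0 - r.beta, "32": r.beta}
        for p in oc.PAIRS:
            out[p] = np.where(t_grid == 0.0, 1.0 if p in ("22", "33") else 0.0,
                              lim[p] * g)
        return out
    avg = _AVERAGERS[method]
    for i, t in enumerate(t_grid):
        if t == 0.0:
            for p in oc.PAIRS:
                out[p][i] = 1.0 if p in ("22", "33") else 0.0
            continue
        for p in oc.PAIRS:
            out[p][i] = avg(p, float(t), r)
    return out


def component_acfs(t_grid: ArrayLike, params, method: str = "exact") -> AcfComponents:
    """Evaluate G_11 ... G_33 and the assembled G(t) on a lag grid.

    ``method`` selects the averaging route for the species-2/3 components:
    ``exact`` (quadrature), ``moment_expansion`` (two terms), ``first_order``
    (one term) or ``effective`` (R -> inf limit).  The components satisfy
    ``G_{i'j'}(0) = delta_{i'j'}`` and the cross identity
    ``(1 - beta) G_32 = beta G_23``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1D and strictly increasing")
    if np.any(t_grid < 0):
        raise ValueError("lag times must be >= 0")
    if method == "auto":
        method = "exact" if t_grid.size <= 256 else "moment_expansion"
    if method not in ("exact", "moment_expansion", "first_order", "effective"):
        raise ValueError(
            f"method {method!r} does not produce components; use one of "
            "{'exact', 'moment_expansion', 'first_order', 'effective', 'auto'}"
        )
    r = _rp(params)
    pairs = _component_pairs(t_grid, r, method)
    chi_D = (t_grid / r.tau_B) * r.tau_ratio
    G11 = gs(chi_D, r.omega)
    G = _assemble(r, G11, pairs)
    return AcfComponents(
        t_grid=t_grid, G11=G11, G22=pairs["22"], G23=pairs["23"],
        G32=pairs["32"], G33=pairs["33"], G=G, method=method,
    )


def _assemble(r, G11: NDArray, pairs: dict[str, NDArray]) -> NDArray:
    nbar = r.Q1 * r.N1 + r.Q2 * r.N2 + r.Q3 * r.N3
    if nbar <= 0:
        raise ValueError("total brightness is zero; at least one fluorescent species required")
    num = (
        r.Q1**2 * r.N1 * G11
        + r.Q2**2 * r.N2 * pairs["22"]
        + r.Q3**2 * r.N3 * pairs["33"]
        + r.Q2 * r.Q3 * (r.N3 * pairs["23"] + r.N2 * pairs["32"])
    )
    return num / nbar**2


def full_acf(t_grid: ArrayLike, params, method: str = "exact") -> NDArray[np.float64]:
    """The assembled autocorrelation function G(t) on a lag grid.

    Component-producing methods (``exact``, ``moment_expansion``,
    ``first_order``, ``auto``) go through :func:`component_acfs`; the
    closed-form reference curves are dispatched to their dedicated
    implementations (``effective``, ``two_component``, ``slow_reaction``,
    ``fast_diffusion``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if method == "two_component":
        if isinstance(params, ModelParams):
            return two_component_acf(t_grid, params)
        return _two_component_reduced(t_grid, _rp(params))
    if method == "effective":
        if isinstance(params, ModelParams):
            return effective_diffusion_acf(t_grid, params)
        return component_acfs(t_grid, params, method="effective").G
    if method == "slow_reaction":
        return slow_reaction_acf(t_grid, params)
    if method == "fast_diffusion":
        return fast_diffusion_acf(t_grid, params)
    return component_acfs(t_grid, params, method=method).G


def _two_component_reduced(t_grid: NDArray, r) -> NDArray:
    """Two-component curve from the reduced view (zero-rate component limit)."""
    chi_B = t_grid / r.tau_B
    pairs = {
        "22": gs(chi_B, r.omega),
        "33": gs(chi_B * r.tau_ratio, r.omega),
        "23": np.zeros_like(t_grid),
        "32": np.zeros_like(t_grid),
    }
    return _assemble(r, gs(chi_B * r.tau_ratio, r.omega), pairs)


# ----------------------------------------------------------------------------
# Slow-reaction asymptotic curve
# ----------------------------------------------------------------------------

def slow_reaction_acf(t_grid: ArrayLike, params) -> NDArray[np.float64]:
    """Slow-reaction asymptote: two-component diffusion plus O(k23) coupling.

    Valid for ``tau_B k23 << 1`` and ``tau_D k32 << 1`` at lags short
    compared to 1/gamma.  Expanding the occupation densities for small
    ``gamma t`` (I0 ~ 1, I1 ~ zeta/2) and keeping first order in the rates::

        G(t) = G_2(t) + (k23 t / n_bar^2) * N_B *
               [ 2 Q_B Q_C J(t) - Q_B^2 G_s(t/tau_B) - Q_C^2 G_s(t/tau_D) ]

    with ``J(t) = int_0^1 G_s(t/tau_rho) d rho`` and ``G_2`` the
    two-component curve.  Every correction is proportional to ``k23``.
    Outside the regime a warning is issued (never an error).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    r = _rp(params)
    k23 = r.beta * r.R
    k32 = (1.0 - r.beta) * r.R
    tau_D_k32 = k32 * r.tau_B / r.tau_ratio if r.tau_ratio > 0 else 0.0
    if k23 * r.tau_B > 0.1 or tau_D_k32 > 0.1:
        warnings.warn(
            "slow-reaction curve requested outside its regime "
            f"(tau_B*k23 = {k23 * r.tau_B:.3g}, tau_D*k32 = {tau_D_k32:.3g}); "
            "accuracy degrades",
            stacklevel=2,
        )
    chi_B = t_grid / r.tau_B
    rho = 0.5 * (_NODES64 + 1.0)
    w = 0.5 * _WEIGHTS64
    J = np.array([
        float(np.sum(w * gs(_chi_of_rho(rho, cb, r.tau_ratio), r.omega))) for cb in chi_B
    ])
    nbar = r.Q1 * r.N1 + r.Q2 * r.N2 + r.Q3 * r.N3
    base = _two_component_reduced(t_grid, r)
    # Q2 = Q_B, Q3 = Q_C, N2 = N_B
    corr = (
        k23 * t_grid / nbar**2 * r.N2
        * (2.0 * r.Q2 * r.Q3 * J - r.Q2**2 * gs(chi_B, r.omega)
           - r.Q3**2 * gs(chi_B * r.tau_ratio, r.omega))
    )
    return base + corr


# ----------------------------------------------------------------------------
# Fast-diffusion regime (immobile binding sites)
# ----------------------------------------------------------------------------

def _gs_weighted_mean_rho(chi_B: float, omega: float) -> tuple[float, float]:
    """(I_g, <rho>_s) where I_g = int_0^1 G_s(chi_B (1-rho)) drho."""
    rho = 0.5 * (_NODES200 + 1.0)
    w = 0.5 * _WEIGHTS200
    g = gs(chi_B * (1.0 - rho), omega)
    I_g = float(np.sum(w * g))
    mean = float(np.sum(w * rho * g)) / I_g
    return I_g, mean


def fast_diffusion_acf(t_grid: ArrayLike, params) -> NDArray[np.float64]:
    """Fast dye diffusion with immobile binding sites (D = 0).

    When ``tau_B -> 0`` the normalized function ``G_s(t/tau_rho)/I_g``
    concentrates at ``rho = 1``, so the occupation average factorizes:
    the continuous part of each ``Phi`` is evaluated at the G_s-weighted mean
    occupation ``<rho>_s`` and multiplied by ``I_g = int G_s d rho``, while
    the endpoint atoms keep their analytic weights (in particular the bound
    dye contributes ``exp(-k32 t)``, the reaction-dominant decay).  The
    regime ends at the transition time of :func:`transition_time`; for
    ``D != 0`` the transition does not occur and this method refuses to run.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    r = _rp(params)
    if r.tau_ratio != 0.0:
        raise ValueError(
            "fast_diffusion_acf requires immobile binding sites (D = 0); "
            f"got tau_B/tau_D = {r.tau_ratio}"
        )
    omega = r.omega
    pairs = {p: np.empty_like(t_grid) for p in oc.PAIRS}
    for i, t in enumerate(t_grid):
        if t == 0.0:
            for p in oc.PAIRS:
                pairs[p][i] = 1.0 if p in ("22", "33") else 0.0
            continue
        theta = r.R * t
        chi_B = t / r.tau_B
        I_g, mean_s = _gs_weighted_mean_rho(chi_B, omega)
        gB = float(gs(chi_B, omega))
        for p in oc.PAIRS:
            atom0, atom1 = oc._atoms(p, theta, r.beta)
            cont = float(oc._phi_cont(p, theta, r.beta, np.asarray(mean_s)))
            pairs[p][i] = atom0 * gB + atom1 * 1.0 + cont * I_g
    G11 = np.ones_like(t_grid)
    G = _assemble(r, G11, pairs)
    return G


def transition_time(params: ModelParams) -> float:
    """Crossover lag t_t = 4 beta^2 (1-beta)^2 / (R^2 tau_B) between the
    fast-diffusion and effective-diffusion regimes (immobile sites only)."""
    s, d = params.scheme, params.diffusion
    if not d.immobile:
        raise ValueError("the fast/effective-diffusion transition requires immobile sites (D = 0)")
    beta = s.beta
    return 4.0 * beta**2 * (1.0 - beta) ** 2 / (s.R**2 * d.tau_B)
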