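"""Applicability diagnostics for the moment-expansion approximation.

The two-term expansion of ``<G_s(t/tau_rho)>`` around the conditional mean
occupation is accurate when the occupation densities are narrow, which is
controlled by the concentration rate ``gamma = sqrt(k23 k32)``.  Expressed
through the bound fraction ``beta`` and the validity parameter

    v = t_f/tau_B + t_b/tau_D        (t_f = 1/k23, t_b = 1/k32),

gamma reads

    gamma(beta, v) = (1/v) [ sqrt((1-beta)/beta)/tau_B
                             + sqrt(beta/(1-beta))/tau_D ],

with its minimum over beta at ``beta_min = tau_D/(tau_D + tau_B)`` and
``gamma_min = 2/(v sqrt(tau_B tau_D))`` inversely proportional to ``v``.
The approximation accuracy ``epsilon_a`` is the worst relative deviation of
the approximate averages from the exact ones over all component pairs and
lag times; the boundary ``v_L(tau_B/tau_D)`` is the largest ``v`` for which
``epsilon_a < epsilon`` for every beta.  For the required accuracy
``epsilon = 0.01`` the boundary is ~2 at ``tau_B/tau_D = 1/6`` and ~0.48 at
``tau_B/tau_D = 0.001``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .engine import approx_average_gs, exact_average_gs, first_order_average_gs, _rp
from .params import MAX_TAU_RATIO, ModelParams, from_dimensionless

__all__ = [
    "RegimeDiagnostics",
    "relative_deviation",
    "accuracy",
    "gamma_of_beta",
    "limiting_v",
    "classify_regime",
    "DEFAULT_EPSILON",
]

#: Required accuracy of the expansion, adequate for FCS experiments.
DEFAULT_EPSILON = 0.01

#: Exact averages smaller than this are treated as fully decayed: the
#: relative deviation is undefined there (0/0) and the point is excluded.
TAIL_FLOOR = 1e-12

#: Pairs entering the accuracy maximum; "32" duplicates "23" exactly.
_ACC_PAIRS = ("22", "23", "33")


def _default_t_grid(params) -> NDArray[np.float64]:
    tau_B = _rp(params).tau_B
    return tau_B * np.logspace(-2, 3, 48)


def relative_deviation(pair: str, t: float, params, order: int = 2) -> float:
    """Relative deviation (approx - exact)/exact of the expansion average.

    Returns NaN when the exact average has decayed below the tail floor
    (the ratio is then 0/0 noise, not information).
    """
    exact = exact_average_gs(pair, t, params)
    if abs(exact) < TAIL_FLOOR:
        return math.nan
    approx = (approx_average_gs if order == 2 else first_order_average_gs)(pair, t, params)
    return (approx - exact) / exact


def accuracy(
    params,
    t_grid: NDArray[np.float64] | None = None,
    order: int = 2,
    stop_above: float | None = None,
) -> float:
    """Worst |relative deviation| over pairs {22, 23, 33} and the lag grid.

    The default grid spans [1e-2, 1e3] tau_B with 48 log-spaced points.
    ``stop_above`` allows early exit once the maximum provably exceeds a
    threshold (used by the bisection in :func:`limiting_v`).
    """
    if t_grid is None:
        t_grid = _default_t_grid(params)
    worst = 0.0
    for t in t_grid:
        for pair in _ACC_PAIRS:
            d = relative_deviation(pair, float(t), params, order=order)
            if not math.isnan(d):
                worst = max(worst, abs(d))
        if stop_above is not None and worst > stop_above:
            return worst
    return worst


def gamma_of_beta(beta: float, v: float, tau_D: float, tau_B: float) -> float:
    """gamma = sqrt(k23 k32) as a function of (beta, v) at fixed diffusion times.

    ``tau_D`` may be ``inf`` (immobile binding sites), in which case only
    the free-state term survives.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if v <= 0 or tau_B <= 0:
        raise ValueError("v and tau_B must be positive")
    term_B = math.sqrt((1.0 - beta) / beta) / tau_B
    term_D = 0.0 if math.isinf(tau_D) else math.sqrt(beta / (1.0 - beta)) / tau_D
    return (term_B + term_D) / v


def _beta_grid(tau_ratio: float, n: int = 25) -> NDArray[np.float64]:
    """Coarse grid on (0,1) refined around beta_min = 1/(1 + tau_ratio)."""
    beta_min = 1.0 / (1.0 + tau_ratio)
    coarse = np.linspace(0.05, 0.95, n - 9)
    width = max(0.02, 0.5 * (1.0 - beta_min))
    fine = beta_min + width * np.linspace(-1.0, 1.0, 9)
    grid = np.union1d(coarse, fine)
    return grid[(grid > 1e-4) & (grid < 1.0 - 1e-4)]


def _accuracy_at(tau_ratio: float, beta: float, v: float, omega: float,
                 order: int, stop_above: float | None) -> float:
    params = from_dimensionless(tau_ratio, beta, v, omega=omega)
    return accuracy(params, order=order, stop_above=stop_above)


def _worst_accuracy(tau_ratio: float, v: float, omega: float, order: int,
                    epsilon: float | None = None) -> float:
    worst = 0.0
    for beta in _beta_grid(tau_ratio):
        worst = max(worst, _accuracy_at(tau_ratio, float(beta), v, omega,
                                        order, epsilon))
        if epsilon is not None and worst > epsilon:
            break
    return worst


def limiting_v(
    tau_ratio: float,
    epsilon: float = DEFAULT_EPSILON,
    order: int = 2,
    omega: float = 5.0,
    rtol: float = 0.02,
    beta_mode: str = "scan",
) -> float:
    """Boundary value v_L below which the expansion meets the accuracy epsilon.

    Determined by bisection on ``v``: at each candidate the accuracy is
    maximized over the default lag grid and over beta -- either a 25-point
    grid refined near ``beta_min`` (``beta_mode="scan"``, the default) or
    the single worst-concentration-rate point ``beta_min =
    tau_D/(tau_D + tau_B)`` (``beta_mode="beta_min"``).  The two modes can
    differ at small ``tau_B/tau_D``, where the scan also probes the hybrid
    region (``k32 << k23``) in which the averages degrade even though their
    contribution to G(t) often does not; see the methods note.
    ``order=2`` gives the two-term boundary v_L, ``order=1`` the first-order
    boundary v_L^0 (roughly an order of magnitude smaller).  The bisection
    resolves v_L to 2% relative, matching the 1-2 significant figures to
    which the boundary is meaningful (it also depends mildly on omega).
    """
    if not 0.0 <= tau_ratio <= MAX_TAU_RATIO:
        raise ValueError(
            f"tau_B/tau_D = {tau_ratio} outside the studied range [0, {MAX_TAU_RATIO}]"
        )
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if beta_mode not in ("scan", "beta_min"):
        raise ValueError("beta_mode must be 'scan' or 'beta_min'")

    if beta_mode == "scan":
        def ok(v: float) -> bool:
            return _worst_accuracy(tau_ratio, v, omega, order, epsilon) < epsilon
    else:
        beta_min = 1.0 / (1.0 + tau_ratio)

        def ok(v: float) -> bool:
            return _accuracy_at(tau_ratio, beta_min, v, omega, order, epsilon) < epsilon

    lo, hi = 0.02, 0.05
    # expand until bracketing
    while ok(hi):
        lo, hi = hi, hi * 2.0
        if hi > 64.0:
            return hi  # entire studied range is valid
    while not ok(lo):
        hi, lo = lo, lo / 2.0
        if lo < 1e-3:
            raise RuntimeError("no valid v found above 1e-3")
    while hi / lo - 1.0 > rtol:
        mid = math.sqrt(lo * hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


@dataclass(frozen=True)
class RegimeDiagnostics:
    """Raw diagnostics plus an advisory regime label."""

    v: float
    v_L: float
    v_L0: float
    epsilon: float
    epsilon_a: float
    gamma_min: float
    beta_min: float
    label: str
    note: str
    t_t: float | None = None


#: "much smaller than" operationalized for the advisory labels.
_MUCH_LESS = 0.1


def classify_regime(
    params: ModelParams,
    epsilon: float = DEFAULT_EPSILON,
    compute_boundaries: bool = True,
) -> RegimeDiagnostics:
    """Classify the parameter point into the limiting regimes.

    The label is advisory; all decisions derive from the raw numbers carried
    in the returned diagnostics.  ``v > v_L`` does not automatically mean
    the expansion fails -- if the offending average enters G(t) with a small
    coefficient its error is harmless -- so the note records the context
    instead of rejecting the point.
    """
    s, d = params.scheme, params.diffusion
    tau_ratio = d.tau_ratio
    v = params.v
    beta_min = 1.0 / (1.0 + tau_ratio)
    gamma_min = gamma_of_beta(beta_min, v, d.tau_D, d.tau_B) if 0 < beta_min < 1 else math.nan

    eps_a = accuracy(params)
    v_L = v_L0 = math.nan
    if compute_boundaries and tau_ratio <= MAX_TAU_RATIO:
        v_L = limiting_v(tau_ratio, epsilon=epsilon, order=2, omega=params.volume.omega)
        v_L0 = limiting_v(tau_ratio, epsilon=epsilon, order=1, omega=params.volume.omega)

    t_t = None
    if d.immobile:
        beta = s.beta
        t_t = 4.0 * beta**2 * (1.0 - beta) ** 2 / (s.R**2 * d.tau_B)

    note = ""
    if s.k23 / s.k32 < _MUCH_LESS:
        label = "pure_diffusion"
        note = "most dye is free; G22 ~ G_s(t/tau_B)"
    elif s.k32 / s.k23 < _MUCH_LESS:
        if s.k23 * d.tau_B < _MUCH_LESS:
            label = "reaction_dominant"
            note = "G33 ~ exp(-k32 t): complexes decay before diffusing"
        else:
            label = "hybrid"
    elif s.k23 * d.tau_B < _MUCH_LESS and (d.immobile or s.k32 * d.tau_D < _MUCH_LESS):
        label = "reaction_dominant" if d.immobile else "slow_reaction"
    elif s.beta * (1.0 - s.beta) * v < _MUCH_LESS * epsilon:
        label = "effective_diffusion_ok"
        note = "R tau_beta >> 1: the reaction rates drop out of G(t)"
    elif not math.isnan(v_L0) and v < v_L0:
        label = "fast_reaction"
    elif (not math.isnan(v_L) and v < v_L) or eps_a < epsilon:
        label = "intermediate"
    else:
        label = "intermediate"
        note = (
            f"v = {v:.3g} exceeds v_L; epsilon_a = {eps_a:.3g} -- the expansion "
            "may still be usable where the affected averages carry small weight"
        )
    return RegimeDiagnostics(
        v=v, v_L=v_L, v_L0=v_L0, epsilon=epsilon, epsilon_a=eps_a,
        gamma_min=gamma_min, beta_min=beta_min, label=label, note=note, t_t=t_t,
    )
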