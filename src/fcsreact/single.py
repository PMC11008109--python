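"""Single-component diffusion ACF and the two closed-form reference models.

``gs`` is the textbook autocorrelation function for one species diffusing
through a 3D-Gaussian observation volume with aspect ratio ``omega``:

    G_s(chi) = 1 / ((1 + chi) * sqrt(1 + chi / omega^2)),   chi = t / tau.

It is normalized to 1 at zero lag, strictly decreasing in ``chi``, and --
viewed as a function of the occupation fraction ``rho`` through
``chi = t/tau_rho`` -- increasing and convex in ``rho``.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["gs", "gs_dd", "effective_diffusion_acf", "two_component_acf"]


def _check_chi(chi: NDArray) -> None:
    if np.any(chi < 0):
        raise ValueError("dimensionless lag chi must be >= 0")


def gs(chi: ArrayLike, omega: float) -> NDArray[np.float64]:
    """One-component diffusion ACF on a 3D-Gaussian volume, G_s(0) = 1."""
    chi = np.asarray(chi, dtype=float)
    _check_chi(chi)
    if omega <= 0:
        raise ValueError("aspect ratio omega must be positive")
    if np.isinf(omega):            # 2D limit: axial decay switched off
        return 1.0 / (1.0 + chi)
    return 1.0 / ((1.0 + chi) * np.sqrt(1.0 + chi / omega**2))


def gs_dd(chi: ArrayLike, omega: float) -> NDArray[np.float64]:
    """Analytic second derivative d^2 G_s / d chi^2; positive for chi >= 0."""
    chi = np.asarray(chi, dtype=float)
    _check_chi(chi)
    if omega <= 0:
        raise ValueError("aspect ratio omega must be positive")
    if np.isinf(omega):
        return 2.0 / (1.0 + chi) ** 3
    w2 = omega**2
    u = 1.0 + chi
    s = 1.0 + chi / w2
    return (
        2.0 / (u**3 * np.sqrt(s))
        + 1.0 / (w2 * u**2 * s**1.5)
        + 0.75 / (w2**2 * u * s**2.5)
    )


def effective_diffusion_acf(t: ArrayLike, params) -> NDArray[np.float64]:
    """Fast-reaction limit of the full ACF (R -> infinity at fixed beta).

    The dye pool then behaves as one species with the population-averaged
    diffusion coefficient ``D_beta = (1-beta) D_B + beta D`` and effective
    quantum yield ``Q_beta``::

        G_inf(t) = [Q_C^2 N_1 G_s(t/tau_D)
                    + Q_beta^2 (N_2 + N_3) G_s(t/tau_beta)] / n_bar^2

    which has the form of independent two-component diffusion with
    coefficients ``D`` and ``D_beta``.  The reaction rate constants drop out;
    only the equilibrium constant (through ``beta``) survives.
    """
    t = np.asarray(t, dtype=float)
    s, d, b = params.scheme, params.diffusion, params.brightness
    beta = s.beta
    D_beta = (1.0 - beta) * d.D_B + beta * d.D
    tau_beta = d.L**2 / (4.0 * D_beta)
    omega = params.volume.omega
    N1 = params.N_bar("1")
    N23 = params.N_bar("2") + params.N_bar("3")
    Qb = b.Q_beta(beta)
    nbar = params.n_bar
    slow = b.Q_C**2 * N1 * (gs(t * d.tau_D_inv, omega) if not d.immobile else np.ones_like(t))
    fast = Qb**2 * N23 * gs(t / tau_beta, omega)
    return (slow + fast) / nbar**2


def two_component_acf(t: ArrayLike, params) -> NDArray[np.float64]:
    """ACF for two noninteracting species: the dye (tau_B) and A/C pool (tau_D).

    This is the zero-rate limit of the full model: with the reaction switched
    off the dye-pool fluctuations decay purely by diffusion with ``tau_B``
    and the macromolecule/complex fluctuations with ``tau_D``::

        G_2(t) = [Q_C^2 N_C G_s(t/tau_D) + Q_B^2 N_B G_s(t/tau_B)] / n_bar^2
    """
    t = np.asarray(t, dtype=float)
    d, b = params.diffusion, params.brightness
    omega = params.volume.omega
    N_B = params.N_bar("B")
    N_C = params.N_bar("C")
    nbar = params.n_bar
    slow = b.Q_C**2 * N_C * (gs(t * d.tau_D_inv, omega) if not d.immobile else np.ones_like(t))
    fast = b.Q_B**2 * N_B * gs(t / d.tau_B, omega)
    return (slow + fast) / nbar**2
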