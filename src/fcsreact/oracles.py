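"""Independent brute-force oracles.

These deliberately avoid the analytical machinery of the rest of the
package: the occupation-time sampler runs exact-event (Gillespie) two-state
paths, and the single-species ACF oracle evaluates the defining wave-vector
integral numerically.  They are slow-path APIs used by the test suite and
for auditing individual parameter points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import quad

from .params import ReactionScheme

__all__ = ["OccupationSamples", "sample_occupation", "gs_bruteforce"]


@dataclass(frozen=True)
class OccupationSamples:
    """Vectorized collection of two-state occupation-time samples."""

    start_state: int
    t: float
    rho: NDArray[np.float64]          # fraction of [0, t] spent in state 3
    end_state: NDArray[np.int64]      # 2 or 3
    n_switches: NDArray[np.int64]

    def conditioned(self, end_state: int) -> NDArray[np.float64]:
        """Occupation fractions of the paths ending in ``end_state``
        (conditioning by partitioning the sample, never by reweighting)."""
        return self.rho[self.end_state == end_state]


def sample_occupation(
    scheme: ReactionScheme | object,
    t: float,
    start_state: int,
    n_paths: int,
    seed: int,
) -> OccupationSamples:
    """Simulate exact-event two-state paths and their occupation fractions.

    State 2 (free dye) switches to state 3 at rate ``k23``; state 3 (bound)
    switches back at rate ``k32``.  Sojourn times are drawn exactly from
    their exponential laws, so there is no time-discretization error.  The
    generator is seeded with ``seed`` only; paths are simulated in lockstep
    rounds (one exponential draw per still-active path per round), which
    keeps the draws for early switches unchanged when ``n_paths`` grows.
    """
    if start_state not in (2, 3):
        raise ValueError("start_state must be 2 or 3")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if t <= 0:
        raise ValueError("t must be positive")
    k23 = scheme.k23
    k32 = scheme.k32
    rng = np.random.default_rng(seed)

    elapsed = np.zeros(n_paths)
    time_in_3 = np.zeros(n_paths)
    state = np.full(n_paths, start_state, dtype=np.int64)
    n_switches = np.zeros(n_paths, dtype=np.int64)
    active = np.ones(n_paths, dtype=bool)

    while np.any(active):
        idx = np.flatnonzero(active)
        rate = np.where(state[idx] == 2, k23, k32)
        with np.errstate(divide="ignore"):
            sojourn = rng.exponential(1.0, size=idx.size) / rate
        end = elapsed[idx] + sojourn
        finished = end >= t
        # paths whose current sojourn outlasts the window
        fin = idx[finished]
        time_in_3[fin] += np.where(state[fin] == 3, t - elapsed[fin], 0.0)
        elapsed[fin] = t
        active[fin] = False
        # paths that switch within the window
        sw = idx[~finished]
        time_in_3[sw] += np.where(state[sw] == 3, sojourn[~finished], 0.0)
        elapsed[sw] = end[~finished]
        state[sw] = 5 - state[sw]
        n_switches[sw] += 1

    return OccupationSamples(
        start_state=start_state, t=t, rho=time_in_3 / t,
        end_state=state, n_switches=n_switches,
    )


def gs_bruteforce(t: float, tau: float, omega: float) -> float:
    """Single-species ACF by direct numerical wave-vector integration.

    Evaluates the Gaussian-filtered free-diffusion propagator integral

        G(t) ~ int d^3q exp(-q_r^2 L^2/4 - q_z^2 H^2/4) exp(-D q^2 t)

    (radial and axial factors separately, by adaptive quadrature) and
    normalizes by its value at ``t = 0``.  Agrees with the closed form
    ``1/((1+chi) sqrt(1+chi/omega^2))`` to ~1e-6 relative.
    """
    if t < 0 or tau <= 0 or omega <= 0:
        raise ValueError("need t >= 0, tau > 0, omega > 0")
    chi = t / tau
    # units L = 1, so D t = chi/4 and H = omega
    rad = quad(lambda q: q * np.exp(-q * q * (0.25 + 0.25 * chi)), 0.0, np.inf)[0]
    rad0 = quad(lambda q: q * np.exp(-q * q * 0.25), 0.0, np.inf)[0]
    ax = quad(lambda q: np.exp(-q * q * (0.25 * omega**2 + 0.25 * chi)), 0.0, np.inf)[0]
    ax0 = quad(lambda q: np.exp(-q * q * 0.25 * omega**2), 0.0, np.inf)[0]
    return (rad / rad0) * (ax / ax0)
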