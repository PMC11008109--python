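"""Physical parameters, species bookkeeping and derived dimensionless quantities.

The model describes a dilute solution in equilibrium containing macromolecules
``A``, fluorescent dyes ``B`` and fluorescent complexes ``C`` formed in the
reversible reaction ``A + B <=> C`` with rate constants ``k_plus`` and
``k_minus``.  The macromolecule and the complex share the diffusion
coefficient ``D``; the free dye diffuses with ``D_B > D``.

Linearizing the reaction term about equilibrium gives the pseudo-first-order
rates

    k_A = k_plus * C_B,   k_B = k_plus * C_A,   k_C = k_minus.

A linear transformation of the concentration fluctuations decouples the
three-component system into a freely diffusing species 1 and a two-state
(free/bound dye) pair of species 2 and 3 exchanging through a fictitious
unimolecular reaction ``2 <=> 3`` with rates

    k23 = k_B,   k32 = k_A + k_C,

chemical relaxation rate ``R = k23 + k32`` and bound fraction
``beta = k23 / R``.

Units at the boundary are SI-derived: seconds, micrometres, um^2/s, and
concentrations in molecules/um^3 (so that ``N = C * V`` is a molecule count).
All engine-level computation is carried out in dimensionless form
(``t/tau_B``, ``tau_B/tau_D``, ``beta``, ``v``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FocalVolume",
    "ReactionScheme",
    "DiffusionSet",
    "Brightness",
    "ModelParams",
    "ParameterError",
    "build_params",
    "dimensionless_view",
    "from_dimensionless",
]

#: Relative tolerance on the detailed-balance check.  Equilibrium consistency
#: is an input contract; inconsistent inputs are rejected, never repaired.
EQUILIBRIUM_RTOL = 1e-10

#: Largest diffusion-coefficient ratio D/D_B for which the equal-coefficient
#: approximation for macromolecule and complex is considered meaningful.
MAX_TAU_RATIO = 0.30


class ParameterError(ValueError):
    """Raised when model parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class FocalVolume:
    """3D-Gaussian observation volume with beam radius L and axial size H (um)."""

    L: float
    H: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.H <= 0:
            raise ParameterError(f"focal dimensions must be positive, got L={self.L}, H={self.H}")

    @property
    def omega(self) -> float:
        """Aspect ratio H/L."""
        return self.H / self.L

    @property
    def V(self) -> float:
        """Effective sampling volume pi^{3/2} L^2 H (um^3)."""
        return math.pi ** 1.5 * self.L ** 2 * self.H


@dataclass(frozen=True)
class ReactionScheme:
    """Rates and equilibrium concentrations of A + B <=> C and its 2 <=> 3 reduction."""

    k_plus: float      # um^3 s^-1 (per-molecule bimolecular rate)
    k_minus: float     # s^-1
    C_A: float         # molecules/um^3
    C_B: float
    C_C: float

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_minus", "C_A", "C_B", "C_C"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        K = self.k_plus / self.k_minus
        K_conc = self.C_C / (self.C_A * self.C_B)
        resid = abs(K_conc - K) / K
        if resid > EQUILIBRIUM_RTOL:
            raise ParameterError(
                "equilibrium inconsistency: C_C/(C_A*C_B) = "
                f"{K_conc:.12g} but k_plus/k_minus = {K:.12g} "
                f"(relative residual {resid:.3g} > {EQUILIBRIUM_RTOL:g})"
            )

    # linearized pseudo-first-order rates
    @property
    def k_A(self) -> float:
        return self.k_plus * self.C_B

    @property
    def k_B(self) -> float:
        return self.k_plus * self.C_A

    @property
    def k_C(self) -> float:
        return self.k_minus

    # fictitious 2 <=> 3 reaction
    @property
    def k23(self) -> float:
        """Binding rate of a free dye (2 -> 3), s^-1."""
        return self.k_B

    @property
    def k32(self) -> float:
        """Release rate of a bound dye (3 -> 2), s^-1."""
        return self.k_A + self.k_C

    @property
    def R(self) -> float:
        """Chemical relaxation rate k23 + k32, s^-1."""
        return self.k23 + self.k32

    @property
    def beta(self) -> float:
        """Equilibrium bound fraction of the dye, k23/R."""
        return self.k23 / self.R

    @property
    def t_f(self) -> float:
        """Relaxation time of the free state, 1/k23 (s)."""
        return 1.0 / self.k23

    @property
    def t_b(self) -> float:
        """Relaxation time of the bound state, 1/k32 (s)."""
        return 1.0 / self.k32

    @property
    def gamma(self) -> float:
        """Concentration rate sqrt(k23*k32) of the occupation densities (s^-1)."""
        return math.sqrt(self.k23 * self.k32)


@dataclass(frozen=True)
class DiffusionSet:
    """Diffusion coefficients (um^2/s) and derived diffusion times.

    ``D`` is shared by the macromolecule and the complex and may be zero
    (immobile binding sites); the immobile case is carried as the explicit
    ``immobile`` flag and enters all formulas through ``tau_D_inv = 0``,
    never through a floating-point infinity.
    """

    D: float
    D_B: float
    L: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ParameterError(f"D must be >= 0, got {self.D}")
        if self.D_B <= 0:
            raise ParameterError(f"D_B must be positive, got {self.D_B}")
        if self.D >= self.D_B:
            raise ParameterError(
                f"unsupported regime: D = {self.D} >= D_B = {self.D_B}; the model "
                "assumes the dye diffuses strictly faster than the macromolecule "
                "(studied up to D/D_B < 0.3)"
            )

    @property
    def immobile(self) -> bool:
        return self.D == 0.0

    @property
    def tau_B(self) -> float:
        """Dye diffusion time L^2/4D_B (s)."""
        return self.L ** 2 / (4.0 * self.D_B)

    @property
    def tau_D(self) -> float:
        """Macromolecule/complex diffusion time L^2/4D (s); inf when immobile."""
        return math.inf if self.immobile else self.L ** 2 / (4.0 * self.D)

    @property
    def tau_D_inv(self) -> float:
        return 0.0 if self.immobile else 4.0 * self.D / self.L ** 2

    @property
    def tau_ratio(self) -> float:
        """tau_B/tau_D = D/D_B; zero for immobile binding sites."""
        return self.D / self.D_B

    @property
    def tau_Delta_inv(self) -> float:
        """1/tau_B - 1/tau_D (s^-1); the ``slope`` of 1/tau_rho in rho."""
        return 1.0 / self.tau_B - self.tau_D_inv

    def D_rho(self, rho: float) -> float:
        """Occupation-averaged diffusion coefficient (1-rho) D_B + rho D."""
        return (1.0 - rho) * self.D_B + rho * self.D

    def tau_rho_inv(self, rho: float) -> float:
        """1/tau_rho = (1-rho)/tau_B + rho/tau_D."""
        return (1.0 - rho) / self.tau_B + rho * self.tau_D_inv


@dataclass(frozen=True)
class Brightness:
    """Quantum yields (molecular brightness weights) of the fluorescent species."""

    Q_B: float
    Q_C: float

    def __post_init__(self) -> None:
        if self.Q_B < 0 or self.Q_C < 0:
            raise ParameterError("quantum yields must be nonnegative")
        if self.Q_B == 0 and self.Q_C == 0:
            raise ParameterError("at least one of Q_B, Q_C must be positive")

    # species 1/2/3 yields: the transformation mixes A with C, so species 1
    # carries the complex brightness.
    @property
    def Q_1(self) -> float:
        return self.Q_C

    @property
    def Q_2(self) -> float:
        return self.Q_B

    @property
    def Q_3(self) -> float:
        return self.Q_C

    def Q_beta(self, beta: float) -> float:
        """Effective quantum yield Q_B (1-beta) + Q_C beta of the dye pool."""
        return self.Q_B * (1.0 - beta) + self.Q_C * beta


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the reaction-diffusion FCS model."""

    volume: FocalVolume
    scheme: ReactionScheme
    diffusion: DiffusionSet
    brightness: Brightness

    # --- species concentrations -------------------------------------------
    # Species 2 is the free dye.  Species 3 inherits the fictitious-reaction
    # equilibrium C_3/C_2 = k23/k32.  Species 1 absorbs the remaining
    # macromolecule/complex fluctuation weight; detailed balance makes the
    # initial covariances of the three transformed fields diagonal, with
    # C_1 + C_3 = C_C.
    @property
    def C_1(self) -> float:
        s = self.scheme
        return (s.k_A / s.k32) ** 2 * (s.C_A + s.C_C)

    @property
    def C_2(self) -> float:
        return self.scheme.C_B

    @property
    def C_3(self) -> float:
        s = self.scheme
        return s.beta / (1.0 - s.beta) * s.C_B

    def N_bar(self, species: str) -> float:
        """Mean molecule number C_i * V for i in {A,B,C,1,2,3}."""
        V = self.volume.V
        table = {
            "A": self.scheme.C_A, "B": self.scheme.C_B, "C": self.scheme.C_C,
            "1": self.C_1, "2": self.C_2, "3": self.C_3,
        }
        return table[species] * V

    @property
    def n_bar(self) -> float:
        """Mean brightness-weighted molecule number Q_B N_B + Q_C N_C."""
        b = self.brightness
        return b.Q_B * self.N_bar("B") + b.Q_C * self.N_bar("C")

    @property
    def v(self) -> float:
        """Validity parameter v = t_f/tau_B + t_b/tau_D (dimensionless)."""
        s, d = self.scheme, self.diffusion
        return s.t_f / d.tau_B + s.t_b * d.tau_D_inv


def build_params(
    k_plus: float,
    k_minus: float,
    C_A: float,
    C_B: float,
    C_C: float,
    D: float,
    D_B: float,
    L: float,
    H: float,
    Q_B: float = 1.0,
    Q_C: float = 1.0,
) -> ModelParams:
    """Assemble and validate a :class:`ModelParams` from physical inputs.

    Parameters use s / um units; concentrations are molecules/um^3.
    Raises :class:`ParameterError` on inconsistent equilibrium
    (``C_C/(C_A C_B) != k_plus/k_minus``) or ``D >= D_B``.
    """
    volume = FocalVolume(L=L, H=H)
    scheme = ReactionScheme(k_plus=k_plus, k_minus=k_minus, C_A=C_A, C_B=C_B, C_C=C_C)
    diffusion = DiffusionSet(D=D, D_B=D_B, L=L)
    brightness = Brightness(Q_B=Q_B, Q_C=Q_C)
    return ModelParams(volume=volume, scheme=scheme, diffusion=diffusion, brightness=brightness)


def dimensionless_view(params: ModelParams) -> tuple[float, float, float, float]:
    """Return the independent dimensionless parameters.

    Returns ``(tau_ratio, beta, v, R_tau_B)`` where ``tau_ratio = tau_B/tau_D``,
    ``beta = k23/R``, ``v = t_f/tau_B + t_b/tau_D`` and ``R_tau_B = R * tau_B``.
    Exact inverse of the derivation performed by :func:`from_dimensionless`.
    """
    s, d = params.scheme, params.diffusion
    return (d.tau_ratio, s.beta, params.v, s.R * d.tau_B)


def from_dimensionless(
    tau_ratio: float,
    beta: float,
    v: float,
    omega: float = 5.0,
    tau_B: float = 20e-6,
    L: float = 0.2,
    N_B: float = 1.0,
    N_A: float = 50.0,
    Q_B: float = 1.0,
    Q_C: float = 1.0,
) -> ModelParams:
    """Construct a physical :class:`ModelParams` realizing a dimensionless point.

    ``(tau_ratio, beta, v)`` are the three independent dimensionless model
    parameters; the remaining arguments anchor the physical scales (by default
    a small organic dye: ``tau_B`` = 20 us through a ``L`` = 0.2 um focal spot)
    and the amplitudes.  ``tau_ratio = 0`` selects immobile binding sites.

    The relaxation rate follows from ``v``::

        R = (1/v) * (1/(beta*tau_B) + tau_ratio/((1-beta)*tau_B))

    and the microscopic rates/concentrations are chosen consistently with
    detailed balance.  When the requested ``N_B`` is too large for the bound
    fraction ``beta`` (which requires ``k_plus C_B < k32``), the free-dye
    number is reduced to ``0.2 N_A (1-beta)/beta``; this changes only the
    correlation amplitude, never the dimensionless point.
    """
    if not 0.0 < beta < 1.0:
        raise ParameterError(f"beta must be in (0, 1), got {beta}")
    if not 0.0 <= tau_ratio < 1.0:
        raise ParameterError(f"tau_B/tau_D must be in [0, 1), got {tau_ratio}")
    if v <= 0 or tau_B <= 0:
        raise ParameterError("v and tau_B must be positive")

    D_B = L ** 2 / (4.0 * tau_B)
    D = tau_ratio * D_B
    H = omega * L
    V = math.pi ** 1.5 * L ** 2 * H

    R = (1.0 / (beta * tau_B) + tau_ratio / ((1.0 - beta) * tau_B)) / v
    k23 = beta * R
    k32 = (1.0 - beta) * R

    N_B = min(N_B, 0.2 * N_A * (1.0 - beta) / beta)
    C_A = N_A / V
    C_B = N_B / V
    k_plus = k23 / C_A                       # k23 = k_plus C_A
    k_A = k_plus * C_B                       # < k32 by the N_B cap above
    k_minus = k32 - k_A
    C_C = k_plus * C_A * C_B / k_minus       # detailed balance
    return build_params(
        k_plus=k_plus, k_minus=k_minus, C_A=C_A, C_B=C_B, C_C=C_C,
        D=D, D_B=D_B, L=L, H=H, Q_B=Q_B, Q_C=Q_C,
    )
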