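"""Correlogram I/O, synthetic-curve generation and least-squares fitting.

The experimental unit is a :class:`CorrelationCurve`: strictly increasing
lag times (s), correlation values, and optional per-point standard errors.
Files are plain delimited text with columns ``lag_s  G  [sigma]`` and
``#``-prefixed comment lines.

Fitting works in the reduced coordinates that fully determine G(t):

    tau_B, tau_D, beta, R (or k23, k32), N1, N2, q = Q_C/Q_B, omega

Positive parameters are fitted in log space and ``beta`` through its logit,
so positivity and 0 < beta < 1 hold without constrained solvers; when both
rates are free the internal coordinates are (log R, logit beta), which are
near-orthogonal for FCS curves.  A seeded multi-start (log-perturbed
initials) guards against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares

from .engine import full_acf
from .params import ModelParams, ParameterError

__all__ = [
    "CorrelationCurve",
    "FitResult",
    "read_curve",
    "write_curve",
    "synthesize_curve",
    "fit_acf",
    "REDUCED_NAMES",
]

#: Parameter names understood by the fitting layer.  (k23, k32) and
#: (beta, R) are interchangeable descriptions of the reaction.
REDUCED_NAMES = ("tau_B", "tau_D", "beta", "R", "k23", "k32", "N1", "N2", "q", "omega")


@dataclass(frozen=True)
class CorrelationCurve:
    """Measured or synthetic FCS correlogram."""

    lag: NDArray[np.float64]
    g: NDArray[np.float64]
    sigma: NDArray[np.float64] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lag", lag)
        object.__setattr__(self, "g", g)
        if lag.ndim != 1 or lag.size == 0:
            raise ValueError("curve must contain at least one point")
        if lag.shape != g.shape:
            raise ValueError("lag and g must have equal length")
        if np.any(lag <= 0):
            raise ValueError("lag times must be positive")
        if np.any(np.diff(lag) <= 0):
            i = int(np.flatnonzero(np.diff(lag) <= 0)[0])
            raise ValueError(f"lag times must be strictly increasing (violated at row {i + 1})")
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sig)
            if sig.shape != lag.shape:
                raise ValueError("sigma must have the same length as lag")
            if np.any(sig <= 0):
                raise ValueError("sigma values must be positive")

    def __len__(self) -> int:
        return int(self.lag.size)


def read_curve(path) -> CorrelationCurve:
    """Read a correlogram from delimited text (columns lag_s, G[, sigma]).

    Comment lines start with '#'.  Malformed rows are rejected with their
    1-based line number in the file.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.replace(",", " ").split()))
    if not rows:
        raise ValueError(f"{path}: no data rows found (header/comments only?)")
    first_len = len(rows[0][1])
    if first_len not in (2, 3):
        raise ValueError(f"{path}: line {rows[0][0]}: expected 2 or 3 columns, got {first_len}")
    # a non-numeric first row is treated as a header
    def _numeric(tokens: list[str]) -> bool:
        try:
            [float(t) for t in tokens]
            return True
        except ValueError:
            return False

    if not _numeric(rows[0][1]):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no data rows found below the header")
    data = []
    for lineno, tokens in rows:
        if len(tokens) != first_len:
            raise ValueError(f"{path}: line {lineno}: expected {first_len} columns, got {len(tokens)}")
        try:
            data.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    arr = np.asarray(data)
    lag, g = arr[:, 0], arr[:, 1]
    dup = np.flatnonzero(np.diff(lag) <= 0)
    if dup.size:
        raise ValueError(
            f"{path}: line {rows[int(dup[0]) + 1][0]}: lag not strictly increasing"
        )
    sigma = arr[:, 2] if first_len == 3 else None
    return CorrelationCurve(lag=lag, g=g, sigma=sigma, meta={"path": str(path)})


def write_curve(curve: CorrelationCurve, path) -> None:
    """Write a correlogram as delimited text; exact (repr-precision) round-trip."""
    with open(path, "wt", encoding="utf-8") as fh:
        for key, val in curve.meta.items():
            fh.write(f"# {key}: {val}\n")
        cols = "lag_s G" + (" sigma" if curve.sigma is not None else "")
        fh.write(f"# columns: {cols}\n")
        for i in range(len(curve)):
            row = f"{curve.lag[i]:.17g} {curve.g[i]:.17g}"
            if curve.sigma is not None:
                row += f" {curve.sigma[i]:.17g}"
            fh.write(row + "\n")


def synthesize_curve(
    params: ModelParams,
    method: str = "exact",
    noise_model: str | tuple[str, float] = "none",
    seed: int = 0,
    t_min: float = 1e-3,
    t_max: float = 1e4,
    n: int = 128,
) -> CorrelationCurve:
    """Generate a synthetic correlogram from the engine on a log-spaced grid.

    ``noise_model`` is ``"none"``, ``("proportional", c)`` (zero-mean Gaussian
    with sd ``c * G``) or ``("additive", s)`` (constant sd ``s``).  The seed
    fully determines the output.  ``t_min``/``t_max`` are in units of tau_B.
    """
    tau_B = params.diffusion.tau_B
    lag = tau_B * np.logspace(np.log10(t_min), np.log10(t_max), n)
    g = full_acf(lag, params, method=method)
    sigma = None
    if noise_model != "none":
        kind, level = noise_model
        rng = np.random.default_rng(seed)
        if kind == "proportional":
            sigma = level * np.abs(g)
        elif kind == "additive":
            sigma = np.full_like(g, float(level))
        else:
            raise ValueError(f"unknown noise model {kind!r}")
        g = g + rng.normal(0.0, 1.0, size=g.shape) * sigma
    return CorrelationCurve(
        lag=lag, g=g, sigma=sigma,
        meta={"method": method, "seed": seed, "noise": str(noise_model)},
    )


# ----------------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Point estimates, asymptotic errors and diagnostics of one fit."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    fixed: dict[str, float]
    chi2_red: float
    converged: bool
    method: str
    nfev: int
    n_restarts: int
    nonidentifiable: tuple[str, ...] = ()

    @property
    def k23(self) -> float:
        return self._rate("k23")

    @property
    def k32(self) -> float:
        return self._rate("k32")

    def _rate(self, name: str) -> float:
        vals = {**self.fixed, **self.estimates}
        if name in vals:
            return vals[name]
        beta, R = vals["beta"], vals["R"]
        return beta * R if name == "k23" else (1.0 - beta) * R


def _canonical(values: Mapping[str, float]) -> dict[str, float]:
    """Normalize (k23, k32) <-> (beta, R) to the canonical (beta, R) form."""
    vals = dict(values)
    if "k23" in vals or "k32" in vals:
        if not ("k23" in vals and "k32" in vals):
            raise ValueError("provide both k23 and k32 (or beta and R)")
        if "beta" in vals or "R" in vals:
            raise ValueError("give either (k23, k32) or (beta, R), not both")
        k23, k32 = vals.pop("k23"), vals.pop("k32")
        vals["R"] = k23 + k32
        vals["beta"] = k23 / (k23 + k32)
    return vals


_POSITIVE = ("tau_B", "tau_D", "R", "N1", "N2", "q", "omega")


def _to_internal(name: str, value: float) -> float:
    if name == "beta":
        return math.log(value / (1.0 - value))
    return math.log(value)


def _from_internal(name: str, u: float) -> float:
    if name == "beta":
        return 1.0 / (1.0 + math.exp(-u))
    return math.exp(u)


def _reduced_namespace(vals: Mapping[str, float]) -> SimpleNamespace:
    beta = vals["beta"]
    if not 0.0 < beta < 1.0:
        raise ParameterError(f"beta must be in (0,1), got {beta}")
    tau_D = vals["tau_D"]
    tau_ratio = 0.0 if math.isinf(tau_D) else vals["tau_B"] / tau_D
    q = vals["q"]
    return SimpleNamespace(
        tau_B=vals["tau_B"], tau_ratio=tau_ratio, beta=beta, R=vals["R"],
        omega=vals["omega"], N1=vals["N1"], N2=vals["N2"],
        N3=beta / (1.0 - beta) * vals["N2"],
        Q1=q, Q2=1.0, Q3=q,
    )


def fit_acf(
    curve: CorrelationCurve,
    model_method: str = "moment_expansion",
    initial: Mapping[str, float] | None = None,
    fixed: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Weighted nonlinear least squares of an engine model to a correlogram.

    ``initial`` holds starting values for the free parameters, ``fixed`` the
    values held constant; together they must cover the reduced set
    {tau_B, tau_D, beta, R (or k23, k32), N1, N2, q, omega}.  Weights are
    1/sigma when the curve carries uncertainties, else uniform (documented
    approximation: FCS noise is lag-correlated, so the asymptotic errors are
    then indicative only).  ``n_restarts`` seeded log-perturbed restarts are
    run and the best converged solution returned.
    """
    if initial is None or not initial:
        raise ValueError("at least one free parameter (initial) is required")
    free0 = _canonical(initial)
    fixed_c = _canonical(fixed or {})
    rate_pair = "k23" in (initial or {})  # report back in rate coordinates?
    names = sorted(free0)
    overlap = set(names) & set(fixed_c)
    if overlap:
        raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
    missing = {"tau_B", "tau_D", "beta", "R", "N1", "N2", "q", "omega"} - set(names) - set(fixed_c)
    if missing:
        raise ValueError(f"model underspecified; missing {sorted(missing)}")

    weights = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(curve.g)

    def residuals(u: NDArray) -> NDArray:
        vals = dict(fixed_c)
        vals.update({n: _from_internal(n, ui) for n, ui in zip(names, u)})
        model = full_acf(curve.lag, _reduced_namespace(vals), method=model_method)
        return (model - curve.g) * weights

    lb = np.full(len(names), -np.inf)
    ub = np.full(len(names), np.inf)
    if bounds:
        bnd = _canonical({k: v[0] for k, v in bounds.items()})
        bnd_hi = _canonical({k: v[1] for k, v in bounds.items()})
        for i, n in enumerate(names):
            if n in bnd:
                lb[i] = _to_internal(n, bnd[n])
                ub[i] = _to_internal(n, bnd_hi[n])

    u0 = np.array([_to_internal(n, free0[n]) for n in names])
    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for k in range(max(1, n_restarts)):
        start = u0 if k == 0 else u0 + rng.normal(0.0, 0.3, size=u0.size)
        start = np.clip(start, lb, ub)
        try:
            sol = least_squares(residuals, start, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12)
        except (ValueError, ParameterError) as exc:
            diagnostics.append(f"restart {k}: {exc}")
            continue
        diagnostics.append(f"restart {k}: cost={sol.cost:.6g} success={sol.success}")
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("no restart converged:\n" + "\n".join(diagnostics))

    n_pts, n_par = len(curve), len(names)
    dof = max(n_pts - n_par, 1)
    chi2_red = 2.0 * best.cost / dof
    # covariance in internal coordinates, scaled by the residual variance
    J = best.jac
    try:
        cov_u = np.linalg.inv(J.T @ J) * chi2_red
    except np.linalg.LinAlgError:
        cov_u = np.full((n_par, n_par), np.nan)

    est_canon = {n: _from_internal(n, ui) for n, ui in zip(names, best.x)}
    # delta method to the reporting coordinates
    report_names = list(names)
    if rate_pair and "beta" in names and "R" in names:
        report_names = [n for n in names if n not in ("beta", "R")] + ["k23", "k32"]

    def to_report(u: NDArray) -> NDArray:
        vals = {n: _from_internal(n, ui) for n, ui in zip(names, u)}
        out = []
        for n in report_names:
            if n == "k23":
                out.append(vals["beta"] * vals["R"])
            elif n == "k32":
                out.append((1.0 - vals["beta"]) * vals["R"])
            else:
                out.append(vals[n])
        return np.asarray(out)

    rep = to_report(best.x)
    D = np.empty((len(report_names), n_par))
    h = 1e-6
    for j in range(n_par):
        up = best.x.copy()
        up[j] += h
        dn = best.x.copy()
        dn[j] -= h
        D[:, j] = (to_report(up) - to_report(dn)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", D, cov_u, D)
    stderr = {n: float(np.sqrt(v)) if v >= 0 else math.nan
              for n, v in zip(report_names, var)}
    estimates = {n: float(v) for n, v in zip(report_names, rep)}
    nonid = tuple(n for n in report_names
                  if not math.isfinite(stderr[n]) or stderr[n] > abs(estimates[n]))
    return FitResult(
        estimates=estimates, stderr=stderr, fixed=dict(fixed_c),
        chi2_red=float(chi2_red), converged=True, method=model_method,
        nfev=int(best.nfev), n_restarts=max(1, n_restarts),
        nonidentifiable=nonid,
    )
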