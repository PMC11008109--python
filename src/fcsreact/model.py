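"""Model/Results interface for fitting correlograms.

:class:`FcsReactionModel` wraps a :class:`~fcsreact.fitio.CorrelationCurve`
together with the engine route and the parameters held fixed; ``fit()``
returns an :class:`FcsReactionResults` carrying estimates, asymptotic
standard errors, diagnostics and a ``summary()`` table.

Example
-------
>>> from fcsreact.params import from_dimensionless
>>> from fcsreact.fitio import synthesize_curve
>>> from fcsreact.model import FcsReactionModel
>>> truth = from_dimensionless(1/6, 0.5, 1.0)
>>> curve = synthesize_curve(truth, noise_model=("proportional", 0.01), seed=1, n=256)
>>> model = FcsReactionModel(curve, fixed=dict(
...     tau_B=2e-5, tau_D=1.2e-4, N1=..., N2=..., q=1.0, omega=5.0))
>>> res = model.fit(start=dict(k23=5e4, k32=5e4))
>>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .engine import full_acf
from .fitio import CorrelationCurve, FitResult, _reduced_namespace, fit_acf

__all__ = ["FcsReactionModel", "FcsReactionResults"]


class FcsReactionModel:
    """Reaction-diffusion FCS model bound to one measured correlogram."""

    def __init__(
        self,
        curve: CorrelationCurve,
        method: str = "moment_expansion",
        fixed: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ):
        self.curve = curve
        self.method = method
        self.fixed = dict(fixed or {})
        self.bounds = dict(bounds or {})

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, lag_col: str = "lag_s", g_col: str = "G",
        sigma_col: str | None = None, **kwargs
    ) -> "FcsReactionModel":
        sigma = df[sigma_col].to_numpy() if sigma_col else None
        curve = CorrelationCurve(df[lag_col].to_numpy(), df[g_col].to_numpy(), sigma)
        return cls(curve, **kwargs)

    def fit(
        self,
        start: Mapping[str, float],
        n_restarts: int = 8,
        seed: int = 0,
    ) -> "FcsReactionResults":
        res = fit_acf(
            self.curve, model_method=self.method, initial=start,
            fixed=self.fixed, bounds=self.bounds,
            n_restarts=n_restarts, seed=seed,
        )
        return FcsReactionResults(self, res)


class FcsReactionResults:
    """Fit results with statsmodels-flavoured accessors."""

    def __init__(self, model: FcsReactionModel, raw: FitResult):
        self.model = model
        self.raw = raw

    @property
    def params(self) -> dict[str, float]:
        return dict(self.raw.estimates)

    @property
    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors of the estimates."""
        return dict(self.raw.stderr)

    @property
    def chi2_red(self) -> float:
        return self.raw.chi2_red

    @property
    def converged(self) -> bool:
        return self.raw.converged

    def predict(self, lag: NDArray | None = None) -> NDArray:
        """Model curve at the fitted point (on the data lags by default)."""
        lag = self.model.curve.lag if lag is None else np.asarray(lag, dtype=float)
        vals = {**self.raw.fixed}
        est = dict(self.raw.estimates)
        if "k23" in est:
            k23, k32 = est.pop("k23"), est.pop("k32")
            est["R"] = k23 + k32
            est["beta"] = k23 / (k23 + k32)
        vals.update(est)
        return full_acf(lag, _reduced_namespace(vals), method=self.raw.method)

    def resid(self) -> NDArray:
        return self.model.curve.g - self.predict()

    def summary(self) -> str:
        r = self.raw
        lines = [
            "FCS reaction-diffusion fit",
            "=" * 58,
            f"engine method:    {r.method}",
            f"n points:         {len(self.model.curve)}",
            f"restarts:         {r.n_restarts}",
            f"reduced chi^2:    {r.chi2_red:.4g}",
            f"converged:        {r.converged}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>16}{'std err':>16}",
        ]
        for name, val in r.estimates.items():
            flag = "  (non-identifiable)" if name in r.nonidentifiable else ""
            lines.append(f"{name:<12}{val:>16.6g}{r.stderr[name]:>16.3g}{flag}")
        if r.fixed:
            lines.append("-" * 58)
            for name, val in sorted(r.fixed.items()):
                lines.append(f"{name:<12}{val:>16.6g}{'(fixed)':>16}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FcsReactionResults chi2_red={self.chi2_red:.3g} params={self.params}>"
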