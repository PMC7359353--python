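"""Fraction-bound transformation and single-site saturation-binding fits.

A pull-down depletion assay reports prey binding as the percent loss of
prey fluorescence from the supernatant when immobilised bait is present:

    y = 100 * (y_o - y_c) / y_o                                  (fraction bound, %)

where ``y_o`` and ``y_c`` are the supernatant signals without and with
bait.  Fraction bound as a function of bait concentration x follows the
single-site saturation hyperbola

    y(x) = B_max * x / (K_d + x)

with ``B_max`` the maximal amplitude (%) and ``K_d`` the equilibrium
dissociation constant (same units as x; here nM).  Note the half-
saturation identity y(K_d) = B_max / 2.

The fit is exposed statsmodels-style: build a
:class:`SaturationBindingModel` from (x, y) data, call :meth:`fit`, and
read estimates, standard errors and a ``summary()`` table off the
:class:`SaturationFit` result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "BindingDataset",
    "fraction_bound",
    "saturation_model",
    "SaturationBindingModel",
    "SaturationFit",
    "fit_saturation_binding",
]

log = logging.getLogger(__name__)


def fraction_bound(y_o, y_c):
    """Percent depletion of prey signal from the supernatant.

    Accepts scalars or arrays.  Negative values (supernatant signal
    *increased* with bait) are returned but logged as suspicious.
    """
    y_o = np.asarray(y_o, dtype=float)
    y_c = np.asarray(y_c, dtype=float)
    if np.any(y_o <= 0):
        raise ValueError("baseline supernatant signal y_o must be > 0")
    y = 100.0 * (y_o - y_c) / y_o
    if np.any(np.asarray(y) < 0):
        log.warning("negative fraction bound: y_c exceeds y_o")
    if y.ndim == 0:
        return float(y)
    return y


def saturation_model(x, b_max, k_d):
    """Single-site hyperbola y = B_max * x / (K_d + x)."""
    x = np.asarray(x, dtype=float)
    return b_max * x / (k_d + x)


@dataclass
class BindingDataset:
    """Concentration series of a depletion pull-down.

    ``y_o`` is the bait-free supernatant signal; ``y_c`` the signal at
    each bait concentration ``x`` (nM).  ``fraction_bound()`` derives
    the fit input.  Rows with y_c > y_o are flagged, not dropped.
    """

    x: np.ndarray
    y_o: float
    y_c: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_c = np.asarray(self.y_c, dtype=float)
        if np.any(self.x < 0) or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be non-negative and strictly increasing")
        if self.y_o <= 0:
            raise ValueError("y_o must be > 0")
        if len(self.x) != len(self.y_c):
            raise ValueError("x and y_c length mismatch")

    def fraction_bound(self) -> np.ndarray:
        return fraction_bound(self.y_o, self.y_c)


@dataclass
class SaturationFit:
    """Result of a saturation-binding least-squares fit."""

    k_d: float
    b_max: float
    k_d_se: float
    b_max_se: float
    rss: float
    converged: bool
    n_obs: int
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.b_max, self.k_d])

    def predict(self, x) -> np.ndarray:
        return saturation_model(x, self.b_max, self.k_d)

    def summary(self) -> str:
        lines = [
            "Saturation binding fit: y = Bmax*x/(Kd + x)",
            f"  n observations : {self.n_obs}",
            f"  converged      : {self.converged}",
            f"  Kd   = {self.k_d:10.4g} +/- {self.k_d_se:.3g}",
            f"  Bmax = {self.b_max:10.4g} +/- {self.b_max_se:.3g}",
            f"  RSS  = {self.rss:.4g}",
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


class SaturationBindingModel:
    """Nonlinear least squares for the single-site binding hyperbola."""

    def __init__(self, x: Sequence[float], y: Sequence[float]) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(np.unique(self.x)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if len(self.x) != len(self.y):
            raise ValueError("x and y length mismatch")

    @classmethod
    def from_dataset(cls, data: BindingDataset) -> "SaturationBindingModel":
        return cls(data.x, data.fraction_bound())

    def _start(self) -> tuple[float, float]:
        b0 = float(self.y.max())
        if b0 <= 0:
            b0 = 1.0
        half = b0 / 2.0
        idx = int(np.argmin(np.abs(self.y - half)))
        k0 = float(self.x[idx]) if self.x[idx] > 0 else float(
            np.median(self.x[self.x > 0])
        )
        return b0, k0

    def fit(self, start: Optional[tuple[float, float]] = None) -> SaturationFit:
        """Run the least squares; ``start`` optionally overrides the
        automatic (B_max, K_d) initial guess."""
        b0, k0 = self._start() if start is None else start
        try:
            popt, pcov = optimize.curve_fit(
                saturation_model, self.x, self.y, p0=(b0, k0), maxfev=10000
            )
            resid = self.y - saturation_model(self.x, *popt)
            rss = float(resid @ resid)
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.diag(pcov))
            converged = bool(np.all(np.isfinite(popt)))
            message = ""
            if not np.all(np.isfinite(se)):
                message = "singular Jacobian: standard errors unavailable"
                converged = False
        except RuntimeError as exc:   # non-convergence: flagged, no raise
            popt = np.array([b0, k0])
            se = np.array([np.nan, np.nan])
            rss = float("nan")
            converged = False
            message = str(exc)
        return SaturationFit(
            k_d=float(popt[1]),
            b_max=float(popt[0]),
            k_d_se=float(se[1]),
            b_max_se=float(se[0]),
            rss=rss,
            converged=converged,
            n_obs=len(self.x),
            message=message,
        )


def fit_saturation_binding(x, y=None, *, start=None) -> SaturationFit:
    """Fit (K_d, B_max) to fraction-bound data.

    Accepts either a :class:`BindingDataset` or ``(x, y)`` arrays of
    concentrations and fraction bound (%); ``start`` optionally
    overrides the automatic (B_max, K_d) initial guess.
    """
    if isinstance(x, BindingDataset):
        model = SaturationBindingModel.from_dataset(x)
    else:
        model = SaturationBindingModel(x, y)
    return model.fit(start=start)
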