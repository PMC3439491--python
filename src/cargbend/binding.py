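"""Saturation binding (BMAX/KD) and ligase-mediated circularization kinetics.

One-site saturation binding follows the hyperbolic isotherm

    bound(x) = BMAX * x / (KD + x)

where ``x`` is the supplied probe amount (units as supplied — the package
does not assume a concentration scale, and KD is reported in those same
units), BMAX is the maximal bound signal and KD the probe amount at
half-saturation.

Minicircle formation in a ligase-mediated circularization assay is
summarised with first-order kinetics

    pct(t) = plateau * (1 - exp(-k * t))

where ``pct`` is the percentage of minicircles relative to the no-protein
control (taken as 100%). Comparing the fitted rate for the in-phase probe
against the out-of-phase probe quantifies the cooperative-bending ordering
(in-phase circularizes faster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._fitbase import FitResults, covariance_from_jacobian
from .exceptions import CargBendError, DegenerateFitError, InsufficientDataError


@dataclass(frozen=True)
class BindingSeries:
    """Bound signal vs probe amount, strictly increasing in probe amount."""

    points: tuple  # of (probe_amount, bound_signal)
    label: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple((float(x), float(y)) for x, y in self.points))
        xs = [x for x, _ in self.points]
        if len(self.points) < 5:
            raise InsufficientDataError(
                f"need >= 5 binding points, got {len(self.points)}"
            )
        if any(x < 0 for x in xs):
            raise CargBendError("probe amounts must be non-negative")
        if not all(b > a for a, b in zip(xs, xs[1:])):
            raise CargBendError("probe amounts must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


class SaturationResults(FitResults):
    """Fitted one-site binding isotherm: BMAX, KD."""

    model_name = "One-site saturation binding fit"

    def __init__(self, bmax, kd, cov, series, rss, saturation_warning):
        self.bmax = float(bmax)
        self.kd = float(kd)
        self.rss = float(rss)
        self.nobs = len(series.points)
        self.series = series
        self.cov = cov
        #: True when the curve is still rising steeply at the largest probe
        #: amount — KD is then poorly constrained from above
        self.saturation_warning = bool(saturation_warning)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.bse = {"bmax": se[0], "kd": se[1]}
        self._param_rows = [
            ("bmax", self.bmax, se[0]),
            ("kd", self.kd, se[1]),
        ]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bmax * x / (self.kd + x)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, self.series.x.max() * 1.05, 200)
        ax.plot(self.series.x, self.series.y, "o", label=self.series.label)
        ax.plot(grid, self.predict(grid), "-", label="one-site fit")
        ax.axvline(self.kd, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("probe amount (as supplied)")
        ax.set_ylabel("bound signal")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "bmax": self.bmax,
            "kd": self.kd,
            "rss": self.rss,
            "nobs": self.nobs,
            "saturation_warning": self.saturation_warning,
        }


class SaturationBindingModel:
    """Hyperbolic one-site model for a saturation binding series."""

    def __init__(self, series: BindingSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "other") -> "SaturationBindingModel":
        return cls(BindingSeries(points=list(zip(df["x"], df["signal"])), label=label))

    def fit(self) -> SaturationResults:
        x, y = self.series.x, self.series.y
        if np.all(y == 0):
            raise DegenerateFitError("all bound signals are zero")
        bmax0 = float(y.max())
        half = bmax0 / 2
        kd0 = float(np.interp(half, y, x)) if np.any(y >= half) else float(x[-1])
        kd0 = max(kd0, 1e-9)

        def resid(theta):
            bmax, kd = theta
            return bmax * x / (kd + x) - y

        sol = least_squares(
            resid, x0=[bmax0, kd0], bounds=([0, 1e-12], [np.inf, np.inf]), method="trf"
        )
        bmax, kd = sol.x
        rss = float(np.sum(sol.fun**2))
        cov = covariance_from_jacobian(sol.jac, rss, len(y))
        # non-saturating data: terminal slope still > 90% of the initial slope
        warn = False
        if len(x) >= 3 and x[1] > x[0] and x[-1] > x[-2]:
            s0 = (y[1] - y[0]) / (x[1] - x[0])
            s1 = (y[-1] - y[-2]) / (x[-1] - x[-2])
            warn = s0 > 0 and s1 > 0.9 * s0
        return SaturationResults(bmax, kd, cov, self.series, rss, warn)


def fit_saturation(series: BindingSeries) -> SaturationResults:
    """Convenience wrapper around :class:`SaturationBindingModel`."""
    return SaturationBindingModel(series).fit()


@dataclass(frozen=True)
class CircularizationSeries:
    """Minicircle percentage vs ligation time (minutes)."""

    points: tuple  # of (time_min, minicircle_pct)
    phase_label: str = "in_phase"
    protein_present: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple((float(t), float(p)) for t, p in self.points))
        ts = [t for t, _ in self.points]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise CargBendError("time points must be non-decreasing")
        if any(p < 0 for _, p in self.points):
            raise CargBendError("minicircle percentage cannot be negative")

    @property
    def t(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def pct(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


class CircularizationResults(FitResults):
    """Fitted first-order circularization kinetics: rate and plateau."""

    model_name = "First-order circularization fit"

    def __init__(self, rate_k, plateau_pct, cov, series, rss, monotone_warning):
        self.rate_k = float(rate_k)
        self.plateau_pct = float(plateau_pct)
        self.rss = float(rss)
        self.nobs = len(series.points)
        self.series = series
        self.cov = cov
        #: True when the observed percentages decrease over time, which the
        #: first-order model cannot represent
        self.monotone_warning = bool(monotone_warning)
        se = (
            np.sqrt(np.clip(np.diag(cov), 0, None))
            if cov is not None
            else (None, None)
        )
        self._param_rows = [
            ("rate_k [1/min]", self.rate_k, se[1] if cov is not None else None),
            ("plateau [%]", self.plateau_pct, se[0] if cov is not None else None),
        ]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau_pct * (1 - np.exp(-self.rate_k * t))

    def to_dict(self) -> dict:
        return {
            "rate_k": self.rate_k,
            "plateau_pct": self.plateau_pct,
            "rss": self.rss,
            "nobs": self.nobs,
            "monotone_warning": self.monotone_warning,
        }


class CircularizationModel:
    """First-order kinetic model for a minicircle time course."""

    def __init__(self, series: CircularizationSeries):
        if len(series.points) < 4:
            raise InsufficientDataError(
                f"need >= 4 time points, got {len(series.points)}"
            )
        if 0.0 not in set(series.t.tolist()):
            raise InsufficientDataError("time course must include t = 0")
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CircularizationModel":
        return cls(
            CircularizationSeries(points=list(zip(df["time"], df["pct"])), **kwargs)
        )

    def fit(self) -> CircularizationResults:
        t, pct = self.series.t, self.series.pct
        if np.ptp(pct) == 0:
            # degenerate flat series: by contract rate 0 and plateau at the
            # observed level
            return CircularizationResults(
                0.0, float(pct[0]), None, self.series, 0.0, False
            )
        plateau0 = float(pct.max())
        # crude rate guess from the earliest nonzero rise
        rising = np.nonzero((t > 0) & (pct > 0) & (pct < plateau0))[0]
        if rising.size:
            i = rising[0]
            frac = min(pct[i] / plateau0, 0.999)
            k0 = -math.log(1 - frac) / t[i]
        else:
            k0 = 1.0 / max(t.max(), 1.0)

        def resid(theta):
            plateau, k = theta
            return plateau * (1 - np.exp(-k * t)) - pct

        sol = least_squares(
            resid, x0=[plateau0, max(k0, 1e-6)], bounds=([0, 0], [np.inf, np.inf]),
            method="trf",
        )
        plateau, k = sol.x
        rss = float(np.sum(sol.fun**2))
        cov = covariance_from_jacobian(sol.jac, rss, len(pct))
        monotone_warning = bool(np.any(np.diff(pct) < 0))
        return CircularizationResults(k, plateau, cov, self.series, rss, monotone_warning)


def fit_circularization(series: CircularizationSeries) -> CircularizationResults:
    """Convenience wrapper around :class:`CircularizationModel`."""
    return CircularizationModel(series).fit()


def normalize_to_control(signal, control_signal) -> np.ndarray:
    """Express minicircle signal as percent of the no-protein control."""
    control = np.asarray(control_signal, dtype=float)
    if np.any(control <= 0):
        raise CargBendError("control signal must be positive")
    return 100.0 * np.asarray(signal, dtype=float) / control


@dataclass(frozen=True)
class PhaseRateComparison:
    """Ratio of in-phase to out-of-phase circularization rates."""

    ratio: float
    verdict: str
    infinite: bool = False


def compare_phase_rates(
    in_fit: CircularizationResults, out_fit: CircularizationResults
) -> PhaseRateComparison:
    """Compare fitted circularization rates for in- vs out-of-phase probes."""
    if out_fit.rate_k == 0:
        return PhaseRateComparison(
            ratio=float("inf"),
            verdict="in>out" if in_fit.rate_k > 0 else "equal",
            infinite=True,
        )
    ratio = in_fit.rate_k / out_fit.rate_k
    if ratio > 1:
        verdict = "in>out"
    elif ratio < 1:
        verdict = "out>in"
    else:
        verdict = "equal"
    return PhaseRateComparison(ratio=ratio, verdict=verdict)
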