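"""Phasing analysis: helical modulation of complex mobility.

In a phasing assay an intrinsic A-tract bend and the protein-induced bend
are separated by linkers of varying length, rotating the two bend centres
around the DNA helix. When the bends point the same way (in phase) they
add, giving the slowest complex; half a helical turn later they oppose and
partially cancel (out of phase), giving the fastest complex. The relative
mobility therefore oscillates with the spacing at the DNA helical repeat
(10.5 bp/turn for B-DNA):

    r(s) = baseline - amplitude * cos(2*pi*(s - s0) / repeat)

with the mobility minimum at the in-phase spacing ``s0``.

The assay geometry couples linker length to bend-centre spacing by a fixed
offset: linkers of 12-20 bp give spacings of 51-59 bp, so spacing =
linker + 39.

For a fixed repeat the model is linear in (baseline, cos, sin) components,
so the fit is a direct linear solve; a free repeat is profiled over a
deterministic grid on [9, 12] bp/turn and refined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._fitbase import FitResults, covariance_from_jacobian
from .exceptions import (
    CargBendError,
    IndeterminatePhaseError,
    InsufficientDataError,
    UnidentifiableError,
)

#: bp from linker length to bend-centre spacing, fixed by the construct
#: geometry (12 bp linker -> 51 bp spacing, 20 bp -> 59 bp).
LINKER_TO_SPACING_OFFSET = 39

#: B-DNA helical repeat, bp per turn.
DEFAULT_HELICAL_REPEAT = 10.5


def spacing_from_linker(linker: float) -> float:
    """Bend-centre spacing (bp) for a given linker length (bp)."""
    if linker < 0:
        raise CargBendError("linker length must be non-negative")
    return linker + LINKER_TO_SPACING_OFFSET


def helical_turns(spacing: float, repeat: float = DEFAULT_HELICAL_REPEAT) -> float:
    """Number of helical turns spanned by a spacing, rounded to 1 decimal."""
    if repeat <= 0:
        raise CargBendError("helical repeat must be positive")
    if spacing < 0:
        raise CargBendError("spacing must be non-negative")
    return round(spacing / repeat, 1)


@dataclass(frozen=True)
class PhasingLane:
    """One phasing-probe lane: linker/spacing plus migrations."""

    linker: float
    spacing: float
    free_migration: float
    complex_migration: float

    def __post_init__(self) -> None:
        if self.free_migration <= 0 or self.complex_migration <= 0:
            raise CargBendError("migration distances must be positive")


@dataclass(frozen=True)
class PhasingSeries:
    lanes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        offs = {round(ln.spacing - ln.linker, 6) for ln in self.lanes}
        if len(offs) > 1:
            raise CargBendError(
                "spacing - linker offset must be constant across the series"
            )


class PhasingResults(FitResults):
    """Fitted phasing sinusoid: amplitude, in-phase spacing, turn count."""

    model_name = "Phasing sinusoid fit"

    _AMPLITUDE_TOL = 1e-12

    def __init__(self, baseline, amplitude, s0, repeat, cov, series, rss):
        self.baseline = float(baseline)
        self.amplitude = float(amplitude)
        self.helical_repeat = float(repeat)
        self.series = series
        self.rss = float(rss)
        self.nobs = len(series.lanes)
        self.cov = cov
        self.phase_indeterminate = self.amplitude <= self._AMPLITUDE_TOL
        spacings = [ln.spacing for ln in series.lanes]
        if self.phase_indeterminate:
            self.in_phase_spacing = float("nan")
        else:
            self.in_phase_spacing = self._wrap_into_window(
                float(s0), min(spacings), max(spacings)
            )
        self.turns_at_min = (
            round(self.in_phase_spacing / self.helical_repeat, 1)
            if not self.phase_indeterminate
            else float("nan")
        )
        se = np.sqrt(np.clip(np.diag(cov), 0, None)) if cov is not None else [None] * 3
        self._param_rows = [
            ("baseline", self.baseline, se[0]),
            ("amplitude", self.amplitude, se[1]),
            ("in_phase_spacing [bp]", self.in_phase_spacing, se[2]),
            ("helical_repeat [bp]", self.helical_repeat, None),
            ("turns_at_min", self.turns_at_min, None),
        ]

    def _wrap_into_window(self, s0: float, lo: float, hi: float) -> float:
        """Shift s0 by whole repeats into the sampled spacing window."""
        T = self.helical_repeat
        mid = 0.5 * (lo + hi)
        k = round((mid - s0) / T)
        return s0 + k * T

    def predict(self, spacings) -> np.ndarray:
        s = np.asarray(spacings, dtype=float)
        if self.phase_indeterminate:
            return np.full_like(s, self.baseline)
        return self.baseline - self.amplitude * np.cos(
            2 * np.pi * (s - self.in_phase_spacing) / self.helical_repeat
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = np.array([ln.spacing for ln in self.series.lanes])
        r = np.array([ln.complex_migration / ln.free_migration for ln in self.series.lanes])
        grid = np.linspace(s.min() - 2, s.max() + 2, 200)
        ax.plot(s, r, "o", label="lanes")
        ax.plot(grid, self.predict(grid), "-", label="sinusoid fit")
        ax.set_xlabel("bend-centre spacing [bp]")
        ax.set_ylabel("relative mobility")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "in_phase_spacing": self.in_phase_spacing,
            "helical_repeat": self.helical_repeat,
            "turns_at_min": self.turns_at_min,
            "phase_indeterminate": self.phase_indeterminate,
            "rss": self.rss,
            "nobs": self.nobs,
        }


class PhasingModel:
    """Sinusoidal mobility model for a phasing series."""

    def __init__(self, series: PhasingSeries):
        if len(series.lanes) < 5:
            raise InsufficientDataError(
                f"need >= 5 phasing lanes, got {len(series.lanes)}"
            )
        self.series = series
        self.spacings = np.array([ln.spacing for ln in series.lanes], dtype=float)
        self.mobility = np.array(
            [ln.complex_migration / ln.free_migration for ln in series.lanes],
            dtype=float,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhasingModel":
        """Build from a table with linker, free_migration, complex_migration
        (and optionally an explicit spacing column)."""
        lanes = []
        for row in df.itertuples():
            linker = float(row.linker)
            spacing = float(getattr(row, "spacing", spacing_from_linker(linker)))
            lanes.append(
                PhasingLane(
                    linker=linker,
                    spacing=spacing,
                    free_migration=float(row.free_migration),
                    complex_migration=float(row.complex_migration),
                )
            )
        return cls(PhasingSeries(lanes=lanes))

    def _linear_solve(self, repeat: float):
        """For a fixed repeat the sinusoid is linear in (c, u, v)."""
        w = 2 * np.pi / repeat
        X = np.column_stack(
            [np.ones_like(self.spacings), np.cos(w * self.spacings), np.sin(w * self.spacings)]
        )
        coef, *_ = np.linalg.lstsq(X, self.mobility, rcond=None)
        rss = float(np.sum((X @ coef - self.mobility) ** 2))
        return coef, rss

    @staticmethod
    def _to_phase(coef, repeat: float):
        """Convert (c, u, v) to (baseline, amplitude>=0, s0 at the minimum)."""
        c, u, v = coef
        amplitude = math.hypot(u, v)
        if amplitude == 0:
            return c, 0.0, 0.0
        psi = math.atan2(v, u)  # r = c + A*cos(w*s - psi); min at w*s - psi = pi
        s0 = (psi + math.pi) * repeat / (2 * math.pi)
        return c, amplitude, s0

    def fit(
        self,
        repeat: float | None = DEFAULT_HELICAL_REPEAT,
        repeat_bounds: tuple = (9.0, 12.0),
    ) -> PhasingResults:
        """Fit the sinusoid; ``repeat=None`` profiles a free helical repeat."""
        span = float(self.spacings.max() - self.spacings.min())
        if repeat is None:
            if span < repeat_bounds[1] / 2:
                raise UnidentifiableError(
                    f"spacing span {span} bp cannot constrain a free helical repeat"
                )
            grid = np.linspace(repeat_bounds[0], repeat_bounds[1], 61)
            best = min(grid, key=lambda T: self._linear_solve(T)[1])
            coef, _ = self._linear_solve(best)
            c0, A0, s00 = self._to_phase(coef, best)

            def resid(theta):
                c, A, s0, T = theta
                return c - A * np.cos(2 * np.pi * (self.spacings - s0) / T) - self.mobility

            sol = least_squares(
                resid,
                x0=[c0, A0, s00, best],
                bounds=(
                    [-np.inf, 0.0, -np.inf, repeat_bounds[0]],
                    [np.inf, np.inf, np.inf, repeat_bounds[1]],
                ),
                method="trf",
            )
            c, A, s0, T = sol.x
            rss = float(np.sum(sol.fun**2))
            cov = covariance_from_jacobian(sol.jac[:, :3], rss, len(self.mobility))
            return PhasingResults(c, A, s0, T, cov, self.series, rss)

        if repeat <= 0:
            raise CargBendError("helical repeat must be positive")
        coef, rss = self._linear_solve(repeat)
        c, A, s0 = self._to_phase(coef, repeat)
        # covariance in the (c, A, s0) parameterisation via the jacobian
        w = 2 * np.pi / repeat
        J = np.column_stack(
            [
                np.ones_like(self.spacings),
                -np.cos(w * (self.spacings - s0)),
                -A * np.sin(w * (self.spacings - s0)) * w,
            ]
        )
        cov = covariance_from_jacobian(J, rss, len(self.mobility))
        return PhasingResults(c, A, s0, repeat, cov, self.series, rss)


def fit_phasing(
    series: PhasingSeries, repeat: float | None = DEFAULT_HELICAL_REPEAT
) -> PhasingResults:
    """Convenience wrapper around :class:`PhasingModel`."""
    return PhasingModel(series).fit(repeat=repeat)


def classify_phase(spacing: float, fit: PhasingResults, tol_turns: float = 0.125) -> str:
    """Classify a spacing as in_phase / out_of_phase / intermediate.

    The phase distance is the circular distance (in turns) between the
    spacing and the fitted in-phase spacing, modulo the helical repeat.
    Within ``tol_turns`` of an integer turn -> in_phase; within ``tol_turns``
    of a half turn -> out_of_phase; otherwise intermediate.
    """
    if fit.phase_indeterminate:
        raise IndeterminatePhaseError(
            "cannot classify phase: fitted amplitude is zero"
        )
    T = fit.helical_repeat
    frac = ((spacing - fit.in_phase_spacing) % T) / T
    d = min(frac, 1 - frac)  # circular distance in turns, in [0, 0.5]
    if d <= tol_turns:
        return "in_phase"
    if abs(d - 0.5) <= tol_turns:
        return "out_of_phase"
    return "intermediate"
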