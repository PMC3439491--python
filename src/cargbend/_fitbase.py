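"""Shared machinery for the nonlinear-least-squares Results objects."""

from __future__ import annotations

import numpy as np


def covariance_from_jacobian(jac: np.ndarray, rss: float, nobs: int) -> np.ndarray:
    """Asymptotic parameter covariance s^2 (J'J)^-1 from a least-squares fit.

    Degenerate (rank-deficient) Jacobians yield a pseudo-inverse; with zero
    residual degrees of freedom the noise variance is taken as 0.
    """
    npar = jac.shape[1]
    dof = max(nobs - npar, 0)
    s2 = rss / dof if dof > 0 else 0.0
    jtj = jac.T @ jac
    return s2 * np.linalg.pinv(jtj)


class FitResults:
    """Base class: parameter table rendering shared by all fit results."""

    #: ordered (name, value, stderr-or-None) rows; set by subclasses
    _param_rows: list
    model_name: str = "fit"
    nobs: int = 0
    rss: float = float("nan")

    def summary(self) -> str:
        """Plain-text summary table of the fitted parameters."""
        width = 58
        lines = [
            "=" * width,
            f"{self.model_name}".center(width),
            "-" * width,
            f"No. observations: {self.nobs:<10d} RSS: {self.rss:.6g}",
            "-" * width,
            f"{'parameter':<22}{'estimate':>14}{'std err':>14}",
            "-" * width,
        ]
        for name, value, se in self._param_rows:
            se_str = f"{se:>14.4g}" if se is not None and np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<22}{value:>14.5g}{se_str}")
        lines.append("=" * width)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{n}={v:.4g}" for n, v, _ in self._param_rows)
        return f"<{type(self).__name__} {pairs}>"
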