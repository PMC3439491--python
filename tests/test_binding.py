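"""Saturation binding (BMAX/KD) and circularization kinetics."""

import numpy as np
import pytest

from cargbend.binding import (
    BindingSeries,
    CircularizationModel,
    CircularizationSeries,
    compare_phase_rates,
    fit_circularization,
    fit_saturation,
    normalize_to_control,
)
from cargbend.exceptions import CargBendError, DegenerateFitError, InsufficientDataError
from cargbend.simulate import SimulationConfig, gen_binding_series, gen_circularization


def hyperbola(x, bmax, kd):
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


class TestSaturation:
    X = np.geomspace(0.5, 32.0, 8)

    def test_noiseless_round_trip(self):
        series = BindingSeries(points=list(zip(self.X, hyperbola(self.X, 1.0, 4.515))))
        fit = fit_saturation(series)
        assert fit.kd == pytest.approx(4.515, abs=1e-6)
        assert fit.bmax == pytest.approx(1.0, abs=1e-6)

    def test_half_saturation_identity(self):
        series = BindingSeries(points=list(zip(self.X, hyperbola(self.X, 2.0, 3.0))))
        fit = fit_saturation(series)
        assert fit.predict(fit.kd) == pytest.approx(fit.bmax / 2, abs=1e-9)

    def test_ninety_percent_bound_at_nine_kd(self):
        """Closed-form identity: bound reaches 90% of bmax at x = 9*kd."""
        series = BindingSeries(points=list(zip(self.X, hyperbola(self.X, 1.0, 2.0))))
        fit = fit_saturation(series)
        assert fit.predict(9 * fit.kd) == pytest.approx(0.9 * fit.bmax, abs=1e-9)

    def test_scale_equivariance(self):
        y = hyperbola(self.X, 1.0, 4.0)
        base = fit_saturation(BindingSeries(points=list(zip(self.X, y))))
        scaled = fit_saturation(BindingSeries(points=list(zip(10 * self.X, y))))
        assert scaled.kd == pytest.approx(10 * base.kd, rel=1e-6)
        assert scaled.bmax == pytest.approx(base.bmax, rel=1e-6)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_saturation(BindingSeries(points=[(x, 0.0) for x in self.X]))

    def test_non_saturating_data_warns_but_fits(self):
        x = np.linspace(0.1, 1.0, 6)  # far below kd: nearly linear response
        series = BindingSeries(points=list(zip(x, hyperbola(x, 1.0, 50.0))))
        fit = fit_saturation(series)
        assert fit.saturation_warning

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            BindingSeries(points=[(1, 0.1), (2, 0.2), (3, 0.3), (4, 0.35)])

    def test_non_increasing_x_rejected(self):
        with pytest.raises(CargBendError):
            BindingSeries(points=[(1, 0.1), (1, 0.2), (3, 0.3), (4, 0.35), (5, 0.4)])

    @pytest.mark.parametrize("kd_true", [4.515, 10.63])
    def test_noisy_kd_recovery(self, kd_true):
        kds = []
        for i in range(100):
            cfg = SimulationConfig(seed=9000 + i).with_truth(kd=kd_true)
            series, _ = gen_binding_series(cfg)
            kds.append(fit_saturation(series).kd)
        assert abs(np.mean(kds) - kd_true) / kd_true < 0.05


class TestCircularization:
    TIMES = np.arange(0, 61, 10)

    def first_order(self, t, plateau, k):
        return plateau * (1 - np.exp(-k * np.asarray(t, dtype=float)))

    def test_noiseless_round_trip(self):
        pct = self.first_order(self.TIMES, 100.0, 0.1)
        fit = fit_circularization(CircularizationSeries(points=list(zip(self.TIMES, pct))))
        assert fit.rate_k == pytest.approx(0.1, abs=1e-8)
        assert fit.plateau_pct == pytest.approx(100.0, abs=1e-6)

    def test_constant_zero_series(self):
        fit = fit_circularization(
            CircularizationSeries(points=[(t, 0.0) for t in self.TIMES])
        )
        assert (fit.rate_k, fit.plateau_pct) == (0.0, 0.0)

    def test_constant_nonzero_series(self):
        fit = fit_circularization(
            CircularizationSeries(points=[(t, 40.0) for t in self.TIMES])
        )
        assert (fit.rate_k, fit.plateau_pct) == (0.0, 40.0)

    def test_non_monotone_data_warns(self):
        pct = [0.0, 50.0, 70.0, 80.0, 60.0, 55.0, 50.0]
        fit = fit_circularization(CircularizationSeries(points=list(zip(self.TIMES, pct))))
        assert fit.monotone_warning

    def test_negative_pct_rejected(self):
        with pytest.raises(CargBendError):
            CircularizationSeries(points=[(0, 0.0), (10, -1.0), (20, 5.0), (30, 10.0)])

    def test_missing_t0_rejected(self):
        pct = self.first_order([10, 20, 30, 40], 100.0, 0.1)
        with pytest.raises(InsufficientDataError):
            CircularizationModel(CircularizationSeries(points=list(zip([10, 20, 30, 40], pct))))

    def test_protein_free_plateau_near_100(self):
        """The no-protein control is 100% by normalisation; the fit returns it."""
        cfg = SimulationConfig(seed=3, circ_sigma=1.0).with_truth(
            k_in=0.15, plateau_in=100.0
        )
        s_in, _, _ = gen_circularization(cfg)
        fit = fit_circularization(s_in)
        assert fit.plateau_pct == pytest.approx(100.0, abs=5.0)

    def test_normalize_to_control(self):
        pct = normalize_to_control([5.0, 10.0], [10.0, 10.0])
        assert pct.tolist() == [50.0, 100.0]
        with pytest.raises(CargBendError):
            normalize_to_control([1.0], [0.0])


class TestComparePhaseRates:
    def _fit(self, k, plateau=80.0):
        t = np.arange(0, 61, 10)
        pct = plateau * (1 - np.exp(-k * t))
        return fit_circularization(CircularizationSeries(points=list(zip(t, pct))))

    def test_in_faster(self):
        cmp = compare_phase_rates(self._fit(0.2), self._fit(0.1))
        assert cmp.ratio == pytest.approx(2.0, rel=1e-6)
        assert cmp.verdict == "in>out"

    def test_equal(self):
        cmp = compare_phase_rates(self._fit(0.1), self._fit(0.1))
        assert cmp.ratio == pytest.approx(1.0, rel=1e-9)
        assert cmp.verdict == "equal"

    def test_zero_out_rate_flagged_infinite(self):
        cmp = compare_phase_rates(self._fit(0.1), self._fit(0.0, plateau=0.0))
        assert cmp.infinite and np.isinf(cmp.ratio)

    def test_generator_defaults_order_in_over_out(self):
        cfg = SimulationConfig(seed=11)
        s_in, s_out, _ = gen_circularization(cfg)
        cmp = compare_phase_rates(fit_circularization(s_in), fit_circularization(s_out))
        assert cmp.verdict == "in>out"
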