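import numpy as np
import pytest

from nfdelay import (
    admissible_delay_scale,
    contraction_constant,
    delay_dependent_condition,
    delay_independent_condition,
    evaluate_bounds,
    hs_norm,
    integrability_threshold,
    linearize,
    make_ring_model,
    nondelayed_decay,
    op_norm,
    square_integrability_scan,
)
from nfdelay.bifurcation import ring_at, spectral_abscissa
from nfdelay.spectrum import StationaryState


def trivial_lin(c, sigma, n=32, coeffs=((0, -1.0), (2, 1.5))):
    m = make_ring_model(list(coeffs), c=c, sigma=sigma, n=n)
    return linearize(m, StationaryState(values=np.zeros((1, n)), residual=0.0))


SIGMA0 = 8.0 / (3.0 * np.pi)


class TestDecayEstimate:
    def test_ring_closed_form(self):
        # eps = l - sigma*s1*Jhat_max = 1 - sigma * 0.375*pi
        d = nondelayed_decay(trivial_lin(1.0, 0.5))
        assert d.eps == pytest.approx(1.0 - 0.5 * 0.375 * np.pi, abs=1e-12)
        assert d.m_eps == 1.0 and d.self_adjoint

    def test_zero_gain_gives_leak_rate(self):
        d = nondelayed_decay(trivial_lin(1.0, 1e-12))
        assert d.eps == pytest.approx(1.0, abs=1e-10)

    def test_eps_vanishes_at_pitchfork_gain(self):
        d = nondelayed_decay(trivial_lin(1.0, SIGMA0))
        assert d.eps == pytest.approx(0.0, abs=1e-12)


class TestNorms:
    def test_ring_closed_forms(self):
        lin = trivial_lin(1.0, 0.5)
        gamma = 0.5 * 0.25
        assert hs_norm(lin) == pytest.approx(gamma * np.pi * np.sqrt(8.5), rel=1e-12)
        assert op_norm(lin) == pytest.approx(gamma * 2 * np.pi, rel=1e-12)

    def test_operator_norm_below_hilbert_schmidt(self):
        for sigma in (0.2, 0.7, 1.5):
            lin = trivial_lin(1.5, sigma)
            assert op_norm(lin) <= hs_norm(lin) + 1e-12

    def test_tabulated_kernel_matches_ring_norms(self):
        lin = trivial_lin(1.0, 0.5)
        m = lin.model
        from nfdelay.model import DelaySpec, MatrixKernel, NeuralFieldModel

        tab = NeuralFieldModel(
            grid=m.grid,
            leak=m.leak,
            kernel=MatrixKernel(m.kernel.matrix(m.grid)),
            delay=DelaySpec(c=m.delay.c, matrix_values=m.delay.tau_matrix(m.grid)),
            sigmoid=m.sigmoid,
        )
        lin_tab = linearize(
            tab, StationaryState(values=np.zeros((1, m.n)), residual=0.0)
        )
        assert hs_norm(lin_tab) == pytest.approx(hs_norm(lin), rel=1e-10)
        assert op_norm(lin_tab) == pytest.approx(op_norm(lin), rel=1e-6)
        d = nondelayed_decay(lin_tab)
        assert d.eps == pytest.approx(nondelayed_decay(lin).eps, abs=1e-8)


class TestDelayIndependent:
    def test_zero_kernel_margin_is_leak(self):
        lin = trivial_lin(1.0, 1.0, coeffs=())
        ok, margin = delay_independent_condition(lin)
        assert ok and margin == pytest.approx(1.0)

    def test_threshold_gain_below_pitchfork(self):
        # sigma2 = l / (s1 ||J||_{L2}) must be below sigma0
        sigma2 = 1.0 / (0.25 * np.pi * np.sqrt(8.5))
        assert sigma2 < SIGMA0
        ok_lo, _ = delay_independent_condition(trivial_lin(2.0, 0.95 * sigma2))
        ok_hi, _ = delay_independent_condition(trivial_lin(2.0, 1.05 * sigma2))
        assert ok_lo and not ok_hi


class TestDelayDependent:
    def test_no_delay_is_certified_with_zero_constant(self):
        lin = trivial_lin(0.0, 0.5)
        ok, _, alpha = delay_dependent_condition(lin)
        assert ok and alpha == 0.0

    def test_unstable_without_delays_is_refused(self):
        lin = trivial_lin(1.0, 2 * SIGMA0)
        ok, beta, alpha = delay_dependent_condition(lin)
        assert not ok and beta is None

    def test_contraction_constant_monotone_in_c(self):
        decays = nondelayed_decay(trivial_lin(0.0, 0.5))
        ks = []
        for c in (0.25, 0.5, 1.0, 2.0):
            lin = trivial_lin(c, 0.5)
            ks.append(
                contraction_constant(0.3, decays.eps, decays.m_eps, lin.tau_max, lin)
            )
        assert np.all(np.diff(ks) > 0)

    def test_beta_outside_valid_range_rejected(self):
        lin = trivial_lin(1.0, 0.5)
        d = nondelayed_decay(lin)
        with pytest.raises(ValueError):
            contraction_constant(0.8, d.eps, d.m_eps, lin.tau_max, lin)

    def test_admissible_delay_scale_positive_whenever_eps_positive(self):
        """Small delays never destabilize a state stable without delays."""
        for sigma in np.linspace(0.05, 0.95 * SIGMA0, 8):
            lin = trivial_lin(1.0, float(sigma))
            c_bound = admissible_delay_scale(lin)
            assert c_bound > 0

    def test_certified_region_monotone_in_c(self):
        """At fixed gain, the verdict flips from True to False at one c."""
        sigma = 0.3
        verdicts = []
        for c in np.linspace(0.01, 1.0, 12):
            ok, _, _ = delay_dependent_condition(trivial_lin(float(c), sigma))
            verdicts.append(ok)
        assert verdicts[0] and not verdicts[-1]
        flips = sum(a != b for a, b in zip(verdicts, verdicts[1:]))
        assert flips == 1


class TestSufficiency:
    def test_certified_points_are_cv_stable(self):
        """Wherever either bound holds, the spectral abscissa is negative."""
        base = make_ring_model([(0, -1.0), (2, 1.5)], c=1.0, sigma=1.0, n=32)
        for c in np.linspace(0.0, 4.0, 6):
            for sigma in np.linspace(0.05, 1.2, 6):
                lin = ring_at(base, float(c), float(sigma))
                ok1, _, _ = delay_dependent_condition(lin)
                ok2, _ = delay_independent_condition(lin)
                if ok1 or ok2:
                    assert spectral_abscissa(base, float(c), float(sigma), modes=8) < 0


class TestBoundsReport:
    def test_report_is_consistent(self):
        rep = evaluate_bounds(trivial_lin(0.5, 0.3))
        assert rep.op_norm <= rep.hs_norm
        assert rep.eps > 0
        assert rep.cond1 == (rep.alpha_star < 1)
        assert rep.cond2 == (rep.margin2 > 0)


class TestPlanarIntegrability:
    def test_divergence_threshold_is_one(self):
        scan = square_integrability_scan([0.8, 0.9, 0.95, 0.99, 1.0, 1.05])
        assert all(scan[b] for b in (0.8, 0.9, 0.95))
        assert not scan[1.0] and not scan[1.05]
        assert integrability_threshold() == 1.0
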