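import numpy as np
import pytest

from nfdelay import (
    assemble_spectrum,
    build_generator_matrix,
    char_residual,
    count_roots_in_rectangle,
    find_stationary,
    fourier_cos_coefficient,
    generator_eigenvalues,
    integrate,
    linearize,
    make_ring_model,
    solve_mode_roots,
)
from nfdelay.spectrum import StationaryState


def trivial_lin(ring_factory, c, sigma, n=48):
    m = ring_factory(c=c, sigma=sigma, n=n)
    state = StationaryState(values=np.zeros((1, m.n)), residual=0.0)
    return linearize(m, state)


class TestStationary:
    def test_trivial_state_of_centered_model(self, ring_factory):
        m = ring_factory(c=1.0, sigma=0.5)
        states = find_stationary(m)
        assert any(s.norm(m.grid.weights) < 1e-12 for s in states)

    def test_zero_connectivity_unique_state(self):
        m = make_ring_model([], c=0.0, sigma=1.0, n=16)
        states = find_stationary(m)
        assert len(states) == 1
        assert np.allclose(states[0].values, 0.0)

    def test_three_states_past_pitchfork(self, ring_factory, sigma0):
        """Beyond the pitchfork gain the trivial state coexists with a
        symmetric pair of patterns, confirmed by simulation limits."""
        m = ring_factory(c=0.5, sigma=1.3 * sigma0, n=32)
        states = find_stationary(m)
        assert len(states) >= 3
        norms = sorted(s.norm(m.grid.weights) for s in states)
        assert norms[0] < 1e-10 and norms[-1] > 0.1
        # a long simulation from a generic start lands on one of them
        rng = np.random.default_rng(7)
        tr = integrate(m, rng.uniform(0, 0.1, (1, 32)), t_end=80.0, dt=0.02)
        final_norm = tr.norms[-1]
        assert min(abs(final_norm - nv) for nv in norms) < 1e-3

    def test_states_are_delay_independent(self, ring_factory):
        wa = ring_factory(c=0.0, sigma=1.1, n=32)
        wb = ring_factory(c=3.0, sigma=1.1, n=32)
        sa = find_stationary(wa)
        sb = find_stationary(wb)
        assert len(sa) == len(sb)
        for a, b in zip(sa, sb):
            assert np.allclose(a.values, b.values, atol=1e-9)


class TestLinearize:
    def test_mode_gains_at_trivial_state(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0)
        # g_k = sigma * s1 * Jhat_k
        assert lin.mode_gain(2) == pytest.approx(0.25 * 1.5 * np.pi)
        assert lin.mode_gain(0) == pytest.approx(-0.25 * 2 * np.pi)

    def test_gains_linear_in_gain(self, ring_factory):
        l1 = trivial_lin(ring_factory, c=1.0, sigma=0.7)
        l2 = trivial_lin(ring_factory, c=1.0, sigma=1.4)
        assert l2.mode_gain(2) == pytest.approx(2 * l1.mode_gain(2))

    def test_vanishing_gain_kills_kernel(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1e-12)
        assert np.max(np.abs(lin.jtilde)) < 1e-10


class TestCharacteristicEquation:
    def test_c_zero_closed_form_roots(self, ring_factory):
        lin = trivial_lin(ring_factory, c=0.0, sigma=1.0)
        for k in range(9):
            expect = -1.0 + lin.mode_gain(k)
            region = (min(-2.0, expect - 0.5), 2.0, 5.0)
            roots = solve_mode_roots(lin, k, region=region)
            assert any(abs(r.lam - expect) < 1e-8 for r in roots)

    def test_delta_at_zero_is_c_independent(self, ring_factory):
        for c in (0.0, 1.0, 2.5):
            lin = trivial_lin(ring_factory, c=c, sigma=1.0)
            d = char_residual(lin, 2, 0.0)
            assert d == pytest.approx(1.0 - 0.25 * 1.5 * np.pi, abs=1e-10)

    def test_conjugate_symmetry(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.5, sigma=1.0)
        lam = 0.3 + 1.7j
        assert char_residual(lin, 1, np.conj(lam)) == pytest.approx(
            np.conj(char_residual(lin, 1, lam)), abs=1e-12
        )

    def test_root_count_matches_argument_principle(self, ring_factory):
        """The winding number of Delta_k over a rectangle is an independent
        oracle for the number of roots found inside it."""
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0)
        for k in (0, 2, 4):
            rect = ((-0.95, 1.0), (0.05, 5.0))
            n_roots = count_roots_in_rectangle(lin, k, *rect)
            found = [
                r
                for r in solve_mode_roots(lin, k, region=(-0.95, 1.0, 5.0))
                if 0.05 < r.lam.imag < 5.0
            ]
            assert len(found) == n_roots

    def test_root_count_stable_under_grid_refinement(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0)
        a = solve_mode_roots(lin, 0, grid_density=(10, 12))
        b = solve_mode_roots(lin, 0, grid_density=(20, 24))
        near = lambda roots: sorted(r.lam.real for r in roots if r.lam.real > -0.9)
        assert np.allclose(near(a), near(b), atol=1e-8)


class TestGeneratorMatrix:
    def test_pure_leak_spectrum(self):
        m = make_ring_model([], c=1.0, sigma=1.0, n=12)
        lin = linearize(m, StationaryState(values=np.zeros((1, 12)), residual=0.0))
        ev = generator_eigenvalues(lin, m_delay=12)
        assert np.min(np.abs(ev - (-1.0))) < 1e-8

    def test_c_zero_degenerates_to_nondelayed_operator(self, ring_factory):
        lin = trivial_lin(ring_factory, c=0.0, sigma=1.0, n=32)
        a = build_generator_matrix(lin)
        assert a.shape == (32, 32)
        ev = np.sort(np.linalg.eigvals(a).real)[::-1]
        for k in range(9):
            expect = -1.0 + lin.mode_gain(k)
            assert np.min(np.abs(ev - expect)) < 1e-8

    def test_matches_mode_roots_on_reference_model(self, ring_factory):
        """Cross-method oracle: A_N eigenvalues vs per-mode Newton roots."""
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0, n=48)
        ev = generator_eigenvalues(lin, m_delay=20)
        roots = []
        for k in range(7):
            roots.extend(solve_mode_roots(lin, k))
        roots.sort(key=lambda r: -r.lam.real)
        for r in roots[:8]:
            assert np.min(np.abs(ev - r.lam)) < 1e-7

    def test_spectral_convergence_in_m(self, ring_factory):
        """The error of the rightmost eigenvalue decays faster than any fixed
        power of the collocation size."""
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0, n=32)
        exact = solve_mode_roots(lin, 2)[0].lam
        errs = []
        for m_delay in (4, 8, 16):
            ev = generator_eigenvalues(lin, m_delay=m_delay)
            errs.append(np.min(np.abs(ev - exact)))
        assert errs[2] < 1e-10
        # super-algebraic: each doubling gains more than the previous one
        assert errs[1] / errs[2] > errs[0] / max(errs[1], 1e-300) or errs[1] < 1e-12

    def test_conjugate_symmetry_of_spectrum(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0, n=24)
        ev = generator_eigenvalues(lin, m_delay=14)
        complex_ev = ev[np.abs(ev.imag) > 1e-8]
        for lam in complex_ev[:20]:
            assert np.min(np.abs(ev - np.conj(lam))) < 1e-7

    def test_essential_accumulation_at_minus_leak(self, ring_factory):
        """With enough spatial modes the eigenvalue sequence piles up at -l."""
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0, n=96)
        ev = generator_eigenvalues(lin, m_delay=12)
        tail = ev[100:150]
        assert abs(np.median(tail.real) - (-1.0)) < 0.1


class TestAssembledSpectrum:
    def test_zero_gain_is_stable_with_leak_abscissa(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1e-9, n=24)
        spec = assemble_spectrum(lin, method="mode-newton", modes=4)
        assert spec.verdict == "stable"
        assert spec.abscissa == pytest.approx(-1.0, abs=1e-6)
        assert spec.essential == pytest.approx([-1.0])

    def test_verdict_flips_at_pitchfork_gain(self, ring_factory, sigma0):
        lo = assemble_spectrum(
            trivial_lin(ring_factory, c=0.0, sigma=0.95 * sigma0, n=24),
            method="mode-newton", modes=6,
        )
        hi = assemble_spectrum(
            trivial_lin(ring_factory, c=0.0, sigma=1.05 * sigma0, n=24),
            method="mode-newton", modes=6,
        )
        assert lo.verdict == "stable"
        assert hi.verdict == "unstable"

    def test_both_methods_reconcile(self, ring_factory):
        lin = trivial_lin(ring_factory, c=1.0, sigma=1.0, n=48)
        spec = assemble_spectrum(lin, method="both", modes=6, m_delay=20)
        assert spec.details["reconciled"] > 0
        assert spec.verdict == "unstable"  # sigma = 1 > sigma0

    @pytest.mark.parametrize(
        "c,sigma,expect_sign",
        [(0.5, 0.4, -1), (0.5, 1.2, 1), (2.0, 0.5, -1), (2.0, 1.2, 1), (4.0, 0.7, -1)],
    )
    def test_verdict_matches_simulated_dynamics(self, ring_factory, c, sigma, expect_sign):
        """Negative abscissa <=> small perturbations decay in simulation."""
        lin = trivial_lin(ring_factory, c=c, sigma=sigma, n=32)
        spec = assemble_spectrum(lin, method="mode-newton", modes=8)
        assert np.sign(spec.abscissa) == expect_sign
        m = ring_factory(c=c, sigma=sigma, n=32)
        rng = np.random.default_rng(11)
        v0 = rng.uniform(-1e-3, 1e-3, (1, 32))
        tr = integrate(m, v0, t_end=60.0, dt=0.05)
        if expect_sign < 0:
            assert tr.norms[-1] < 0.3 * tr.norms[0]
        else:
            assert tr.norms[-1] > 3.0 * tr.norms[0]
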