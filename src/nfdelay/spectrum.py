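"""Linear stability of stationary states via the spectrum of the delay operator.

Stationary (persistent) states solve ``0 = -L0 V + \\int J S(V) + I`` and do
not depend on the delays.  Linearizing about a state ``V^f`` gives a delay
operator whose spectrum splits into

* the essential spectrum ``{-l_i}`` (the leak rates), an accumulation set, and
* the characteristic values (CVs): eigenvalues, at most finitely many to the
  right of ``-min l_i``.

Two independent computations of the CVs are provided:

1. ``solve_mode_roots`` — for the homogeneous ring, the eigenfunctions are the
   ring harmonics ``cos(kx), sin(kx)`` and each mode contributes a scalar
   characteristic equation

       Delta_k(lambda) = lambda + l - gamma * G_k(lambda) = 0,
       G_k(lambda) = \\int_Omega J(z) exp(-lambda c d(z)) cos(w_k z) dz

   with ``gamma`` the linearized sigmoid gain; the roots are found by damped
   complex Newton iteration from a grid of starting points.

2. ``build_generator_matrix`` — a pseudospectral discretization A_N of the
   infinitesimal generator acting on the history segment ``[-tau_max, 0]``
   (Chebyshev-Gauss-Lobatto collocation in the delay variable, barycentric
   interpolation at the delayed arguments); its eigenvalues converge
   spectrally to the CVs.

The state is asymptotically stable iff the spectral abscissa (max real part
over the CVs) is negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from .model import CosineKernel, NeuralFieldModel, fourier_cos_coefficient

__all__ = [
    "StationaryState",
    "LinearizedModel",
    "CharacteristicRoot",
    "SpectrumResult",
    "find_stationary",
    "linearize",
    "char_residual",
    "char_residual_deriv",
    "solve_mode_roots",
    "count_roots_in_rectangle",
    "build_generator_matrix",
    "generator_eigenvalues",
    "assemble_spectrum",
]

_STATE_TOL = 1e-10


@dataclass
class StationaryState:
    """A persistent state ``V^f`` with its fixed-point residual norm."""

    values: np.ndarray  # (p, N)
    residual: float

    def norm(self, weights: np.ndarray) -> float:
        return float(np.sqrt(np.sum(weights[None, :] * self.values**2)))


@dataclass
class LinearizedModel:
    """Linearization about a stationary state.

    ``jtilde`` is the effective kernel ``J(r, r') * S'(V^f(r'))`` (density, no
    quadrature weights).  For a homogeneous ring linearized at a uniform state
    the operator is a convolution and ``mode_gain(k) = gamma * Jhat_k``.
    """

    model: NeuralFieldModel
    state: StationaryState
    jtilde: np.ndarray  # (p, p, N, N)
    gamma: float | None  # uniform sigmoid slope, homogeneous case only

    @property
    def homogeneous(self) -> bool:
        return self.gamma is not None

    @property
    def l(self) -> float:
        return self.model.l_min

    @property
    def tau_max(self) -> float:
        return self.model.tau_max

    def mode_gain(self, k: int) -> float:
        """g_k = gamma * Jhat_k, the non-delayed feedback gain of mode k."""
        if not self.homogeneous:
            raise ValueError("mode gains are defined for the homogeneous ring only")
        return self.gamma * fourier_cos_coefficient(self.model, k)

    def weighted_matrix(self) -> np.ndarray:
        """Discretized operator ``J~ W`` acting on grid values, shape (pN, pN)."""
        w = self.model.grid.weights
        p, n = self.model.populations, self.model.n
        jw = self.jtilde * w[None, None, None, :]
        return jw.transpose(0, 2, 1, 3).reshape(p * n, p * n)

    def nondelayed_matrix(self) -> np.ndarray:
        """Discretization of ``-L0 + J~`` (the non-delayed linearized operator)."""
        p, n = self.model.populations, self.model.n
        leak = np.repeat(self.model.leak, n)
        return -np.diag(leak) + self.weighted_matrix()


@dataclass
class CharacteristicRoot:
    lam: complex
    mode: int
    residual: float
    conjugate_pair: bool

    @property
    def multiplicity_note(self) -> str:
        return "with conjugate" if self.conjugate_pair else "real"


@dataclass
class SpectrumResult:
    essential: np.ndarray
    roots: list[CharacteristicRoot]
    abscissa: float
    verdict: str
    method: str
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stationary states and linearization
# ---------------------------------------------------------------------------

def _fixed_point_residual(model: NeuralFieldModel, v: np.ndarray) -> np.ndarray:
    kq = model.kernel_matrix() * model.grid.weights[None, None, None, :]
    drive = np.einsum("abik,bk->ai", kq, model.sigmoid.fire(v))
    return -model.leak[:, None] * v + drive + model.external_current(0.0)


def find_stationary(
    model: NeuralFieldModel,
    guesses: Sequence[np.ndarray] | None = None,
    max_iter: int = 80,
    tol: float = _STATE_TOL,
) -> list[StationaryState]:
    """Damped-Newton solve of the delay-independent fixed-point equation.

    Returns deduplicated converged states, sorted by increasing norm.  With no
    ``guesses``, tries 0 plus ± the dominant kernel modes at a few amplitudes.
    """
    p, n = model.populations, model.n
    w = model.grid.weights

    if guesses is None:
        guesses = [np.zeros((p, n))]
        if isinstance(model.kernel, CosineKernel):
            x = model.grid.nodes
            for wn, a in model.kernel.coeffs:
                if a > 0 and wn > 0:
                    for amp in (0.5, 2.0):
                        pattern = np.broadcast_to(np.cos(wn * x), (p, n))
                        guesses.append(amp * pattern)
                        guesses.append(-amp * pattern)

    kq = model.kernel_matrix() * w[None, None, None, :]
    leak = np.repeat(model.leak, n)
    states: list[StationaryState] = []
    for guess in guesses:
        v = np.broadcast_to(np.asarray(guess, dtype=float), (p, n)).copy()
        converged = False
        for _ in range(max_iter):
            f = _fixed_point_residual(model, v)
            res = float(np.sqrt(np.sum(w[None, :] * f**2)))
            if res < tol:
                converged = True
                break
            sprime = model.sigmoid.fire_deriv(v)  # (p, N)
            jac = -np.diag(leak) + np.einsum(
                "abik,bk->abik", kq, sprime
            ).transpose(0, 2, 1, 3).reshape(p * n, p * n)
            try:
                step = np.linalg.solve(jac, -f.ravel()).reshape(p, n)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            for _ in range(30):
                trial = v + lam * step
                f_trial = _fixed_point_residual(model, trial)
                if np.sqrt(np.sum(w[None, :] * f_trial**2)) < res:
                    break
                lam /= 2
            v = v + lam * step
        if converged:
            f = _fixed_point_residual(model, v)
            res = float(np.sqrt(np.sum(w[None, :] * f**2)))
            if not any(
                np.sqrt(np.sum(w[None, :] * (v - s.values) ** 2)) < 1e-6 for s in states
            ):
                states.append(StationaryState(values=v, residual=res))
    states.sort(key=lambda s: s.norm(w))
    return states


def linearize(model: NeuralFieldModel, state: StationaryState) -> LinearizedModel:
    """Effective kernel of the linearization about ``state``."""
    if state.residual > 1e-6:
        raise ValueError(f"state residual {state.residual:.2e} too large to linearize")
    sprime = model.sigmoid.fire_deriv(state.values)  # (p, N)
    jt = model.kernel_matrix() * sprime[None, :, None, :]
    gamma = None
    if model.homogeneous and np.ptp(state.values) < 1e-9:
        gamma = float(sprime.ravel()[0])
    return LinearizedModel(model=model, state=state, jtilde=jt, gamma=gamma)


# ---------------------------------------------------------------------------
# per-mode characteristic equation (homogeneous ring)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _gauss_half(nq: int, half: float):
    xg, wg = leggauss(nq)
    return (xg + 1) * (half / 2), wg * (half / 2)


def _quad_points(lin: LinearizedModel, lam_scale: float):
    """Gauss nodes on [0, period/2] sized to resolve exp(-lambda c z)."""
    half = lin.model.grid.period / 2
    c = lin.model.delay.c
    nq = int(min(2000, 80 + 0.8 * lam_scale * c * half))
    return _gauss_half(nq, half)


def _g_factor(lin: LinearizedModel, k: int, lam: np.ndarray) -> np.ndarray:
    """G_k(lambda) = \\int_Omega J(z) exp(-lambda c |z|_ring) cos(w_k z) dz.

    Vectorized over ``lam``; the integrand is split at the ring-distance kink
    (z = 0), i.e. computed as twice the integral over half the ring.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=complex))
    c = lin.model.delay.c
    wk = 2 * np.pi * k / lin.model.grid.period
    z, w = _quad_points(lin, float(np.max(np.abs(lam))) if lam.size else 1.0)
    base = w * lin.model.kernel(z) * np.cos(wk * z)
    return 2.0 * (np.exp(-np.outer(lam, c * z)) @ base)


def _g_factor_deriv(lin: LinearizedModel, k: int, lam: np.ndarray) -> np.ndarray:
    lam = np.atleast_1d(np.asarray(lam, dtype=complex))
    c = lin.model.delay.c
    wk = 2 * np.pi * k / lin.model.grid.period
    z, w = _quad_points(lin, float(np.max(np.abs(lam))) if lam.size else 1.0)
    base = w * lin.model.kernel(z) * np.cos(wk * z)
    return -2.0 * (np.exp(-np.outer(lam, c * z)) @ (c * z * base))


def char_residual(lin: LinearizedModel, k: int, lam) -> complex | np.ndarray:
    """Delta_k(lambda) = lambda + l - gamma * G_k(lambda); roots are the CVs
    of mode k.  At c = 0 this reduces to ``lambda + l - g_k``."""
    if not lin.homogeneous:
        raise ValueError(
            "the per-mode characteristic equation requires a homogeneous ring "
            "linearization; use the generator matrix instead"
        )
    scalar = np.isscalar(lam) or np.asarray(lam).ndim == 0
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=complex))
    out = lam_arr + lin.l - lin.gamma * _g_factor(lin, k, lam_arr)
    return complex(out[0]) if scalar else out


def char_residual_deriv(lin: LinearizedModel, k: int, lam) -> complex | np.ndarray:
    scalar = np.isscalar(lam) or np.asarray(lam).ndim == 0
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=complex))
    out = 1.0 - lin.gamma * _g_factor_deriv(lin, k, lam_arr)
    return complex(out[0]) if scalar else out


def _residual_scale(lin: LinearizedModel, lam: np.ndarray) -> np.ndarray:
    """Conditioning of |Delta|: exp growth of the delay factor left of 0."""
    c = lin.model.delay.c
    half = lin.model.grid.period / 2
    z, w = _gauss_half(200, half)
    l1j = 2.0 * float(np.sum(w * np.abs(lin.model.kernel(z))))
    grow = np.exp(np.maximum(0.0, -np.real(lam)) * c * half)
    return 1.0 + abs(lin.gamma) * l1j * grow


def solve_mode_roots(
    lin: LinearizedModel,
    k: int,
    region: tuple[float, float, float] | None = None,
    grid_density: tuple[int, int] = (12, 14),
    max_iter: int = 80,
    dedup_tol: float = 1e-6,
) -> list[CharacteristicRoot]:
    """All characteristic values of mode ``k`` inside the search region.

    ``region = (re_min, re_max, omega_max)``; the upper half-plane is searched
    (roots come in conjugate pairs) from a ``grid_density`` rectangular grid of
    Newton starting points.  Converged roots are polished to small residual and
    deduplicated within ``dedup_tol``.
    """
    if region is None:
        om = max(20.0, 10.0 / (lin.tau_max + 0.1))
        region = (-lin.l - 1.0, 2.0, om)
    re_min, re_max, om_max = region
    n_re, n_im = grid_density
    res, ims = np.meshgrid(
        np.linspace(re_min, re_max, n_re), np.linspace(0.0, om_max, n_im)
    )
    lam = (res + 1j * ims).ravel()
    active = np.ones(lam.size, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        f = char_residual(lin, k, lam[active])
        df = char_residual_deriv(lin, k, lam[active])
        df = np.where(np.abs(df) < 1e-14, 1e-14, df)
        step = f / df
        # damp wild steps so starts do not fly out of the analytic region
        big = np.abs(step) > 1.0
        step[big] *= 1.0 / np.abs(step[big])
        lam[active] -= step
        done = np.abs(step) < 1e-13
        idx = np.nonzero(active)[0]
        active[idx[done]] = False

    f = np.abs(char_residual(lin, k, lam))
    scale = _residual_scale(lin, lam)
    ok = (
        (f < 1e-9 * scale)
        & np.isfinite(lam)
        & (lam.real >= re_min - 1e-6)
        & (lam.real <= re_max + 1e-6)
        & (lam.imag >= -1e-9)
        & (lam.imag <= om_max + 1e-6)
    )
    roots: list[CharacteristicRoot] = []
    for lv, rv in sorted(zip(lam[ok], f[ok]), key=lambda t: -t[0].real):
        if abs(lv.imag) < 1e-8:
            lv = complex(lv.real, 0.0)
        if any(abs(lv - r.lam) < dedup_tol for r in roots):
            continue
        roots.append(
            CharacteristicRoot(
                lam=lv, mode=k, residual=float(rv), conjugate_pair=lv.imag != 0
            )
        )
    return roots


def count_roots_in_rectangle(
    lin: LinearizedModel,
    k: int,
    re_range: tuple[float, float],
    im_range: tuple[float, float],
    n_side: int = 400,
) -> int:
    """Winding number of ``Delta_k`` around a rectangle: the number of roots
    inside (with multiplicity), by the argument principle."""
    a, b = re_range
    lo, hi = im_range
    edges = [
        np.linspace(a + 1j * lo, b + 1j * lo, n_side),
        np.linspace(b + 1j * lo, b + 1j * hi, n_side),
        np.linspace(b + 1j * hi, a + 1j * hi, n_side),
        np.linspace(a + 1j * hi, a + 1j * lo, n_side),
    ]
    contour = np.concatenate(edges)
    vals = char_residual(lin, k, contour)
    args = np.angle(vals)
    d = np.diff(np.concatenate([args, args[:1]]))
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return int(np.round(d.sum() / (2 * np.pi)))


# ---------------------------------------------------------------------------
# generator matrix
# ---------------------------------------------------------------------------

def _cheb(m: int):
    """Chebyshev-Gauss-Lobatto points on [-1, 1] (first point = 1) and the
    spectral differentiation matrix (Trefethen's construction)."""
    if m == 0:
        return np.array([1.0]), np.zeros((1, 1))
    x = np.cos(np.pi * np.arange(m + 1) / m)
    cc = np.r_[2.0, np.ones(m - 1), 2.0] * (-1.0) ** np.arange(m + 1)
    big_x = np.tile(x, (m + 1, 1)).T
    dx = big_x - big_x.T
    d = np.outer(cc, 1.0 / cc) / (dx + np.eye(m + 1))
    d -= np.diag(d.sum(axis=1))
    return x, d


def _bary_rows(xi: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Barycentric interpolation weights at ``targets`` for CGL nodes."""
    m = len(xi) - 1
    w = (-1.0) ** np.arange(m + 1)
    w[0] *= 0.5
    w[-1] *= 0.5
    d = targets[:, None] - xi[None, :]
    exact = np.abs(d) < 1e-13
    d = np.where(exact, 1.0, d)
    r = w[None, :] / d
    rows = r / r.sum(axis=1, keepdims=True)
    hit = exact.any(axis=1)
    if hit.any():
        rows[hit] = 0.0
        rows[np.nonzero(hit)[0], np.argmax(exact[hit], axis=1)] = 1.0
    return rows


def _trig_cardinal(u: np.ndarray, n: int) -> np.ndarray:
    """Cardinal function of trigonometric interpolation on a uniform n-grid
    (n even): D(u) = sin(n u / 2) / (n tan(u / 2))."""
    u = np.asarray(u, dtype=float)
    wrapped = np.remainder(u + np.pi, 2 * np.pi) - np.pi
    small = np.abs(wrapped) < 1e-12
    uu = np.where(small, 1.0, u)
    val = np.sin(n * uu / 2) / (n * np.tan(uu / 2))
    return np.where(small, 1.0, val)


def build_generator_matrix(
    lin: LinearizedModel,
    n_space: int | None = None,
    m_delay: int = 24,
    n_quad: int = 80,
) -> np.ndarray:
    """Pseudospectral discretization A_N of the infinitesimal generator.

    The history segment ``u(theta, x)``, ``theta in [-tau_max, 0]``, is
    collocated at ``m_delay + 1`` Chebyshev-Gauss-Lobatto points tensored with
    the spatial grid.  Interior rows apply spectral differentiation in theta
    (the generator acts as d/d theta); the boundary row (theta = 0) applies
    the delayed operator ``-L0 u(0) + \\int J~(x, y) u(-tau(x, y), y) dy`` with
    ``u`` at the delayed argument obtained by barycentric interpolation.

    For homogeneous ring models the boundary integral is evaluated by Gauss
    quadrature split at the delay kink with trigonometric interpolation in
    space (spectrally accurate); tabulated models fall back to the periodic
    trapezoid rule on the grid, accurate to O(N^-2) because of the kink of the
    delay function at coincident points.

    ``tau_max = 0`` degenerates to the non-delayed operator ``-L0 + J~``.
    """
    if m_delay < 1:
        raise ValueError("m_delay must be >= 1")
    model = lin.model
    tau_m = lin.tau_max
    if tau_m == 0:
        return lin.nondelayed_matrix()

    homogeneous = lin.homogeneous and (n_space is None or n_space == model.n)
    if lin.homogeneous and n_space is not None and n_space != model.n:
        # re-sample the homogeneous model on a finer ring
        from .model import make_ring_model

        resampled = make_ring_model(
            list(model.kernel.coeffs),
            c=model.delay.c,
            sigma=model.sigmoid.gain,
            leak=float(model.leak[0]),
            s1=model.sigmoid.s1,
            n=n_space,
            period=model.grid.period,
            centered=model.sigmoid.centered,
            threshold=model.sigmoid.threshold,
        )
        from copy import copy

        lin2 = copy(lin)
        lin2.model = resampled
        lin2.state = StationaryState(
            values=np.full((1, n_space), float(lin.state.values.ravel()[0])),
            residual=lin.state.residual,
        )
        return build_generator_matrix(lin2, None, m_delay, n_quad)

    p, n = model.populations, model.n
    if n_space is not None and n_space != n:
        raise ValueError("n_space can only be changed for homogeneous ring models")
    nn = p * n
    xi, d_cheb = _cheb(m_delay)
    d_theta = (2.0 / tau_m) * d_cheb
    size = (m_delay + 1) * nn
    a = np.zeros((size, size))
    a[nn:, :] = np.kron(d_theta, np.eye(nn))[nn:, :]
    a[:nn, :nn] -= np.diag(np.repeat(model.leak, n))

    if homogeneous:
        half = model.grid.period / 2
        c = model.delay.c
        xg, wg = leggauss(n_quad)
        y1 = (xg + 1) * (half / 2)  # (0, half): d = y
        w1 = wg * (half / 2)
        yq = np.r_[y1, model.grid.period - y1]  # second panel: d = period - y
        dq = np.r_[y1, y1]
        wq = np.r_[w1, w1]
        gamma = lin.gamma
        jq = gamma * model.kernel(yq)
        targets = (2.0 / tau_m) * (-c * dq) + 1.0
        th_rows = _bary_rows(xi, targets)  # (2Q, M+1)
        x0 = model.grid.nodes
        sp = _trig_cardinal(yq[:, None] - (x0 - x0[0])[None, :], n)  # (2Q, N)
        blk0 = np.einsum("q,qj,qi->ji", wq * jq, th_rows, sp)  # (M+1, N)
        for i in range(n):
            a[i, :] += np.roll(blk0, i, axis=1).ravel()
    else:
        tau = model.delay.tau_matrix(model.grid)
        jw = (lin.jtilde * model.grid.weights[None, None, None, :]).transpose(
            0, 2, 1, 3
        ).reshape(nn, nn)
        tau_full = np.tile(tau, (p, p))
        targets = (2.0 / tau_m) * (-tau_full.ravel()) + 1.0
        rows = _bary_rows(xi, targets).reshape(nn, nn, m_delay + 1)
        for j in range(m_delay + 1):
            a[:nn, j * nn : (j + 1) * nn] += jw * rows[:, :, j]
    return a


def generator_eigenvalues(
    lin: LinearizedModel,
    n_space: int | None = None,
    m_delay: int = 24,
    n_keep: int | None = None,
) -> np.ndarray:
    """Eigenvalues of A_N sorted by decreasing real part."""
    a = build_generator_matrix(lin, n_space=n_space, m_delay=m_delay)
    ev = np.linalg.eigvals(a)
    ev = ev[np.argsort(-ev.real)]
    return ev if n_keep is None else ev[:n_keep]


# ---------------------------------------------------------------------------
# assembled spectrum with verdict
# ---------------------------------------------------------------------------

class SpectrumConsistencyError(RuntimeError):
    pass


def assemble_spectrum(
    lin: LinearizedModel,
    method: str = "both",
    modes: int = 16,
    region: tuple[float, float, float] | None = None,
    m_delay: int = 24,
    marginal_tol: float = 1e-6,
    reconcile_tol: float = 1e-4,
    n_reconcile: int = 10,
) -> SpectrumResult:
    """Compute CVs, attach the essential spectrum ``{-l_i}``, and issue the
    stability verdict:

    * ``stable``   if the spectral abscissa < -marginal_tol,
    * ``unstable`` if it is > +marginal_tol,
    * ``marginal`` within the tolerance band.

    With ``method="both"``, per-mode Newton roots and A_N eigenvalues are
    computed and the rightmost roots cross-checked; disagreement beyond
    ``reconcile_tol`` raises :class:`SpectrumConsistencyError`.
    """
    if method not in ("mode-newton", "generator-matrix", "both"):
        raise ValueError("method must be 'mode-newton', 'generator-matrix' or 'both'")
    if method != "generator-matrix" and not lin.homogeneous:
        raise ValueError("mode-newton requires a homogeneous ring linearization")

    essential = -np.unique(lin.model.leak)
    details: dict = {}
    roots: list[CharacteristicRoot] = []

    if method in ("mode-newton", "both"):
        for k in range(modes + 1):
            roots.extend(solve_mode_roots(lin, k, region=region))
        roots.sort(key=lambda r: -r.lam.real)
        details["n_mode_roots"] = len(roots)

    if method in ("generator-matrix", "both"):
        ev = generator_eigenvalues(lin, m_delay=m_delay)
        details["generator_eigenvalues"] = ev
        if method == "generator-matrix":
            lam_max = ev[0]
            roots = [
                CharacteristicRoot(
                    lam=complex(e),
                    mode=-1,
                    residual=float("nan"),
                    conjugate_pair=abs(e.imag) > 1e-8,
                )
                for e in ev[: 4 * (modes + 1)]
                if e.imag >= -1e-8
            ]

    if method == "both" and roots:
        mismatches = []
        for r in roots[:n_reconcile]:
            ev = details["generator_eigenvalues"]
            gap = float(np.min(np.abs(ev - r.lam)))
            if gap > reconcile_tol:
                mismatches.append((r.lam, gap))
        if mismatches:
            raise SpectrumConsistencyError(
                f"mode roots and generator eigenvalues disagree: {mismatches}"
            )
        details["reconciled"] = min(n_reconcile, len(roots))

    if roots:
        abscissa = max(r.lam.real for r in roots)
    else:
        abscissa = float(essential.max())
    if abscissa < -marginal_tol:
        verdict = "stable"
    elif abscissa > marginal_tol:
        verdict = "unstable"
    else:
        verdict = "marginal"
    return SpectrumResult(
        essential=essential,
        roots=roots,
        abscissa=abscissa,
        verdict=verdict,
        method=method,
        details=details,
    )
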