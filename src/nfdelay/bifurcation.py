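"""Bifurcation curves of the homogeneous ring in the (c, sigma) plane.

Along the trivial (centered) stationary state, two instability mechanisms
compete as the sigmoid gain ``sigma`` and delay scale ``c`` vary:

* **Pitchfork line** — a zero characteristic value.  Since ``lambda = 0``
  kills the delay factor, the condition ``l = sigma * s1 * Jhat_k`` is
  independent of ``c``: the line is vertical at
  ``sigma0 = l / (s1 * max_k Jhat_k)`` and marks the birth of stationary
  spatial patterns (the mode of the largest positive kernel coefficient).

* **Hopf curve** — a purely imaginary pair ``+-i omega``.  For mode ``k``,
  splitting ``Delta_k(i omega) = 0`` into real and imaginary parts gives

      l     = sigma * s1 * C_k(omega),      (real part)
      omega = -sigma * s1 * S_k(omega),     (imaginary part)

  with ``C_k, S_k`` the cosine/sine transforms of the kernel against the
  delay phase.  Eliminating the gain reduces the Hopf condition to the scalar
  equation ``omega * C_k(omega) + l * S_k(omega) = 0`` with ``C_k > 0``, which
  is solved per mode by bracketing and bisection; the curve retains, per
  ``c``, the smallest gain over modes and branches.  No Hopf point exists at
  ``c = 0`` (the non-delayed ring dynamics is gradient-like).

The **fold-Hopf point** is the intersection of the two curves: the delay
scale ``c*`` where an imaginary pair emerges on top of the zero eigenvalue.
Because gain and sigmoid slope enter only through the product
``sigma * s1``, ``c*`` does not depend on the slope normalization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .model import NeuralFieldModel, fourier_cos_coefficient, make_ring_model
from .spectrum import (
    LinearizedModel,
    StationaryState,
    char_residual,
    linearize,
    solve_mode_roots,
)

__all__ = [
    "HopfPoint",
    "FoldHopfPoint",
    "BifurcationDiagram",
    "ring_at",
    "pitchfork_gain",
    "hopf_gain_at",
    "hopf_curve",
    "fold_hopf",
    "spectral_abscissa",
    "stability_map",
]


@dataclass
class HopfPoint:
    c: float
    sigma: float
    omega: float
    mode: int
    residual: float


@dataclass
class FoldHopfPoint:
    c: float
    sigma: float
    omega: float
    mode_zero: int
    mode_hopf: int


@dataclass
class BifurcationDiagram:
    sigma0: float | None
    hopf_branch: list[HopfPoint]
    fold_hopf: FoldHopfPoint | None
    c_values: np.ndarray | None = None
    sigma_values: np.ndarray | None = None
    abscissa: np.ndarray | None = None
    cv_stable: np.ndarray | None = None
    cond1: np.ndarray | None = None
    cond2: np.ndarray | None = None
    flagged: list[tuple[int, int, str]] = field(default_factory=list)


def ring_at(model: NeuralFieldModel, c: float, sigma: float) -> LinearizedModel:
    """Linearization of the centered ring model at the trivial state for the
    requested (delay scale, gain) point."""
    if not model.homogeneous:
        raise ValueError("bifurcation tracing requires a homogeneous ring model")
    m = make_ring_model(
        list(model.kernel.coeffs),
        c=c,
        sigma=sigma,
        leak=float(model.leak[0]),
        s1=model.sigmoid.s1,
        n=model.n,
        period=model.grid.period,
        centered=True,
    )
    state = StationaryState(values=np.zeros((1, m.n)), residual=0.0)
    return linearize(m, state)


# ---------------------------------------------------------------------------
# pitchfork
# ---------------------------------------------------------------------------

def pitchfork_gain(model: NeuralFieldModel, modes: int = 32) -> float | None:
    """``sigma0 = l / (s1 * max_k Jhat_k)``; None if no coefficient is
    positive (no static instability at any gain)."""
    jh = [fourier_cos_coefficient(model, k) for k in range(modes + 1)]
    j_max = max(jh)
    if j_max <= 0:
        return None
    return float(model.l_min / (model.sigmoid.s1 * j_max))


def _dominant_mode(model: NeuralFieldModel, modes: int = 32) -> int:
    jh = [fourier_cos_coefficient(model, k) for k in range(modes + 1)]
    return int(np.argmax(jh))


# ---------------------------------------------------------------------------
# Hopf curve
# ---------------------------------------------------------------------------

from .spectrum import _gauss_half


def _transform_base(model: NeuralFieldModel, k: int, omega_max: float, c: float):
    """Cached quadrature data for C_k / S_k evaluations up to ``omega_max``."""
    half = model.grid.period / 2
    nq = int(min(2000, 120 + 0.8 * omega_max * c * half))
    z, w = _gauss_half(nq, half)
    wk = 2 * np.pi * k / model.grid.period
    return z, w * model.kernel(z) * np.cos(wk * z)


def _cos_sin_transforms(model: NeuralFieldModel, k: int, omegas: np.ndarray, c: float):
    """C_k(omega), S_k(omega): kernel transforms against the delay phase."""
    z, base = _transform_base(model, k, float(np.max(omegas, initial=1.0)), c)
    ph = np.outer(omegas, c * z)
    return 2.0 * (np.cos(ph) @ base), 2.0 * (np.sin(ph) @ base)


def hopf_gain_at(
    model: NeuralFieldModel,
    c: float,
    modes: int = 12,
    omega_max: float | None = None,
    n_scan: int = 2400,
) -> HopfPoint | None:
    """Smallest gain with a purely imaginary characteristic pair at this c.

    For each mode the scalar Hopf condition is bracketed on an omega grid and
    solved by bisection; candidates need ``C_k(omega) > 0`` for a positive
    gain.  Returns None when no mode admits a Hopf point (e.g. c = 0).
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if c == 0:
        return None
    l = model.l_min
    s1 = model.sigmoid.s1
    if omega_max is None:
        tau_m = c * model.grid.period / 2
        omega_max = max(25.0, 12.0 / (tau_m + 0.05))
    best: HopfPoint | None = None
    omegas = np.linspace(1e-6, omega_max, n_scan)
    for k in range(modes + 1):
        z, base = _transform_base(model, k, omega_max, c)

        def cs(om):
            ph = np.outer(np.atleast_1d(om), c * z)
            return 2.0 * (np.cos(ph) @ base), 2.0 * (np.sin(ph) @ base)

        ck, sk = cs(omegas)
        f = omegas * ck + l * sk
        if np.max(np.abs(f)) < 1e-10:
            continue  # mode absent from the kernel
        sign_change = np.nonzero(f[:-1] * f[1:] < 0)[0]
        for i in sign_change:
            def fun(om):
                ckk, skk = cs(om)
                return om * ckk[0] + l * skk[0]

            om0 = brentq(fun, omegas[i], omegas[i + 1], xtol=1e-13, rtol=1e-15)
            ck0 = cs(om0)[0]
            if ck0[0] <= 1e-10:
                continue
            sigma = l / (s1 * ck0[0])
            if sigma <= 0:
                continue
            if best is None or sigma < best.sigma:
                lin = ring_at(model, c, sigma)
                resid = abs(char_residual(lin, k, 1j * om0))
                best = HopfPoint(c=c, sigma=float(sigma), omega=float(om0), mode=k, residual=float(resid))
    return best


def hopf_curve(
    model: NeuralFieldModel,
    c_values: Sequence[float],
    modes: int = 12,
    omega_max: float | None = None,
) -> list[HopfPoint]:
    """Trace the Hopf curve over ``c_values`` (minimal gain per c)."""
    branch: list[HopfPoint] = []
    for c in c_values:
        pt = hopf_gain_at(model, float(c), modes=modes, omega_max=omega_max)
        if pt is not None:
            branch.append(pt)
    return branch


# ---------------------------------------------------------------------------
# fold-Hopf
# ---------------------------------------------------------------------------

def fold_hopf(
    model: NeuralFieldModel,
    c_range: tuple[float, float] = (0.2, 6.0),
    n_bracket: int = 30,
    tol_c: float = 1e-4,
    modes: int = 12,
) -> FoldHopfPoint | None:
    """Intersection of the Hopf curve with the pitchfork line.

    Brackets ``sigma_H(c) - sigma0`` over ``c_range`` and bisects; returns
    None (range reported by the caller) when the branch does not cross.
    """
    sigma0 = pitchfork_gain(model)
    if sigma0 is None:
        return None

    def gap(c: float) -> float | None:
        pt = hopf_gain_at(model, c, modes=modes)
        return None if pt is None else pt.sigma - sigma0

    cs = np.linspace(c_range[0], c_range[1], n_bracket)
    gaps = [gap(float(c)) for c in cs]
    bracket = None
    for (c1, g1), (c2, g2) in zip(zip(cs, gaps), zip(cs[1:], gaps[1:])):
        if g1 is not None and g2 is not None and g1 * g2 < 0:
            bracket = (float(c1), float(c2))
            break
    if bracket is None:
        return None
    a, b = bracket
    while b - a > tol_c:
        mid = 0.5 * (a + b)
        gm = gap(mid)
        ga = gap(a)
        if gm is None or ga is None:
            break
        if ga * gm <= 0:
            b = mid
        else:
            a = mid
    c_star = 0.5 * (a + b)
    pt = hopf_gain_at(model, c_star, modes=modes)
    return FoldHopfPoint(
        c=float(c_star),
        sigma=float(sigma0),
        omega=float(pt.omega),
        mode_zero=_dominant_mode(model),
        mode_hopf=pt.mode,
    )


# ---------------------------------------------------------------------------
# stability map
# ---------------------------------------------------------------------------

def spectral_abscissa(
    model: NeuralFieldModel, c: float, sigma: float, modes: int = 10
) -> float:
    """Rightmost characteristic value of the trivial state at (c, sigma),
    from the per-mode characteristic equation."""
    lin = ring_at(model, c, sigma)
    best = -lin.l
    for k in range(modes + 1):
        roots = solve_mode_roots(lin, k, grid_density=(8, 10))
        if roots:
            best = max(best, max(r.lam.real for r in roots))
    return float(best)


def stability_map(
    model: NeuralFieldModel,
    c_values: Sequence[float],
    sigma_values: Sequence[float],
    modes: int = 10,
    hopf_modes: int = 12,
) -> BifurcationDiagram:
    """Characteristic-value verdict and both sufficient bounds over a grid.

    Produces the two-parameter stability diagram: the pitchfork line, the
    Hopf branch, the fold-Hopf point, the spectral abscissa per cell and the
    regions certified by the delay-dependent/-independent conditions.
    """
    from .bounds import delay_dependent_condition, delay_independent_condition, nondelayed_decay

    c_values = np.asarray(list(c_values), dtype=float)
    sigma_values = np.asarray(list(sigma_values), dtype=float)
    nc, ns = len(c_values), len(sigma_values)
    absc = np.full((nc, ns), np.nan)
    cv_ok = np.zeros((nc, ns), dtype=bool)
    c1 = np.zeros((nc, ns), dtype=bool)
    c2 = np.zeros((nc, ns), dtype=bool)
    flagged: list[tuple[int, int, str]] = []
    for i, c in enumerate(c_values):
        for j, s in enumerate(sigma_values):
            try:
                a = spectral_abscissa(model, float(c), float(s), modes=modes)
                absc[i, j] = a
                cv_ok[i, j] = a < 0
                lin = ring_at(model, float(c), float(s))
                dec = nondelayed_decay(lin)
                c2[i, j] = delay_independent_condition(lin)[0]
                c1[i, j] = delay_dependent_condition(lin, dec)[0]
            except Exception as exc:  # record, do not crash the map
                flagged.append((i, j, repr(exc)))
    branch = hopf_curve(model, c_values[c_values > 0], modes=hopf_modes)
    return BifurcationDiagram(
        sigma0=pitchfork_gain(model),
        hopf_branch=branch,
        fold_hopf=fold_hopf(model, (max(min(c_values), 0.1), max(c_values))),
        c_values=c_values,
        sigma_values=sigma_values,
        abscissa=absc,
        cv_stable=cv_ok,
        cond1=c1,
        cond2=c2,
        flagged=flagged,
    )
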