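"""Sufficient stability bounds that avoid computing characteristic values.

Two certified conditions are evaluated for a linearized state:

* **Delay-independent** (condition 2): if the Hilbert-Schmidt norm of the
  effective kernel is below the smallest leak rate,
  ``||J~||_{L2(Omega^2)} < l``, the state is asymptotically stable whatever
  the delays.  The sharper operator norm is also reported for information.

* **Delay-dependent** (condition 1): if the state is stable without delays
  (the non-delayed semigroup decays, ``||exp(t(-L0+J~))|| <= M_eps e^{-eps t}``
  with ``eps > 0``), a contraction argument on the variation-of-parameters
  formulation yields stability of the delayed equation whenever

      K(beta) = tau_max^{1-beta} * ||J~ tau^beta||_{L2(Omega^2)}
                * (1 + M_eps * ||A0|| / eps)  <  1

  for some exponent ``beta in (0, 1/2]``, where ``A0 = -L0 + J~`` is the
  non-delayed operator.  ``K`` is obtained by bounding the mismatch between
  delayed and instantaneous feedback through a Cauchy-Schwarz split of the
  kernel against ``tau^beta``; see the methods note for the derivation.  The
  constant vanishes with ``tau_max`` (small delays never destabilize a state
  that is stable without delays) and grows linearly in the delay scale ``c``
  on the ring, so it yields an admissible delay range per gain.

Both conditions are sufficient only: where they fail the state may well still
be stable, which only the characteristic values can decide.

The module also provides the square-integrability scan of inverse-power delay
kernels ``tau^{-beta}`` over a planar disk, whose divergence threshold at
``beta = 1`` delimits the exponents usable in two-dimensional domains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate as _sciint

from .model import CosineKernel, NeuralFieldModel
from .spectrum import LinearizedModel

__all__ = [
    "DecayEstimate",
    "BoundsReport",
    "nondelayed_decay",
    "kernel_l2_norm",
    "hs_norm",
    "op_norm",
    "weighted_kernel_norm",
    "delay_independent_condition",
    "contraction_constant",
    "delay_dependent_condition",
    "admissible_delay_scale",
    "evaluate_bounds",
    "disk_pair_integral",
    "square_integrability_scan",
    "integrability_threshold",
]


@dataclass
class DecayEstimate:
    """Exponential decay of the non-delayed linearized semigroup:
    ``||exp(t(-L0+J~))|| <= M_eps * exp(-eps t)``."""

    eps: float
    m_eps: float
    self_adjoint: bool


@dataclass
class BoundsReport:
    eps: float
    m_eps: float
    hs_norm: float
    op_norm: float
    tau_max: float
    beta_star: float | None
    alpha_star: float | None
    cond1: bool  # delay-dependent
    cond2: bool  # delay-independent
    margin1: float | None
    margin2: float
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# norms
# ---------------------------------------------------------------------------

def kernel_l2_norm(model: NeuralFieldModel) -> float:
    """``||J||_{L2(Omega^2)}`` of the raw connectivity kernel."""
    if isinstance(model.kernel, CosineKernel):
        return float(np.sqrt(model.grid.period * model.kernel.l2_density_norm_sq()))
    w = model.grid.weights
    k = model.kernel_matrix()
    return float(np.sqrt(np.einsum("i,k,abik->", w, w, k**2)))


def hs_norm(lin: LinearizedModel) -> float:
    """Hilbert-Schmidt norm ``||J~||_{L2(Omega^2)}`` of the effective kernel."""
    if lin.homogeneous:
        k = CosineKernel(
            [(w, lin.gamma * a) for w, a in lin.model.kernel.coeffs],
            lin.model.grid.period,
        )
        return float(np.sqrt(lin.model.grid.period * k.l2_density_norm_sq()))
    w = lin.model.grid.weights
    return float(np.sqrt(np.einsum("i,k,abik->", w, w, lin.jtilde**2)))


def op_norm(lin: LinearizedModel, modes: int = 64) -> float:
    """Operator norm of the effective kernel on weighted L2.

    Ring convolution: ``max_k |gamma * Jhat_k|``; otherwise the 2-norm of the
    symmetrically weighted matrix.
    """
    if lin.homogeneous:
        return max(abs(lin.mode_gain(k)) for k in range(modes + 1))
    p = lin.model.populations
    w = np.tile(lin.model.grid.weights, p)
    sw = np.sqrt(w)
    # J~ W is similar (via D^{1/2}) to D^{1/2} J~ D^{1/2}, which shares its
    # singular values with the weighted-L2 operator
    sym = sw[:, None] * (lin.weighted_matrix() / w[None, :]) * sw[None, :]
    return float(np.linalg.norm(sym, 2))


def weighted_kernel_norm(lin: LinearizedModel, beta: float, n_quad: int = 200) -> float:
    """``||J~ tau^beta||_{L2(Omega^2)}`` — the kernel weighted by the delay."""
    model = lin.model
    if lin.homogeneous:
        half = model.grid.period / 2
        xg, wg = leggauss(n_quad)
        z = (xg + 1) * (half / 2)
        w = wg * (half / 2)
        c = model.delay.c
        jz = lin.gamma * model.kernel(z)
        inner = 2.0 * np.sum(w * jz**2 * (c * z) ** (2 * beta))
        return float(np.sqrt(model.grid.period * inner))
    w = model.grid.weights
    tau = model.delay.tau_matrix(model.grid)
    return float(
        np.sqrt(np.einsum("i,k,abik->", w, w, lin.jtilde**2 * tau[None, None] ** (2 * beta)))
    )


# ---------------------------------------------------------------------------
# decay of the non-delayed semigroup
# ---------------------------------------------------------------------------

def nondelayed_decay(lin: LinearizedModel, modes: int = 64) -> DecayEstimate:
    """Decay rate ``eps = -max Re Sigma(-L0 + J~)`` and semigroup constant.

    The homogeneous ring convolution is self-adjoint, so the spectrum is
    ``{-l} ∪ {-l + g_k}`` and ``M_eps = 1``.  In the general case ``eps`` comes
    from the eigenvalues of the discretized operator; ``M_eps = 1`` if the
    weighted kernel matrix is symmetric, otherwise the eigenvector condition
    number is used as a computable bound.
    """
    if lin.homogeneous:
        g_max = max(lin.mode_gain(k) for k in range(modes + 1))
        eps = lin.l - max(g_max, 0.0)
        return DecayEstimate(eps=float(eps), m_eps=1.0, self_adjoint=True)
    a0 = lin.nondelayed_matrix()
    w = np.tile(lin.model.grid.weights, lin.model.populations)
    sym = np.sqrt(w)[:, None] * (a0 / w[None, :]) * np.sqrt(w)[None, :]
    if np.allclose(sym, sym.T, atol=1e-10):
        eig = np.linalg.eigvalsh(sym)
        return DecayEstimate(eps=float(-eig.max()), m_eps=1.0, self_adjoint=True)
    eig, vec = np.linalg.eig(a0)
    cond = float(np.linalg.cond(vec))
    return DecayEstimate(eps=float(-eig.real.max()), m_eps=cond, self_adjoint=False)


def _a0_norm(lin: LinearizedModel, modes: int = 64) -> float:
    """Operator norm of the non-delayed operator ``A0 = -L0 + J~``."""
    if lin.homogeneous:
        vals = [abs(-lin.l + lin.mode_gain(k)) for k in range(modes + 1)]
        return max(lin.l, max(vals))
    return float(np.linalg.norm(lin.nondelayed_matrix(), 2))


# ---------------------------------------------------------------------------
# the two sufficient conditions
# ---------------------------------------------------------------------------

def delay_independent_condition(lin: LinearizedModel) -> tuple[bool, float]:
    """Condition 2: ``||J~||_HS < l`` certifies stability for any delays.

    Returns (verdict, margin) with ``margin = l - ||J~||_HS``.
    """
    h = hs_norm(lin)
    margin = lin.l - h
    return margin > 0, float(margin)


def contraction_constant(
    beta: float,
    eps: float,
    m_eps: float,
    tau_max: float,
    lin: LinearizedModel,
) -> float:
    """The contraction value K(beta) of the delay-dependent condition.

    ``K = tau_max^(1-beta) * ||J~ tau^beta||_{L2} * (1 + M_eps ||A0|| / eps)``,
    valid for ``beta in (0, 1/2]``; stability is certified when K < 1.
    """
    if not 0 < beta <= 0.5:
        raise ValueError("beta must lie in (0, 1/2] for this bound")
    if eps <= 0:
        return np.inf
    if tau_max == 0:
        return 0.0
    wn = weighted_kernel_norm(lin, beta)
    return float(tau_max ** (1.0 - beta) * wn * (1.0 + m_eps * _a0_norm(lin) / eps))


def delay_dependent_condition(
    lin: LinearizedModel,
    decay: DecayEstimate | None = None,
    beta_grid: np.ndarray | None = None,
    alpha_max: float = 1.0,
) -> tuple[bool, float | None, float | None]:
    """Condition 1: scan ``beta`` for a contraction value below ``alpha_max``.

    Returns ``(verdict, beta_star, alpha_star)``.  Requires the state to be
    stable without delays (``decay.eps > 0``); otherwise the verdict is False
    immediately (the condition cannot certify anything).
    """
    if decay is None:
        decay = nondelayed_decay(lin)
    if decay.eps <= 0:
        return False, None, None
    if lin.tau_max == 0:
        return True, None, 0.0
    if beta_grid is None:
        beta_grid = np.geomspace(1e-3, 0.5, 40)
    best_beta, best_k = None, np.inf
    for beta in beta_grid:
        k = contraction_constant(float(beta), decay.eps, decay.m_eps, lin.tau_max, lin)
        if k < best_k:
            best_beta, best_k = float(beta), float(k)
    return best_k < alpha_max, best_beta, best_k


def admissible_delay_scale(lin: LinearizedModel, decay: DecayEstimate | None = None) -> float:
    """Largest ring delay scale ``c`` certified stable at this gain.

    On the ring ``K`` is proportional to ``c``, so the bound is
    ``c < c_ref / K(c_ref)``; returns 0 when the non-delayed state is already
    unstable and ``inf`` when the kernel vanishes.
    """
    if not lin.homogeneous:
        raise ValueError("the admissible delay scale is a ring quantity")
    if decay is None:
        decay = nondelayed_decay(lin)
    if decay.eps <= 0:
        return 0.0
    model = lin.model
    c_ref = model.delay.c
    if c_ref == 0:
        from .model import make_ring_model
        from .spectrum import linearize

        ref = make_ring_model(
            list(model.kernel.coeffs),
            c=1.0,
            sigma=model.sigmoid.gain,
            leak=float(model.leak[0]),
            s1=model.sigmoid.s1,
            n=model.n,
            period=model.grid.period,
            centered=model.sigmoid.centered,
        )
        lin = linearize(ref, lin.state)
        c_ref = 1.0
    _, _, alpha = delay_dependent_condition(lin, decay)
    if alpha == 0:
        return np.inf
    return float(c_ref / alpha)


def evaluate_bounds(lin: LinearizedModel, beta_grid: np.ndarray | None = None) -> BoundsReport:
    """Evaluate both sufficient conditions and collect the norms."""
    decay = nondelayed_decay(lin)
    h = hs_norm(lin)
    o = op_norm(lin)
    ok2, margin2 = delay_independent_condition(lin)
    ok1, beta_star, alpha_star = delay_dependent_condition(lin, decay, beta_grid)
    margin1 = None if alpha_star is None else 1.0 - alpha_star
    return BoundsReport(
        eps=decay.eps,
        m_eps=decay.m_eps,
        hs_norm=h,
        op_norm=o,
        tau_max=lin.tau_max,
        beta_star=beta_star,
        alpha_star=alpha_star,
        cond1=ok1,
        cond2=ok2,
        margin1=margin1,
        margin2=margin2,
        details={"self_adjoint": decay.self_adjoint},
    )


# ---------------------------------------------------------------------------
# square integrability of tau^-beta on a planar disk (2-D delay kernels)
# ---------------------------------------------------------------------------

def disk_pair_integral(beta: float, s_min: float, radius: float = 1.0) -> float:
    """``\\int\\int_{D^2, |r-r'| > s_min} |r - r'|^{-2 beta} dr dr'`` on the disk.

    Reduced to a radial integral through the autocorrelation of the disk
    indicator: the area of overlap of two unit disks at distance s is
    ``A(s) = 2 R^2 acos(s/2R) - (s/2) sqrt(4R^2 - s^2)``, giving

        I = \\int_{s_min}^{2R} s^{-2 beta} A(s) 2 pi s ds.
    """
    r = radius
    if s_min <= 0:
        raise ValueError("s_min must be positive (the point of the scan)")

    # substitute s = e^u: the integrand becomes smooth on [ln s_min, ln 2R]
    def integrand(u):
        s = np.exp(u)
        a = 2 * r * r * np.arccos(np.clip(s / (2 * r), -1, 1)) - (s / 2) * np.sqrt(
            max(4 * r * r - s * s, 0.0)
        )
        return 2 * np.pi * s ** (2.0 - 2.0 * beta) * a

    val, _ = _sciint.quad(integrand, np.log(s_min), np.log(2 * r), limit=400)
    return float(val)


def square_integrability_scan(
    betas,
    cutoffs: np.ndarray | None = None,
    ratio_tol: float = 0.98,
) -> dict[float, bool]:
    """Classify each exponent: is ``tau^{-beta}`` square-integrable on the disk?

    The integral with an inner cutoff ``s > s_min`` is evaluated on a sequence
    of shrinking cutoffs (decades).  The increments between successive decades
    behave like ``s_min^{2-2 beta}``, so their ratio tends to
    ``10^{-(2-2 beta)}``: a ratio below 1 (Cauchy criterion) signals a
    convergent integral, a ratio at or above 1 a divergent one.
    """
    if cutoffs is None:
        cutoffs = 10.0 ** -np.arange(2, 9)
    out: dict[float, bool] = {}
    for beta in betas:
        vals = np.array([disk_pair_integral(beta, s) for s in cutoffs])
        inc = np.diff(vals)
        if np.all(np.abs(inc) < 1e-12):
            out[float(beta)] = True
            continue
        ratios = inc[1:] / np.where(np.abs(inc[:-1]) < 1e-300, 1e-300, inc[:-1])
        out[float(beta)] = bool(ratios[-1] < ratio_tol)
    return out


def integrability_threshold(betas=None) -> float:
    """Smallest scanned exponent at which the pair integral diverges — the
    supremum of square-integrable exponents of the inverse-power delay kernel
    on a planar domain."""
    if betas is None:
        betas = [0.8, 0.9, 0.95, 0.99, 1.0, 1.05]
    verdicts = square_integrability_scan(betas)
    divergent = sorted(b for b, ok in verdicts.items() if not ok)
    if not divergent:
        return float("inf")
    return float(divergent[0])
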