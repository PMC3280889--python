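"""Model definitions for delayed neural field equations on a ring.

The field equation describes the mean membrane potential ``V(t, r)`` of ``p``
neural populations over a bounded domain (here a one-dimensional ring):

    dV_i/dt = -l_i V_i(t, r)
              + sum_j \\int J_ij(r, r') S[sigma_j (V_j(t - tau(r, r'), r') - h_j)] dr'
              + I_i^ext(t, r)

with leak rates ``l_i > 0``, a connectivity kernel ``J``, a bounded sigmoidal
firing-rate function ``S`` and a space-dependent propagation delay
``tau(r, r') = c * d(r, r')`` proportional to the ring distance ``d`` (``c`` is
the inverse propagation speed).  The reference configuration is a scalar
(``p = 1``) homogeneous field on the ring of circumference ``2*pi`` with
``J(x - y) = -1 + 1.5*cos(2(x - y))``, the saw-like delay ``c*d(x, y)`` and
unit leak.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpatialGrid",
    "SigmoidSpec",
    "DelaySpec",
    "CosineKernel",
    "MatrixKernel",
    "NeuralFieldModel",
    "sigmoid",
    "ring_distance",
    "make_ring_model",
    "fourier_cos_coefficient",
]


def _require_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def ring_distance(x, y, period: float):
    """Distance along a ring of circumference ``period``.

    Returns ``min(|x-y| mod period, period - |x-y| mod period)``; the maximum
    possible value is ``period / 2`` (antipodal points).
    """
    if not period > 0:
        raise ValueError("period must be positive")
    x = _require_finite(x, "x")
    y = _require_finite(y, "y")
    d = np.abs(x - y) % period
    return np.minimum(d, period - d)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform quadrature grid on a ring.

    ``nodes`` are angles in ``[-period/2, period/2)``; ``weights`` are the
    periodic-trapezoid quadrature weights (all equal to ``period / N``), which
    integrate trigonometric polynomials on the ring exactly.
    """

    nodes: np.ndarray
    weights: np.ndarray
    period: float
    dimension: int = 1

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("need at least two nodes")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        if abs(weights.sum() - self.period) > 1e-12 * max(1.0, self.period):
            raise ValueError("quadrature weights must sum to the period")

    @classmethod
    def uniform_ring(cls, n: int, period: float = 2 * np.pi) -> "SpatialGrid":
        if n < 4:
            raise ValueError("need at least 4 grid nodes")
        nodes = -period / 2 + period * np.arange(n) / n
        weights = np.full(n, period / n)
        return cls(nodes=nodes, weights=weights, period=period)

    @property
    def n(self) -> int:
        return self.nodes.size

    def integrate(self, values: np.ndarray) -> float:
        return float(np.sum(self.weights * values))

    def distance_matrix(self) -> np.ndarray:
        return ring_distance(self.nodes[:, None], self.nodes[None, :], self.period)


@dataclass(frozen=True)
class SigmoidSpec:
    """Sigmoidal firing-rate nonlinearity.

    The base sigmoid is a logistic rescaled so that its slope at the origin is
    ``s1``: ``S(x) = logistic(4 * s1 * x)`` (so ``s1 = 1/4`` recovers the plain
    logistic).  ``centered`` subtracts 1/2, giving an odd function with
    ``S0(0) = 0`` and range ``(-1/2, 1/2)``.  The firing rate of a population
    with potential ``V`` is ``S(gain * (V - threshold))``.
    """

    gain: float
    threshold: float = 0.0
    s1: float = 0.25
    centered: bool = True

    def __post_init__(self):
        if not self.gain >= 0:
            raise ValueError("gain must be >= 0")
        if not self.s1 > 0:
            raise ValueError("s1 must be > 0")

    def base(self, x):
        x = _require_finite(x, "sigmoid argument")
        v = 1.0 / (1.0 + np.exp(-4.0 * self.s1 * x))
        return v - 0.5 if self.centered else v

    def base_deriv(self, x):
        x = np.asarray(x, dtype=float)
        u = 1.0 / (1.0 + np.exp(-4.0 * self.s1 * x))
        return 4.0 * self.s1 * u * (1.0 - u)

    def fire(self, v):
        """Firing rate S(gain * (V - threshold))."""
        return self.base(self.gain * (np.asarray(v, dtype=float) - self.threshold))

    def fire_deriv(self, v):
        """d(firing rate)/dV; equals gain * s1 at the centered rest state."""
        return self.gain * self.base_deriv(self.gain * (np.asarray(v, dtype=float) - self.threshold))


def sigmoid(x, spec: SigmoidSpec):
    """Evaluate the (possibly centered) base sigmoid of ``spec`` at ``x``."""
    return spec.base(x)


class CosineKernel:
    """Homogeneous even connectivity kernel given as a cosine series.

    ``J(z) = sum_m a_m cos(w_m z)`` with wavenumbers ``w_m`` that are integer
    harmonics of the ring (``w_m * period / (2*pi)`` integer), so the kernel is
    ``period``-periodic and even.
    """

    def __init__(self, coeffs: Sequence[tuple[float, float]], period: float = 2 * np.pi):
        self.period = float(period)
        cleaned = []
        for w, a in coeffs:
            a = float(a)
            w = float(w)
            if not np.isfinite(a) or not np.isfinite(w):
                raise ValueError("kernel coefficients must be finite")
            harmonic = w * self.period / (2 * np.pi)
            if abs(harmonic - round(harmonic)) > 1e-9:
                raise ValueError(
                    f"wavenumber {w} is not compatible with period {self.period}: "
                    "the kernel would not be periodic"
                )
            cleaned.append((w, a))
        self.coeffs = tuple(cleaned)

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for w, a in self.coeffs:
            out = out + a * np.cos(w * z)
        return out

    def matrix(self, grid: SpatialGrid) -> np.ndarray:
        return self(grid.nodes[:, None] - grid.nodes[None, :])

    def l2_density_norm_sq(self) -> float:
        """``\\int_Omega J(z)^2 dz`` by Parseval (cosine orthogonality)."""
        p = self.period
        total = 0.0
        for w, a in self.coeffs:
            total += a * a * (p if w == 0 else p / 2)
        # cross terms vanish only between distinct wavenumbers; duplicates
        # are not merged, so handle them pairwise.
        ws = [w for w, _ in self.coeffs]
        for i in range(len(ws)):
            for j in range(i + 1, len(ws)):
                if ws[i] == ws[j]:
                    wi, ai = self.coeffs[i]
                    _, aj = self.coeffs[j]
                    total += 2 * ai * aj * (p if wi == 0 else p / 2)
        return total


class MatrixKernel:
    """Connectivity tabulated over the grid; shape (p, p, N, N)."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[None, None, :, :]
        if values.ndim != 4 or values.shape[0] != values.shape[1] or values.shape[2] != values.shape[3]:
            raise ValueError("kernel matrix must have shape (p, p, N, N) or (N, N)")
        if not np.all(np.isfinite(values)):
            raise ValueError("kernel values must be finite")
        self.values = values

    def matrix(self, grid: SpatialGrid) -> np.ndarray:
        if self.values.shape[-1] != grid.n:
            raise ValueError("kernel matrix does not match the grid size")
        return self.values


@dataclass(frozen=True)
class DelaySpec:
    """Propagation delay ``tau(r, r')``.

    The reference choice is ``tau = c * d(r, r')`` with ``d`` the ring
    distance, giving the saw-like delay profile with maximum
    ``tau_max = c * period / 2``.  A tabulated (N, N) matrix is accepted for
    general geometries.
    """

    c: float = 0.0
    matrix_values: np.ndarray | None = None
    ring: bool = True

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("inverse propagation speed c must be >= 0")
        if self.matrix_values is not None:
            m = np.asarray(self.matrix_values, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("delay matrix must be square")
            if np.any(m < 0) or not np.all(np.isfinite(m)):
                raise ValueError("delays must be finite and >= 0")
            object.__setattr__(self, "matrix_values", m)
            object.__setattr__(self, "ring", False)

    def tau(self, x, y, period: float):
        if not self.ring:
            raise ValueError("tabulated delay has no closed form; use tau_matrix")
        return self.c * ring_distance(x, y, period)

    def tau_matrix(self, grid: SpatialGrid) -> np.ndarray:
        if self.ring:
            return self.c * grid.distance_matrix()
        if self.matrix_values.shape[0] != grid.n:
            raise ValueError("delay matrix does not match the grid size")
        return self.matrix_values

    def tau_max(self, grid: SpatialGrid) -> float:
        if self.ring:
            return self.c * grid.period / 2
        return float(self.matrix_values.max())


@dataclass
class NeuralFieldModel:
    """Complete parameterization of the delayed neural field equation."""

    grid: SpatialGrid
    leak: np.ndarray
    kernel: CosineKernel | MatrixKernel
    delay: DelaySpec
    sigmoid: SigmoidSpec
    populations: int = 1
    i_ext: Callable[[float, np.ndarray], np.ndarray] | np.ndarray | float = 0.0

    def __post_init__(self):
        leak = np.atleast_1d(np.asarray(self.leak, dtype=float))
        if leak.size != self.populations:
            raise ValueError("leak must have one rate per population")
        if np.any(leak <= 0) or not np.all(np.isfinite(leak)):
            raise ValueError("leak rates must be positive and finite")
        self.leak = leak
        if isinstance(self.kernel, CosineKernel) and self.populations != 1:
            raise ValueError("cosine kernels are scalar; use a matrix kernel for p > 1")

    # -- basic derived quantities ------------------------------------------

    @property
    def n(self) -> int:
        return self.grid.n

    @property
    def homogeneous(self) -> bool:
        return isinstance(self.kernel, CosineKernel) and self.delay.ring

    @property
    def tau_max(self) -> float:
        return self.delay.tau_max(self.grid)

    @property
    def l_min(self) -> float:
        return float(self.leak.min())

    def kernel_matrix(self) -> np.ndarray:
        """Kernel values over the grid, shape (p, p, N, N)."""
        m = self.kernel.matrix(self.grid)
        if m.ndim == 2:
            m = m[None, None, :, :]
        return m

    def external_current(self, t: float) -> np.ndarray:
        """External current at time ``t``, shape (p, N)."""
        if callable(self.i_ext):
            out = np.asarray(self.i_ext(t, self.grid.nodes), dtype=float)
        else:
            out = np.asarray(self.i_ext, dtype=float)
        return np.broadcast_to(out, (self.populations, self.n)).astype(float)

    def rhs(self, t: float, v: np.ndarray, v_delayed: np.ndarray) -> np.ndarray:
        """Vector field with the delayed field ``v_delayed[j, i, i'] =
        V_j(t - tau(r_i, r_i'), r_i')`` supplied by the integrator."""
        k = self.kernel_matrix() * self.grid.weights[None, None, None, :]
        drive = np.einsum("abik,bik->ai", k, self.sigmoid.fire(v_delayed))
        return -self.leak[:, None] * v + drive + self.external_current(t)


def make_ring_model(
    cos_coeffs: Sequence[tuple[float, float]],
    c: float,
    sigma: float,
    leak: float = 1.0,
    s1: float = 0.25,
    n: int = 64,
    period: float = 2 * np.pi,
    threshold: float = 0.0,
    centered: bool = True,
    i_ext: float | np.ndarray | Callable = 0.0,
) -> NeuralFieldModel:
    """Scalar homogeneous neural field on the uniform ring.

    ``cos_coeffs`` is a list of ``(wavenumber, amplitude)`` pairs defining the
    even kernel ``J(z) = sum a*cos(w z)``; the delay is ``c`` times the ring
    distance, so ``tau_max = c * period / 2``.
    """
    if n < 8:
        raise ValueError("ring grid needs at least 8 nodes")
    grid = SpatialGrid.uniform_ring(n, period)
    kernel = CosineKernel(cos_coeffs, period)
    return NeuralFieldModel(
        grid=grid,
        leak=np.array([leak]),
        kernel=kernel,
        delay=DelaySpec(c=c),
        sigmoid=SigmoidSpec(gain=sigma, threshold=threshold, s1=s1, centered=centered),
        i_ext=i_ext,
    )


def fourier_cos_coefficient(model: NeuralFieldModel, k: int, method: str = "exact") -> float:
    """Cosine-mode coefficient ``Jhat_k = \\int_Omega J(z) cos(w_k z) dz`` of a
    homogeneous kernel, with ``w_k = 2*pi*k/period`` the k-th ring harmonic.

    ``method="exact"`` uses cosine orthogonality (exact for cosine-series
    kernels); ``method="quadrature"`` integrates on the grid with the periodic
    trapezoid rule, which is also exact for trigonometric polynomials resolved
    by the grid.
    """
    if not isinstance(model.kernel, CosineKernel):
        raise ValueError("Fourier coefficients require a homogeneous (cosine) kernel")
    if k < 0:
        raise ValueError("mode index must be >= 0")
    p = model.grid.period
    wk = 2 * np.pi * k / p
    if method == "quadrature":
        z = model.grid.nodes
        return float(np.sum(model.grid.weights * model.kernel(z) * np.cos(wk * z)))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'quadrature'")
    total = 0.0
    for w, a in model.kernel.coeffs:
        if abs(w - wk) < 1e-12:
            total += a * (p if k == 0 else p / 2)
    return total
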