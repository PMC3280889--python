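"""Time integration of the delayed field equation.

The integrator is a fixed-step explicit Runge-Kutta 4 scheme in which the
delayed field values are read from a cubic (4-point Lagrange) interpolant of
the already-committed solution samples, stored on a uniform time grid with
step ``dt``.  Queries that fall past the last committed sample (which happens
for vanishing delays at the later stages of a step) are served by evaluating
the same cubic beyond its last node, i.e. a short extrapolation of at most one
step.  The scheme is convergent; its empirical order is measured in the test
suite rather than asserted a priori.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import NeuralFieldModel

__all__ = [
    "HistorySegment",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "ultimate_bound",
    "random_history",
]


class IntegrationError(RuntimeError):
    """Raised when the state stops being finite or explodes."""

    def __init__(self, message: str, t_bad: float):
        super().__init__(message)
        self.t_bad = t_bad


@dataclass
class HistorySegment:
    """Initial history ``phi`` on ``[-tau_max, 0]``.

    ``values`` has shape (T, p, N) sampled at ``times`` (increasing, spanning
    at least ``[-tau_max, 0]``).  Piecewise-cubic evaluation; queries outside
    the sampled span raise.
    """

    times: np.ndarray
    values: np.ndarray
    interpolation_order: int = 3

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("history times must be strictly increasing")
        if self.values.shape[0] != self.times.size:
            raise ValueError("values must have one sample per time")

    @classmethod
    def constant(cls, v0: np.ndarray, tau_max: float) -> "HistorySegment":
        v0 = np.atleast_2d(np.asarray(v0, dtype=float))
        span = max(tau_max, 1e-12)
        times = np.array([-span, 0.0])
        return cls(times=times, values=np.stack([v0, v0]))

    @classmethod
    def from_function(
        cls, phi: Callable[[float], np.ndarray], tau_max: float, dt: float
    ) -> "HistorySegment":
        span = max(tau_max, dt)
        m = max(2, int(np.ceil(span / dt)) + 1)
        times = np.linspace(-span, 0.0, m)
        values = np.stack([np.atleast_2d(np.asarray(phi(t), dtype=float)) for t in times])
        return cls(times=times, values=values)

    def __call__(self, t: float) -> np.ndarray:
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(f"history evaluated outside its span at t={t}")
        return np.stack(
            [
                [np.interp(t, self.times, self.values[:, a, i]) for i in range(self.values.shape[2])]
                for a in range(self.values.shape[1])
            ]
        )


@dataclass
class Trajectory:
    """Solution samples ``V(t_k, r_i)`` with the weighted L2 norm per time."""

    times: np.ndarray
    values: np.ndarray  # (T, p, N)
    norms: np.ndarray
    dt: float
    meta: dict

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]

    def norm_tail(self, fraction: float = 0.3) -> np.ndarray:
        k = max(1, int(len(self.norms) * fraction))
        return self.norms[-k:]


def _l2_norms(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("tai,i->t", values**2, weights))


def _lagrange_cubic_weights(s: np.ndarray):
    """Weights of the 4-point Lagrange cubic at offsets (-1, 0, 1, 2)."""
    return (
        -s * (s - 1) * (s - 2) / 6.0,
        (s + 1) * (s - 1) * (s - 2) / 2.0,
        -(s + 1) * s * (s - 2) / 2.0,
        (s + 1) * s * (s - 1) / 6.0,
    )


def integrate(
    model: NeuralFieldModel,
    phi: HistorySegment | np.ndarray | float,
    t_end: float,
    dt: float = 1e-2,
    store_every: int = 1,
    blowup_factor: float = 100.0,
) -> Trajectory:
    """Integrate the delayed field equation from history ``phi`` to ``t_end``.

    ``phi`` may be a :class:`HistorySegment`, a constant field (array of shape
    (p, N) or scalar), or a callable ``t -> field``.  The solution is computed
    on a uniform grid of step ``dt`` and stored every ``store_every`` steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p, n = model.populations, model.n
    tau_m = model.tau_max
    if tau_m > 0 and dt > tau_m / 4:
        import warnings

        warnings.warn(
            f"dt={dt} exceeds tau_max/4={tau_m / 4:.3g}; delayed values are "
            "interpolated coarsely",
            stacklevel=2,
        )

    if callable(phi) and not isinstance(phi, HistorySegment):
        phi = HistorySegment.from_function(phi, tau_m, dt)
    elif not isinstance(phi, HistorySegment):
        v0 = np.broadcast_to(np.asarray(phi, dtype=float), (p, n)).copy()
        phi = HistorySegment.constant(v0, tau_m)
    if phi.times[0] > -tau_m + 1e-12 and tau_m > 0:
        raise ValueError("history must span [-tau_max, 0]")

    n_hist = max(1, int(np.ceil(tau_m / dt))) + 2
    n_steps = int(np.round(t_end / dt))
    t0 = -n_hist * dt
    buf = np.empty((n_hist + n_steps + 1, p, n))
    for k in range(n_hist + 1):
        t = t0 + k * dt
        buf[k] = phi(np.clip(t, phi.times[0], phi.times[-1]))

    tau = model.delay.tau_matrix(model.grid)  # (N, N)
    kq = model.kernel_matrix() * model.grid.weights[None, None, None, :]
    leak = model.leak[:, None]
    r_bound = ultimate_bound(model)
    guard = blowup_factor * max(r_bound, 1.0)
    w = model.grid.weights

    def delayed_field(t_query: float, committed: int) -> np.ndarray:
        """V_j(t_query - tau[i, i'], r_i') for all (j, i, i'), shape (p,N,N)."""
        tq = t_query - tau  # (N, N)
        u = (tq - t0) / dt
        i0 = np.clip(np.floor(u).astype(int), 1, committed - 2)
        s = u - i0
        w_m1, w_0, w_1, w_2 = _lagrange_cubic_weights(s)
        cols = np.broadcast_to(np.arange(n)[None, :], (n, n))
        out = (
            w_m1[None] * buf[i0 - 1, :, cols].transpose(2, 0, 1)
            + w_0[None] * buf[i0, :, cols].transpose(2, 0, 1)
            + w_1[None] * buf[i0 + 1, :, cols].transpose(2, 0, 1)
            + w_2[None] * buf[i0 + 2, :, cols].transpose(2, 0, 1)
        )
        return out

    def rhs(t: float, v: np.ndarray, committed: int) -> np.ndarray:
        vd = delayed_field(t, committed)
        drive = np.einsum("abik,bik->ai", kq, model.sigmoid.fire(vd))
        return -leak * v + drive + model.external_current(t)

    for step in range(n_steps):
        k = n_hist + step
        t = t0 + k * dt
        v = buf[k]
        k1 = rhs(t, v, k)
        k2 = rhs(t + dt / 2, v + dt / 2 * k1, k)
        k3 = rhs(t + dt / 2, v + dt / 2 * k2, k)
        k4 = rhs(t + dt, v + dt * k3, k)
        v_new = v + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(v_new)):
            raise IntegrationError(f"non-finite state at t={t + dt:.6g}", t + dt)
        norm = float(np.sqrt(np.sum(w * v_new**2)))
        if norm > guard:
            raise IntegrationError(
                f"norm {norm:.3g} exceeded the blow-up guard {guard:.3g} at t={t + dt:.6g}",
                t + dt,
            )
        buf[k + 1] = v_new

    idx = np.arange(0, n_steps + 1, store_every)
    times = idx * dt
    values = buf[n_hist + idx]
    return Trajectory(
        times=times,
        values=values,
        norms=_l2_norms(values, w),
        dt=dt,
        meta={"tau_max": tau_m, "ultimate_bound": r_bound, "dt": dt},
    )


def ultimate_bound(model: NeuralFieldModel) -> float:
    """Radius of the attracting ball: all trajectories eventually satisfy
    ``||V|| <= R`` with

        R = (sqrt(p * |Omega|) * ||J||_{L2(Omega^2)} + ||I_ext||_{L2}) / min_i l_i

    using that the firing rate is bounded by 1.  Requires a time-constant
    external current.
    """
    from .bounds import kernel_l2_norm

    omega = model.grid.period
    j_norm = kernel_l2_norm(model)
    i0 = model.external_current(0.0)
    i1 = model.external_current(1.0)
    if not np.allclose(i0, i1):
        raise ValueError("ultimate bound requires a time-constant external current")
    i_norm = float(np.sqrt(np.sum(model.grid.weights[None, :] * i0**2)))
    return (np.sqrt(model.populations * omega) * j_norm + i_norm) / model.l_min


def random_history(
    model: NeuralFieldModel, amplitude: float = 0.1, seed: int = 0
) -> HistorySegment:
    """Random-in-space, constant-in-time initial condition: V uniform in
    ``[-amplitude, amplitude]`` per node."""
    rng = np.random.default_rng(seed)
    v0 = rng.uniform(-amplitude, amplitude, size=(model.populations, model.n))
    return HistorySegment.constant(v0, model.tau_max)
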