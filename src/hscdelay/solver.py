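"""Constant-delay DDE integration by the method of steps.

A system with a single constant delay ``tau`` can be integrated exactly in
structure: on each window no longer than ``tau``, the delayed lookup
``y(t - tau)`` falls entirely inside already-computed history, so the
window is an ordinary ODE initial-value problem.  We solve each window
with an adaptive explicit Runge-Kutta core (``scipy``'s RK45) and keep its
piecewise-polynomial dense output, which then serves as the delayed lookup
for subsequent windows.

Discontinuity handling: a DDE with constant history generically has a
derivative jump at t=0 that propagates to t = k*tau with one extra order
of smoothness per generation; treatment switch-on times and their decay
breakpoints do the same.  Integration windows never straddle any of these
points (tracked for a configurable number of delay generations), so the
Runge-Kutta core only ever sees smooth right-hand sides.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .model import (
    ModelParameters,
    TreatmentSchedule,
    eval_beta_N,
    eval_g_C,
    eval_g_HIA,
    rhs_raw,
)

__all__ = [
    "SolverOptions",
    "HistoryFunction",
    "constant_history",
    "Trajectory",
    "IntegrationError",
    "solve_dde",
    "integrate_dde",
    "detect_steady_state",
    "nadir",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator fails; carries the failure time."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (at t = {t:.6g} d)")
        self.t = t


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options of the method-of-steps integrator.

    ``breakpoints`` are extra times where the right-hand side or its
    derivatives jump; they are merged with the automatically propagated
    delay images.  ``smoothing_order`` is the number of delay generations
    for which discontinuity images are tracked (each generation gains one
    order of smoothness, so deeper images are negligible at the default
    tolerances).  With ``nonneg_guard`` on, states below ``-1e-9`` abort
    the run; smaller undershoot is clamped inside rate evaluations only.
    """

    rtol: float = 1e-8
    atol: float = 1e-8
    max_step: float = 0.1
    breakpoints: tuple[float, ...] = ()
    smoothing_order: int = 3
    nonneg_guard: bool = True

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")


@dataclass(frozen=True)
class HistoryFunction:
    """Initial history: state of the system on ``[t_min, t_max]``.

    ``evaluator`` maps any time in the span to the state vector; queries
    outside the span are refused rather than extrapolated.
    """

    span: tuple[float, float]
    evaluator: Callable[[float], np.ndarray]

    def __call__(self, t: float) -> np.ndarray:
        lo, hi = self.span
        if t < lo - 1e-12 or t > hi + 1e-12:
            raise ValueError(f"history query t={t!r} outside span [{lo}, {hi}]")
        return np.asarray(self.evaluator(min(max(t, lo), hi)), dtype=float)


def constant_history(values: Sequence[float], tau: float) -> HistoryFunction:
    """Constant history ``y(t) = values`` on ``[-tau, 0]``."""
    arr = np.asarray(values, dtype=float)
    return HistoryFunction(span=(-tau, 0.0), evaluator=lambda t: arr.copy())


class _DenseSolution:
    """Piecewise dense solution: initial history plus RK dense segments."""

    def __init__(self, history: HistoryFunction):
        self._history = history
        self._t_ends: list[float] = []   # right edge of each RK segment
        self._segments: list = []        # scipy OdeSolution objects
        self.t_max = history.span[1]

    def append(self, sol) -> None:
        self._t_ends.append(float(sol.ts[-1]))
        self._segments.append(sol)
        self.t_max = float(sol.ts[-1])

    def eval(self, t: float) -> np.ndarray:
        if t <= self._history.span[1]:
            return self._history(t)
        if t > self.t_max + 1e-9:
            raise ValueError(f"dense query t={t!r} beyond computed span")
        i = bisect.bisect_left(self._t_ends, t)
        i = min(i, len(self._segments) - 1)
        return self._segments[i](min(t, self.t_max))

    def eval_array(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        out = np.empty((ts.size,) + self.eval(ts.flat[0]).shape, dtype=float)
        for j, t in enumerate(ts.flat):
            out[j] = self.eval(float(t))
        return out


class Trajectory:
    """Densely evaluable solution of one integration run.

    Stores the accepted-step samples of ``(t, P, N)`` together with the
    instantaneous diagnostics ``g_HIA``, ``g_C`` and ``beta(N)``, and
    supports evaluation at arbitrary times within the span through the
    solver's piecewise-polynomial dense output.
    """

    def __init__(
        self,
        t: np.ndarray,
        y: np.ndarray,
        dense: _DenseSolution,
        params: ModelParameters,
        schedule: TreatmentSchedule,
    ):
        self.t = np.asarray(t, dtype=float)
        self.P = np.asarray(y[:, 0], dtype=float)
        self.N = np.asarray(y[:, 1], dtype=float)
        self._dense = dense
        self.params = params
        self.schedule = schedule
        self.g_HIA = np.array(
            [
                eval_g_HIA(ti - schedule.hia_onset, params)
                if (schedule.hia_on and ti >= schedule.hia_onset
                    and schedule.hia_time_dependent)
                else 1.0
                for ti in self.t
            ]
        )
        self.g_C = np.array(
            [
                eval_g_C(ti - schedule.cta_onset, params)
                if (schedule.cta_on and ti >= schedule.cta_onset)
                else 1.0
                for ti in self.t
            ]
        )
        self.beta_N = np.array([eval_beta_N(max(v, 0.0), params) for v in self.N])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def __call__(self, t):
        """Evaluate (P, N) at scalar or array ``t`` within the span."""
        if np.isscalar(t):
            y = self._dense.eval(float(t))
            return float(y[0]), float(y[1])
        ys = self._dense.eval_array(np.asarray(t, dtype=float))
        return ys[:, 0], ys[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "P": self.P,
                "N": self.N,
                "g_HIA": self.g_HIA,
                "g_C": self.g_C,
                "beta_N": self.beta_N,
            }
        )

    def resample(self, dt: float) -> pd.DataFrame:
        """Uniformly resampled table at spacing ``dt`` days."""
        t0, t1 = self.span
        ts = np.arange(t0, t1 + 0.5 * dt, dt)
        ts[-1] = min(ts[-1], t1)
        P, N = self(ts)
        return pd.DataFrame(
            {
                "t": ts,
                "P": P,
                "N": N,
                "g_HIA": [
                    eval_g_HIA(ti - self.schedule.hia_onset, self.params)
                    if (self.schedule.hia_on and ti >= self.schedule.hia_onset
                        and self.schedule.hia_time_dependent)
                    else 1.0
                    for ti in ts
                ],
                "g_C": [
                    eval_g_C(ti - self.schedule.cta_onset, self.params)
                    if (self.schedule.cta_on and ti >= self.schedule.cta_onset)
                    else 1.0
                    for ti in ts
                ],
                "beta_N": [eval_beta_N(max(v, 0.0), self.params) for v in N],
            }
        )


def _assemble_breakpoints(
    tau: float,
    t_end: float,
    base_points: Sequence[float],
    smoothing_order: int,
) -> list[float]:
    """Base discontinuity times plus their +k*tau images, deduplicated."""
    pts: set[float] = set()
    for b in list(base_points) + [0.0]:
        for k in range(smoothing_order + 1):
            img = b + k * tau
            if 0.0 < img < t_end:
                pts.add(img)
    out: list[float] = []
    for p in sorted(pts):
        if not out or p - out[-1] > 1e-9:
            out.append(p)
    return out


def solve_dde(
    f: Callable[[float, np.ndarray, np.ndarray], Sequence[float]],
    tau: float,
    history: HistoryFunction,
    t_end: float,
    options: SolverOptions = SolverOptions(),
    base_breakpoints: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray, _DenseSolution]:
    """Integrate ``y'(t) = f(t, y(t), y(t - tau))`` over ``[0, t_end]``.

    ``history`` must cover ``[-tau, 0]``; its value at 0 is the initial
    state.  With ``tau == 0`` the equation degenerates to an ODE and the
    delayed argument is the current state.  Returns sample times, states
    at samples (rows), and the dense solution object.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau > 0 and history.span[0] > -tau + 1e-12:
        raise ValueError("history must cover [-tau, 0]")

    dense = _DenseSolution(history)
    y0 = history(0.0)

    if tau > 0:
        def f_ivp(t, y):
            return f(t, y, dense.eval(t - tau))
    else:
        def f_ivp(t, y):
            return f(t, y, y)

    cuts = _assemble_breakpoints(
        tau, t_end, list(base_breakpoints) + list(options.breakpoints),
        options.smoothing_order,
    )
    edges = [0.0] + cuts + [t_end]

    # windows never exceed tau (method of steps) nor straddle a breakpoint
    windows: list[tuple[float, float]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 1e-12:
            continue
        n_sub = max(1, int(math.ceil((b - a) / tau))) if tau > 0 else 1
        sub = np.linspace(a, b, n_sub + 1)
        windows.extend(zip(sub[:-1], sub[1:]))

    ts: list[float] = [0.0]
    ys: list[np.ndarray] = [y0]
    y = y0
    for a, b in windows:
        sol = solve_ivp(
            f_ivp,
            (a, b),
            y,
            method="RK45",
            rtol=options.rtol,
            atol=options.atol,
            max_step=options.max_step,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(f"solver failure: {sol.message}", a)
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError("non-finite state", float(sol.t[-1]))
        if options.nonneg_guard and sol.y.min() < -1e-9:
            t_bad = float(sol.t[int(np.argmin(sol.y.min(axis=0)))])
            raise IntegrationError(
                f"state negativity beyond guard tolerance ({sol.y.min():.3g})",
                t_bad,
            )
        dense.append(sol.sol)
        ts.extend(sol.t[1:].tolist())
        ys.extend(list(sol.y.T[1:]))
        y = sol.y[:, -1]

    return np.asarray(ts), np.asarray(ys), dense


def integrate_dde(
    params: ModelParameters,
    schedule: TreatmentSchedule,
    history: HistoryFunction,
    t_end: float,
    options: SolverOptions = SolverOptions(),
) -> Trajectory:
    """Integrate the HSC model over ``[0, t_end]`` and return a Trajectory.

    Breakpoints contributed by the schedule (treatment switch-on and the
    decay-clock corners ``onset + tau1/tau2/tau3``) are handled
    automatically along with the usual ``k*tau`` history images.
    """
    base: list[float] = []
    if schedule.hia_on:
        base.append(schedule.hia_onset)
        if schedule.hia_time_dependent:
            base.append(schedule.hia_onset + params.tau1)
    if schedule.cta_on:
        base.append(schedule.cta_onset)
        base.append(schedule.cta_onset + params.tau2)
        base.append(schedule.cta_onset + params.tau3)

    def f(t, y, ylag):
        return rhs_raw(t, y[0], y[1], ylag[1], schedule, params)

    ts, ys, dense = solve_dde(
        f, params.tau, history, t_end, options, base_breakpoints=base
    )
    return Trajectory(ts, ys, dense, params, schedule)


def detect_steady_state(
    traj: Trajectory,
    window: float = 50.0,
    rel_tol: float = 1e-6,
) -> tuple[bool, tuple[float, float], float]:
    """Earliest time at which the solution has settled.

    The system counts as settled at time ``t`` when the peak-to-peak
    variation of both P and N over the trailing ``window`` days is below
    ``rel_tol`` relative to their window means.  Returns
    ``(reached, (P, N), time)`` where the value is the trailing-window
    mean at the detection time (at the end of the span if never reached).
    """
    t0, t1 = traj.span
    if window >= t1 - t0:
        raise ValueError("window must be shorter than the trajectory span")
    if traj.t.size == 0:
        raise ValueError("empty trajectory")

    dt = min(0.25, window / 50.0)
    ts = np.arange(t0, t1 + 0.5 * dt, dt)
    P, N = traj(ts)
    k = max(2, int(round(window / dt)))

    def rolling_ok(x: np.ndarray) -> np.ndarray:
        s = pd.Series(x)
        rng = s.rolling(k).max() - s.rolling(k).min()
        mean = s.rolling(k).mean().abs()
        return (rng / np.maximum(mean, 1e-8)).to_numpy()

    var = np.fmax(rolling_ok(P), rolling_ok(N))
    ok = np.flatnonzero(var < rel_tol)
    if ok.size:
        i = int(ok[0])
        sl = slice(i - k + 1, i + 1)
        return True, (float(P[sl].mean()), float(N[sl].mean())), float(ts[i])
    sl = slice(len(ts) - k, len(ts))
    return False, (float(P[sl].mean()), float(N[sl].mean())), float("nan")


def nadir(traj: Trajectory, after: float = 0.0) -> tuple[float, float]:
    """Global minimum of P over ``[after, span end]``.

    Located on a fine uniform grid of the dense solution, then refined
    with a bounded scalar minimization around the grid minimum.
    """
    t0, t1 = traj.span
    if not (t0 <= after <= t1):
        raise ValueError("'after' must lie within the trajectory span")
    ts = np.linspace(after, t1, max(2000, int((t1 - after) / 0.05) + 1))
    P, _ = traj(ts)
    i = int(np.argmin(P))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, len(ts) - 1)]
    if hi - lo < 1e-12:
        return float(ts[i]), float(P[i])
    res = minimize_scalar(
        lambda t: traj(float(t))[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if res.fun <= P[i]:
        return float(res.x), float(res.fun)
    return float(ts[i]), float(P[i])
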