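"""Steady states of the model: closed form, existence bound, numeric root.

With the delayed terms evaluated at equilibrium (``N_tau = N*``) and the
treatment terms replaced by constant rates ``b_HIA`` and ``b_C``, the
system has the trivial state ``P* = N* = 0`` (hematopoietic collapse) and,
when it exists, a unique positive equilibrium.  Writing
``E = exp(-gamma*tau)`` and ``D = delta + b_HIA - b_C``, the quiescent
equation decouples::

    beta(N*) = D / (2E - 1)
    N*       = theta * [ beta0*(2E - 1)/D - 1 ]**(1/n)
    P*       = (N*/gamma) * [ (b_HIA - b_C) + D*(1 - E)/(2E - 1) ]

The positive state exists iff the bracket is positive, equivalently::

    0 < gamma*tau < ln( 2*beta0 / (D + beta0) )

i.e. in-cycle apoptosis must not consume the doubling gained in mitosis.
A positive chemotherapy rate ``b_C`` lowers ``D`` and therefore *raises*
the admissible ``gamma*tau`` range.

Two notions of the effective treatment rates are exposed, because the
closed-form algebra uses bare constants while the simulated model uses
Hill-weighted, time-decaying rates:

* ``constants`` mode reproduces the algebra above for caller-supplied
  ``b_HIA``, ``b_C``;
* ``late_time_limits`` mode solves the coupled system with the treatment
  Hills evaluated at their long-time decay limits (``g_HIA -> 0``;
  ``g_C -> exp(-s2*(tau3 - tau2))``, its frozen residual), which is what
  the simulation actually plateaus at after one administration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .model import ModelParameters

__all__ = [
    "SteadyState",
    "closed_form_steady_state",
    "existence_condition",
    "numeric_steady_state",
    "hill_slope",
]


@dataclass(frozen=True)
class SteadyState:
    """A (P*, N*) equilibrium with its provenance.

    ``exists`` is the positive-equilibrium existence verdict; when it is
    False the values are ``None`` (never NaN).  ``effective_bHIA`` and
    ``effective_bC`` record the constant treatment rates at which the
    algebraic system was solved (for ``late_time_limits`` solutions these
    are the Hill-weighted rates evaluated at the returned ``P*``).
    """

    P_star: Optional[float]
    N_star: Optional[float]
    method: Literal["closed_form", "numeric", "trivial"]
    exists: bool
    effective_bHIA: float = 0.0
    effective_bC: float = 0.0

    def as_tuple(self) -> tuple[float, float]:
        if self.P_star is None or self.N_star is None:
            raise ValueError("steady state does not exist; no values to unpack")
        return self.P_star, self.N_star


def hill_slope(N: float, params: ModelParameters) -> float:
    """Normalized slope F of the quiescent efflux at population N.

    ``F = theta^n * (theta^n + (1-n)*N^n) / (theta^n + N^n)^2``, so that
    ``beta0 * F`` is the derivative d[beta(N)*N]/dN.  Negative F (possible
    only for n > 1) means the total efflux from quiescence *falls* as the
    pool grows — the destabilizing regime of the delayed feedback.
    """
    th = params.theta ** params.n
    Nn = N ** params.n
    return th * (th + (1.0 - params.n) * Nn) / (th + Nn) ** 2


def existence_condition(
    params: ModelParameters, b_hia: float = 0.0, b_c: float = 0.0
) -> tuple[bool, float, float]:
    """Existence bound for the positive equilibrium.

    Returns ``(holds, gamma_tau, bound)`` with
    ``bound = ln(2*beta0 / (delta + b_hia - b_c + beta0))``; the positive
    state exists iff ``0 < gamma*tau < bound`` (and the loss balance
    ``delta + b_hia - b_c`` is positive, which the bound being below
    ``ln 2`` encodes).
    """
    arg = params.delta + b_hia - b_c + params.beta0
    if arg <= 0:
        raise ValueError(
            "existence bound undefined: delta + b_HIA - b_C + beta0 <= 0"
        )
    gamma_tau = params.gamma * params.tau
    bound = math.log(2.0 * params.beta0 / arg)
    holds = 0.0 < gamma_tau < bound and (params.delta + b_hia - b_c) > 0
    return holds, gamma_tau, bound


def closed_form_steady_state(
    params: ModelParameters, b_hia: float = 0.0, b_c: float = 0.0
) -> SteadyState:
    """Positive equilibrium from the closed-form expressions.

    The treatment terms are held at the constant rates ``b_hia``, ``b_c``
    (no Hill weighting, no decay).  If the existence condition fails the
    state is flagged as absent and carries no values.
    """
    E = params.survival()
    D = params.delta + b_hia - b_c
    two_e = 2.0 * E - 1.0
    exists = False
    if D > 0 and two_e > 0:
        bracket = params.beta0 * two_e / D - 1.0
        exists = bracket > 0
    if not exists:
        return SteadyState(None, None, "closed_form", False, b_hia, b_c)
    N_star = params.theta * bracket ** (1.0 / params.n)
    P_star = (N_star / params.gamma) * ((b_hia - b_c) + D * (1.0 - E) / two_e)
    return SteadyState(P_star, N_star, "closed_form", True, b_hia, b_c)


def _effective_rates(
    P: float,
    params: ModelParameters,
    mode: str,
    b_hia: float,
    b_c: float,
    cta_on: bool,
) -> tuple[float, float, float, float]:
    """(b_HIA, b_C, db_HIA/dP, db_C/dP) at proliferating population P."""
    if mode == "constants":
        return b_hia, b_c, 0.0, 0.0
    # late_time_limits: the HIA factor g_HIA decays to 0; the CTA factor
    # freezes at its residual, so only the CTA Hill survives.
    if not cta_on:
        return 0.0, 0.0, 0.0, 0.0
    residual = math.exp(-params.s2 * (params.tau3 - params.tau2))
    th = params.theta2 ** params.w
    Pw = P ** params.w if P > 0 else 0.0
    h = Pw / (th + Pw)
    dh = (
        params.w * th * P ** (params.w - 1.0) / (th + Pw) ** 2
        if P > 0
        else (1.0 / params.theta2 if params.w == 1.0 else 0.0)
    )
    return 0.0, params.beta0_C * residual * h, 0.0, params.beta0_C * residual * dh


def _residuals_and_jacobian(
    P: float,
    N: float,
    params: ModelParameters,
    mode: str,
    b_hia: float,
    b_c: float,
    cta_on: bool,
) -> tuple[np.ndarray, np.ndarray]:
    E = params.survival()
    th = params.theta ** params.n
    Nn = N ** params.n if N > 0 else 0.0
    beta = params.beta0 * th / (th + Nn)
    phi = beta * N
    dphi = params.beta0 * hill_slope(N, params)
    bh, bc, dbh, dbc = _effective_rates(P, params, mode, b_hia, b_c, cta_on)

    r1 = -params.gamma * P + (1.0 - E) * phi + (bh - bc) * N
    r2 = (2.0 * E - 1.0) * phi - params.delta * N - (bh - bc) * N
    jac = np.array(
        [
            [-params.gamma + (dbh - dbc) * N, (1.0 - E) * dphi + (bh - bc)],
            [-(dbh - dbc) * N, (2.0 * E - 1.0) * dphi - params.delta - (bh - bc)],
        ]
    )
    return np.array([r1, r2]), jac


def numeric_steady_state(
    params: ModelParameters,
    mode: Literal["constants", "late_time_limits"] = "constants",
    guess: Optional[tuple[float, float]] = None,
    b_hia: float = 0.0,
    b_c: float = 0.0,
    cta_on: bool = True,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> SteadyState:
    """Numeric root of the algebraic steady-state system.

    Damped Newton iteration with the analytic Jacobian; in ``constants``
    mode a bisection fallback on the decoupled (scalar, monotone) N
    equation re-seeds the iteration if Newton stalls.  Converged solutions
    satisfy both residuals below 1e-10 in absolute value.
    """
    if guess is None:
        cf = closed_form_steady_state(params)
        guess = cf.as_tuple() if cf.exists else (50.0, 100.0)
    if guess[0] <= 0 or guess[1] <= 0:
        raise ValueError("guess must be positive")

    def newton(x0: np.ndarray) -> Optional[np.ndarray]:
        x = x0.copy()
        r, jac = _residuals_and_jacobian(
            x[0], x[1], params, mode, b_hia, b_c, cta_on
        )
        for _ in range(max_iter):
            if np.max(np.abs(r)) < tol:
                return x
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            norm0 = np.max(np.abs(r))
            while lam > 1e-12:
                x_new = x + lam * step
                if x_new[1] > 0 and x_new[0] > -params.theta2:
                    r_new, jac_new = _residuals_and_jacobian(
                        max(x_new[0], 0.0), x_new[1], params, mode,
                        b_hia, b_c, cta_on,
                    )
                    if np.max(np.abs(r_new)) < norm0:
                        x, r, jac = x_new, r_new, jac_new
                        break
                lam *= 0.5
            else:
                return None
        return x if np.max(np.abs(r)) < 1e-10 else None

    def decoupled_seed(bh: float, bc: float) -> Optional[np.ndarray]:
        # beta(N)*(2E-1) = delta + bh - bc is scalar and monotone in N;
        # P then follows linearly from the proliferating equation
        E = params.survival()
        D = params.delta + bh - bc
        two_e = 2.0 * E - 1.0
        if not (D > 0 and two_e > 0 and params.beta0 * two_e > D):
            return None
        th = params.theta ** params.n

        def g(N):
            return params.beta0 * th / (th + N ** params.n) * two_e - D

        hi = params.theta
        while g(hi) > 0:
            hi *= 2.0
        N0 = brentq(g, 1e-12, hi, xtol=1e-13, rtol=8.9e-16)
        P0 = (N0 / params.gamma) * ((bh - bc) + D * (1.0 - E) / two_e)
        return np.array([P0, N0])

    if mode == "constants":
        # the decoupled route is exact here; Newton only polishes
        seed = decoupled_seed(b_hia, b_c)
        x = newton(seed) if seed is not None else newton(
            np.asarray(guess, dtype=float)
        )
    else:
        x = newton(np.asarray(guess, dtype=float))
        if x is None:
            # fixed-point seeding: freeze the CTA Hill at the current P,
            # solve the decoupled system, repeat
            P_cur = float(guess[0])
            seed = None
            for _ in range(50):
                bh, bc, _, _ = _effective_rates(
                    P_cur, params, mode, b_hia, b_c, cta_on
                )
                seed = decoupled_seed(bh, bc)
                if seed is None:
                    break
                if abs(seed[0] - P_cur) < 1e-10 * max(1.0, abs(P_cur)):
                    break
                P_cur = float(max(seed[0], 0.0))
            if seed is not None:
                x = newton(seed)

    if x is None:
        r, _ = _residuals_and_jacobian(
            guess[0], guess[1], params, mode, b_hia, b_c, cta_on
        )
        raise RuntimeError(
            f"steady-state iteration failed to converge "
            f"(last residual max {np.max(np.abs(r)):.3g})"
        )

    bh, bc, _, _ = _effective_rates(x[0], params, mode, b_hia, b_c, cta_on)
    return SteadyState(float(x[0]), float(x[1]), "numeric", True, bh, bc)


def residuals_at(
    P: float, N: float, params: ModelParameters, b_hia: float = 0.0,
    b_c: float = 0.0,
) -> tuple[float, float]:
    """Steady-state residuals of the full right-hand side with constant
    treatment rates; diagnostic helper."""
    r, _ = _residuals_and_jacobian(P, N, params, "constants", b_hia, b_c, True)
    return float(r[0]), float(r[1])
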