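"""Core model: parameters, rate functions and the delayed right-hand side.

The model tracks two compartments of hematopoietic stem cells (HSC),
measured in cells per 10,000 peripheral blood leukocytes:

* ``P`` — proliferating cells (in cycle),
* ``N`` — non-proliferating (quiescent, G0) cells.

Quiescent cells re-enter the cycle at a density-dependent Hill rate
``beta(N)``; a cell that entered proliferation at time ``t - tau``
re-emerges at ``t`` as two daughters, attenuated by the in-cycle apoptosis
factor ``exp(-gamma*tau)``.  Two pharmacological terms act on the
quiescent pool: a hematopoietic inducing agent (HIA, pro-mitotic, rate
``beta_HIA(P) * g_HIA(t)``) and a chemotherapeutic agent (CTA,
anti-mitotic, rate ``beta_C(P) * g_C(t)``).  The ``g`` factors encode the
time-decaying pharmacodynamic effect of a single administration.

The governing delay differential equations are::

    dP/dt = -gamma*P + beta(N)*N - exp(-gamma*tau)*beta(N_tau)*N_tau
            + beta_HIA(P)*N - beta_C(P)*N
    dN/dt = -beta(N)*N - delta*N + 2*exp(-gamma*tau)*beta(N_tau)*N_tau
            - beta_HIA(P)*N + beta_C(P)*N

where ``N_tau = N(t - tau)``.  ``delta`` is the rate of random cell loss
from the quiescent pool to the periphery and enters ``dN/dt`` as a loss
term; only that sign is consistent with delta's meaning and with the
closed-form steady state (see :mod:`hscdelay.steady`).

Units are days and cells per 10,000 peripheral blood leukocytes
throughout; there is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "ModelParameters",
    "StateSnapshot",
    "TreatmentSchedule",
    "eval_beta_N",
    "eval_g_HIA",
    "eval_g_C",
    "eval_beta_HIA",
    "eval_beta_C",
    "eval_rhs",
]

#: states in [-NEG_CLAMP, 0) are clamped to 0 inside rate evaluations;
#: anything more negative is a genuine domain error / solver failure.
NEG_CLAMP = 1e-9


def _clamp_nonneg(x: float, name: str) -> float:
    """Clamp tiny floating-point undershoot to 0; reject real negatives.

    Fractional Hill exponents make ``x**n`` undefined for ``x < 0``, so a
    state driven marginally below zero by interpolation error must not
    reach the power evaluation.
    """
    if x >= 0.0:
        return x
    if x >= -NEG_CLAMP:
        return 0.0
    raise ValueError(f"{name} must be non-negative, got {x!r}")


@dataclass(frozen=True)
class ModelParameters:
    """All rate and shape constants of the model, one record per column
    of the simulation parameter table.

    Attributes
    ----------
    beta0 : float
        Maximal G0 -> S transit rate, 1/day.
    theta : float
        Quiescent population at which re-entry runs at half its maximal
        rate, cells/10,000 leukocytes.
    n : float
        Hill sensitivity of ``beta(N)``, dimensionless.
    beta0_HIA : float
        Maximal HIA-induced transition rate, 1/day.
    theta1 : float
        Half-activation proliferating population for the HIA response.
    m : float
        Hill sensitivity of the HIA response.
    beta0_C : float
        Maximal CTA-induced transition rate, 1/day.
    theta2 : float
        Half-activation proliferating population for the CTA response.
    w : float
        Hill sensitivity of the CTA response.
    delta : float
        Rate of random cell loss to the periphery, 1/day.
    gamma : float
        Apoptosis rate of proliferating cells, 1/day.
    tau : float
        Duration of one proliferation cycle (the delay), days.
    s1, s2 : float
        Decay rates of the HIA and CTA effects, 1/day.
    tau1 : float
        Time after HIA administration at which its effect starts to decay.
    tau2 : float
        Time after CTA administration at which its effect starts to decay.
    tau3 : float
        Time after CTA administration at which the CTA decay freezes to a
        constant residual (``tau3 >= tau2``).
    """

    beta0: float = 1.4
    theta: float = 60.0
    n: float = 2.7
    beta0_HIA: float = 0.08
    theta1: float = 100.0
    m: float = 0.1
    beta0_C: float = 0.206
    theta2: float = 100.0
    w: float = 1.0
    delta: float = 0.09
    gamma: float = 0.15
    tau: float = 2.22
    s1: float = 0.2
    s2: float = 0.2
    tau1: float = 5.0
    tau2: float = 5.0
    tau3: float = 18.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")
        for name in ("theta", "theta1", "theta2", "n", "m", "w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        if self.tau3 < self.tau2:
            raise ValueError(
                f"tau3 ({self.tau3!r}) must be >= tau2 ({self.tau2!r})"
            )

    def survival(self) -> float:
        """In-cycle survival factor ``exp(-gamma * tau)``."""
        return math.exp(-self.gamma * self.tau)

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the named parameters replaced."""
        known = {f.name for f in fields(self)}
        for k in kwargs:
            if k not in known:
                raise KeyError(f"unknown model parameter: {k!r}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StateSnapshot:
    """State of the system at one instant: time, P and N."""

    t: float
    P: float
    N: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", _clamp_nonneg(self.P, "P"))
        object.__setattr__(self, "N", _clamp_nonneg(self.N, "N"))


@dataclass(frozen=True)
class TreatmentSchedule:
    """When each agent is switched on.

    The decay clocks ``g_HIA`` and ``g_C`` run on time *since the
    respective onset*, not absolute simulation time: treatments are
    administered after the untreated system has settled, and the
    pharmacodynamic decay starts at administration.

    Attributes
    ----------
    hia_on, cta_on : bool
        Whether the agent is administered at all.
    hia_onset, cta_onset : float
        Administration times, days (simulation time).
    hia_time_dependent : bool
        If False, the HIA effect never decays (``g_HIA`` forced to 1);
        used to contrast the time-dependent pharmacodynamics with a
        permanently active agent.
    """

    hia_on: bool = False
    cta_on: bool = False
    hia_onset: float = 0.0
    cta_onset: float = 0.0
    hia_time_dependent: bool = True

    def __post_init__(self) -> None:
        if self.hia_onset < 0 or self.cta_onset < 0:
            raise ValueError("treatment onset times must be >= 0")

    @staticmethod
    def off() -> "TreatmentSchedule":
        return TreatmentSchedule()


def eval_beta_N(N: float, params: ModelParameters) -> float:
    """Re-entry rate from quiescence, ``beta(N) = beta0*theta^n/(theta^n + N^n)``.

    Strictly decreasing in N, with ``beta(0) = beta0``.
    """
    N = _clamp_nonneg(N, "N")
    if N == 0.0:
        return params.beta0
    # exp/log form keeps fractional powers well-behaved for large N
    r = math.exp(params.n * (math.log(N) - math.log(params.theta)))
    return params.beta0 / (1.0 + r)


def eval_g_HIA(t_since_onset: float, params: ModelParameters) -> float:
    """Pharmacodynamic decay factor of the HIA effect.

    1 up to ``tau1`` after administration, then exponential decay at rate
    ``s1``.  Continuous and non-increasing.
    """
    if t_since_onset < 0:
        raise ValueError("t_since_onset must be >= 0")
    if t_since_onset <= params.tau1:
        return 1.0
    return math.exp(-params.s1 * (t_since_onset - params.tau1))


def eval_g_C(t_since_onset: float, params: ModelParameters) -> float:
    """Pharmacodynamic decay factor of the CTA effect.

    1 up to ``tau2``, exponential decay at rate ``s2`` on
    ``(tau2, tau3]``, then frozen at the residual
    ``exp(-s2*(tau3 - tau2))``.  Continuous and non-increasing; with
    ``tau3 == tau2`` the decaying branch is empty and the factor is
    identically 1.
    """
    if t_since_onset < 0:
        raise ValueError("t_since_onset must be >= 0")
    if t_since_onset <= params.tau2:
        return 1.0
    t_eff = min(t_since_onset, params.tau3)
    return math.exp(-params.s2 * (t_eff - params.tau2))


def _hill_decreasing(P: float, theta: float, exponent: float) -> float:
    """``theta^e / (theta^e + P^e)`` via logs; exact limit 1 at P=0.

    Evaluated from whichever side keeps the ratio <= 1, so neither branch
    overflows nor cancels to 0 deep in saturation.
    """
    if P == 0.0:
        return 1.0
    u = exponent * (math.log(P) - math.log(theta))
    if u <= 0.0:
        r = math.exp(u)       # (P/theta)^e <= 1
        return 1.0 / (1.0 + r)
    r = math.exp(-u)          # (theta/P)^e < 1
    return r / (1.0 + r)


def _hill_increasing(P: float, theta: float, exponent: float) -> float:
    """``P^e / (theta^e + P^e)``, the complement of :func:`_hill_decreasing`
    computed directly (not as ``1 - ...``, which cancels for P >> theta)."""
    if P == 0.0:
        return 0.0
    u = exponent * (math.log(P) - math.log(theta))
    if u >= 0.0:
        r = math.exp(-u)
        return 1.0 / (1.0 + r)
    r = math.exp(u)
    return r / (1.0 + r)


def eval_beta_HIA(P: float, t_since_onset: float, params: ModelParameters) -> float:
    """HIA-induced G0 -> proliferation transition rate.

    ``beta_HIA(P) = beta0_HIA * theta1^m / (theta1^m + P^m) * g_HIA(t)``:
    strongest when the proliferating pool is depleted, switching off as P
    recovers past ``theta1``, and decaying with time since administration.
    """
    P = _clamp_nonneg(P, "P")
    if params.beta0_HIA == 0.0:
        return 0.0
    return (
        params.beta0_HIA
        * _hill_decreasing(P, params.theta1, params.m)
        * eval_g_HIA(t_since_onset, params)
    )


def eval_beta_C(P: float, t_since_onset: float, params: ModelParameters) -> float:
    """CTA-induced proliferation -> G0 transition rate.

    ``beta_C(P) = beta0_C * P^w / (theta2^w + P^w) * g_C(t)``: the Hill
    numerator is ``P^w`` (increasing in P), so chemotherapy bites hardest
    when the proliferating pool is large and releases as it is depleted
    below ``theta2``.
    """
    P = _clamp_nonneg(P, "P")
    if params.beta0_C == 0.0:
        return 0.0
    return (
        params.beta0_C
        * _hill_increasing(P, params.theta2, params.w)
        * eval_g_C(t_since_onset, params)
    )


def treatment_rates(
    t: float,
    P: float,
    schedule: TreatmentSchedule,
    params: ModelParameters,
) -> tuple[float, float]:
    """Instantaneous (beta_HIA, beta_C) at simulation time ``t``.

    Each agent contributes 0 before its onset; afterwards its decay clock
    runs on ``t - onset``.
    """
    b_hia = 0.0
    b_c = 0.0
    if schedule.hia_on and t >= schedule.hia_onset:
        if schedule.hia_time_dependent:
            b_hia = eval_beta_HIA(P, t - schedule.hia_onset, params)
        else:
            b_hia = params.beta0_HIA * _hill_decreasing(
                _clamp_nonneg(P, "P"), params.theta1, params.m
            )
    if schedule.cta_on and t >= schedule.cta_onset:
        b_c = eval_beta_C(P, t - schedule.cta_onset, params)
    return b_hia, b_c


def eval_rhs(
    now: StateSnapshot,
    delayed: StateSnapshot,
    schedule: TreatmentSchedule,
    params: ModelParameters,
) -> tuple[float, float]:
    """Right-hand side (dP/dt, dN/dt) of the delayed system.

    ``delayed`` must be the state at ``now.t - tau``.
    """
    if not math.isclose(delayed.t, now.t - params.tau, rel_tol=0.0, abs_tol=1e-9):
        raise ValueError(
            f"delayed snapshot at t={delayed.t!r} is not now.t - tau "
            f"= {now.t - params.tau!r}"
        )
    return rhs_raw(now.t, now.P, now.N, delayed.N, schedule, params)


def rhs_raw(
    t: float,
    P: float,
    N: float,
    N_tau: float,
    schedule: TreatmentSchedule,
    params: ModelParameters,
) -> tuple[float, float]:
    """Unchecked scalar right-hand side, shared by :func:`eval_rhs` and
    the integrator hot loop."""
    P = _clamp_nonneg(P, "P")
    N = _clamp_nonneg(N, "N")
    N_tau = _clamp_nonneg(N_tau, "N_tau")

    beta_now = eval_beta_N(N, params)
    influx = beta_now * N
    # cells that entered the cycle tau ago re-emerge, doubled, after
    # in-cycle apoptosis
    emergence = params.survival() * eval_beta_N(N_tau, params) * N_tau
    b_hia, b_c = treatment_rates(t, P, schedule, params)
    transfer = (b_hia - b_c) * N

    dP = -params.gamma * P + influx - emergence + transfer
    dN = -influx - params.delta * N + 2.0 * emergence - transfer
    return dP, dN
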