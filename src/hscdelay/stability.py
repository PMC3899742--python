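"""Linear stability of the positive equilibrium.

Linearizing the quiescent-pool dynamics about ``N*`` (the N equation
decouples from P at equilibrium, and P is slaved to N through a stable
``-gamma`` relaxation) gives a scalar delayed equation for the
perturbation ``n(t)``::

    dn/dt = -A * n(t) - B * n(t - tau)

with coefficients built from the normalized Hill slope
``F = theta^n*(theta^n + (1-n)*N*^n)/(theta^n + N*^n)^2``::

    A = delta + beta0*F + b_HIA
    B = -2*beta0*exp(-gamma*tau)*F - b_C

(``b_HIA``, ``b_C`` are the constant treatment rates of the steady state
being linearized).  The characteristic equation is the classical
transcendental form ``lambda + A + B*exp(-lambda*tau) = 0``, whose
stability chart is the Hayes criterion: every root has negative real part
iff

* ``A + B > 0``, and
* either ``|B| <= A`` (delay-independent branch), or ``B > |A|`` and
  ``tau * sqrt(B**2 - A**2) < arccos(-A/B)`` (delay-dependent branch).

The arccos bound requires ``|A/B| <= 1``; that ratio restriction is
reported separately so a verdict from the delay-independent branch is
auditable.  A numeric oracle for the rightmost characteristic root is
provided through the Lambert W function, for which the scalar equation is
exactly solvable branch by branch.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .model import ModelParameters
from .steady import SteadyState, hill_slope

__all__ = [
    "StabilityReport",
    "linearization_coefficients",
    "paper_stability_criterion",
    "rightmost_characteristic_root",
    "stability_report",
]


@dataclass(frozen=True)
class StabilityReport:
    """Linearization coefficients, criterion verdict and root oracle.

    ``criterion_holds`` is the Hayes verdict; ``ratio_restriction_holds``
    says whether ``-A/B`` lies in the arccos domain (when it does not,
    the verdict comes from the delay-independent branch alone).
    ``verdicts_agree`` compares the criterion with the sign of the real
    part of the numerically located rightmost characteristic root.
    """

    F: float
    A: float
    B: float
    criterion_holds: bool
    ratio_restriction_holds: bool
    rightmost_root: complex
    verdicts_agree: bool


def linearization_coefficients(
    params: ModelParameters, ss: SteadyState
) -> tuple[float, float, float]:
    """(F, A, B) at the supplied positive equilibrium.

    ``F`` is the normalized slope of the quiescent efflux at ``N*``
    (``beta0*F`` is d[beta(N)N]/dN); ``A`` and ``B`` are the local and
    delayed feedback coefficients of the scalar perturbation equation.
    The trivial state has no Hill slope to linearize and is rejected.
    """
    if not ss.exists or ss.N_star is None:
        raise ValueError(
            "linearization requires the positive equilibrium; "
            "the trivial state is not supported"
        )
    F = hill_slope(ss.N_star, params)
    A = params.delta + params.beta0 * F + ss.effective_bHIA
    B = -2.0 * params.beta0 * params.survival() * F - ss.effective_bC
    return F, A, B


def paper_stability_criterion(
    A: float, B: float, tau: float
) -> tuple[bool, bool]:
    """Hayes criterion for ``lambda + A + B*exp(-lambda*tau) = 0``.

    Returns ``(stable, restriction_ok)``.  ``restriction_ok`` reports
    whether ``|A/B| <= 1`` so the arccos bound is defined; outside that
    domain only the delay-independent branch decides.
    """
    restriction_ok = B != 0.0 and abs(A / B) <= 1.0
    if A + B <= 0.0:
        return False, restriction_ok
    if abs(B) <= A:
        # delay-independent: no tau can destabilize
        return True, restriction_ok
    # here A + B > 0 and |B| > A forces B > |A|
    bound = math.acos(-A / B)
    stable = tau * math.sqrt(B * B - A * A) < bound
    return stable, restriction_ok


def rightmost_characteristic_root(
    A: float, B: float, tau: float, n_branches: int = 8
) -> complex:
    """Rightmost root of ``lambda + A + B*exp(-lambda*tau) = 0``.

    Substituting ``z = (lambda + A)*tau`` turns the equation into
    ``z*exp(z) = -B*tau*exp(A*tau)``, solved exactly by the Lambert W
    branches: ``lambda_k = -A + W_k(-B*tau*exp(A*tau))/tau``.  The real
    parts of ``W_k`` decrease with ``|k|``, so scanning a handful of
    branches and taking the maximal real part yields the rightmost root;
    each candidate is polished by Newton iteration and verified to
    residual < 1e-10.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if B == 0.0:
        return complex(-A, 0.0)
    if tau == 0.0:
        return complex(-A - B, 0.0)

    arg = -B * tau * math.exp(A * tau)
    roots = []
    for k in range(-n_branches, n_branches + 1):
        try:
            z = lambertw(arg, k=k)
        except Exception:  # pragma: no cover - scipy handles all finite args
            continue
        if not np.isfinite(z):
            continue
        lam = -A + complex(z) / tau
        # Newton polish on h(lam) = lam + A + B*exp(-lam*tau)
        for _ in range(50):
            h = lam + A + B * cmath.exp(-lam * tau)
            if abs(h) < 1e-13:
                break
            hp = 1.0 - B * tau * cmath.exp(-lam * tau)
            if hp == 0:
                break
            lam = lam - h / hp
        if abs(lam + A + B * cmath.exp(-lam * tau)) < 1e-10:
            roots.append(lam)
    if not roots:
        raise RuntimeError(
            f"no characteristic root found for A={A}, B={B}, tau={tau} "
            f"within {2 * n_branches + 1} Lambert-W branches"
        )
    lam = max(roots, key=lambda r: r.real)
    # report the member of a conjugate pair with non-negative imaginary part
    return lam if lam.imag >= 0 else lam.conjugate()


def stability_report(params: ModelParameters, ss: SteadyState) -> StabilityReport:
    """Full stability analysis of a positive equilibrium."""
    F, A, B = linearization_coefficients(params, ss)
    stable, restriction_ok = paper_stability_criterion(A, B, params.tau)
    root = rightmost_characteristic_root(A, B, params.tau)
    agree = stable == (root.real < 0)
    return StabilityReport(
        F=F,
        A=A,
        B=B,
        criterion_holds=stable,
        ratio_restriction_holds=restriction_ok,
        rightmost_root=root,
        verdicts_agree=agree,
    )
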