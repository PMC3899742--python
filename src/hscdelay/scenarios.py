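"""Named simulation protocols: control, single agents, combination, sweeps.

Every protocol follows the same clinical template: the untreated system is
burned in from its initial conditions until it settles on its plateau,
treatments are switched on at the detected settling time, and the run
continues long enough for the pharmacodynamic decay to play out.  Metrics
(burn-in plateau, post-onset nadir, final plateau) are extracted from the
dense trajectory.

Scenario ids and the preset they run on:

* ``control``   — no treatment, baseline preset (``no_cta``).
* ``hia_only``  — HIA at onset, baseline preset.
* ``cta_only``  — CTA at onset, elevated-baseline preset (``with_cta``).
* ``combined``  — HIA and CTA at the same onset, elevated-baseline preset.

Variant batteries re-run these under published parameter changes:
``fig2`` contrasts a permanently active HIA with the time-decaying one;
``fig4`` moves the treatment Hills (m 0.1->1, theta1 100->60, w 1->2,
theta2 100->60); ``fig5`` halves both decay rates (s1 = s2 = 0.1).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from .model import ModelParameters, TreatmentSchedule
from .presets import load_preset
from .solver import (
    SolverOptions,
    Trajectory,
    constant_history,
    detect_steady_state,
    integrate_dde,
    nadir,
)

__all__ = [
    "ScenarioResult",
    "SCENARIO_IDS",
    "HIA_DOSE_LEVELS",
    "run_scenario",
    "run_variant",
    "dose_sweep",
]

SCENARIO_IDS = ("control", "hia_only", "cta_only", "combined")

_PRESET_FOR = {
    "control": "no_cta",
    "hia_only": "no_cta",
    "cta_only": "with_cta",
    "combined": "with_cta",
}

#: HIA dose sweep levels (low / moderate / high maximal rates, 1/day).
#: The moderate level is the default beta0_HIA; low and high bracket it
#: to produce, respectively, an inadequate nadir rescue and an overshoot
#: past the untreated plateau.
HIA_DOSE_LEVELS = (0.04, 0.08, 0.16)

#: Post-onset simulation length, days: long enough for both decay clocks
#: to run out and the post-treatment plateau to settle.
POST_ONSET_DURATION = 300.0

#: Burn-in settling detection: trailing-window length and relative
#: peak-to-peak tolerance, and the hard cap on burn-in length.
BURN_IN_WINDOW = 50.0
BURN_IN_REL_TOL = 1e-6
BURN_IN_CAP = 1000.0


@dataclass(frozen=True)
class ScenarioResult:
    """One protocol run with its extracted metrics.

    ``nadir`` is ``None`` for runs without any treatment (there is no
    post-onset minimum to speak of).  All metrics are recomputable from
    ``trajectory``.
    """

    scenario_id: str
    trajectory: Trajectory
    burn_in_steady: tuple[float, float]
    onset: float
    nadir: Optional[tuple[float, float]]
    final_plateau: tuple[float, float]
    params: ModelParameters
    schedule: TreatmentSchedule
    initial: tuple[float, float]

    def metrics(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "burn_in_steady": {
                "P": self.burn_in_steady[0],
                "N": self.burn_in_steady[1],
            },
            "onset": self.onset,
            "nadir": (
                None
                if self.nadir is None
                else {"t": self.nadir[0], "P_min": self.nadir[1]}
            ),
            "final_plateau": {
                "P": self.final_plateau[0],
                "N": self.final_plateau[1],
            },
        }


@functools.lru_cache(maxsize=64)
def _burn_in(
    params: ModelParameters,
    P0: float,
    N0: float,
    options: SolverOptions,
) -> tuple[float, float, float]:
    """Settling time and plateau of the untreated system.

    Integrates from constant history (P0, N0), extending the horizon
    until the trailing-window criterion is met or the cap is reached.
    """
    t_try = 400.0
    while True:
        traj = integrate_dde(
            params,
            TreatmentSchedule.off(),
            constant_history([P0, N0], params.tau),
            t_try,
            options,
        )
        reached, (P, N), t_on = detect_steady_state(
            traj, window=BURN_IN_WINDOW, rel_tol=BURN_IN_REL_TOL
        )
        if reached:
            return t_on, P, N
        if t_try >= BURN_IN_CAP:
            raise RuntimeError(
                f"burn-in did not settle within {BURN_IN_CAP} d "
                f"(window {BURN_IN_WINDOW} d, rel_tol {BURN_IN_REL_TOL}); "
                f"trailing value P={P:.4g}, N={N:.4g}"
            )
        t_try = min(2.0 * t_try, BURN_IN_CAP)


def _final_plateau(traj: Trajectory, window: float = BURN_IN_WINDOW):
    import numpy as np

    t0, t1 = traj.span
    ts = np.linspace(t1 - window, t1, 200)
    P, N = traj(ts)
    return float(P.mean()), float(N.mean())


def run_scenario(
    scenario_id: Literal["control", "hia_only", "cta_only", "combined"],
    params: Optional[ModelParameters] = None,
    overrides: Optional[Mapping[str, float]] = None,
    *,
    initial: Optional[tuple[float, float]] = None,
    hia_time_dependent: bool = True,
    post_duration: float = POST_ONSET_DURATION,
    options: SolverOptions = SolverOptions(),
) -> ScenarioResult:
    """Burn in, apply the scenario's treatments, extract metrics.

    ``params``/``initial`` default to the scenario's preset; ``overrides``
    is a mapping of model parameter names (plus ``P0``/``N0``) applied on
    top.  Unknown names are rejected.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}"
        )
    preset = load_preset(_PRESET_FOR[scenario_id])
    p = params if params is not None else preset.params
    P0, N0 = initial if initial is not None else (preset.P0, preset.N0)
    if overrides:
        ov = dict(overrides)
        P0 = float(ov.pop("P0", P0))
        N0 = float(ov.pop("N0", N0))
        p = p.with_overrides(**ov)

    t_on, Pb, Nb = _burn_in(p, P0, N0, options)

    schedule = TreatmentSchedule(
        hia_on=scenario_id in ("hia_only", "combined"),
        cta_on=scenario_id in ("cta_only", "combined"),
        hia_onset=t_on,
        cta_onset=t_on,
        hia_time_dependent=hia_time_dependent,
    )
    traj = integrate_dde(
        p,
        schedule,
        constant_history([P0, N0], p.tau),
        t_on + post_duration,
        options,
    )
    nad = (
        nadir(traj, after=t_on)
        if (schedule.hia_on or schedule.cta_on)
        else None
    )
    return ScenarioResult(
        scenario_id=scenario_id,
        trajectory=traj,
        burn_in_steady=(Pb, Nb),
        onset=t_on,
        nadir=nad,
        final_plateau=_final_plateau(traj),
        params=p,
        schedule=schedule,
        initial=(P0, N0),
    )


def run_variant(
    figure: Literal["fig2", "fig4", "fig5"],
    params: Optional[ModelParameters] = None,
) -> list[ScenarioResult]:
    """Published variant batteries (see module docstring)."""
    if figure == "fig2":
        decaying = run_scenario("hia_only", params)
        persistent = run_scenario(
            "hia_only", params, hia_time_dependent=False
        )
        return [
            _relabel(persistent, "fig2:hia_persistent"),
            _relabel(decaying, "fig2:hia_decaying"),
        ]
    if figure == "fig4":
        ov = {"m": 1.0, "theta1": 60.0, "w": 2.0, "theta2": 60.0}
    elif figure == "fig5":
        ov = {"s1": 0.1, "s2": 0.1}
    else:
        raise ValueError(f"unknown variant {figure!r}")
    return [
        _relabel(run_scenario(sid, params, ov), f"{figure}:{sid}")
        for sid in SCENARIO_IDS
    ]


def _relabel(res: ScenarioResult, new_id: str) -> ScenarioResult:
    from dataclasses import replace

    return replace(res, scenario_id=new_id)


def dose_sweep(
    agent: Literal["CTA", "HIA"],
    levels: Sequence[float],
    params: Optional[ModelParameters] = None,
) -> list[ScenarioResult]:
    """Dose-response battery over maximal treatment rates.

    ``CTA``: chemotherapy alone at each ``beta0_C`` level (no HIA).
    ``HIA``: each ``beta0_HIA`` level on top of chemotherapy at the
    default dose.  Results are ordered as the levels are given.
    """
    if any(lv < 0 for lv in levels):
        raise ValueError("dose levels must be >= 0")
    out = []
    for lv in levels:
        if agent == "CTA":
            res = run_scenario("cta_only", params, {"beta0_C": float(lv)})
        elif agent == "HIA":
            res = run_scenario("combined", params, {"beta0_HIA": float(lv)})
        else:
            raise ValueError(f"unknown agent {agent!r}; expected CTA or HIA")
        out.append(_relabel(res, f"{agent.lower()}_sweep:{lv:g}"))
    return out
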