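"""Lumped astrocyte compartment: calcium dynamics and gliotransmitter release.

A single glial compartment (Postnov-style functional model) tracks four
dimensionless state variables:

* ``c``   cytosolic calcium,
* ``ce``  endoplasmic-reticulum calcium,
* ``S_m`` a second messenger (IP3-like) driven by the presynaptic signal,
* ``G_m`` the released gliotransmitter level.

The cytosol and ER exchange calcium through a nonlinear flux f(c, ce); the
second messenger gates calcium influx; supra-threshold calcium switches
gliotransmitter production on.  The gliotransmitter feeds back onto the
neurons as a current I_astro = K_glio * delta * G_m, where delta is the
transporter-activity factor of the active protocol mode.

Time is in seconds here: the stated relaxation times (5 s, 0.05 s, 0.025 s)
produce calcium oscillations with multi-second periods, so the compartment
takes one 1-ms Euler step per network step (dt = 0.001 s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AstrocyteState",
    "AstroParameters",
    "calcium_exchange",
    "astro_drive",
    "step_astrocyte",
    "astro_current",
]


@dataclass
class AstrocyteState:
    """Continuous state of the glial compartment (dimensionless units)."""

    c: float = 0.1
    ce: float = 1.0
    s_m: float = 0.0
    g_m: float = 0.0
    t: float = 0.0


#: Rest-like initial condition (cold start: the second messenger needs a
#: couple of seconds of drive before release begins).
REST_INIT = (0.1, 1.0, 0.0, 0.0)

#: State on the driven attractor at a calcium minimum, obtained by
#: integrating 60 s at saturated drive (drive = 1.9) and sampling the
#: cytosolic-calcium minimum of the late trajectory.  Use for runs that
#: assume an astrocyte already engaged by sustained presynaptic activity.
PRIMED_INIT = (0.2268, 0.6928, 0.8507, 0.3163)


@dataclass(frozen=True)
class AstroParameters:
    """Fixed constants of the calcium / gliotransmitter equations.

    Two defaults are repository choices (see docs/methods.md): ``k_glio``,
    the feedback-current gain, is calibrated so the gliotransmitter pulse
    current discriminates transporter states in the withdrawal network
    (subthreshold for population bursting at delta = 0.8, suprathreshold
    at delta = 1); and ``messenger_influx`` is
    0.06, the smallest round value at which second-messenger accumulation
    pushes the calcium subsystem across its oscillation onset (influx
    ~0.333) — the switch the release mechanism depends on.  All other
    constants are fixed model values.
    """

    tau_c: float = 0.05           # s, cytosolic calcium relaxation
    exchange_gain: float = 2.0 / 0.04   # = 50, cytosol<->ER flux weight
    basal_influx: float = 0.31    # constant calcium influx
    messenger_influx: float = 0.06  # calcium influx gated by S_m
    tau_ce: float = 0.04 * 0.05   # s, ER calcium time scale
    exch_amp: float = 0.13        # amplitude of the c^2/(1+c^2) uptake term
    exch_half: float = 0.94       # half-saturation of the c^4 release term
    er_leak: float = 0.004        # linear ER leak
    tau_sm: float = 5.0           # s, second-messenger relaxation
    drive_gain: float = 5.0       # slope inside the drive tanh
    drive_threshold: float = 0.45  # presynaptic-signal threshold
    tau_gm: float = 0.025         # s, gliotransmitter relaxation
    gm_slope: float = 10.0        # slope of the calcium gate
    gm_threshold: float = 0.5     # calcium level switching release on
    decay_divisor: float = 3.0    # S_m, G_m decay read as -x/3
    k_glio: float = 1.0           # feedback current gain (repo default)

    def with_gain(self, k_glio: float) -> "AstroParameters":
        return replace(self, k_glio=k_glio)


def calcium_exchange(c, ce, params: AstroParameters = AstroParameters()):
    """Nonlinear cytosol/ER calcium exchange flux f(c, ce).

    f = 0.13 c^2/(1+c^2) - (ce^2/(1+ce^2)) (c^4/(0.94+c^4)) - 0.004 ce

    Positive flux moves calcium from cytosol into the ER.
    """
    c = np.asarray(c, dtype=float)
    ce = np.asarray(ce, dtype=float)
    c2 = c * c
    ce2 = ce * ce
    c4 = c2 * c2
    uptake = params.exch_amp * c2 / (1.0 + c2)
    release = (ce2 / (1.0 + ce2)) * (c4 / (params.exch_half + c4))
    return uptake - release - params.er_leak * ce


def astro_drive(k_exc, f1_astro, params: AstroParameters = AstroParameters()):
    """Presynaptic activation of the second messenger, in (0, 2).

    Returns 1 + tanh(5 (K_exc |f1| - 0.45)): a sigmoidal switch that
    saturates near 2 once the rectified presynaptic signal K_exc |f1|
    clears the 0.45 threshold.
    """
    return 1.0 + np.tanh(
        params.drive_gain * (np.abs(f1_astro) * k_exc - params.drive_threshold)
    )


def step_astrocyte(
    state: AstrocyteState,
    drive,
    dt_s: float = 0.001,
    params: AstroParameters = AstroParameters(),
) -> AstrocyteState:
    """One forward-Euler step of the four-variable glial dynamics.

    ``drive`` is the activation value from :func:`astro_drive` for this
    step.  S_m and G_m are clamped to [0, 1] after the step to guard
    against Euler overshoot of their saturating kinetics.
    """
    c, ce, s_m, g_m = state.c, state.ce, state.s_m, state.g_m
    if not (np.isfinite(c) and np.isfinite(ce)):
        raise FloatingPointError(
            f"non-finite astrocyte state at t={state.t:.3f} s"
        )
    f = calcium_exchange(c, ce, params)
    dc = (-c - params.exchange_gain * f
          + params.basal_influx + params.messenger_influx * s_m) / params.tau_c
    dce = f / params.tau_ce
    ds = (drive * (1.0 - s_m) - s_m / params.decay_divisor) / params.tau_sm
    gate = 1.0 + np.tanh(params.gm_slope * (c - params.gm_threshold))
    dg = (gate * (1.0 - g_m) - g_m / params.decay_divisor) / params.tau_gm
    c = c + dt_s * dc
    ce = ce + dt_s * dce
    s_m = min(1.0, max(0.0, s_m + dt_s * ds))
    g_m = min(1.0, max(0.0, g_m + dt_s * dg))
    if not (np.isfinite(c) and np.isfinite(ce)):
        raise FloatingPointError(
            f"non-finite astrocyte state at t={state.t + dt_s:.3f} s"
        )
    return AstrocyteState(c=float(c), ce=float(ce), s_m=float(s_m),
                          g_m=float(g_m), t=state.t + dt_s)


def astro_current(g_m: float, delta: float, k_glio: float) -> float:
    """Gliotransmitter feedback current I_astro = K_glio * delta * G_m.

    The engine broadcasts this scalar to the target neurons.
    """
    return float(k_glio) * float(delta) * float(g_m)
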