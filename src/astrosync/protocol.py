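"""Addiction-mode parameter sets and declarative experiment timelines.

Four canonical operating modes of the network are defined by the external
drive amplitudes (K_exc, K_inh), the synaptic weight scales (s_exc, s_inh),
and the astrocytic transporter-activity factor delta:

* ``normal``      baseline: K_exc=5, K_inh=2, s_exc=0.5, s_inh=-1, delta=0.8
* ``acute``       disinhibition: excitatory drive +50%, inhibitory drive -50%
* ``chronic``     drives drift back toward normal while excitatory weights
                  strengthen 25% and inhibitory weights weaken 25%
* ``withdrawal``  excitatory drive -25%, inhibitory drive +25%, weights
                  partway back to normal

A :class:`Schedule` is an ordered, contiguous list of half-open segments
mapping simulation time to a :class:`ModeParameters`; the canonical
timelines (mode sequence, gliotransmitter toggling, prevention
interventions, relapse manipulation) are provided as builders and are
addressable by name in run configs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Iterable

__all__ = [
    "ModeParameters",
    "Segment",
    "Schedule",
    "mode_parameters",
    "addiction_timeline",
    "glio_toggle_schedule",
    "prevention_schedule",
    "relapse_schedule",
    "single_mode_schedule",
    "get_schedule",
    "MODE_NAMES",
]


class ConfigurationError(ValueError):
    """Unknown mode or malformed schedule."""


@dataclass(frozen=True)
class ModeParameters:
    """One operating point of the network.

    ``delta`` is the transporter-activity factor (0.5 = high clearance,
    0.8 = normal, 1.0 = transporters inactive); ``glio_release_scale``
    multiplies the gliotransmitter current gain, 0 silencing release while
    leaving the astrocyte's internal dynamics running.
    """

    k_exc: float
    k_inh: float
    s_exc: float
    s_inh: float
    delta: float = 0.8
    glio_release_scale: float = 1.0

    def override(self, **kwargs) -> "ModeParameters":
        return replace(self, **kwargs)


_MODES = {
    "normal": ModeParameters(k_exc=5.0, k_inh=2.0, s_exc=0.5, s_inh=-1.0, delta=0.8),
    "acute": ModeParameters(k_exc=7.5, k_inh=1.0, s_exc=0.5, s_inh=-1.0, delta=0.8),
    "chronic": ModeParameters(k_exc=6.25, k_inh=1.5, s_exc=0.625, s_inh=-0.75, delta=0.8),
    "withdrawal": ModeParameters(k_exc=3.75, k_inh=2.5, s_exc=0.56, s_inh=-0.875, delta=0.8),
}

MODE_NAMES = tuple(_MODES)


def mode_parameters(mode_name: str) -> ModeParameters:
    """Canonical parameter set for one of the four addiction modes."""
    try:
        return _MODES[mode_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown mode {mode_name!r}; valid modes: {', '.join(_MODES)}"
        ) from None


@dataclass(frozen=True)
class Segment:
    t_start_ms: float
    t_end_ms: float
    params: ModeParameters
    label: str = ""


@dataclass
class Schedule:
    """Piecewise-constant mode timeline over [0, total_duration_ms)."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("schedule needs at least one segment")
        t = 0.0
        for seg in self.segments:
            if seg.t_start_ms != t or seg.t_end_ms < seg.t_start_ms:
                raise ConfigurationError(
                    "segments must be contiguous, non-overlapping and start at 0"
                )
            t = seg.t_end_ms

    @property
    def total_duration_ms(self) -> float:
        return self.segments[-1].t_end_ms

    def parameters_at(self, t_ms: float) -> ModeParameters:
        """Parameters of the half-open segment [start, end) containing t."""
        if not (0 <= t_ms < self.total_duration_ms):
            raise ConfigurationError(
                f"t={t_ms} ms outside schedule [0, {self.total_duration_ms})"
            )
        for seg in self.segments:
            if seg.t_start_ms <= t_ms < seg.t_end_ms:
                return seg.params
        raise AssertionError("unreachable: contiguous segments cover the range")

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "t_start_ms": seg.t_start_ms,
                    "t_end_ms": seg.t_end_ms,
                    "label": seg.label,
                    "params": asdict(seg.params),
                }
                for seg in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Schedule":
        return cls(
            segments=[
                Segment(
                    t_start_ms=float(s["t_start_ms"]),
                    t_end_ms=float(s["t_end_ms"]),
                    params=ModeParameters(**s["params"]),
                    label=s.get("label", ""),
                )
                for s in data["segments"]
            ]
        )


def _build(spec: Iterable[tuple[float, float, ModeParameters, str]]) -> Schedule:
    return Schedule([Segment(a, b, p, lab) for a, b, p, lab in spec])


def single_mode_schedule(params: ModeParameters | str, duration_ms: float,
                         label: str = "") -> Schedule:
    if isinstance(params, str):
        label = label or params
        params = mode_parameters(params)
    return _build([(0.0, float(duration_ms), params, label)])


def addiction_timeline() -> Schedule:
    """8-s mode sequence: normal 0-2 s, acute 2-3 s, chronic 3-6 s, withdrawal 6-8 s."""
    return _build([
        (0.0, 2000.0, mode_parameters("normal"), "normal"),
        (2000.0, 3000.0, mode_parameters("acute"), "acute"),
        (3000.0, 6000.0, mode_parameters("chronic"), "chronic"),
        (6000.0, 8000.0, mode_parameters("withdrawal"), "withdrawal"),
    ])


def glio_toggle_schedule(mode_name: str) -> Schedule:
    """2-s run of one mode: gliotransmitter release off for 0-1 s, on for 1-2 s.

    The astrocyte is driven throughout; only the feedback current is gated.
    """
    base = mode_parameters(mode_name)
    return _build([
        (0.0, 1000.0, base.override(glio_release_scale=0.0), f"{mode_name}/glio-off"),
        (1000.0, 2000.0, base.override(glio_release_scale=1.0), f"{mode_name}/glio-on"),
    ])


def prevention_schedule() -> Schedule:
    """6-s chronic-mode run probing one candidate intervention per second.

    Second-by-second single-parameter overrides of the chronic state:
    excitatory drive cut to K_exc=3.8 (24% below normal), interneuron drive
    doubled (K_inh=4), excitatory weights cut to s_exc=0.47 (6% below
    normal), inhibitory weights strengthened 40% (s_inh=-1.4), and
    transporter activity raised (delta=0.5).
    """
    chronic = mode_parameters("chronic")
    return _build([
        (0.0, 1000.0, chronic, "chronic"),
        (1000.0, 2000.0, chronic.override(k_exc=3.8), "reduce-exc-input"),
        (2000.0, 3000.0, chronic.override(k_inh=4.0), "boost-inh-input"),
        (3000.0, 4000.0, chronic.override(s_exc=0.47), "weaken-exc-weights"),
        (4000.0, 5000.0, chronic.override(s_inh=-1.4), "strengthen-inh-weights"),
        (5000.0, 6000.0, chronic.override(delta=0.5), "boost-transporters"),
    ])


def relapse_schedule(reduced_release_scale: float = 0.25) -> Schedule:
    """3-s withdrawal run: transporter collapse, then reduced gliotransmitter release.

    Withdrawal with normal transporters (delta=0.8) for 0-1 s; transporters
    inactive (delta=1) for 1-2 s, which resynchronizes the network (the
    relapse signature); 2-3 s additionally scales the gliotransmitter
    current down (default 0.25, config-exposed), abolishing the synchrony.
    """
    wd = mode_parameters("withdrawal")
    return _build([
        (0.0, 1000.0, wd, "withdrawal"),
        (1000.0, 2000.0, wd.override(delta=1.0), "transporters-off"),
        (2000.0, 3000.0,
         wd.override(delta=1.0, glio_release_scale=float(reduced_release_scale)),
         "transporters-off/reduced-release"),
    ])


_CANONICAL = {
    "timeline": addiction_timeline,
    "prevention": prevention_schedule,
    "relapse": relapse_schedule,
}


def get_schedule(name: str) -> Schedule:
    """Resolve a canonical schedule by name.

    Names: ``timeline``, ``prevention``, ``relapse``, ``glio:<mode>``
    (e.g. ``glio:chronic``), and ``mode:<mode>:<seconds>`` for a constant
    single-mode run.
    """
    if name in _CANONICAL:
        return _CANONICAL[name]()
    if name.startswith("glio:"):
        return glio_toggle_schedule(name.split(":", 1)[1])
    if name.startswith("mode:"):
        parts = name.split(":")
        if len(parts) != 3:
            raise ConfigurationError("expected mode:<name>:<seconds>")
        return single_mode_schedule(parts[1], float(parts[2]) * 1000.0)
    raise ConfigurationError(
        f"unknown schedule {name!r}; valid: timeline, prevention, relapse, "
        f"glio:<mode>, mode:<mode>:<seconds>"
    )
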