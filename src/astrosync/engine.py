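"""Seeded simulation loop coupling network, astrocyte, and protocol.

One outer step per millisecond: look up the active mode, rebuild the weight
matrix if the segment changed the synaptic scales (same connectivity
realization throughout a run), draw the noise, add the recurrent input from
last step's spikes and the gliotransmitter feedback current, advance the
neurons, then advance the astrocyte.  Everything stochastic comes from four
independent named streams spawned from the master seed (heterogeneity,
connectivity, neuron noise, astrocyte drive), so changing one component's
draws never perturbs another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .astrocyte import (
    PRIMED_INIT,
    REST_INIT,
    AstroParameters,
    AstrocyteState,
    astro_current,
    astro_drive,
    step_astrocyte,
)
from .network import (
    external_current,
    init_connectivity,
    init_population,
    initial_state,
    step_neurons,
    synaptic_current,
)
from .protocol import ConfigurationError, ModeParameters, Schedule, get_schedule
from .raster import SpikeRaster

__all__ = ["SimulationConfig", "SimulationResult", "run_simulation", "sweep"]

STREAM_NAMES = ("heterogeneity", "connectivity", "neuron-noise", "astro-drive")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    schedule: Schedule | str = "timeline"
    master_seed: int = 0
    n_exc: int = 800
    n_inh: int = 200
    dt_ms: float = 1.0
    astro: AstroParameters = field(default_factory=AstroParameters)
    # (c, ce, S_m, G_m) start state, or "rest" / "primed" presets
    astro_init: tuple[float, float, float, float] | str = "rest"
    astro_targets: str = "all"      # "all" | "excitatory"
    noise_shared: bool = False      # shared scalar noise per class per step
    record_astro: bool = True

    def resolved_schedule(self) -> Schedule:
        return get_schedule(self.schedule) if isinstance(self.schedule, str) else self.schedule


@dataclass
class SimulationResult:
    """Recorded outputs of one run."""

    raster: SpikeRaster
    psc: np.ndarray                    # spikes per outer step, full population
    astro_trace: pd.DataFrame | None   # time_s, c, ce, Sm, Gm, I_astro per step
    config: SimulationConfig
    seeds: dict

    @property
    def duration_ms(self) -> float:
        return self.raster.duration_ms

    def save(self, outdir) -> None:
        """Write raster / PSC / astrocyte trace CSVs and a run manifest."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.raster.to_csv(out / "raster.csv")
        pd.DataFrame(
            {"time_ms": np.arange(len(self.psc)) * self.config.dt_ms,
             "count": self.psc}
        ).to_csv(out / "psc.csv", index=False)
        if self.astro_trace is not None:
            self.astro_trace.to_csv(out / "astro_trace.csv", index=False)
        manifest = {
            "seeds": self.seeds,
            "n_exc": self.config.n_exc,
            "n_inh": self.config.n_inh,
            "dt_ms": self.config.dt_ms,
            "schedule": self.config.resolved_schedule().to_dict(),
            "astro": asdict(self.config.astro),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_simulation(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the full coupled simulation; bit-identical per (config, seed)."""
    master = config.master_seed if seed is None else seed
    schedule = config.resolved_schedule()
    n_steps = int(round(schedule.total_duration_ms / config.dt_ms))
    dt_ms = config.dt_ms
    dt_s = dt_ms / 1000.0

    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STREAM_NAMES))
    streams = dict(zip(STREAM_NAMES, children))
    pop = init_population(config.n_exc, config.n_inh,
                          np.random.default_rng(streams["heterogeneity"]))
    syn = init_connectivity(config.n_exc, config.n_inh,
                            np.random.default_rng(streams["connectivity"]))
    noise_rng = np.random.default_rng(streams["neuron-noise"])
    astro_rng = np.random.default_rng(streams["astro-drive"])

    state = initial_state(pop)
    astro_init = config.astro_init
    if isinstance(astro_init, str):
        try:
            astro_init = {"rest": REST_INIT, "primed": PRIMED_INIT}[astro_init]
        except KeyError:
            raise ConfigurationError(
                f"astro_init preset must be 'rest' or 'primed', got {astro_init!r}"
            ) from None
    astro = AstrocyteState(*astro_init)
    params = config.astro
    target_mask = None
    if config.astro_targets == "excitatory":
        target_mask = pop.is_excitatory.astype(float)
    elif config.astro_targets != "all":
        raise ConfigurationError("astro_targets must be 'all' or 'excitatory'")

    spike_times: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    psc = np.zeros(n_steps, dtype=np.int64)
    trace = np.zeros((n_steps, 6)) if config.record_astro else None

    for k in range(n_steps):
        t_ms = k * dt_ms
        mode: ModeParameters = schedule.parameters_at(t_ms)
        syn.set_scales(mode.s_exc, mode.s_inh)

        i_ext = external_current(mode, pop, noise_rng, shared=config.noise_shared)
        i_syn = synaptic_current(syn, state.fired)
        i_astro = astro_current(
            astro.g_m, mode.delta, params.k_glio * mode.glio_release_scale
        )
        i_total = i_ext + i_syn + (
            i_astro if target_mask is None else i_astro * target_mask
        )

        try:
            state = step_neurons(state, pop, i_total, dt_ms)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"{exc} (step {k}, segment containing t={t_ms} ms)"
            ) from exc

        f1_astro = astro_rng.standard_normal()
        drive = astro_drive(mode.k_exc, f1_astro, params)
        astro = step_astrocyte(astro, drive, dt_s, params)

        idx = np.flatnonzero(state.fired)
        if idx.size:
            spike_times.append(np.full(idx.size, t_ms))
            spike_ids.append(idx)
        psc[k] = idx.size
        if trace is not None:
            trace[k] = (t_ms / 1000.0, astro.c, astro.ce, astro.s_m, astro.g_m, i_astro)

    times = np.concatenate(spike_times) if spike_times else np.array([])
    ids = np.concatenate(spike_ids) if spike_ids else np.array([], dtype=np.int64)
    raster = SpikeRaster(times, ids, pop.n, schedule.total_duration_ms,
                         pop.is_excitatory)
    astro_df = None
    if trace is not None:
        astro_df = pd.DataFrame(
            trace, columns=["time_s", "c", "ce", "Sm", "Gm", "I_astro"]
        )
    return SimulationResult(
        raster=raster,
        psc=psc,
        astro_trace=astro_df,
        config=config,
        seeds={"master": int(master),
               "streams": {name: list(child.spawn_key)
                           for name, child in streams.items()}},
    )


def _override_schedule(schedule: Schedule, field_name: str, value: float) -> Schedule:
    segs = [
        type(seg)(seg.t_start_ms, seg.t_end_ms,
                  seg.params.override(**{field_name: value}), seg.label)
        for seg in schedule.segments
    ]
    return Schedule(segs)


def _apply_parameter(config: SimulationConfig, path: str, value: float) -> SimulationConfig:
    from dataclasses import replace as dc_replace

    scope, _, name = path.partition(".")
    if scope == "mode":
        sched = config.resolved_schedule()
        if name not in ModeParameters.__dataclass_fields__:
            raise ConfigurationError(f"unknown mode parameter {name!r}")
        return dc_replace(config, schedule=_override_schedule(sched, name, value))
    if scope == "astro":
        if name not in AstroParameters.__dataclass_fields__:
            raise ConfigurationError(f"unknown astrocyte parameter {name!r}")
        from dataclasses import replace as rep
        return dc_replace(config, astro=rep(config.astro, **{name: value}))
    raise ConfigurationError(
        f"parameter path must start with 'mode.' or 'astro.', got {path!r}"
    )


def sweep(
    config: SimulationConfig,
    parameter_path: str,
    values: Sequence[float],
    metric: Callable[[SimulationResult], float],
    seeds: Sequence[int] = (0,),
    threshold: float | None = None,
    below: bool = True,
) -> pd.DataFrame:
    """Run one simulation per (value, seed) and tabulate a scalar metric.

    ``parameter_path`` addresses one scalar, e.g. ``mode.k_exc`` (applied
    to every schedule segment) or ``astro.k_glio``.  All values share the
    same seed list, so runs differ only through the swept parameter.  The
    returned frame has one row per value with per-seed metric columns and
    their median; if ``threshold`` is given, a boolean ``crossed`` column
    marks values whose median is below (or above, ``below=False``) it.
    """
    rows = []
    for value in values:
        cfg = _apply_parameter(config, parameter_path, value)
        per_seed = [metric(run_simulation(cfg, seed=s)) for s in seeds]
        row = {"value": float(value),
               **{f"seed_{s}": m for s, m in zip(seeds, per_seed)},
               "median": float(np.median(per_seed))}
        rows.append(row)
    df = pd.DataFrame(rows)
    if threshold is not None:
        df["crossed"] = (df["median"] < threshold) if below else (df["median"] > threshold)
    return df


def first_crossing(table: pd.DataFrame, threshold: float, below: bool = True) -> float | None:
    """First swept value (in sweep order) whose median metric crosses the threshold."""
    mask = (table["median"] < threshold) if below else (table["median"] > threshold)
    hits = table.loc[mask, "value"]
    return float(hits.iloc[0]) if len(hits) else None
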