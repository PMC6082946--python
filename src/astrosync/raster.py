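"""Spike raster container and its CSV round-trip.

A raster is the canonical recording of a network simulation: one row per
spike, holding the spike time (outer-step resolution, ms), the 0-based
neuron index, and whether the neuron is excitatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RASTER_COLUMNS = ("time_ms", "neuron_id", "is_excitatory")


@dataclass
class SpikeRaster:
    """All spikes of one run, in time order.

    Attributes
    ----------
    times_ms : float array of spike times (outer-step resolution).
    neuron_ids : int array, 0-based neuron indices, same length.
    n_neurons : total population size (needed even when some neurons
        never fire).
    duration_ms : simulated duration; spikes satisfy 0 <= t < duration.
    is_excitatory : per-*neuron* boolean identity vector (length
        ``n_neurons``); excitatory neurons occupy the low indices.
    """

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    n_neurons: int
    duration_ms: float
    is_excitatory: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.times_ms.shape != self.neuron_ids.shape:
            raise ValueError("times_ms and neuron_ids must have equal length")
        if self.is_excitatory is None:
            self.is_excitatory = np.ones(self.n_neurons, dtype=bool)
        self.is_excitatory = np.asarray(self.is_excitatory, dtype=bool)
        if self.is_excitatory.shape != (self.n_neurons,):
            raise ValueError("is_excitatory must have one flag per neuron")

    @property
    def n_spikes(self) -> int:
        return int(self.times_ms.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "neuron_id": self.neuron_ids,
                "is_excitatory": self.is_excitatory[self.neuron_ids]
                if self.n_spikes
                else np.array([], dtype=bool),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int | None = None,
                 duration_ms: float | None = None) -> "SpikeRaster":
        """Load a raster written by :meth:`to_csv`.

        ``n_neurons``/``duration_ms`` may be supplied when the CSV alone
        cannot determine them (silent neurons at the top of the index
        range, or a quiet tail).
        """
        df = pd.read_csv(path)
        missing = set(RASTER_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"raster CSV missing columns: {sorted(missing)}")
        ids = df["neuron_id"].to_numpy(dtype=np.int64)
        times = df["time_ms"].to_numpy(dtype=float)
        if n_neurons is None:
            n_neurons = int(ids.max()) + 1 if ids.size else 0
        if duration_ms is None:
            duration_ms = float(np.floor(times.max()) + 1) if times.size else 0.0
        is_exc = np.ones(n_neurons, dtype=bool)
        if ids.size:
            flags = df["is_excitatory"].to_numpy(dtype=bool)
            is_exc[ids] = flags
        return cls(times, ids, n_neurons, duration_ms, is_exc)
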