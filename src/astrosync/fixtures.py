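"""Synthetic rasters with known structure for exercising the analysis layer.

Two generators: independent homogeneous-Poisson spiking (the null case for
every synchrony statistic) and rhythmically modulated inhomogeneous-Poisson
spiking with an optional coincident subpopulation (a controlled positive
case with a known dominant frequency).  Spike times come from exact
thinning of a homogeneous process, so the statistics do not depend on any
binning choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

__all__ = ["SyntheticRasterSpec", "poisson_raster", "rhythmic_raster"]


@dataclass(frozen=True)
class SyntheticRasterSpec:
    n_neurons: int = 1000
    duration_ms: float = 4000.0
    base_rate_hz: float = 5.0
    modulation_freq_hz: float | None = None
    modulation_depth: float = 0.0
    coincidence_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate_hz < 0:
            raise ValueError("base_rate_hz must be nonnegative")
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not 0 <= self.coincidence_fraction <= 1:
            raise ValueError("coincidence_fraction must lie in [0, 1]")


def _homogeneous_times(rate_hz: float, duration_ms: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Exact homogeneous Poisson times in ms: count then order statistics."""
    mean = rate_hz * duration_ms / 1000.0
    n = rng.poisson(mean)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def _thinned_times(spec: SyntheticRasterSpec, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson times via thinning of the peak-rate process."""
    f = spec.modulation_freq_hz
    if f is None or spec.modulation_depth == 0:
        return _homogeneous_times(spec.base_rate_hz, spec.duration_ms, rng)
    peak = spec.base_rate_hz * (1.0 + spec.modulation_depth)
    cand = _homogeneous_times(peak, spec.duration_ms, rng)
    rate = spec.base_rate_hz * (
        1.0 + spec.modulation_depth * np.sin(2.0 * np.pi * f * cand / 1000.0)
    )
    keep = rng.uniform(0.0, peak, size=cand.size) < rate
    return cand[keep]


def poisson_raster(spec: SyntheticRasterSpec) -> SpikeRaster:
    """Independent homogeneous Poisson spiking; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    times, ids = [], []
    for i in range(spec.n_neurons):
        t = _homogeneous_times(spec.base_rate_hz, spec.duration_ms, rng)
        times.append(t)
        ids.append(np.full(t.size, i, dtype=np.int64))
    return _assemble(spec, times, ids)


def rhythmic_raster(spec: SyntheticRasterSpec) -> SpikeRaster:
    """Rate-modulated spiking r(t) = base (1 + depth sin(2 pi f t)).

    The first ``coincidence_fraction`` of the population shares one spike
    train drawn from the same modulated process (perfect coincidence);
    remaining neurons draw independently.
    """
    rng = np.random.default_rng(spec.seed)
    n_coinc = int(round(spec.coincidence_fraction * spec.n_neurons))
    times, ids = [], []
    if n_coinc:
        shared = _thinned_times(spec, rng)
        for i in range(n_coinc):
            times.append(shared)
            ids.append(np.full(shared.size, i, dtype=np.int64))
    for i in range(n_coinc, spec.n_neurons):
        t = _thinned_times(spec, rng)
        times.append(t)
        ids.append(np.full(t.size, i, dtype=np.int64))
    return _assemble(spec, times, ids)


def _assemble(spec: SyntheticRasterSpec, times: list, ids: list) -> SpikeRaster:
    t = np.concatenate(times) if times else np.array([])
    i = np.concatenate(ids) if ids else np.array([], dtype=np.int64)
    order = np.lexsort((i, t))
    return SpikeRaster(t[order], i[order], spec.n_neurons, spec.duration_ms)
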