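"""Heterogeneous two-variable (quadratic integrate-and-reset) spiking network.

The population follows the standard cortical-network recipe: 800 regular
spiking excitatory neurons and 200 fast-spiking inhibitory neurons, each with
membrane equation

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

Heterogeneity enters through a per-neuron uniform draw ``r``: excitatory
neurons get (c, d) = (-65, 8) + (15, -6) r^2, inhibitory neurons get
(a, b) = (0.02, 0.25) + (0.08, -0.05) r.  All-to-all random connectivity is
encoded as a signed dense weight matrix with separately rescalable
excitatory and inhibitory blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronPopulation",
    "SynapticMatrix",
    "NetworkState",
    "init_population",
    "init_connectivity",
    "synaptic_current",
    "external_current",
    "step_neurons",
]

SPIKE_THRESHOLD_MV = 30.0


class ConfigurationError(ValueError):
    """Invalid population size or parameter addressing."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class NeuronPopulation:
    """Per-neuron model parameters and excitatory/inhibitory identity.

    Excitatory neurons occupy indices ``[0, n_exc)``; inhibitory neurons
    follow.  ``r`` is the uniform heterogeneity draw each neuron's
    parameters were derived from.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    is_excitatory: np.ndarray
    r: np.ndarray

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def n_exc(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def n_inh(self) -> int:
        return self.n - self.n_exc


@dataclass
class SynapticMatrix:
    """Signed dense connectivity ``S = [s_exc * g1, s_inh * g2]``.

    ``g1`` (n x n_exc) and ``g2`` (n x n_inh) hold the raw uniform-[0,1]
    connection strengths and are kept so the excitatory / inhibitory scale
    factors can be changed mid-run without redrawing the connectivity
    realization.  Rows are targets, columns sources.
    """

    g1: np.ndarray
    g2: np.ndarray
    s_exc: float = 0.5
    s_inh: float = -1.0
    S: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self._assemble()

    def _assemble(self) -> None:
        self.S = np.hstack([self.s_exc * self.g1, self.s_inh * self.g2])

    def set_scales(self, s_exc: float, s_inh: float) -> None:
        """Rescale blocks in place; connectivity realization is untouched."""
        if (s_exc, s_inh) != (self.s_exc, self.s_inh):
            self.s_exc = float(s_exc)
            self.s_inh = float(s_inh)
            self._assemble()

    @property
    def n(self) -> int:
        return self.g1.shape[0]

    @property
    def n_exc(self) -> int:
        return self.g1.shape[1]


@dataclass
class NetworkState:
    """Membrane voltage, recovery variable, and last-step spike flags."""

    v: np.ndarray
    u: np.ndarray
    fired: np.ndarray
    t: float = 0.0


def init_population(n_exc: int = 800, n_inh: int = 200, seed=None) -> NeuronPopulation:
    """Draw a heterogeneous population of ``n_exc`` + ``n_inh`` neurons.

    Identical seed gives an identical population.  Degenerate populations
    (all excitatory or all inhibitory) are allowed.
    """
    if n_exc < 0 or n_inh < 0 or n_exc + n_inh < 1:
        raise ConfigurationError(
            f"population sizes must be nonnegative with at least one neuron, "
            f"got n_exc={n_exc}, n_inh={n_inh}"
        )
    rng = _as_rng(seed)
    r = rng.uniform(0.0, 1.0, size=n_exc + n_inh)
    re, ri = r[:n_exc], r[n_exc:]
    a = np.concatenate([np.full(n_exc, 0.02), 0.02 + 0.08 * ri])
    b = np.concatenate([np.full(n_exc, 0.2), 0.25 - 0.05 * ri])
    c = np.concatenate([-65.0 + 15.0 * re**2, np.full(n_inh, -65.0)])
    d = np.concatenate([8.0 - 6.0 * re**2, np.full(n_inh, 2.0)])
    is_exc = np.zeros(n_exc + n_inh, dtype=bool)
    is_exc[:n_exc] = True
    return NeuronPopulation(a=a, b=b, c=c, d=d, is_excitatory=is_exc, r=r)


def init_connectivity(
    n_exc: int = 800,
    n_inh: int = 200,
    seed=None,
    s_exc: float = 0.5,
    s_inh: float = -1.0,
) -> SynapticMatrix:
    """Draw all-to-all uniform-[0,1] connectivity with signed block scaling.

    Self-connections are kept (the diagonal is not zeroed); at these
    densities a single self-weight is negligible against ~1000 afferents.
    """
    if n_exc < 0 or n_inh < 0 or n_exc + n_inh < 1:
        raise ConfigurationError("connectivity requires at least one neuron")
    rng = _as_rng(seed)
    n = n_exc + n_inh
    g1 = rng.uniform(0.0, 1.0, size=(n, n_exc))
    g2 = rng.uniform(0.0, 1.0, size=(n, n_inh))
    return SynapticMatrix(g1=g1, g2=g2, s_exc=s_exc, s_inh=s_inh)


def synaptic_current(S, fired: np.ndarray) -> np.ndarray:
    """Total recurrent input: sum of weight columns of the neurons that fired.

    ``S`` may be a :class:`SynapticMatrix` or a plain (targets x sources)
    array.  Returns one current value per target neuron.
    """
    mat = S.S if isinstance(S, SynapticMatrix) else np.asarray(S, dtype=float)
    fired = np.asarray(fired)
    if fired.shape != (mat.shape[1],):
        raise ValueError(
            f"fired has shape {fired.shape}, expected ({mat.shape[1]},)"
        )
    idx = np.flatnonzero(fired)
    if idx.size == 0:
        return np.zeros(mat.shape[0])
    return mat[:, idx].sum(axis=1)


def external_current(
    mode,
    population: NeuronPopulation,
    rng: np.random.Generator,
    shared: bool = False,
) -> np.ndarray:
    """Noisy mode-dependent drive: delta * K_exc * f1 (exc), delta * K_inh * f2 (inh).

    ``f1``/``f2`` are standard-normal; by default each neuron gets an
    independent draw each step, ``shared=True`` switches to one scalar per
    class per step (the alternative reading of a population-level drive).
    """
    n_exc, n_inh = population.n_exc, population.n_inh
    if shared:
        f1 = np.full(n_exc, rng.standard_normal())
        f2 = np.full(n_inh, rng.standard_normal())
    else:
        f1 = rng.standard_normal(n_exc)
        f2 = rng.standard_normal(n_inh)
    return np.concatenate([mode.delta * mode.k_exc * f1, mode.delta * mode.k_inh * f2])


def step_neurons(
    state: NetworkState,
    population: NeuronPopulation,
    I_total: np.ndarray,
    dt_ms: float = 1.0,
) -> NetworkState:
    """Advance one outer step of ``dt_ms`` and apply the spike/reset rule.

    The voltage equation is integrated with two half-steps of forward Euler
    (the stability convention of the source neuron model); the recovery
    variable takes one full step against the updated voltage.  Neurons whose
    voltage reaches 30 mV are flagged as fired and reset to (c, u + d), so
    post-step voltages are always below threshold.
    """
    v = state.v.copy()
    u = state.u.copy()
    half = 0.5 * dt_ms
    for _ in range(2):
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + I_total)
    u += dt_ms * population.a * (population.b * v - u)
    fired = v >= SPIKE_THRESHOLD_MV
    v[fired] = population.c[fired]
    u[fired] = u[fired] + population.d[fired]
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise FloatingPointError(
            f"non-finite membrane state after step at t={state.t + dt_ms:.1f} ms"
        )
    return NetworkState(v=v, u=u, fired=fired, t=state.t + dt_ms)


def initial_state(population: NeuronPopulation, v0: float = -65.0) -> NetworkState:
    """Rest-like initial condition: v = v0, u = b * v0, nothing fired."""
    v = np.full(population.n, float(v0))
    u = population.b * v
    return NetworkState(v=v, u=u, fired=np.zeros(population.n, dtype=bool), t=0.0)
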