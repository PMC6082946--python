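# Methods

This note records the model equations as implemented, the numerical
conventions, the calibrated constants with their rationale, and what the
synthetic protocols do and do not establish.

## Network model and integration

Neurons follow the two-variable quadratic integrate-and-reset model with
the standard cortical parameterization (excitatory "regular spiking",
inhibitory "fast spiking"; heterogeneity r ~ U[0,1] as in the README).
Connectivity is all-to-all with uniform-[0,1] weights, scaled by s_Exc
(excitatory columns) and s_Inh (inhibitory columns); self-connections are
kept — one self-weight among ~1000 afferents is negligible, and it keeps
"randomly connected" literal. Weight-scale changes at segment boundaries
rescale the stored g1/g2 blocks, so a single connectivity realization
spans an entire run and within-run weight interventions are exactly
comparable.

Integration is forward Euler with a 1-ms outer step: the voltage equation
advances in two 0.5-ms substeps, the recovery variable once per outer step
against the updated voltage, then spikes (v ≥ 30 mV) are detected and
reset. This is the reference convention of the underlying neuron-model
family, kept for reproducibility of the published firing regimes rather
than for accuracy: because the last substep can overshoot threshold and
the u-update sees the overshot voltage, the scheme's inter-spike-interval
discretization error against a dt = 0.01 ms oracle is ~15% for tonic
spiking at I = 10. The population-level regimes (asynchrony, theta-range
bursting, fast collective oscillation) are insensitive to this bias; the
unit test asserts the measured error class.

Noise: f1, f2 are standard-normal, drawn independently per neuron per
outer step (the convention of the source network model, and the one that
yields heterogeneous rasters). A config switch (`noise_shared`) substitutes
one scalar per class per step. Synaptic transmission acts with one outer
step of latency (spikes of step k enter I_syn at step k+1).

Four named RNG streams (heterogeneity, connectivity, neuron-noise,
astro-drive) are spawned from the master seed, so changing one component's
draws never perturbs another's; runs are bit-identical per (config, seed).

## Astrocyte

State (c, ce, S_m, G_m), integrated in seconds with one 1-ms Euler step per
network step (the stated relaxation constants — 5 s, 0.05 s, 0.025 s —
put calcium dynamics on a seconds scale):

    0.05 dc/dt  = −c − 50 f(c, ce) + 0.31 + β S_m
    0.002 dce/dt = f(c, ce)
    f(c, ce) = 0.13 c²/(1+c²) − (ce²/(1+ce²)) (c⁴/(0.94+c⁴)) − 0.004 ce
    5 dS_m/dt = (1 + tanh[5(K_Exc|f1| − 0.45)]) (1 − S_m) − S_m/3
    0.025 dG_m/dt = (1 + tanh[10(c − 0.5)]) (1 − G_m) − G_m/3
    I_astro = K_Glio δ G_m

The S_m and G_m decay terms are read as −x/3 (relaxation with divisor 3),
the standard form of this model family; the saturated fixed points are
then S_m* = G_m* = 6/7, which the tests assert.

**Messenger-influx coefficient β = 0.06.** The calcium subsystem has an
oscillation onset at total influx ≈ 0.333: below it c settles near the
influx value, above it c executes large relaxation oscillations whose
peaks cross the 0.5 release gate. A coefficient of 0.006 would cap the
influx at 0.315 — the stimulated astrocyte could never oscillate and no
gliotransmitter would ever be released, contradicting the mechanism this
model exists to express (stimulation → calcium oscillations → release).
β = 0.06 is the smallest round value that puts the fully stimulated state
(S_m → 6/7, influx 0.361) across the onset while leaving the unstimulated
state (0.31) below it. With it, a driven astrocyte emits ~1-Hz calcium
spikes and G_m pulses of amplitude ≈ 0.86.

**Feedback gain K_Glio = 1.0.** No published value exists. The gain was
calibrated once against the relapse protocol, which requires a
discrimination window: gliotransmitter pulses must not ignite population
bursts in the withdrawal network at normal transporter activity (δ = 0.8,
peak I_astro = 0.8·K_Glio·0.86) but must ignite them when transporters are
inactive (δ = 1). That window is K_Glio ≈ 0.8–1.3; 1.0 is its round
center. Above ~1.6 the δ = 0.8 state synchronizes too and the transporter
manipulation loses its effect.

S_m and G_m are clamped to [0, 1] after each Euler step (overshoot guard at
dt = 0.001 s). Initial conditions are config-exposed with two presets:
`rest` = (0.1, 1.0, 0, 0) — a cold start needs ~2–3 s of drive before the
first release — and `primed` = (0.2268, 0.6928, 0.8507, 0.3163), a point
on the driven attractor at a calcium minimum (60 s of saturated drive),
used for experiments that assume an already-engaged astrocyte (the
intervention sweeps, the release-toggle and relapse protocols).
I_astro targets all neurons by default (`astro_targets` switches to
excitatory-only); the release toggles in the protocols scale K_Glio, not
G_m, so the astrocyte's internal dynamics continue while release is off.

## Protocols

Canonical mode parameters are listed in the README. Schedules are
piecewise-constant, half-open segments. The chronic segment of the 8-s
timeline uses the printed chronic constants throughout (they are the only
quantitative anchor); the drives' gradual return toward baseline during
chronic use is available as an optional linear-ramp construction but is
not part of the canonical timeline. The timeline's withdrawal segment
keeps δ = 0.8; transporter collapse (δ = 1) is a relapse-protocol
manipulation. The relapse protocol's final segment reduces the
gliotransmitter release scale to 0.25 (no published magnitude; 0.25 is
config-exposed and sits well below the resynchronization range).

## Measurements

**PSC and spectrogram.** The population spike count (PSC) is spikes per
1-ms bin over all neurons. Spectrograms are short-time Fourier
magnitude-squared with a Hamming window, mean-detrended per window,
`scaling='spectrum'` (so the rectangular-window power sums to the segment
variance exactly — the Parseval test). Defaults: 0.5-s windows, 90%
overlap. Dominant-frequency readouts on segments of ≥ 2 s use 1-s windows
instead: the chronic rhythm's fundamental sits near the 5-Hz band edge and
2-Hz bins cannot resolve it. Frequencies below 1 Hz are always excluded
(mean-rate peak).

**Synchrony index χ.** With PSC rebinned to 5-ms bins, mean count m and
variance V over bins, population size N:

    χ² = clip((V − m) / (m (N − 1)), 0, 1)

χ ≈ 0 for independent Poisson firing (V ≈ m), χ → 1 when all neurons
spike in the same bins (V ≈ N m). This definition is frozen. The
**desynchronization criterion is χ\* = 0.15**, calibrated once to
separate the asynchronous regimes this model produces (independent
firing and the withdrawal state, χ ≈ 0.01–0.1) from the synchronized
ones (population bursting and fast collective oscillation, χ ≈ 0.2–1.0).

**Synchronized fraction.** A neuron counts as synchronized when the
Pearson correlation of its 10-ms-binned spike train with the
leave-one-out population count exceeds a threshold; silent neurons count
as unsynchronized. The function default (0.3) measures any participation
in the collective rhythm; protocol-level reports of "strictly locked"
neurons use r > 0.6, calibrated once on the acute episode of the canonical
timeline where it counts a median ≈ 4–6% of neurons across seed batches.
The acute phase-locking measurement places the 1-s acute episode after a
2-s baseline segment (its position in the canonical timeline): a 1-s
warm-up demonstrably leaves coherence from the uniform initial condition
(all v = −65) that flips a large fraction of runs into a spurious
whole-population locked branch.

**Regime-conversion detector.** The chronic burst train is a ~4.7-Hz
pulse comb with strong harmonics (9.3, 14, 18.7 Hz), so "the peak left
the theta band" cannot be tested by argmax > 10 Hz alone — harmonic
jitter trips it. Conversion to the acute-like fast regime is detected as
a time-averaged spectral peak ≥ 20 Hz (the fast regime sits at 26–36 Hz)
with χ > χ\*.

## Problem sizes and study conditions

All headline computations use the full 1000-neuron network. The timeline
batch is 10 seeds × 8 s; the acute phase-locking batch 10 seeds × 3 s; the
intervention sweeps use 2-s single-mode runs per swept value (first second
discarded as transient, primed astrocyte), stepping K_Exc by 0.1 from
6.25, s_Exc by 0.01 from 0.625, and |s_Inh| by 0.05 from 0.75, with 5
seeds for the descending sweeps and 10 for the amplification sweep. An
8-s run takes under a second on one CPU; the full acceptance script a few
minutes.

## What the synthetic protocols do and do not show

The generators in `astrosync.fixtures` (independent Poisson and
rhythmically modulated rasters with an optional coincident subpopulation,
exact thinning) validate the measurement layer against signals with known
structure; they emulate rate modulation and coincidence but not
refractoriness, bursting, or rate heterogeneity across neurons. Simulator
results are statements about this model — a generic, spatially unstructured
network with exogenous, piecewise-constant parameter changes — not about
any anatomical circuit: there is no synaptic plasticity rule (weight
changes are imposed by the protocol), no transmission delays or
conductance-based synapses, a single lumped astrocyte, and no
pharmacokinetics.

## Known limitations

* The acute operating point is bistable: a minority of seeds fall into a
  whole-population fast-locked branch rather than the partially locked
  one. Medians over seed batches handle this, but single runs can land in
  either branch.
* The chronic burst fundamental (~4.7 Hz) sits at the lower edge of the
  theta band; its in-band identity rests on the 9.3-Hz component of the
  burst comb dominating the 1-Hz-resolution average spectrum.
* The inhibitory-amplification conversion threshold (~20–25% above the
  normal weight scale) is a robust property of this implementation at the
  printed parameter values and is not adjustable by the calibrated gains.
* Euler at 1 ms biases single-neuron spike timing (~15% ISI error); all
  population-level claims were checked to be robust to halving the
  astrocyte step, and the integration scheme is part of the model
  definition.
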