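# astrosync

A seeded simulator of a 1000-neuron excitatory/inhibitory spiking network
coupled to an astrocyte, built to study how opioid-like changes in drive,
synaptic weights, and glial transporter activity reshape population rhythms
— and, in particular, how a theta-band (5–10 Hz) synchronized state emerges
under "chronic" parameters and how candidate interventions abolish it.

## Who this is for

Computational neuroscientists studying neuron–glia interaction, E/I-balance
protocols, and population synchrony. The package provides the simulator,
declarative experiment timelines, and the measurement layer (spectrograms,
dominant frequencies, synchrony statistics) in one place, all deterministic
per seed.

## The model

**Network.** 800 excitatory (regular-spiking) and 200 inhibitory
(fast-spiking) two-variable quadratic integrate-and-reset neurons:

    v' = 0.04 v² + 5v + 140 − u + I_syn + I_ext + I_astro
    u' = a (b v − u),      if v ≥ 30 mV:  v ← c,  u ← u + d

with per-neuron heterogeneity r ~ U[0,1]: excitatory (c,d) = (−65,8) +
(15,−6) r², inhibitory (a,b) = (0.02,0.25) + (0.08,−0.05) r. All-to-all
random connectivity S = [s_Exc·g1, s_Inh·g2] with g1, g2 uniform [0,1];
I_syn sums the weight columns of the neurons that fired last step. External
drive is white noise per neuron, δ·K_Exc·f1 (excitatory) and δ·K_Inh·f2
(inhibitory), where δ ∈ [0.5, 1] models astrocytic transporter activity.

**Astrocyte.** A lumped compartment (c, c_e, S_m, G_m): cytosolic/ER
calcium exchanging through a nonlinear flux, a second messenger S_m driven
by the rectified presynaptic signal through 1 + tanh(5(K_Exc|f1| − 0.45)),
and gliotransmitter G_m gated by calcium through 1 + tanh(10(c − 0.5)).
Sustained stimulation accumulates S_m, pushes the calcium subsystem across
its oscillation onset, and produces ~1-Hz calcium spikes with accompanying
gliotransmitter pulses that feed back as a uniform current
I_astro = K_Glio·δ·G_m.

**Modes.** Four canonical operating points (K_Exc, K_Inh, s_Exc, s_Inh, δ):
normal (5, 2, 0.5, −1, 0.8), acute (7.5, 1, 0.5, −1, 0.8), chronic
(6.25, 1.5, 0.625, −0.75, 0.8), withdrawal (3.75, 2.5, 0.56, −0.875, 0.8).
Timelines (`timeline`, `glio:<mode>`, `prevention`, `relapse`) switch modes
and single-parameter overrides on 1-s segments.

## Worked example

```python
from astrosync import SimulationConfig, run_simulation, window_report

res = run_simulation(SimulationConfig(schedule="timeline", master_seed=1))
print(f"{res.raster.n_spikes} spikes from {res.raster.n_neurons} neurons")
for name, (lo, hi) in {"normal": (0, 2000), "acute": (2000, 3000),
                       "chronic": (3000, 6000), "withdrawal": (6000, 8000)}.items():
    rep = window_report(res.raster, (lo, hi))
    print(f"{name:11s} chi={rep.chi:5.3f}  dominant={rep.dominant_freq_hz:5.1f} Hz  "
          f"theta fraction={rep.band_power_fraction:.2f}  "
          f"locked fraction={rep.synchronized_fraction:.2f}")
```

prints

```
222155 spikes from 1000 neurons
normal      chi=0.107  dominant=  6.0 Hz  theta fraction=0.35  locked fraction=0.13
acute       chi=0.230  dominant= 30.0 Hz  theta fraction=0.01  locked fraction=0.37
chronic     chi=1.000  dominant=  9.0 Hz  theta fraction=0.25  locked fraction=1.00
withdrawal  chi=0.049  dominant=  1.0 Hz  theta fraction=0.13  locked fraction=0.07
```

Reading: the baseline network is weakly synchronous; the acute segment
locks part of the population into a fast (~30 Hz) collective oscillation;
the chronic segment collapses into full-population theta-range bursting
(synchrony index χ saturates, spectral peak inside 5–10 Hz); withdrawal is
asynchronous and sparse. In the `relapse` schedule, deactivating the
transporters (δ → 1) resynchronizes the withdrawal network and reducing
gliotransmitter release de-synchronizes it again.

The same experiments run from the shell:

```bash
astrosync simulate --config run.yaml --seed 7 --out outdir/
astrosync reproduce timeline --seeds 10 --out outdir/
astrosync sweep --param mode.k_exc --from 6.25 --to 3.0 --steps 14 \
    --schedule mode:chronic:2 --metric synchrony --out sweep.csv
astrosync analyze --raster outdir/seed_0/raster.csv \
    --windows "normal=0:2,chronic=3:6" --out report.json
astrosync fixtures make --kind rhythmic --freq 6 --out raster.csv
```

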