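"""Simulate spiking activity on a structural network.

Runs 30 s of Izhikevich dynamics (regular-spiking excitatory, fast-spiking
inhibitory, exponential synapses, pooled Poisson drive) and summarises the
spike trains the correlation stage consumes.
"""

import numpy as np

import spikeplex as sp

net = sp.build_structural_network(sp.BuildParams(), rng=42)
params = sp.SimulationParams(duration_ms=30_000, rng_seed=7)
spikes = sp.simulate(net, params)

rates = spikes.firing_rates()
inh = net.is_inhibitory
print(f"simulated {params.duration_ms / 1000:.0f} s at dt = {params.dt} ms")
print(f"mean firing rate: {rates.mean():.1f} Hz "
      f"(excitatory {rates[~inh].mean():.1f} Hz, inhibitory {rates[inh].mean():.1f} Hz)")
print(f"total spikes: {sum(len(t) for t in spikes.spike_times)}")

binned = spikes.binned
print(f"binned matrix: {binned.shape[0]} neurons x {binned.shape[1]} one-ms bins, "
      f"spike probability per bin {binned.mean():.4f}")
print("a few spike times of neuron 0 (ms):", np.round(spikes.spike_times[0][:5], 1))
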