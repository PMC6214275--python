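"""Build a structural network: lattice, small-world rewiring, recurrence control.

Constructs the default 100-neuron network (10x10 grid, neighbour cutoff
sqrt(2), rewiring probability 0.4, 40% of undirected edges made
unidirectional) and prints its composition.
"""

import numpy as np

import spikeplex as sp

net = sp.build_regular_lattice(10, 10)
print(f"regular lattice: {net.n_undirected_edges()} undirected edges "
      "(interior neurons have 8 neighbours, edges 5, corners 3)")

rng = np.random.default_rng(42)
net = sp.rewire_small_world(net, p_rw=0.4, rng=rng)
net = sp.reduce_recurrence(net, p_r=0.4, p_d=0.5, rng=rng)
net = sp.assign_types_and_weights(net, inhibitory_fraction=0.2, rng=rng)

n_rec = len(net.undirected_edges())
print(f"after rewiring and recurrence reduction: {net.n_directed_edges} directed edges, "
      f"{n_rec} recurrent pairs ({100 * n_rec / 342:.1f}% of connections recurrent)")
print(f"neuron types: {int((~net.is_inhibitory).sum())} excitatory, "
      f"{int(net.is_inhibitory.sum())} inhibitory")
w = net.weights[net.weights > 0]
print(f"excitatory synaptic amplitudes: mean {w.mean():.2f} mV, sd {w.std():.2f} mV "
      "(inhibitory fixed at -1.5 mV)")
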