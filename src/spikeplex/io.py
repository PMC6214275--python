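"""Readers and writers for the pipeline's on-disk artefacts.

Conventions: 0-based vertex indices everywhere; directed edge lists as CSV
with columns ``source,target,weight``; GraphML carries ``neuron_type``
(``"excitatory"`` / ``"inhibitory"``) and grid ``pos_row`` / ``pos_col``
node attributes; spike trains as ``neuron_id,spike_time_ms`` CSV or as an
HDF5 container of the binned binary matrix; censuses and Z-score tables as
tidy CSV; run manifests as YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .multiplex import DYAD_TRANSFORMATIONS, DiscrepancySet
from .network import StructuralNetwork
from .nulls import ZScoreTable
from .simulate import SpikeTrainSet

__all__ = [
    "save_edgelist_csv",
    "load_edgelist_csv",
    "save_graphml",
    "load_graphml",
    "save_spikes_csv",
    "load_spikes_csv",
    "save_binned_hdf5",
    "load_binned_hdf5",
    "save_correlation_csv",
    "load_correlation_csv",
    "save_dyadic_census_csv",
    "save_triadic_census_csv",
    "save_zscores_csv",
    "save_discrepancies_csv",
    "save_manifest",
    "load_manifest",
]


def _adjacency_weights(net) -> tuple[np.ndarray, np.ndarray]:
    adj = np.asarray(getattr(net, "adjacency", net))
    weights = getattr(net, "weights", None)
    if weights is None:
        weights = adj.astype(float)
    return adj, np.asarray(weights)


def save_edgelist_csv(net, path) -> None:
    """Directed edge list with columns ``source,target,weight``."""
    adj, weights = _adjacency_weights(net)
    tgt, src = np.nonzero(adj)
    pd.DataFrame(
        {"source": src, "target": tgt, "weight": weights[tgt, src]}
    ).to_csv(path, index=False)


def load_edgelist_csv(path, n_neurons: int | None = None) -> StructuralNetwork:
    """Rebuild a network from an edge-list CSV (positions default to a line)."""
    df = pd.read_csv(path)
    n = n_neurons or (int(df[["source", "target"]].max().max()) + 1 if len(df) else 0)
    adj = np.zeros((n, n), dtype=np.uint8)
    weights = np.zeros((n, n))
    adj[df["target"], df["source"]] = 1
    weights[df["target"], df["source"]] = df["weight"]
    inh = np.zeros(n, dtype=bool)
    for j in range(n):
        out = weights[:, j][adj[:, j] > 0]
        if out.size and np.all(out < 0):
            inh[j] = True
    return StructuralNetwork(
        adjacency=adj,
        positions=np.column_stack([np.zeros(n, dtype=int), np.arange(n)]),
        is_inhibitory=inh,
        weights=weights,
    )


def save_graphml(net, path) -> None:
    """GraphML export with neuron type and grid position node attributes."""
    adj, weights = _adjacency_weights(net)
    g = nx.DiGraph()
    inh = np.asarray(getattr(net, "is_inhibitory", np.zeros(adj.shape[0], dtype=bool)))
    pos = getattr(net, "positions", None)
    for v in range(adj.shape[0]):
        attrs = {"neuron_type": "inhibitory" if inh[v] else "excitatory"}
        if pos is not None:
            attrs["pos_row"], attrs["pos_col"] = int(pos[v][0]), int(pos[v][1])
        g.add_node(v, **attrs)
    tgt, src = np.nonzero(adj)
    for s, t in zip(src.tolist(), tgt.tolist()):
        g.add_edge(s, t, weight=float(weights[t, s]))
    nx.write_graphml(g, path)


def load_graphml(path) -> StructuralNetwork:
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes, key=int)
    n = len(nodes)
    idx = {v: int(v) for v in nodes}
    adj = np.zeros((n, n), dtype=np.uint8)
    weights = np.zeros((n, n))
    for s, t, data in g.edges(data=True):
        adj[idx[t], idx[s]] = 1
        weights[idx[t], idx[s]] = float(data.get("weight", 1.0))
    inh = np.array([g.nodes[v].get("neuron_type") == "inhibitory" for v in nodes])
    pos = np.array(
        [(int(g.nodes[v].get("pos_row", 0)), int(g.nodes[v].get("pos_col", 0))) for v in nodes]
    )
    return StructuralNetwork(adjacency=adj, positions=pos, is_inhibitory=inh, weights=weights)


def save_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    rows = [
        (i, t) for i, times in enumerate(spikes.spike_times) for t in np.asarray(times)
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"]).to_csv(path, index=False)


def load_spikes_csv(path, n_neurons: int, duration_ms: float) -> SpikeTrainSet:
    df = pd.read_csv(path)
    times = [
        np.sort(df.loc[df["neuron_id"] == i, "spike_time_ms"].to_numpy(dtype=float))
        for i in range(n_neurons)
    ]
    return SpikeTrainSet(spike_times=times, duration_ms=duration_ms)


def save_binned_hdf5(spikes: SpikeTrainSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("binned", data=spikes.binned, compression="gzip")
        f.attrs["duration_ms"] = spikes.duration_ms
        if spikes.rng_seed is not None:
            f.attrs["rng_seed"] = spikes.rng_seed


def load_binned_hdf5(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["binned"][...]


def save_correlation_csv(corr, path, manifest_path=None) -> None:
    """Dense correlation matrix CSV plus an optional YAML sidecar manifest."""
    pd.DataFrame(corr.values).to_csv(path, index=False, header=False)
    if manifest_path is not None:
        save_manifest(
            {
                "method": corr.method,
                "params": vars(corr.params) if corr.params is not None else {},
                "n_neurons": int(corr.values.shape[0]),
            },
            manifest_path,
        )


def load_correlation_csv(path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def save_dyadic_census_csv(counts, path) -> None:
    pd.DataFrame(
        {"transformation": list(DYAD_TRANSFORMATIONS), "count": np.asarray(counts)}
    ).to_csv(path, index=False)


def save_triadic_census_csv(counts, path) -> None:
    """Tidy 256-row table: structural_class, functional_class, count."""
    counts = np.asarray(counts)
    rows = [
        (s + 1, f, int(counts[s, f - 1]))
        for s in range(16)
        for f in range(1, 17)
    ]
    pd.DataFrame(rows, columns=["structural_class", "functional_class", "count"]).to_csv(
        path, index=False
    )


def save_zscores_csv(table: ZScoreTable, labels, path) -> None:
    """Tidy Z-score table: transformation, observed, mu, sigma, z, defined."""
    z = table.z.ravel()
    pd.DataFrame(
        {
            "transformation": list(labels),
            "observed": table.observed.ravel(),
            "mu": table.mu.ravel(),
            "sigma": table.sigma.ravel(),
            "z": z,
            "defined": table.defined.ravel(),
        }
    ).to_csv(path, index=False)


def save_discrepancies_csv(disc: DiscrepancySet, path) -> None:
    rows = [(s, t, "FP") for s, t in disc.false_positives] + [
        (s, t, "FN") for s, t in disc.false_negatives
    ]
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(path, index=False)


def save_manifest(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_results_bundle(bundle, outdir) -> None:
    """Write one experiment's artefacts under ``outdir``.

    Per trial: structural network (edge-list CSV + GraphML), spike times
    (CSV), correlation matrices (CSV), and per (method, kappa) the
    functional edge list, censuses, discrepancies and Z-score tables as
    tidy CSV; plus a top-level YAML manifest with every seed and parameter.
    """
    from .multiplex import DYAD_TRANSFORMATIONS as _DY

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    manifest = {
        "n_trials": len(bundle.trials),
        "trial_seeds": [t.trial_seed for t in bundle.trials],
    }
    if cfg is not None:
        manifest.update(
            {
                "build": vars(cfg.build),
                "sim": {
                    k: v for k, v in vars(cfg.sim).items() if not isinstance(v, np.ndarray)
                },
                "methods": list(cfg.methods),
                "kappas": list(cfg.kappas),
                "n_null": cfg.n_null,
                "null_iterations": cfg.null_iterations,
                "seed": cfg.seed,
            }
        )
    save_manifest(manifest, outdir / "manifest.yaml")
    tri_labels = [f"{s}->{f}" for s in range(1, 17) for f in range(1, 17)]
    for t in bundle.trials:
        tdir = outdir / f"trial_{t.trial_seed}"
        tdir.mkdir(exist_ok=True)
        save_edgelist_csv(t.network, tdir / "structural.csv")
        save_graphml(t.network, tdir / "structural.graphml")
        save_spikes_csv(t.spikes, tdir / "spikes.csv")
        for method, corr in t.correlations.items():
            save_correlation_csv(
                corr, tdir / f"correlation_{method}.csv", tdir / f"correlation_{method}.yaml"
            )
        for (method, kappa), rec in t.reconstructions.items():
            tag = f"{method}_kappa{kappa}"
            save_edgelist_csv(rec.functional, tdir / f"functional_{tag}.csv")
            save_dyadic_census_csv(rec.dyadic_counts, tdir / f"dyadic_census_{tag}.csv")
            save_triadic_census_csv(rec.triadic_counts, tdir / f"triadic_census_{tag}.csv")
            save_discrepancies_csv(rec.discrepancies, tdir / f"discrepancies_{tag}.csv")
            save_zscores_csv(rec.dyadic_z, _DY, tdir / f"dyadic_z_{tag}.csv")
            save_zscores_csv(rec.triadic_z, tri_labels, tdir / f"triadic_z_{tag}.csv")
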