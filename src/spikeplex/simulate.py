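"""Izhikevich spiking-network simulation: the pipeline's synthetic-data stage.

Two neuron classes are simulated with forward Euler:

* regular-spiking excitatory (pyramidal) cells,
      ``100 dv/dt = 0.7 (v+60)(v+40) - u + I_E``,
      ``du/dt = 0.03 (-2 (v+60)) - u``,
  reset at ``v >= 35`` mV to ``v = -50``, ``u <- u + 100``;
* fast-spiking inhibitory interneurons,
      ``20 dv/dt = (v+55)(v+40) - u + I_I``,
      ``du/dt = 0.2 (U(v) - u)`` with ``U(v) = 0.025 (v - v_b)^3`` for
      ``v >= v_b`` (``v_b = -55`` mV) and 0 otherwise,
  reset at ``v >= 25`` mV to ``v = -45``.

Synapses follow a simple exponential decay: a presynaptic spike at ``t_k``
contributes ``v_X exp(-(t - t_X - t_k)/tau)`` for ``t >= t_k + t_X``
(amplitude ``v_X`` mV, onset delay ``t_X`` = 5 ms excitatory / 1 ms
inhibitory, ``tau`` = 3 ms). Because all synapses share ``tau``, the
superposed contribution per neuron is tracked exactly by one decaying
accumulator plus a delay ring buffer.

The summed synaptic trace enters the current term as
``I = (C / tau) * sum_k S_X``, so that the total membrane charge delivered
by one synaptic event is ``C * v_X`` and the peak depolarisation of a
quiescent cell approximates the synaptic amplitude ``v_X`` -- the natural
reading of "maximum voltage increase delivered to the postsynaptic cell".
The gain is configurable (``synaptic_gain_exc`` / ``synaptic_gain_inh``,
one value per *target* population).

External drive is a pooled excitatory Poisson event train per neuron
(events pass through the standard excitatory synapse with amplitude drawn
from N(3.1, 0.1) mV), modelling many independent external afferents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "NeuronState",
    "SynapseSpec",
    "SimulationParams",
    "SpikeTrainSet",
    "step_excitatory",
    "step_inhibitory",
    "synaptic_contribution",
    "simulate",
    "bin_spikes",
]

V_PEAK_EXC = 35.0
V_RESET_EXC = -50.0
V_PEAK_INH = 25.0
V_RESET_INH = -45.0
V_REST_EXC = -60.0
V_REST_INH = -55.0


class SimulationError(RuntimeError):
    """Raised when the integration becomes non-finite or unstable."""


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and adaptation variable ``u``."""

    v: float
    u: float


@dataclass
class SynapseSpec:
    """One synaptic event: amplitude ``v_x`` (mV), onset delay ``t_x`` (ms),
    decay constant ``tau`` (ms) and presynaptic spike time ``t_k`` (ms)."""

    v_x: float
    t_x: float
    tau: float
    t_k: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.t_x < 0:
            raise ValueError("t_x must be non-negative")


@dataclass
class SimulationParams:
    """Simulation configuration.

    ``poisson_rate_exc`` / ``poisson_rate_inh`` are the *pooled* external
    Poisson event rates (Hz) seen by each excitatory / inhibitory neuron;
    they stand for many external afferents (e.g. a pooled 1000 Hz equals
    100 afferents at the nominal 10 Hz per-afferent rate). Defaults put
    both populations in a fluctuation-driven regime with mean drive near
    rheobase, yielding irregular firing at a few spikes per second.
    """

    duration_ms: float = 600_000.0
    dt: float = 0.025
    poisson_rate_exc: float = 170.0
    poisson_rate_inh: float = 700.0
    poisson_amp_mean: float = 3.1
    poisson_amp_sd: float = 0.1
    v_b: float = -55.0
    tau_syn: float = 3.0
    delay_exc: float = 5.0
    delay_inh: float = 1.0
    synaptic_gain_exc: float = 100.0 / 3.0
    synaptic_gain_inh: float = 20.0 / 3.0
    rng_seed: int = 0
    v_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms <= 0 or abs(self.duration_ms - round(self.duration_ms)) > 1e-9:
            raise ValueError("duration_ms must be a positive whole number of ms")


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times (ms) over ``[0, duration_ms)``."""

    spike_times: list[np.ndarray]
    duration_ms: float
    rng_seed: int | None = None
    _binned: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def binned(self) -> np.ndarray:
        """``(n, T)`` binary matrix with 1 ms bins (entry 1 iff >= 1 spike)."""
        if self._binned is None:
            self._binned = bin_spikes(self.spike_times, self.duration_ms)
        return self._binned

    def firing_rates(self) -> np.ndarray:
        """Mean rate per neuron in Hz."""
        counts = np.array([len(t) for t in self.spike_times], dtype=float)
        return counts / (self.duration_ms / 1000.0)


def step_excitatory(state: NeuronState, i_ext: float, dt: float) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the regular-spiking model; returns (state, spiked)."""
    v, u = state.v, state.u
    if not (np.isfinite(v) and np.isfinite(u) and np.isfinite(i_ext)):
        raise SimulationError("non-finite excitatory state or input")
    dv = (0.7 * (v + 60.0) * (v + 40.0) - u + i_ext) / 100.0
    du = 0.03 * (-2.0 * (v + 60.0)) - u
    v_new = v + dt * dv
    u_new = u + dt * du
    if v_new >= V_PEAK_EXC:
        return NeuronState(V_RESET_EXC, u_new + 100.0), True
    return NeuronState(v_new, u_new), False


def step_inhibitory(
    state: NeuronState, i_ext: float, dt: float, v_b: float = -55.0
) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the fast-spiking model; returns (state, spiked)."""
    v, u = state.v, state.u
    if not (np.isfinite(v) and np.isfinite(u) and np.isfinite(i_ext)):
        raise SimulationError("non-finite inhibitory state or input")
    u_v = 0.025 * (v - v_b) ** 3 if v >= v_b else 0.0
    dv = ((v + 55.0) * (v + 40.0) - u + i_ext) / 20.0
    du = 0.2 * (u_v - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    if v_new >= V_PEAK_INH:
        return NeuronState(V_RESET_INH, u_new), True
    return NeuronState(v_new, u_new), False


def synaptic_contribution(spec: SynapseSpec, t: float) -> float:
    """Voltage contribution of one synaptic event at time ``t`` (ms).

    Zero before onset (``t < t_k + t_x``); afterwards the amplitude decays
    exponentially with constant ``tau``. Contributions of successive spikes
    superpose linearly.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    onset = spec.t_k + spec.t_x
    if t < onset:
        return 0.0
    return spec.v_x * np.exp(-(t - onset) / spec.tau)


@njit(cache=True)
def _run_kernel(
    n_steps,
    dt,
    v,
    u,
    is_inh,
    out_ptr,
    out_tgt,
    out_w,
    d_exc,
    d_inh,
    decay,
    gain,
    v_b,
    ev_ptr,
    ev_step,
    ev_amp,
    buf,
    spike_n,
    spike_t,
):
    n = v.shape[0]
    ring = buf.shape[1]
    g = np.zeros(n)
    eidx = ev_ptr[:-1].copy()
    count = 0
    cap = spike_n.shape[0]
    for t in range(n_steps):
        slot = t % ring
        for i in range(n):
            g[i] = g[i] * decay + buf[i, slot]
            buf[i, slot] = 0.0
            while eidx[i] < ev_ptr[i + 1] and ev_step[eidx[i]] == t:
                g[i] += ev_amp[eidx[i]]
                eidx[i] += 1
        for i in range(n):
            cur = gain[i] * g[i]
            vi = v[i]
            ui = u[i]
            spiked = False
            if is_inh[i]:
                if vi >= v_b:
                    dv_b = vi - v_b
                    u_v = 0.025 * dv_b * dv_b * dv_b
                else:
                    u_v = 0.0
                vn = vi + dt * (((vi + 55.0) * (vi + 40.0) - ui + cur) / 20.0)
                un = ui + dt * (0.2 * (u_v - ui))
                if vn >= 25.0:
                    vn = -45.0
                    spiked = True
            else:
                vn = vi + dt * ((0.7 * (vi + 60.0) * (vi + 40.0) - ui + cur) / 100.0)
                un = ui + dt * (0.03 * (-2.0 * (vi + 60.0)) - ui)
                if vn >= 35.0:
                    vn = -50.0
                    un = un + 100.0
                    spiked = True
            if not np.isfinite(vn) or abs(vn) > 1.0e3:
                return count, 1
            v[i] = vn
            u[i] = un
            if spiked:
                if count >= cap:
                    return count, 2
                spike_n[count] = i
                spike_t[count] = (t + 1) * dt
                count += 1
                d = d_inh if is_inh[i] else d_exc
                arrive = (t + 1 + d) % ring
                for e in range(out_ptr[i], out_ptr[i + 1]):
                    buf[out_tgt[e], arrive] += out_w[e]
    return count, 0


def simulate(net, params: SimulationParams) -> SpikeTrainSet:
    """Simulate the network and return its spike trains.

    Deterministic for a fixed ``params.rng_seed`` (external Poisson event
    times are generated in ms, independent of ``dt``, so refining the step
    keeps the drive identical). Raises :class:`SimulationError` on
    numerical blow-up.
    """
    n = net.n_neurons
    dt = params.dt
    n_steps = int(round(params.duration_ms / dt))
    rng = np.random.default_rng(params.rng_seed)

    is_inh = np.asarray(net.is_inhibitory, dtype=np.bool_)
    # CSR over sources: targets and weights of each neuron's out-edges
    targets, sources = np.nonzero(net.adjacency)
    order = np.argsort(sources, kind="stable")
    sources = sources[order]
    targets = targets[order]
    w = net.weights[targets, sources].astype(np.float64)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_ptr, sources + 1, 1)
    out_ptr = np.cumsum(out_ptr)

    # external Poisson events: per-neuron pooled train, excitatory synapse shape
    ev_step_parts: list[np.ndarray] = []
    ev_amp_parts: list[np.ndarray] = []
    ev_ptr = np.zeros(n + 1, dtype=np.int64)
    d_exc = int(round(params.delay_exc / dt))
    d_inh = int(round(params.delay_inh / dt))
    for i in range(n):
        rate = params.poisson_rate_inh if is_inh[i] else params.poisson_rate_exc
        n_ev = rng.poisson(rate * params.duration_ms / 1000.0)
        t_ev = np.sort(rng.uniform(0.0, params.duration_ms, size=n_ev))
        steps = np.floor(t_ev / dt).astype(np.int64) + d_exc
        keep = steps < n_steps
        ev_step_parts.append(steps[keep])
        ev_amp_parts.append(
            rng.normal(params.poisson_amp_mean, params.poisson_amp_sd, size=n_ev)[keep]
        )
        ev_ptr[i + 1] = ev_ptr[i] + int(keep.sum())
    ev_step = np.concatenate(ev_step_parts) if n else np.empty(0, dtype=np.int64)
    ev_amp = np.concatenate(ev_amp_parts) if n else np.empty(0)

    v = np.where(is_inh, V_REST_INH, V_REST_EXC).astype(np.float64)
    if params.v_init is not None:
        v = np.asarray(params.v_init, dtype=np.float64).copy()
    u = np.zeros(n)
    gain = np.where(is_inh, params.synaptic_gain_inh, params.synaptic_gain_exc).astype(
        np.float64
    )
    decay = float(np.exp(-dt / params.tau_syn))
    ring = max(d_exc, d_inh) + 2
    buf = np.zeros((n, ring))

    cap = int(n * params.duration_ms / 1000.0 * 150) + 1024  # 150 Hz mean-rate headroom
    spike_n = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap)
    count, status = _run_kernel(
        n_steps,
        dt,
        v,
        u,
        is_inh,
        out_ptr,
        targets,
        w,
        d_exc,
        d_inh,
        decay,
        gain,
        params.v_b,
        ev_ptr,
        ev_step,
        ev_amp,
        buf,
        spike_n,
        spike_t,
    )
    if status == 1:
        raise SimulationError("membrane potential diverged (|v| > 1e3 mV)")
    if status == 2:
        raise SimulationError("spike buffer overflow (sustained firing above 150 Hz)")
    # a spike in the very last step would land exactly at `duration`; keep it
    # inside the half-open train domain [0, duration)
    np.clip(spike_t[:count], 0.0, np.nextafter(params.duration_ms, 0.0), out=spike_t[:count])
    spike_times = [
        np.sort(spike_t[:count][spike_n[:count] == i]).astype(float) for i in range(n)
    ]
    return SpikeTrainSet(
        spike_times=spike_times,
        duration_ms=float(params.duration_ms),
        rng_seed=int(params.rng_seed),
    )


def bin_spikes(spike_times: list[np.ndarray], duration_ms: float) -> np.ndarray:
    """Bin spike times into a binary ``(n, T)`` matrix with 1 ms bins.

    Bin index is ``floor(t)``; multiple spikes in one bin clip to 1.
    Times outside ``[0, duration_ms)`` are rejected.
    """
    t_bins = int(round(duration_ms))
    out = np.zeros((len(spike_times), t_bins), dtype=np.uint8)
    for i, times in enumerate(spike_times):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        if times.min() < 0 or times.max() >= duration_ms:
            raise ValueError("spike time outside [0, duration)")
        out[i, np.floor(times).astype(int)] = 1
    return out
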