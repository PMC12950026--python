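"""Fixed-step integrate-and-fire neuron models.

Two model classes drive the whole network: an Adaptive Exponential
Integrate-and-Fire (AdEx) neuron for mechanosensory afferents, whose
spike-triggered adaptation current produces the phasic-tonic response of
hair-field sensilla, and a Leaky Integrate-and-Fire (LIF) neuron for the
downstream interneurons, which integrates weighted presynaptic spikes.

All state equations are advanced with a backward-difference (implicit
Euler) scheme on a uniform grid.  The AdEx exponential spike-initiation
term is the one nonlinearity; it is evaluated at the previous step's
voltage (semi-implicit) so each update stays a linear solve.  Units
throughout: time in ms, voltage in mV, current in pA, capacitance in pF,
conductance in nS.  Rates are reported in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AdExParams",
    "LIFParams",
    "CurrentTrace",
    "SpikeTrain",
    "integrate_adex",
    "integrate_lif",
    "steady_state_rate",
]

#: Default ceiling on the AdEx exponential argument (V - V_T)/delta_T.
#: Spikes are detected at V > V_T, so the clamp only limits the size of
#: the (discarded) overshoot, never whether a spike occurs.
EXP_ARG_CAP = 20.0

#: Hard divergence ceiling for the membrane potential (mV).  With the
#: exponential clamp the overshoot is finite; anything beyond this is a
#: genuine numerical failure and is rejected with a diagnostic.
V_CEILING = 1e9


@dataclass(frozen=True)
class AdExParams:
    """AdEx neuron parameters.

    Defaults are the optimized sensory-afferent values: C = 200 pF,
    g_L = 2 nS, E_L = -70 mV, delta_T = 2 mV, V_T = -50 mV, a = 2 nS,
    tau_w = 50 ms, b = 264 pA.  ``b`` is the spike-triggered increment of
    the adaptation *current* w and therefore carries units of pA.
    """

    C: float = 200.0
    g_L: float = 2.0
    E_L: float = -70.0
    delta_T: float = 2.0
    V_T: float = -50.0
    a: float = 2.0
    tau_w: float = 50.0
    b: float = 264.0
    exp_cap: float = EXP_ARG_CAP

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g_L < 0:
            raise ValueError("g_L must be non-negative")
        if self.delta_T <= 0:
            raise ValueError("delta_T must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if not self.V_T > self.E_L:
            raise ValueError("V_T must exceed E_L")


@dataclass(frozen=True)
class LIFParams:
    """LIF interneuron parameters.

    The only tunable parameters are the membrane decay time constant
    ``tau`` (ms) and the synaptic weight ``omega`` (mV) added per
    presynaptic spike.  Resting/reset potential and threshold default to
    the shared -70 / -50 mV of the network.
    """

    tau: float
    omega: float
    E_L: float = -70.0
    V_T: float = -50.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.V_T > self.E_L:
            raise ValueError("V_T must exceed E_L")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


def _check_uniform_grid(t: np.ndarray, dt: float | None = None) -> float:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 samples")
    steps = np.diff(t)
    if steps.min() <= 0:
        raise ValueError("time grid must be strictly increasing")
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=1e-9, atol=1e-9):
        raise ValueError("time grid must be uniform")
    if dt is not None and not np.isclose(step, dt, rtol=1e-9, atol=1e-9):
        raise ValueError(f"dt={dt} does not match grid step {step}")
    return step


@dataclass
class CurrentTrace:
    """Input current I(t) in pA on a uniform time grid (ms)."""

    t: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have identical shape")
        _check_uniform_grid(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @classmethod
    def constant(cls, I: float, duration: float, dt: float) -> "CurrentTrace":
        n = int(round(duration / dt))
        t = np.arange(n) * dt
        return cls(t, np.full(n, float(I)))


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) of one neuron over [0, duration]."""

    spike_times: np.ndarray
    duration: float
    neuron_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in ms."""
        return np.diff(self.spike_times)

    def peak_rate(self) -> float:
        """Peak instantaneous rate, 1000 / min ISI, in Hz (0 if < 2 spikes)."""
        isis = self.isis()
        return 1000.0 / isis.min() if isis.size else 0.0


# ---------------------------------------------------------------------------
# AdEx integration
# ---------------------------------------------------------------------------

def adex_matrix(
    I: np.ndarray,
    params: AdExParams,
    dt: float,
    b: np.ndarray | None = None,
    record: bool = False,
):
    """Integrate a bank of AdEx neurons sharing all parameters except,
    optionally, the adaptation increment ``b``.

    Parameters
    ----------
    I : array, shape (n_neurons, n_steps)
        Input current per neuron and step, pA.
    b : optional array, shape (n_neurons,)
        Per-neuron spike-triggered adaptation increment, overriding
        ``params.b`` (used by the grid search).

    Returns
    -------
    spikes : bool array (n_neurons, n_steps); optionally also the voltage
    and adaptation traces when ``record`` is true.

    Scheme: linear terms implicit, exponential term evaluated at the
    previous voltage.  With k = dt*a/(tau_w + dt) the coupled update is

        V' = [C V + dt (I + g_L E_L + E_exp - tau_w w/(tau_w+dt) + k E_L)]
             / (C + dt g_L + dt k)
        w' = tau_w w/(tau_w+dt) + k (V' - E_L)

    followed by threshold test V' > V_T, reset to E_L, and w' += b.
    """
    p = params
    I = np.atleast_2d(np.asarray(I, dtype=float))
    n, T = I.shape
    b_vec = np.full(n, p.b) if b is None else np.asarray(b, dtype=float)
    V = np.full(n, p.E_L)
    w = np.zeros(n)
    k = dt * p.a / (p.tau_w + dt)
    w_keep = p.tau_w / (p.tau_w + dt)
    denom = p.C + dt * (p.g_L + k)
    spikes = np.zeros((n, T), dtype=bool)
    V_rec = np.empty((n, T)) if record else None
    w_rec = np.empty((n, T)) if record else None
    gLdT = p.g_L * p.delta_T
    for i in range(T):
        e_term = gLdT * np.exp(np.minimum((V - p.V_T) / p.delta_T, p.exp_cap))
        w_part = w_keep * w
        V = (p.C * V + dt * (I[:, i] + p.g_L * p.E_L + e_term - w_part + k * p.E_L)) / denom
        w = w_part + k * (V - p.E_L)
        s = V > p.V_T
        spikes[:, i] = s
        if np.any(s):
            V = np.where(s, p.E_L, V)
            w = np.where(s, w + b_vec, w)
        if record:
            V_rec[:, i] = V
            w_rec[:, i] = w
    if not np.all(np.abs(V) < V_CEILING) or not np.all(np.isfinite(V)):
        raise FloatingPointError(
            "AdEx membrane potential diverged despite the exponential clamp; "
            "check dt and parameter magnitudes"
        )
    if record:
        return spikes, V_rec, w_rec
    return spikes


def integrate_adex(
    current: CurrentTrace,
    params: AdExParams,
    dt: float | None = None,
    record_voltage: bool = False,
    neuron_id: str = "",
):
    """Integrate one AdEx neuron driven by ``current``.

    Initial state is rest: V = E_L, w = 0.  A spike is recorded at every
    step whose updated voltage exceeds V_T; the voltage then resets to
    E_L and the adaptation current jumps by ``b``.  Returns a
    :class:`SpikeTrain`; with ``record_voltage`` also the voltage and
    adaptation arrays on the input grid.
    """
    step = _check_uniform_grid(current.t, dt)
    duration = float(current.t[-1] - current.t[0] + step)
    out = adex_matrix(current.I[None, :], params, step, record=record_voltage)
    if record_voltage:
        spikes, V, w = out
    else:
        spikes = out
    times = (np.flatnonzero(spikes[0]) + 1) * step
    train = SpikeTrain(times, duration=duration, neuron_id=neuron_id)
    if record_voltage:
        return train, V[0], w[0]
    return train


# ---------------------------------------------------------------------------
# LIF integration
# ---------------------------------------------------------------------------

def lif_matrix(
    w_in: np.ndarray,
    params: LIFParams,
    dt: float,
    tau: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate a bank of LIF neurons from per-step summed input weights.

    ``w_in`` has shape (n_neurons, n_steps) and holds, for each step, the
    total voltage increment (mV) delivered by presynaptic spikes binned
    into that step.  ``tau`` optionally overrides the time constant per
    neuron.  Returns a bool spike matrix.  Per step: implicit decay
    toward E_L, then the synaptic increment, then threshold/reset.
    """
    p = params
    w_in = np.atleast_2d(np.asarray(w_in, dtype=float))
    n, T = w_in.shape
    tau_vec = np.full(n, p.tau) if tau is None else np.asarray(tau, dtype=float)
    decay = 1.0 / (1.0 + dt / tau_vec)
    V = np.full(n, p.E_L)
    spikes = np.zeros((n, T), dtype=bool)
    for i in range(T):
        V = p.E_L + (V - p.E_L) * decay + w_in[:, i]
        s = V > p.V_T
        spikes[:, i] = s
        if np.any(s):
            V = np.where(s, p.E_L, V)
    return spikes


def events_to_grid(
    times: np.ndarray, weights: np.ndarray, dt: float, n_steps: int
) -> np.ndarray:
    """Bin (time, weight) events onto the simulation grid.

    Events are assigned to the nearest step; multiple events in one step
    sum their weights.  An event at time t lands on step round(t/dt) - 1,
    i.e. spikes emitted at the end of step i act on step i of the
    postsynaptic update (zero transmission delay).
    """
    idx = np.rint(np.asarray(times, dtype=float) / dt).astype(int) - 1
    idx = np.clip(idx, 0, n_steps - 1)
    out = np.zeros(n_steps)
    np.add.at(out, idx, np.asarray(weights, dtype=float))
    return out


def integrate_lif(
    events: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    params: LIFParams,
    dt: float,
    duration: float,
    neuron_id: str = "",
) -> SpikeTrain:
    """Integrate one LIF neuron from presynaptic (time, weight) events.

    The voltage decays toward E_L with time constant tau between events;
    each event adds its weight; V > V_T emits a spike and resets to E_L.
    Events must lie within [0, duration].
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if isinstance(events, tuple) and len(events) == 2 and np.ndim(events[0]) == 1:
        times = np.asarray(events[0], dtype=float)
        weights = np.asarray(events[1], dtype=float)
    else:
        ev = list(events)
        times = np.array([e[0] for e in ev], dtype=float)
        weights = np.array([e[1] for e in ev], dtype=float)
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ValueError("event times must lie within [0, duration]")
    n_steps = int(round(duration / dt))
    w_in = events_to_grid(times, weights, dt, n_steps)
    spikes = lif_matrix(w_in[None, :], params, dt)
    spike_times = (np.flatnonzero(spikes[0]) + 1) * dt
    return SpikeTrain(spike_times, duration=n_steps * dt, neuron_id=neuron_id)


# ---------------------------------------------------------------------------
# Steady-state (tonic) rate
# ---------------------------------------------------------------------------

def steady_state_rate(
    params: AdExParams,
    I_const: float,
    dt: float = 0.25,
    settle_time: float | None = None,
    window: float = 500.0,
) -> float:
    """Equilibrium tonic firing rate (Hz) under a constant current.

    Simulates for ``settle_time`` (default 10 * tau_w, at least 500 ms)
    plus a measurement window and returns the reciprocal of the mean
    inter-spike interval over the window.  On a fixed grid the
    equilibrium generally alternates between the two ISIs bracketing the
    continuous-time interval, so the mean ISI — not any single one — is
    the equilibrium interval.  Returns 0 if no two spikes occur after
    settling.
    """
    if settle_time is None:
        settle_time = max(10.0 * params.tau_w, 500.0)
    duration = settle_time + window
    train = integrate_adex(CurrentTrace.constant(I_const, duration, dt), params)
    tail = train.spike_times[train.spike_times >= settle_time]
    if tail.size < 2:
        return 0.0
    return 1000.0 * (tail.size - 1) / float(tail[-1] - tail[0])
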