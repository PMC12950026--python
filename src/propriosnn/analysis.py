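"""Rate estimation, normalization, evaluation metrics and grid searches.

The decoding metrics mirror how the network is evaluated:

* MAE — mean absolute error between model and reference peak and
  steady-state afferent rates over the ten ramp-and-hold trials,
  MAE = (1/20) * sum_i (|dx_ss_i| + |dx_max_i|), in Hz;
* MSE — mean squared difference between the z-normalized combined
  interneuron rate (plus minus minus) and the z-normalized stimulus,
  averaged over time steps, joints and trials (dimensionless, z-units^2);
* confusion counts — velocity interneurons treated as binary direction
  classifiers: vel_plus spikes during rising / falling joint angle are
  TP / FP, vel_minus spikes during rising / falling are FN / TN, with
  TPR = TP/(TP+FN), TNR = TN/(TN+FP), ACC = (TPR+TNR)/2.

The spike-rate estimator is not part of the model proper; the default
(reciprocal ISI held over each interval) is a convention, with a boxcar
count alternative for smoothed traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .neurons import AdExParams, SpikeTrain, adex_matrix, lif_matrix
from .network import JointEncoderConfig, LayerOutputs, encode_joint
from .stimuli import JointAngleTrace, ramp_battery

__all__ = [
    "RateTrace",
    "ReferenceRates",
    "EvalReport",
    "ConfusionCounts",
    "spike_rate",
    "znorm",
    "combined_signal",
    "mae_fit",
    "mse_traces",
    "lag_shift",
    "velocity_confusion",
    "fit_rate_velocity",
    "ramp_response_rates",
    "grid_search_adex",
    "grid_search_position",
]

#: Angular speeds below this (deg/ms) count as "stationary" and are
#: excluded from direction-classification tallies.
ZERO_VELOCITY_EPS = 1e-6


@dataclass
class RateTrace:
    """Instantaneous-rate time course on the simulation grid (Hz)."""

    t: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.t.shape != self.rate.shape:
            raise ValueError("t and rate must have equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def spike_rate(
    train: SpikeTrain,
    dt: float,
    method: str = "isi_holdover",
    width: float = 50.0,
) -> RateTrace:
    """Estimate an instantaneous-rate time course from a spike train.

    ``isi_holdover`` assigns 1000/ISI (Hz) over each inter-spike
    interval and 0 before the first and after the last spike.
    ``boxcar`` counts spikes in a centred window of ``width`` ms and
    divides by the window length.
    """
    if train.duration <= 0:
        raise ValueError("train duration must be positive")
    n = int(round(train.duration / dt))
    t = (np.arange(n) + 1) * dt
    times = train.spike_times
    if method == "isi_holdover":
        rate = np.zeros(n)
        if times.size >= 2:
            rates = 1000.0 / np.diff(times)
            # sample i falls in interval k when times[k] <= t_i < times[k+1]
            k = np.searchsorted(times, t, side="right") - 1
            valid = (k >= 0) & (k < rates.size)
            rate[valid] = rates[k[valid]]
        return RateTrace(t, rate)
    if method == "boxcar":
        counts = np.zeros(n)
        idx = np.clip(np.rint(times / dt).astype(int) - 1, 0, n - 1)
        np.add.at(counts, idx, 1.0)
        win = max(int(round(width / dt)), 1)
        kernel = np.ones(win)
        smoothed = signal.convolve(counts, kernel, mode="same")
        return RateTrace(t, smoothed / (win * dt / 1000.0))
    raise ValueError("method must be 'isi_holdover' or 'boxcar'")


def znorm(x: np.ndarray) -> np.ndarray:
    """Z-normalize a series to zero mean, unit SD; rejects zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant series")
    return (x - x.mean()) / sd


def combined_signal(plus: RateTrace, minus: RateTrace) -> RateTrace:
    """Z-normalized difference of antagonistic rates, znorm(plus - minus).

    The result is in z-units, not Hz; swapping the inputs flips its sign.
    """
    if plus.t.shape != minus.t.shape or not np.allclose(plus.t, minus.t):
        raise ValueError("rate traces must share the same grid")
    return RateTrace(plus.t, znorm(plus.rate - minus.rate))


# ---------------------------------------------------------------------------
# MAE over the ramp batteries (afferent fitting)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceRates:
    """Steady-state and peak rates (Hz) for the ten reference ramp trials."""

    x_ss: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_ss = np.asarray(self.x_ss, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_ss.shape != self.x_max.shape or self.x_ss.ndim != 1:
            raise ValueError("x_ss and x_max must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return int(self.x_ss.size)

    @classmethod
    def from_csv(cls, path) -> "ReferenceRates":
        df = pd.read_csv(path, comment="#")
        return cls(df["x_ss_hz"].to_numpy(), df["x_max_hz"].to_numpy())

    @classmethod
    def synthetic_reference(cls) -> "ReferenceRates":
        """The bundled synthetic stand-in table (see data/ for caveats)."""
        from importlib.resources import files

        return cls.from_csv(files("propriosnn.data") / "reference_rates_synthetic.csv")


def mae_fit(model: ReferenceRates, reference: ReferenceRates) -> float:
    """Mean absolute error (Hz) between model and reference rate tables."""
    if len(model) != len(reference):
        raise ValueError("model and reference must contain the same trials")
    n = 2 * len(model)
    return float(
        (
            np.abs(model.x_ss - reference.x_ss).sum()
            + np.abs(model.x_max - reference.x_max).sum()
        )
        / n
    )


def ramp_response_rates(
    adex: AdExParams,
    gain: float,
    dt: float = 0.25,
    ss_window: float = 100.0,
    trials: Sequence[JointAngleTrace] | None = None,
) -> ReferenceRates:
    """Run the ten-ramp battery through the afferent and extract rates.

    The peak is the reciprocal of the minimum inter-spike interval; the
    steady state is the mean rate over the trailing ``ss_window`` ms of
    the hold phase (spike count / window).
    """
    trains = _battery_trains(adex, np.array([gain]), None, dt, trials)[0]
    return _rates_from_trains(trains, dt, ss_window)


def _battery_trains(adex, gains, bs, dt, trials=None):
    """Afferent spike trains for each (gain[, b]) cell over the battery.

    Cells are vectorized as a bank of AdEx neurons per trial.  Returns a
    list over cells; each entry is a list of (spike_times, hold_end) per
    trial.
    """
    trials = ramp_battery(dt) if trials is None else trials
    gains = np.asarray(gains, dtype=float)
    n_cells = gains.size
    b_vec = None if bs is None else np.asarray(bs, dtype=float)
    out = [[] for _ in range(n_cells)]
    for trace in trials:
        I = np.outer(gains, trace.theta)
        spikes = adex_matrix(I, adex, dt, b=b_vec)
        # hold phase ends where the down-ramp starts
        hold_value = trace.theta.max()
        at_hold = np.flatnonzero(np.isclose(trace.theta, hold_value))
        hold_end = (at_hold[-1] + 1) * dt
        for c in range(n_cells):
            times = (np.flatnonzero(spikes[c]) + 1) * dt
            out[c].append((times, hold_end))
    return out


def _rates_from_trains(cell_trains, dt, ss_window):
    x_ss, x_max = [], []
    for times, hold_end in cell_trains:
        isis = np.diff(times)
        x_max.append(1000.0 / isis.min() if isis.size else 0.0)
        lo = hold_end - ss_window
        n_in = np.count_nonzero((times > lo) & (times <= hold_end))
        x_ss.append(n_in / (ss_window / 1000.0))
    return ReferenceRates(np.array(x_ss), np.array(x_max))


def grid_search_adex(
    reference: ReferenceRates,
    gain_range: tuple[float, float] = (10.0, 150.0),
    b_range: tuple[float, float] = (50.0, 350.0),
    steps: int = 8,
    adex: AdExParams = AdExParams(),
    dt: float = 0.25,
    ss_window: float = 100.0,
    tie_break: str = "lexicographic",
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[tuple[float, float]], tuple[float, float]]:
    """MAE surface over the (gain, b) grid of the afferent fit.

    Returns (surface, argmin_cells, selected) where ``surface`` is a
    DataFrame indexed by gain with one column per b value, ``argmin_cells``
    lists every cell attaining the minimum, and ``selected`` is one of
    them — the lexicographically smallest by default, or a seeded random
    choice with ``tie_break='random'`` (mirroring a random pick among
    equivalent optima).
    """
    gains = np.linspace(*gain_range, steps)
    bs = np.linspace(*b_range, steps)
    gain_grid, b_grid = [a.ravel() for a in np.meshgrid(gains, bs, indexing="ij")]
    cells = _battery_trains(adex, gain_grid, b_grid, dt)
    mae = np.array(
        [mae_fit(_rates_from_trains(tr, dt, ss_window), reference) for tr in cells]
    ).reshape(steps, steps)
    surface = pd.DataFrame(mae, index=gains, columns=bs)
    surface.index.name = "gain_pA_per_deg"
    surface.columns.name = "b_pA"
    flat_min = mae.min()
    argmin = [
        (float(gains[i]), float(bs[j]))
        for i, j in zip(*np.nonzero(np.isclose(mae, flat_min)))
    ]
    if tie_break == "random":
        rng = np.random.default_rng(seed)
        selected = argmin[int(rng.integers(len(argmin)))]
    else:
        selected = sorted(argmin)[0]
    return surface, argmin, selected


# ---------------------------------------------------------------------------
# MSE over decoded time courses
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Decoding-quality summary for a set of encoded trials."""

    mse: float
    per_group: pd.DataFrame | None = None
    lag_applied: float = 0.0  # s
    mae: float | None = None  # Hz (afferent fit, if computed)
    slope: float | None = None  # Hz per (deg/s)
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")


def mse_traces(
    model: Sequence[np.ndarray] | np.ndarray,
    reference: Sequence[np.ndarray] | np.ndarray,
    grouping: Sequence[tuple[str, str]] | None = None,
) -> EvalReport:
    """Mean squared difference between z-scale series, pooled over trials.

    ``model`` and ``reference`` are matching (lists of) z-normalized
    series; every sample of every series carries equal weight, i.e. the
    squared differences are averaged over time steps, joints and trials
    together.  With ``grouping`` (one (leg, joint) label per series) a
    per-group table of per-series MSE means and SDs is included for
    factor-level aggregation.
    """
    if isinstance(model, np.ndarray) and model.ndim == 1:
        model, reference = [model], [reference]  # type: ignore[list-item]
    if len(model) != len(reference):
        raise ValueError("model and reference must contain the same series")
    sq_sum = 0.0
    n_tot = 0
    per_series = []
    for m, r in zip(model, reference):
        m = np.asarray(m, dtype=float)
        r = np.asarray(r, dtype=float)
        if m.shape != r.shape:
            raise ValueError("model/reference series lengths differ")
        d2 = (m - r) ** 2
        sq_sum += d2.sum()
        n_tot += d2.size
        per_series.append(d2.mean())
    report = EvalReport(mse=sq_sum / n_tot)
    if grouping is not None:
        df = pd.DataFrame(
            {
                "leg": [g[0] for g in grouping],
                "joint": [g[1] for g in grouping],
                "mse": per_series,
            }
        )
        report.per_group = (
            df.groupby(["leg", "joint"])["mse"].agg(["mean", "std", "count"]).reset_index()
        )
    return report


def lag_shift(trace: RateTrace, dt_shift: float) -> RateTrace:
    """Advance a rate trace by ``dt_shift`` seconds to undo a decoding lag.

    A positive shift moves the trace earlier in time (sample i takes the
    value of sample i+k); the ``k`` samples lost at the edge are trimmed
    from both t and rate, so compare against a reference trimmed to the
    same overlap.  |dt_shift| must be shorter than the trace.
    """
    k = int(round(dt_shift * 1000.0 / trace.dt))
    n = trace.rate.size
    if abs(k) >= n:
        raise ValueError("shift exceeds trace duration")
    if k == 0:
        return RateTrace(trace.t.copy(), trace.rate.copy())
    if k > 0:
        return RateTrace(trace.t[:-k], trace.rate[k:])
    return RateTrace(trace.t[-k:], trace.rate[:k])


def angular_velocity(
    trace: JointAngleTrace, lowpass_hz: float | None = 10.0
) -> np.ndarray:
    """Ground-truth dtheta/dt (deg/ms) by central finite difference.

    Optionally low-pass filtered (zero-phase Butterworth) to suppress
    sample-level jitter before sign classification.
    """
    v = np.gradient(trace.theta, trace.dt)
    if lowpass_hz is not None:
        nyq = 1000.0 / trace.dt / 2.0
        sos = signal.butter(2, lowpass_hz / nyq, output="sos")
        v = signal.sosfiltfilt(sos, v)
    return v


@dataclass
class ConfusionCounts:
    """Direction-classifier tallies for the velocity interneurons."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def TPR(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else float("nan")

    @property
    def TNR(self) -> float:
        d = self.TN + self.FP
        return self.TN / d if d else float("nan")

    @property
    def ACC(self) -> float:
        return (self.TPR + self.TNR) / 2.0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
        )


def velocity_confusion(
    vel_plus: SpikeTrain,
    vel_minus: SpikeTrain,
    theta: JointAngleTrace,
    lowpass_hz: float | None = 10.0,
    zero_eps: float = ZERO_VELOCITY_EPS,
) -> ConfusionCounts:
    """Tally velocity-IN spikes against the sign of the true velocity.

    Each spike is classified by the sign of dtheta/dt at its time:
    vel_plus spikes during rising angle are TP, during falling FP;
    vel_minus spikes during rising are FN, during falling TN.  Spikes at
    samples with |dtheta/dt| < ``zero_eps`` deg/ms are excluded (the
    direction is undefined there).
    """
    v = angular_velocity(theta, lowpass_hz)

    def signs_at(train: SpikeTrain) -> np.ndarray:
        idx = np.clip(
            np.rint(train.spike_times / theta.dt).astype(int) - 1, 0, v.size - 1
        )
        vv = v[idx]
        return vv[np.abs(vv) >= zero_eps]

    vp = signs_at(vel_plus)
    vm = signs_at(vel_minus)
    return ConfusionCounts(
        TP=int(np.count_nonzero(vp > 0)),
        FP=int(np.count_nonzero(vp < 0)),
        FN=int(np.count_nonzero(vm > 0)),
        TN=int(np.count_nonzero(vm < 0)),
    )


def fit_rate_velocity(
    speeds: Sequence[float], rates: Sequence[float]
) -> tuple[float, float]:
    """OLS fit of mean interneuron rate (Hz) on sweep speed (deg/s).

    Returns (slope, r_squared); the slope has units Hz/(deg/s) = 1/deg,
    i.e. spikes emitted per degree traversed.
    """
    speeds = np.asarray(speeds, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if speeds.size < 3:
        raise ValueError("need at least 3 speeds for a regression")
    res = stats.linregress(speeds, rates)
    return float(res.slope), float(res.rvalue**2)


def velocity_rate_curve(
    cfg: JointEncoderConfig,
    speeds: Sequence[float] = (50, 100, 150, 200, 250, 300, 350, 400),
    angle_range: tuple[float, float] = (0.0, 180.0),
    reps: int = 1,
    settle_ms: float = 500.0,
    central_frac: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean velocity-IN output rate at each constant sweep speed.

    Runs one triangular sweep per speed through the full encoder and
    counts, for each interneuron, the spikes falling in the central
    ``central_frac`` of every phase of its preferred direction, divided
    by that window's duration.  The central window measures the
    steady-crossing regime: it excludes the carryover burst after each
    reversal (a documented artefact of residual afferent adaptation) and
    the working-range edges where the extended fields saturate.  Returns
    (speeds, rates) in (deg/s, Hz).
    """
    from .stimuli import constant_velocity_sweep

    speeds = np.asarray(speeds, dtype=float)
    rates = []
    traces = constant_velocity_sweep(speeds, angle_range, reps, cfg.dt, settle_ms)
    span = angle_range[1] - angle_range[0]
    for v, trace in zip(speeds, traces):
        out = encode_joint(trace, cfg)
        half = span / v * 1000.0
        n_spikes = 0
        window_s = 0.0
        for phase, train in enumerate((out.vel_plus, out.vel_minus)):
            for rep in range(reps):
                t0 = settle_ms + (2 * rep + phase) * half
                a = t0 + (1.0 - central_frac) / 2.0 * half
                b = t0 + (1.0 + central_frac) / 2.0 * half
                n_spikes += int(
                    np.count_nonzero(
                        (train.spike_times >= a) & (train.spike_times < b)
                    )
                )
                window_s += (b - a) / 1000.0
        # combined preferred-phase spikes over combined preferred-phase time
        # = the average per-IN rate while the joint moves in its direction
        rates.append(n_spikes / window_s)
    return speeds, np.asarray(rates)


# ---------------------------------------------------------------------------
# position-IN (tau, omega) sweep
# ---------------------------------------------------------------------------

def grid_search_position(
    tau_range: Sequence[float],
    omega_range: Sequence[float],
    traces: Sequence[JointAngleTrace],
    cfg_builder=None,
    rate_method: str = "isi_holdover",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """MSE surface of the position decoder over (tau, omega) cells.

    For each trace the afferent layer is simulated once; every grid cell
    then re-runs only the two position LIFs (vectorized as one bank per
    field with per-neuron tau), decodes the combined z-normalized rate
    and accumulates the squared error against the z-normalized joint
    angle.  Returns the surface (indexed by tau, columns omega) and the
    argmin cell (lexicographically smallest on ties).
    """
    from .network import config_for_trace

    taus = np.asarray(tau_range, dtype=float)
    omegas = np.asarray(omega_range, dtype=float)
    tau_grid, om_grid = [a.ravel() for a in np.meshgrid(taus, omegas, indexing="ij")]
    n_cells = tau_grid.size
    sq = np.zeros(n_cells)
    n_samples = 0
    for trace in traces:
        cfg = cfg_builder(trace) if cfg_builder else config_for_trace(trace)
        from .network import _sensory_matrix

        spikes = _sensory_matrix(trace, cfg)
        n_neg = cfg.plate.field_neg.N_h
        counts_pos = spikes[n_neg:][cfg.plate.position_mask_pos].sum(axis=0)
        counts_neg = spikes[:n_neg][cfg.plate.position_mask_neg].sum(axis=0)
        ref = znorm(trace.theta)
        for side, counts in (("plus", counts_pos), ("minus", counts_neg)):
            w_in = om_grid[:, None] * counts[None, :]
            out = lif_matrix(w_in, cfg.pos_lif, cfg.dt, tau=tau_grid)
            if side == "plus":
                plus_rates = out
            else:
                minus_rates = out
        for c in range(n_cells):
            tr_p = SpikeTrain(
                (np.flatnonzero(plus_rates[c]) + 1) * cfg.dt, trace.theta.size * cfg.dt
            )
            tr_m = SpikeTrain(
                (np.flatnonzero(minus_rates[c]) + 1) * cfg.dt, trace.theta.size * cfg.dt
            )
            rp = spike_rate(tr_p, cfg.dt, rate_method).rate
            rm = spike_rate(tr_m, cfg.dt, rate_method).rate
            diff = rp - rm
            sd = diff.std()
            if sd == 0:
                sq[c] += np.sum(ref**2)  # silent decoder: compare against a flat z-line
            else:
                sq[c] += np.sum(((diff - diff.mean()) / sd - ref) ** 2)
        n_samples += trace.theta.size
    mse = (sq / n_samples).reshape(taus.size, omegas.size)
    surface = pd.DataFrame(mse, index=taus, columns=omegas)
    surface.index.name = "tau_ms"
    surface.columns.name = "omega_mV"
    i, j = np.unravel_index(int(np.argmin(mse)), mse.shape)
    return surface, (float(taus[i]), float(omegas[j]))


# ---------------------------------------------------------------------------
# end-to-end evaluation of encoded outputs
# ---------------------------------------------------------------------------

def evaluate_position(
    outputs: LayerOutputs,
    trace: JointAngleTrace,
    rate_method: str = "isi_holdover",
) -> tuple[np.ndarray, np.ndarray]:
    """(decoded, reference) z-series for position decoding of one joint."""
    dt = trace.dt
    rp = spike_rate(outputs.pos_plus, dt, rate_method)
    rm = spike_rate(outputs.pos_minus, dt, rate_method)
    decoded = combined_signal(rp, rm).rate
    return decoded, znorm(trace.theta)


def evaluate_velocity(
    outputs: LayerOutputs,
    trace: JointAngleTrace,
    lag_s: float = 0.0,
    rate_method: str = "isi_holdover",
    lowpass_hz: float | None = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(decoded, reference) z-series for velocity decoding of one joint.

    The decoded series is the z-normalized vel_plus - vel_minus rate,
    optionally advanced by ``lag_s`` seconds to undo the phasic-peak
    lag; the reference is the z-normalized true angular velocity,
    trimmed to the same overlap.
    """
    dt = trace.dt
    rp = spike_rate(outputs.vel_plus, dt, rate_method)
    rm = spike_rate(outputs.vel_minus, dt, rate_method)
    combined = combined_signal(rp, rm)
    shifted = lag_shift(combined, lag_s)
    v = angular_velocity(trace, lowpass_hz)
    k = int(round(lag_s * 1000.0 / dt))
    if k > 0:
        v_ref = v[:-k]
    elif k < 0:
        v_ref = v[-k:]
    else:
        v_ref = v
    return shifted.rate, znorm(v_ref)
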